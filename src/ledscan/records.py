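"""Shared domain records.

Physical coordinates are nanometers with ``x = col * scale_nm_per_px`` and
``y = row * scale_nm_per_px`` measured at pixel centers (0-based indices).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class ParticleRecord:
    """One detected (or ground-truth) colloidal gold bead.

    ``equivalent_diameter_nm`` is the diameter of the circle whose area equals
    the estimated pre-blur bead footprint; ``size_class`` is one of
    ``"6nm"`` / ``"10nm"``.
    """

    id: int
    centroid_nm: tuple[float, float]  # (x, y)
    equivalent_diameter_nm: float
    circularity: float
    mean_core_intensity: float
    size_class: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.circularity <= 1.1):
            raise ValueError(f"circularity out of range: {self.circularity}")
        if self.equivalent_diameter_nm <= 0:
            raise ValueError("equivalent_diameter_nm must be positive")


@dataclass
class LEDDRegion:
    """One segmented low electron density domain (LEDD).

    ``boundary`` is a closed polygon in (row, col) pixel coordinates traced by
    marching squares at the 0.5 level of the binary mask; ``area_um2`` is the
    pixel count scaled by the calibration squared.
    """

    id: int
    boundary: np.ndarray  # (N, 2) float, (row, col), closed
    area_um2: float
    centroid_nm: tuple[float, float]  # (x, y)
    mask: Optional[np.ndarray] = None  # full-frame boolean, optional

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise ValueError("boundary must be an (N, 2) array of (row, col)")
        if self.area_um2 <= 0:
            raise ValueError("area_um2 must be positive")


@dataclass
class AnnotationSet:
    """Serialized analysis output for one micrograph: particles, LEDDs, provenance.

    ``spatial`` optionally carries the per-particle spatial assignment columns
    (zone, band, chromatin, cluster_id) keyed by particle id.
    """

    particles: list[ParticleRecord] = field(default_factory=list)
    ledds: list[LEDDRegion] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    spatial: Optional["object"] = None  # pandas.DataFrame keyed by particle id
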