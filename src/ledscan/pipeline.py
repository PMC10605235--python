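"""End-to-end pipeline: preprocess → detect → chromatin/LEDD → spatial → summarize.

A :class:`RunConfig` fully determines a run; the effective configuration is
written next to the outputs together with a per-stage log, so every number in
the summary tables is reproducible from the config and seed alone.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .annotations import write_annotations
from .chromatin import classify_chromatin, segment_ledds
from .detection import DetectionParams, detect_particles
from .errors import ProcessingError, ValidationError
from .micrograph import (
    Micrograph,
    adjust_brightness_contrast,
    read_micrograph,
    write_micrograph,
)
from .records import AnnotationSet
from .spatial import build_partition, build_spatial_table, summarize_sections


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    out_dir: str = "ledscan_run"
    inputs: tuple[str, ...] = ()
    scale_nm_per_px: Optional[float] = None
    simulate: Optional[synthetic.SceneSpec] = None
    n_sections: int = 1
    brightness_pct: float = 50.0
    contrast_pct: float = 80.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    smoothing_scale_nm: float = 30.0
    min_ledd_area_um2: float = 0.05
    closing_radius_nm: float = 50.0
    border_halfwidth_nm: float = 300.0
    band_edges_nm: tuple[float, ...] = (1, 100, 200, 300, 400)
    linkage_nm: float = 50.0
    min_cluster_size: int = 3
    seed: int = 0
    condition: Optional[str] = None
    time_point: Optional[str] = None

    def validate(self) -> None:
        if self.simulate is None:
            if not self.inputs:
                raise ValidationError("config requires 'inputs' or a 'simulate' block")
            if self.scale_nm_per_px is None or self.scale_nm_per_px <= 0:
                raise ValidationError("missing or invalid field: scale_nm_per_px")
        if self.n_sections < 1:
            raise ValidationError("n_sections must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "detection" in raw and isinstance(raw["detection"], dict):
            det = dict(raw["detection"])
            if "nominal_diameters_nm" in det:
                det["nominal_diameters_nm"] = tuple(det["nominal_diameters_nm"])
            raw["detection"] = DetectionParams(**det)
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            for key, typ in (("gray", synthetic.GrayLevels),
                             ("ledd", synthetic.LeddSpec),
                             ("particles", synthetic.ParticleSpec)):
                if key in sim and isinstance(sim[key], dict):
                    sub = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in sim[key].items()
                    }
                    sim[key] = typ(**sub)
            if "image_shape" in sim:
                sim["image_shape"] = tuple(sim["image_shape"])
            raw["simulate"] = synthetic.SceneSpec(**sim)
        for key in ("inputs", "band_edges_nm"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def particle_pixel_mask(particles, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Boolean stamp of detected beads (disc of the measured diameter + 1 px)."""
    mask = np.zeros(shape, dtype=bool)
    for p in particles:
        x, y = p.centroid_nm
        r = p.equivalent_diameter_nm / 2 / scale + 1
        r0, r1 = int(np.floor(y / scale - r)), int(np.ceil(y / scale + r)) + 1
        c0, c1 = int(np.floor(x / scale - r)), int(np.ceil(x / scale + r)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, shape[0]), min(c1, shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= np.hypot(yy - y / scale, xx - x / scale) <= r
    return mask


def analyze_micrograph(img: Micrograph, config: RunConfig, section_id: int = 0):
    """Run every analysis stage on one preprocessed-ready micrograph.

    Returns (particles, cmap, ledds, partition, table, stage_log).
    """
    log: dict[str, float] = {}
    pre = adjust_brightness_contrast(img, config.brightness_pct, config.contrast_pct)
    particles = detect_particles(pre, config.detection)
    log["detected"] = len(particles)
    pmask = particle_pixel_mask(particles, pre.shape, pre.scale_nm_per_px)
    cmap = classify_chromatin(pre, particle_mask=pmask,
                              smoothing_scale_nm=config.smoothing_scale_nm)
    ledds = segment_ledds(cmap, pre, min_area_um2=config.min_ledd_area_um2,
                          closing_radius_nm=config.closing_radius_nm)
    log["ledds"] = len(ledds)
    partition = build_partition(
        ledds, pre.shape, pre.scale_nm_per_px,
        analysis_mask=pre.analysis_mask(),
        border_halfwidth_nm=config.border_halfwidth_nm,
        band_edges_nm=config.band_edges_nm,
    )
    table = build_spatial_table(
        particles, partition, cmap,
        linkage_nm=config.linkage_nm, min_cluster_size=config.min_cluster_size,
        section_id=section_id, condition=config.condition, time_point=config.time_point,
    )
    log["dropped_excluded"] = table.particles.attrs.get("n_dropped_excluded", 0)
    log["clusters"] = len(table.clusters)
    return particles, cmap, ledds, partition, table, log


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts under ``config.out_dir``.

    Outputs per section: 16-bit TIFF (simulated inputs only), particle CSV and
    LEDD JSON annotations; plus one summary CSV, the effective config and a
    per-stage log. Deterministic for a fixed config and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    sections: list[tuple[str, Micrograph]] = []
    if config.simulate is not None:
        spec = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = synthetic.generate_dataset(config.n_sections, spec,
                                             condition=config.condition)
        for i, (img, truth) in enumerate(dataset):
            name = f"section_{i:03d}"
            write_micrograph(img, out / f"{name}.tif")
            truth.particles.to_csv(out / f"{name}.truth.csv", index=False,
                                   float_format="%.3f")
            sections.append((name, img))
    else:
        for path in config.inputs:
            img = read_micrograph(path, config.scale_nm_per_px)
            sections.append((Path(path).stem, img))

    tables = []
    for i, (name, img) in enumerate(sections):
        try:
            particles, cmap, ledds, partition, table, stage_log = analyze_micrograph(
                img, config, section_id=i
            )
        except Exception as exc:
            raise ProcessingError(f"stage failure on {name}: {exc}") from exc
        ann = AnnotationSet(
            particles=particles,
            ledds=ledds,
            provenance={
                "source": name,
                "scale_nm_per_px": img.scale_nm_per_px,
                "image_shape_px": list(img.shape),
                "seed": config.seed,
            },
            spatial=table.particles,
        )
        write_annotations(ann, out / f"{name}.annotations.json")
        tables.append(table)
        log_lines.append(
            f"{name}: " + ", ".join(f"{k}={int(v)}" for k, v in stage_log.items())
        )

    summary = summarize_sections(tables)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def render_overlay(img: Micrograph, particles, ledds, partition=None) -> np.ndarray:
    """Cosmetic RGB overlay: LEDD boundaries, zone shading, class-colored markers.

    Never consumed by analysis. Returns a uint8 (H, W, 3) raster.
    """
    from skimage.draw import circle_perimeter

    base = img.pixels
    lo, hi = np.quantile(base, [0.01, 0.99])
    stretched = np.clip((base - lo) / max(hi - lo, 1e-9), 0, 1)
    rgb = np.repeat((stretched[..., None] * 255).astype(np.uint8), 3, axis=2)

    if partition is not None and not partition.no_ledds:
        border = partition.zone_labels == 2
        rgb[border] = (0.8 * rgb[border] + 0.2 * np.array([80, 160, 255])).astype(np.uint8)
    for r in ledds:
        b = np.round(r.boundary).astype(int)
        b[:, 0] = np.clip(b[:, 0], 0, rgb.shape[0] - 1)
        b[:, 1] = np.clip(b[:, 1], 0, rgb.shape[1] - 1)
        rgb[b[:, 0], b[:, 1]] = (255, 60, 60)
    colors = {"6nm": (0, 220, 220), "10nm": (255, 220, 0)}
    scale = img.scale_nm_per_px
    for p in particles:
        x, y = p.centroid_nm
        rr, cc = circle_perimeter(
            int(round(y / scale)), int(round(x / scale)),
            max(3, int(round(p.equivalent_diameter_nm / scale))),
            shape=rgb.shape[:2],
        )
        rgb[rr, cc] = colors.get(p.size_class, (255, 255, 255))
    return rgb
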