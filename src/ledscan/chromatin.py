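"""Grayscale chromatin classification and LEDD segmentation.

Uranyl acetate stains condensed heterochromatin darker than open euchromatin,
and the electron-lucent LEDDs along heavy-ion tracks are brighter than both.
A single three-class grayscale model therefore covers the whole section:
bead pixels are in-filled with a local median (so the dense gold does not
bias the chromatin histogram), the image is median-smoothed at the chromatin
texture scale, and two cut points are chosen by maximal between-class
variance (multi-Otsu). Classes are assigned by intensity order:
dark → heterochromatin, mid → euchromatin, bright → LEDD.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import rank, threshold_multiotsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.morphology import disk

from .errors import SegmentationError, ValidationError
from .micrograph import Micrograph
from .records import LEDDRegion

LABEL_EXCLUDED = 0
LABEL_HETEROCHROMATIN = 1
LABEL_EUCHROMATIN = 2
LABEL_LEDD = 3

LABEL_NAMES = {
    LABEL_EXCLUDED: "excluded",
    LABEL_HETEROCHROMATIN: "heterochromatin",
    LABEL_EUCHROMATIN: "euchromatin",
    LABEL_LEDD: "ledd",
}


@dataclass
class ChromatinMap:
    """Per-pixel chromatin labels plus the thresholds that produced them.

    ``labels`` uses the module-level codes (0 excluded, 1 heterochromatin,
    2 euchromatin, 3 LEDD); ``thresholds_used`` are the two grayscale cut
    points on the [0, 1] intensity scale.
    """

    labels: np.ndarray
    thresholds_used: tuple[float, float]
    smoothing_scale_nm: float
    scale_nm_per_px: float

    def class_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def area_fraction(self, code: int) -> float:
        """Fraction of non-excluded pixels carrying the given label."""
        valid = self.labels != LABEL_EXCLUDED
        if not valid.any():
            return float("nan")
        return float((self.labels[valid] == code).mean())


def classify_chromatin(
    img: Micrograph,
    particle_mask: Optional[np.ndarray] = None,
    smoothing_scale_nm: float = 30.0,
    fill_radius_nm: float = 15.0,
    min_class_separation_ratio: float = 0.5,
) -> ChromatinMap:
    """Three-class grayscale segmentation of a calibrated micrograph.

    ``particle_mask`` marks bead pixels; they are replaced by the local median
    before smoothing so gold does not masquerade as heterochromatin. Raises
    :class:`SegmentationError` when the image has no three-level structure
    (e.g. a uniform frame).

    Unirradiated sections have no electron-lucent phase, yet a three-class
    threshold will still split the euchromatin noise in two; a bright class
    whose separation from the middle class is below
    ``min_class_separation_ratio`` times the heterochromatin–euchromatin gap
    is therefore merged back into euchromatin (and symmetrically for a
    spurious dark class), so such sections legitimately carry no LEDD label.
    """
    scale = img.scale_nm_per_px
    mask = img.analysis_mask()
    work = img.pixels.copy()

    u8 = np.round(np.clip(work, 0, 1) * 255).astype(np.uint8)
    if particle_mask is not None and particle_mask.any():
        pm = ndimage.binary_dilation(particle_mask, iterations=2)
        fill_r = max(2, int(round(fill_radius_nm / scale)))
        filled = rank.median(u8, footprint=disk(fill_r), mask=~pm)
        u8 = np.where(pm, filled, u8)

    smooth_r = max(1, int(round(smoothing_scale_nm / scale / 2)))
    smoothed = rank.median(u8, footprint=disk(smooth_r))

    values = smoothed[mask]
    if values.size == 0:
        raise SegmentationError("empty analysis mask")
    if np.unique(values).size < 3:
        raise SegmentationError("image lacks three-class grayscale structure")
    try:
        t1, t2 = threshold_multiotsu(values, classes=3)
    except ValueError as exc:
        raise SegmentationError(f"three-class thresholding failed: {exc}") from exc
    if t1 == t2:
        raise SegmentationError("degenerate thresholds; no three-class structure")

    labels = np.full(img.pixels.shape, LABEL_EXCLUDED, dtype=np.uint8)
    labels[mask & (smoothed <= t1)] = LABEL_HETEROCHROMATIN
    labels[mask & (smoothed > t1) & (smoothed <= t2)] = LABEL_EUCHROMATIN
    labels[mask & (smoothed > t2)] = LABEL_LEDD

    counts = [(labels == code).sum()
              for code in (LABEL_HETEROCHROMATIN, LABEL_EUCHROMATIN, LABEL_LEDD)]
    total = sum(counts)
    if total and counts[1] / total < 0.10:
        # a vanishing middle class means the histogram is really bimodal: the
        # "middle" is just the het→eu boundary ramp of a section without any
        # electron-lucent phase (unirradiated control); keep het vs eu only
        labels[labels == LABEL_EUCHROMATIN] = LABEL_EUCHROMATIN
        labels[labels == LABEL_LEDD] = LABEL_EUCHROMATIN
    else:
        means = []
        for code in (LABEL_HETEROCHROMATIN, LABEL_EUCHROMATIN, LABEL_LEDD):
            sel = labels == code
            means.append(float(smoothed[sel].mean()) if sel.any() else np.nan)
        if all(np.isfinite(means)):
            gap_dark, gap_bright = means[1] - means[0], means[2] - means[1]
            if gap_bright < min_class_separation_ratio * gap_dark:
                labels[labels == LABEL_LEDD] = LABEL_EUCHROMATIN
            elif gap_dark < min_class_separation_ratio * gap_bright:
                labels[labels == LABEL_HETEROCHROMATIN] = LABEL_EUCHROMATIN

    return ChromatinMap(
        labels=labels,
        thresholds_used=(float(t1) / 255.0, float(t2) / 255.0),
        smoothing_scale_nm=float(smoothing_scale_nm),
        scale_nm_per_px=scale,
    )


def segment_ledds(
    cmap: ChromatinMap,
    img: Micrograph,
    min_area_um2: float = 0.05,
    closing_radius_nm: float = 50.0,
) -> list[LEDDRegion]:
    """Segment LEDDs from the bright chromatin class.

    LEDD-labeled pixels undergo morphological closing (Euclidean disk of
    ``closing_radius_nm``), hole filling and connected-component analysis;
    components below ``min_area_um2`` are discarded. Regions are sorted by
    area descending with ids assigned in that order. An empty result is valid
    (unirradiated sections have no LEDD).
    """
    scale = img.scale_nm_per_px
    binary = cmap.class_mask(LABEL_LEDD)
    r_px = closing_radius_nm / scale
    if binary.any() and r_px > 0:
        dilated = ndimage.distance_transform_edt(~binary) <= r_px
        binary = dilated & (ndimage.distance_transform_edt(dilated) > r_px)
    binary = ndimage.binary_fill_holes(binary)

    comp = cc_label(binary, connectivity=2)
    regions: list[LEDDRegion] = []
    for rp in regionprops(comp):
        area_um2 = rp.area * scale**2 * 1e-6
        if area_um2 < min_area_um2:
            continue
        full = comp == rp.label
        padded = np.pad(full.astype(float), 1)
        contours = find_contours(padded, 0.5)
        boundary = max(contours, key=len) - 1.0
        cr, cc_ = rp.centroid
        regions.append(LEDDRegion(
            id=-1,
            boundary=boundary,
            area_um2=float(area_um2),
            centroid_nm=(cc_ * scale, cr * scale),
            mask=full,
        ))
    regions.sort(key=lambda r: -r.area_um2)
    for i, r in enumerate(regions):
        r.id = i
    return regions


def ledd_area_summary(
    groups: Mapping[str, Sequence[Sequence]],
) -> pd.DataFrame:
    """Per-group LEDD area statistics across sections.

    ``groups`` maps a group label (e.g. time point) to a list of sections,
    each section being a list of :class:`LEDDRegion` (or bare areas in µm²).
    Returns one row per group with the mean of per-section mean areas, the
    standard error over sections (sd/√n; NaN when n < 2 or no LEDD), and the
    total region count. Empty groups yield a flagged missing row rather than
    an exception.
    """
    rows = []
    for name, sections in groups.items():
        section_means = []
        total = 0
        for sec in sections:
            areas = [r.area_um2 if isinstance(r, LEDDRegion) else float(r) for r in sec]
            total += len(areas)
            if areas:
                section_means.append(float(np.mean(areas)))
        n = len(section_means)
        mean = float(np.mean(section_means)) if n else float("nan")
        se = float(np.std(section_means, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append({
            "group": name,
            "n_sections": len(sections),
            "n_ledds": total,
            "mean_area_um2": mean,
            "se_area_um2": se,
            "missing": n == 0,
        })
    return pd.DataFrame(rows).set_index("group")
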