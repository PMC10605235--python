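"""Gold nanoparticle detection and 6-vs-10-nm size classification.

Beads are the only small, circular, strongly electron-dense objects in the
section, so detection works on the residual of a grayscale closing (a
rolling-ball background estimate for dark features): the residual is ~0
everywhere except in dark valleys narrower than the structuring element,
which equalizes bead contrast across heterochromatin, euchromatin and bright
LEDD backgrounds and makes the subsequent quantile threshold exactly
invariant to additive intensity shifts. Touching beads are split by
watershed on the distance transform. Sizes are estimated from the half-depth
area of the residual profile with a disc⊗Gaussian calibration, so the
reported equivalent diameter approximates the pre-blur bead footprint.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .errors import ValidationError
from .micrograph import Micrograph
from .records import ParticleRecord


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the threshold→split→filter detector.

    All geometric parameters are in nanometers and converted to pixels with
    the micrograph calibration. The two class windows
    ``nominal*(1±size_tolerance)`` may overlap partially but neither may
    contain the other.
    """

    intensity_quantile: float = 0.02
    size_tolerance: float = 0.40
    min_circularity: float = 0.60
    split_min_distance_nm: float = 5.0
    nominal_diameters_nm: tuple[float, float] = (6.0, 10.0)
    core_contrast_min: float = 0.10
    background_radius_nm: float = 20.0
    psf_sigma_nm: float = 2.0
    # gold is far denser (darker) than any chromatin: the object core must be
    # darker than the heterochromatin reference level (5% quantile of the
    # smoothed image) by at least this margin
    density_margin: float = 0.05
    dark_ref_quantile: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.intensity_quantile < 1):
            raise ValidationError("intensity_quantile must lie in (0, 1)")
        if not (0 < self.size_tolerance < 1):
            raise ValidationError("size_tolerance must lie in (0, 1)")
        d_lo, d_hi = sorted(self.nominal_diameters_nm)
        lo_win = (d_lo * (1 - self.size_tolerance), d_lo * (1 + self.size_tolerance))
        hi_win = (d_hi * (1 - self.size_tolerance), d_hi * (1 + self.size_tolerance))
        if lo_win[0] >= hi_win[0] or lo_win[1] >= hi_win[1]:
            raise ValidationError("size-class windows must not contain one another")

    def window(self, nominal: float) -> tuple[float, float]:
        return (nominal * (1 - self.size_tolerance), nominal * (1 + self.size_tolerance))


def classify_size(
    equivalent_diameter_nm: float,
    nominal_diameters_nm: tuple[float, float] = (6.0, 10.0),
    size_tolerance: float = 0.40,
) -> str | None:
    """Assign the size class minimizing relative deviation |d - nominal| / nominal.

    Returns ``None`` (rejection, not an error) when the diameter falls outside
    every class window.
    """
    candidates = [
        n for n in nominal_diameters_nm
        if n * (1 - size_tolerance) <= equivalent_diameter_nm <= n * (1 + size_tolerance)
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda n: abs(equivalent_diameter_nm - n) / n)
    return f"{best:g}nm"


def _closing_residual(pixels: np.ndarray, radius_px: int) -> np.ndarray:
    """image - grayscale closing (separable square structuring element).

    The closing fills dark valleys narrower than the element, so the residual
    is <= 0 and strongly negative exactly at bead-scale dark spots.
    """
    size = 2 * radius_px + 1
    bg = ndimage.minimum_filter(ndimage.maximum_filter(pixels, size=size), size=size)
    return pixels - bg


@lru_cache(maxsize=32)
def _half_depth_calibration(sigma_px_tenths: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Map half-depth radius -> true disc radius for a disc blurred by a Gaussian.

    Computed by rendering radial profiles of unit-depth discs at a grid of
    true radii; cached per rounded PSF sigma (tenths of a pixel).
    """
    sigma = sigma_px_tenths / 10.0
    radii = np.linspace(0.8, 14.0, 200)
    half = []
    n = 41
    ax = np.arange(-n, n + 1)
    yy, xx = np.meshgrid(ax, ax)
    dist = np.hypot(yy, xx)
    for r in radii:
        cov = np.clip(r - dist + 0.5, 0.0, 1.0)
        blurred = ndimage.gaussian_filter(cov, sigma=sigma) if sigma > 0 else cov
        peak = blurred[n, n]
        # area at half the center depth -> equivalent half-depth radius
        area = float((blurred >= peak / 2).sum())
        half.append(np.sqrt(area / np.pi))
    return tuple(half), tuple(radii)


def _corrected_radius_px(r_half_px: float, sigma_px: float) -> float:
    """Invert the half-depth calibration (linear interpolation, clipped)."""
    half, radii = _half_depth_calibration(int(round(max(sigma_px, 0.0) * 10)))
    return float(np.interp(r_half_px, half, radii))


def detect_particles(img: Micrograph, params: DetectionParams | None = None) -> list[ParticleRecord]:
    """Detect gold beads in a preprocessed, calibrated micrograph.

    Pipeline: (1) dark-object thresholding at ``intensity_quantile`` of the
    in-mask closing residual; (2) 8-connected components; (3) watershed
    splitting of merged components with markers separated by at least
    ``split_min_distance_nm``; (4) filters on size window, circularity and
    core-vs-local-background contrast; (5) per-object measurement and size
    classification. Records are sorted in raster order of their centroids and
    ids assigned in that order; particles whose centroid is excluded are
    dropped.
    """
    if params is None:
        params = DetectionParams()
    scale = img.scale_nm_per_px
    pixels = img.pixels
    mask = img.analysis_mask()
    if not mask.any():
        return []

    r_bg = max(2, int(round(params.background_radius_nm / scale)))
    resid = _closing_residual(pixels, r_bg)

    thr = float(np.quantile(resid[mask], params.intensity_quantile))
    binary = (resid < thr) & mask  # strict < : flat regions at the quantile stay out
    if not binary.any():
        return []

    d_lo, d_hi = sorted(params.nominal_diameters_nm)
    win_lo = params.window(d_lo)
    win_hi = params.window(d_hi)
    amin_px = np.pi * (win_lo[0] / 2 / scale) ** 2
    amax_px = np.pi * (win_hi[1] / 2 / scale) ** 2

    # drop specks well below the smallest acceptable bead before splitting
    comp = cc_label(binary, connectivity=2)
    sizes = np.bincount(comp.ravel())
    keep = sizes >= max(2, int(amin_px * 0.3))
    keep[0] = False
    binary = keep[comp]
    if not binary.any():
        return []

    # watershed split of touching beads
    distance = ndimage.distance_transform_edt(binary)
    min_dist_px = max(1, int(round(params.split_min_distance_nm / scale)))
    comp = cc_label(binary, connectivity=2)
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=comp, exclude_border=False
    )
    markers = np.zeros_like(comp)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = comp
    else:
        labels = watershed(-distance, markers, mask=binary)

    resid_s = ndimage.gaussian_filter(resid, sigma=1.0)
    sigma_meas = float(np.hypot(params.psf_sigma_nm / scale, 1.0))

    # absolute darkness reference: heterochromatin-level intensity of the
    # smoothed image (quantile-based, hence invariant to additive shifts).
    # Objects darker than this are gold; objects at heterochromatin level can
    # still be gold when their residual depth exceeds anything chromatin
    # contrast alone could produce (beads sitting on bright LEDDs).
    pixels_s = ndimage.gaussian_filter(pixels, sigma=2.0)
    dark_ref = float(np.quantile(pixels_s[mask], params.dark_ref_quantile))
    median_ref = float(np.median(pixels_s[mask]))
    depth_strong = max(1.5 * (median_ref - dark_ref), 2 * params.core_contrast_min)

    h, w = mask.shape
    records: list[tuple[tuple[float, float], ParticleRecord]] = []
    for rp in regionprops(labels):
        area = rp.area
        if area < amin_px * 0.3 or area > amax_px * 4:
            continue

        # weighted centroid by residual depth (shift invariant)
        coords = rp.coords
        wts = np.maximum(thr - resid[coords[:, 0], coords[:, 1]], 0.0)
        if wts.sum() <= 0:
            wts = np.ones(len(coords))
        cr, cc = coords[:, 0] @ wts / wts.sum(), coords[:, 1] @ wts / wts.sum()
        pr, pc = int(round(cr)), int(round(cc))
        if not (0 <= pr < h and 0 <= pc < w) or not mask[pr, pc]:
            continue

        # local window around the object
        r_obj = max(np.sqrt(area / np.pi), 1.0)
        ext = 3.0 * r_obj + 3
        r0, r1 = max(int(cr - ext), 0), min(int(cr + ext) + 1, h)
        c0, c1 = max(int(cc - ext), 0), min(int(cc + ext) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dd = np.hypot(yy - cr, xx - cc)
        win_labels = labels[r0:r1, c0:c1]
        win_mask = mask[r0:r1, c0:c1]

        # residual baseline from an annulus clear of any detected object
        ann = (dd > 1.5 * r_obj) & (dd <= 3.0 * r_obj) & (win_labels == 0) & win_mask
        baseline = float(np.median(resid_s[r0:r1, c0:c1][ann])) if ann.sum() >= 4 else 0.0

        # baseline-corrected depth and half-depth footprint; background pixels
        # (label 0) near this object may join the footprint when the detection
        # threshold was deeper than the half level
        sub_rs = resid_s[r0:r1, c0:c1]
        own = win_labels == rp.label
        depth = baseline - float(sub_rs[own].min())
        if depth <= 0:
            continue
        half_level = baseline - depth / 2.0
        eligible = (own | (win_labels == 0)) & win_mask & (dd <= 2.2 * r_obj + 2)
        half_mask = eligible & (sub_rs <= half_level)
        # keep only the lobe containing this object's minimum
        half_cc = cc_label(half_mask, connectivity=2)
        min_flat = int(np.argmin(np.where(own, sub_rs, np.inf)))
        lobe = half_cc[np.unravel_index(min_flat, sub_rs.shape)]
        if lobe == 0:
            continue
        half_mask = half_cc == lobe
        half_area = float(half_mask.sum())
        r_true = _corrected_radius_px(np.sqrt(half_area / np.pi), sigma_meas)
        diameter_nm = 2.0 * r_true * scale

        size_class = classify_size(
            diameter_nm, params.nominal_diameters_nm, params.size_tolerance
        )
        if size_class is None:
            continue

        # shape measured on the half-depth level set of the smoothed residual
        # (the binary footprint at the detection threshold is noise-ragged)
        half_rp = regionprops(half_mask.astype(np.uint8))[0]
        perim = half_rp.perimeter_crofton
        if perim <= 0:
            continue
        circ_raw = 4 * np.pi * half_area / perim**2
        if circ_raw < params.min_circularity:
            continue

        # density filters on the original intensities: core vs local background
        # and core vs the absolute heterochromatin reference
        core_vals = np.sort(pixels[coords[:, 0], coords[:, 1]])
        core = float(core_vals[: max(1, len(core_vals) // 3)].mean())
        bg_ann = (dd > 1.2 * r_obj) & (dd <= 2.5 * r_obj) & ~binary[r0:r1, c0:c1] & win_mask
        if bg_ann.sum() < 4:
            continue
        background = float(np.median(pixels[r0:r1, c0:c1][bg_ann]))
        if background - core < params.core_contrast_min:
            continue
        if core >= dark_ref - params.density_margin and depth < depth_strong:
            continue

        rec = ParticleRecord(
            id=-1,
            centroid_nm=(cc * scale, cr * scale),
            equivalent_diameter_nm=float(diameter_nm),
            circularity=float(min(circ_raw, 1.0)),
            mean_core_intensity=core,
            size_class=size_class,
        )
        records.append(((cr, cc), rec))

    records.sort(key=lambda t: t[0])
    out = []
    for i, (_, rec) in enumerate(records):
        rec.id = i
        out.append(rec)
    return out


@dataclass
class MatchResult:
    """Detection-vs-ground-truth matching summary.

    ``precision`` is reported as 1.0 with ``precision_undefined=True`` when
    there are no detections at all.
    """

    n_matched: int
    n_false_positive: int
    n_false_negative: int
    precision: float
    recall: float
    precision_undefined: bool
    class_confusion: dict[tuple[str, str], int]  # (truth class, detected class) -> count

    @property
    def size_accuracy(self) -> float:
        total = sum(self.class_confusion.values())
        if total == 0:
            return 1.0
        correct = sum(v for (a, b), v in self.class_confusion.items() if a == b)
        return correct / total


def match_to_ground_truth(detections, truth_particles, radius_nm: float = 5.0) -> MatchResult:
    """One-to-one greedy nearest-neighbor matching within ``radius_nm``.

    ``truth_particles`` is a DataFrame with columns x_nm, y_nm, size_class
    (as produced by the synthetic generator). Order of detections does not
    affect the result.
    """
    det_xy = np.array([p.centroid_nm for p in detections], dtype=float).reshape(-1, 2)
    det_cls = [p.size_class for p in detections]
    tru_xy = truth_particles[["x_nm", "y_nm"]].to_numpy(dtype=float).reshape(-1, 2)
    tru_cls = list(truth_particles["size_class"])

    pairs = []
    if len(det_xy) and len(tru_xy):
        from scipy.spatial import cKDTree

        tree = cKDTree(tru_xy)
        for di, (neighbors) in enumerate(tree.query_ball_point(det_xy, r=radius_nm)):
            for ti in neighbors:
                d = float(np.hypot(*(det_xy[di] - tru_xy[ti])))
                pairs.append((d, di, ti))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    confusion: dict[tuple[str, str], int] = {}
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        key = (tru_cls[ti], det_cls[di])
        confusion[key] = confusion.get(key, 0) + 1
    n_tp = len(used_d)
    n_fp = len(det_xy) - n_tp
    n_fn = len(tru_xy) - n_tp
    undefined = len(det_xy) == 0
    precision = 1.0 if undefined else n_tp / len(det_xy)
    recall = 1.0 if len(tru_xy) == 0 else n_tp / len(tru_xy)
    return MatchResult(
        n_matched=n_tp, n_false_positive=n_fp, n_false_negative=n_fn,
        precision=precision, recall=recall, precision_undefined=undefined,
        class_confusion=confusion,
    )
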