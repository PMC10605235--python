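"""Ground-truthed synthetic TEM-like micrographs.

The generator emulates uranyl-acetate-contrasted nuclear sections: darker
heterochromatin patches over a lighter euchromatin background, electron-lucent
(bright) elliptical LEDDs at particle-traversal sites, and very dark circular
gold beads of nominal 6 nm and 10 nm diameter. Beads are placed in clusters
whose anchor positions follow either a uniform law over the nucleus or an
exponential decay of density with distance from the nearest LEDD boundary
(the recoverable parameter being the decay length). Exact ground truth
(centroids, diameters, cluster ids, signed boundary distances) is collected
before rendering; rendering applies anti-aliased disc stamps, a Gaussian PSF
blur, then additive Gaussian noise. Everything is deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter, binary_erosion

from .errors import GenerationError, ValidationError
from .micrograph import Micrograph

_SIZE_CLASSES = {6.0: "6nm", 10.0: "10nm"}


@dataclass(frozen=True)
class GrayLevels:
    """Mean intensities of the four scene phases, ordered by electron density.

    Gold is far denser than protein, so beads are darkest; LEDDs are
    electron-lucent and brightest. Defaults are fixed, reproducible choices.
    """

    bead: float = 0.05
    heterochromatin: float = 0.35
    euchromatin: float = 0.55
    ledd: float = 0.80

    def __post_init__(self) -> None:
        order = (self.bead, self.heterochromatin, self.euchromatin, self.ledd)
        if not all(0 <= v <= 1 for v in order):
            raise ValidationError("gray levels must lie in [0, 1]")
        if not (order[0] < order[1] < order[2] < order[3]):
            raise ValidationError(
                "gray levels must satisfy bead < heterochromatin < euchromatin < ledd"
            )


@dataclass(frozen=True)
class LeddSpec:
    """LEDD geometry: how many elliptical domains, their radii and placement.

    ``positions_px`` fixes centers explicitly (row, col); otherwise centers
    are drawn uniformly at least ``margin_nm`` from the frame edge, emulating
    traversal sites well inside the recorded field of view.
    """

    count: int = 2
    radius_nm: tuple[float, float] = (300.0, 450.0)
    axis_ratio: tuple[float, float] = (0.7, 1.0)
    margin_nm: float = 600.0
    positions_px: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("ledd count must be >= 0")
        if self.radius_nm[0] <= 0 or self.radius_nm[1] < self.radius_nm[0]:
            raise ValidationError("radius_nm must be a positive (lo, hi) pair")


@dataclass(frozen=True)
class ParticleSpec:
    """Bead counts, placement law and cluster statistics.

    ``cluster_size_probs`` are probabilities for cluster sizes 1..5 (the last
    entry standing for the ">4" category); most immunogold clusters are the
    two-bead pairs of a single break, so the default mass sits on size 2.
    ``chromatin_ratio`` (het_weight, eu_weight), when given, draws each
    cluster's target chromatin class with those odds and anchors it on a pixel
    of that class (eroded by ``class_margin_nm`` so the target is unambiguous).
    """

    n_6nm: int = 40
    n_10nm: int = 40
    placement: str = "boundary_decay"  # or "uniform"
    decay_length_nm: float = 150.0
    cluster_size_probs: tuple[float, ...] = (0.10, 0.80, 0.06, 0.03, 0.01)
    cluster_spread_nm: float = 40.0
    diameter_jitter: float = 0.10
    chromatin_ratio: Optional[tuple[float, float]] = None
    class_margin_nm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_6nm < 0 or self.n_10nm < 0:
            raise ValidationError("bead counts must be >= 0")
        if self.placement not in ("boundary_decay", "uniform"):
            raise ValidationError("placement must be 'boundary_decay' or 'uniform'")
        if self.decay_length_nm <= 0 or self.cluster_spread_nm <= 0:
            raise ValidationError("geometric parameters must be positive")
        p = np.asarray(self.cluster_size_probs, dtype=float)
        if p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ValidationError("cluster_size_probs must be a probability vector")
        if not (0 <= self.diameter_jitter <= 0.10 + 1e-9):
            raise ValidationError("diameter_jitter must lie in [0, 0.10]")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic nuclear section."""

    image_shape: tuple[int, int] = (1536, 1536)
    scale_nm_per_px: float = 1.0
    gray: GrayLevels = field(default_factory=GrayLevels)
    heterochromatin_fraction: float = 0.30
    hetero_texture_nm: float = 80.0
    ledd: LeddSpec = field(default_factory=LeddSpec)
    particles: ParticleSpec = field(default_factory=ParticleSpec)
    noise_sigma: float = 0.03
    blur_sigma_nm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_nm_per_px <= 0:
            raise ValidationError("scale_nm_per_px must be positive")
        if not (0 <= self.heterochromatin_fraction <= 1):
            raise ValidationError("heterochromatin_fraction must lie in [0, 1]")
        if self.noise_sigma < 0 or self.blur_sigma_nm < 0:
            raise ValidationError("noise and blur must be >= 0")


@dataclass
class GroundTruth:
    """Exact scene truth collected before rendering.

    ``particles`` columns: id, x_nm, y_nm, diameter_nm, size_class,
    cluster_id, boundary_distance_nm (signed; negative inside a LEDD; +inf
    when the scene has no LEDD), placement_class. ``chromatin_label`` uses the
    same codes as the analysis (1 het, 2 eu, 3 ledd).
    """

    particles: pd.DataFrame
    ledd_mask: np.ndarray
    chromatin_label: np.ndarray
    seed: int
    condition: Optional[str] = None
    section_index: int = 0


# chromatin label codes shared with ledscan.chromatin
_HET, _EU, _LEDD = 1, 2, 3

_PARTICLE_COLS = [
    "id", "x_nm", "y_nm", "diameter_nm", "size_class",
    "cluster_id", "boundary_distance_nm", "placement_class",
]


def _chromatin_texture(rng: np.random.Generator, shape, fraction: float, corr_px: float) -> np.ndarray:
    """Smoothed Gaussian random field thresholded to the requested het area fraction."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    fld = gaussian_filter(rng.standard_normal(shape), sigma=max(corr_px, 1.0))
    return fld < np.quantile(fld, fraction)


def _draw_ledds(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Render the union mask of elliptical LEDDs."""
    h, w = spec.image_shape
    mask = np.zeros((h, w), dtype=bool)
    scale = spec.scale_nm_per_px
    margin = spec.ledd.margin_nm / scale
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for i in range(spec.ledd.count):
        r_nm = rng.uniform(*spec.ledd.radius_nm)
        ratio = rng.uniform(*spec.ledd.axis_ratio)
        angle = rng.uniform(0, np.pi)
        if spec.ledd.positions_px is not None:
            cr, cc = spec.ledd.positions_px[i % len(spec.ledd.positions_px)]
        else:
            lo_r, hi_r = margin, h - 1 - margin
            lo_c, hi_c = margin, w - 1 - margin
            if hi_r <= lo_r or hi_c <= lo_c:
                raise GenerationError("image too small for the LEDD margin")
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
        a = r_nm / scale            # semi-major, px
        b = r_nm * ratio / scale    # semi-minor, px
        dr = rows - cr
        dc = cols - cc
        u = dr * np.cos(angle) + dc * np.sin(angle)
        v = -dr * np.sin(angle) + dc * np.cos(angle)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _signed_distance_px(ledd_mask: np.ndarray) -> np.ndarray:
    """Signed pixel distance to the LEDD boundary (negative inside); +inf without LEDDs."""
    if not ledd_mask.any():
        return np.full(ledd_mask.shape, np.inf)
    outside = distance_transform_edt(~ledd_mask)
    inside = distance_transform_edt(ledd_mask)
    return np.where(ledd_mask, -inside, outside)


class _CandidateIndex:
    """Fast lookup of pixels by rounded signed boundary distance (in px)."""

    def __init__(self, sd_px: np.ndarray):
        finite = np.isfinite(sd_px)
        self._finite = bool(finite.all())
        bins = np.round(sd_px.ravel()).astype(np.int64) if self._finite else None
        if bins is not None:
            self._order = np.argsort(bins, kind="stable")
            self._sorted = bins[self._order]
        self._shape = sd_px.shape

    def at(self, bin_px: int) -> np.ndarray:
        """Flat indices of pixels whose rounded signed distance equals bin_px."""
        if not self._finite:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._sorted, bin_px, side="left")
        hi = np.searchsorted(self._sorted, bin_px, side="right")
        return self._order[lo:hi]


def _cluster_sizes(rng: np.random.Generator, n: int, probs: Sequence[float]) -> list[int]:
    """Cluster sizes (1..5) drawn from probs until exactly n beads are allocated."""
    sizes: list[int] = []
    total = 0
    support = np.arange(1, len(probs) + 1)
    while total < n:
        s = int(rng.choice(support, p=probs))
        s = min(s, n - total)
        sizes.append(s)
        total += s
    return sizes


def generate_micrograph(spec: SceneSpec) -> tuple[Micrograph, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Raises :class:`GenerationError` if beads cannot be placed without overlap
    within the retry limit (100 attempts per cluster).
    """
    # independent streams so the rendered scene (texture, LEDDs, noise) is
    # identical for a given seed whatever the particle content
    scene_ss, part_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_scene = np.random.default_rng(scene_ss)
    rng = np.random.default_rng(part_ss)
    rng_noise = np.random.default_rng(noise_ss)
    h, w = spec.image_shape
    scale = spec.scale_nm_per_px

    het = _chromatin_texture(
        rng_scene, (h, w), spec.heterochromatin_fraction, spec.hetero_texture_nm / scale / 2.0
    )
    ledd_mask = _draw_ledds(rng_scene, spec)
    chromatin = np.where(het, _HET, _EU).astype(np.uint8)
    chromatin[ledd_mask] = _LEDD

    sd_px = _signed_distance_px(ledd_mask)
    cand = _CandidateIndex(sd_px)
    flat_class = chromatin.ravel()

    # Eroded per-class masks give unambiguous targets for chromatin-ratio placement.
    margin_px = max(1, int(round(spec.particles.class_margin_nm / scale)))
    selem = np.ones((2 * margin_px + 1,) * 2, dtype=bool)
    eroded = {
        _HET: binary_erosion(chromatin == _HET, selem).ravel(),
        _EU: binary_erosion(chromatin == _EU, selem).ravel(),
    }

    pspec = spec.particles
    placements: list[dict] = []
    accepted_rc: list[np.ndarray] = []   # (row, col) px
    accepted_rad: list[float] = []       # px radii
    edge_px = 12.0 / scale + 2           # keep stamps inside the frame

    def _far_enough(points: np.ndarray, radii: np.ndarray) -> bool:
        if not accepted_rc:
            return True
        existing = np.asarray(accepted_rc)
        er = np.asarray(accepted_rad)
        d = np.hypot(
            points[:, None, 0] - existing[None, :, 0],
            points[:, None, 1] - existing[None, :, 1],
        )
        return bool(np.all(d >= radii[:, None] + er[None, :]))

    cluster_id = 0
    for nominal, count in ((6.0, pspec.n_6nm), (10.0, pspec.n_10nm)):
        if count == 0:
            continue
        sizes = _cluster_sizes(rng, count, pspec.cluster_size_probs)
        for size in sizes:
            target = None
            if pspec.chromatin_ratio is not None:
                wts = np.asarray(pspec.chromatin_ratio, dtype=float)
                target = int(rng.choice([_HET, _EU], p=wts / wts.sum()))
            placed = False
            for _ in range(100):
                # --- anchor ---
                if pspec.placement == "uniform" or not ledd_mask.any():
                    ar = rng.uniform(edge_px, h - 1 - edge_px)
                    ac = rng.uniform(edge_px, w - 1 - edge_px)
                    if target is not None:
                        flat = int(round(ar)) * w + int(round(ac))
                        pool = eroded[target]
                        if not pool[flat]:
                            continue
                else:
                    d_nm = rng.exponential(pspec.decay_length_nm)
                    t = int(round(d_nm / scale))
                    sign = 1 if rng.random() < 0.5 else -1
                    pools = []
                    for s in ((sign, -sign) if target is None else (1,)):
                        idx = cand.at(s * t) if target is None else np.concatenate(
                            [cand.at(t), cand.at(-t)]
                        )
                        pools.append(idx)
                        if target is None and len(idx):
                            break
                    idx = pools[0] if len(pools[0]) else (pools[1] if len(pools) > 1 else pools[0])
                    if target is not None:
                        idx = idx[eroded[target][idx]]
                    if not len(idx):
                        continue
                    flat = int(idx[rng.integers(len(idx))])
                    ar = flat // w + rng.uniform(-0.5, 0.5)
                    ac = flat % w + rng.uniform(-0.5, 0.5)
                # --- members ---
                diam = nominal * (1 + rng.uniform(-pspec.diameter_jitter, pspec.diameter_jitter, size))
                radii_px = diam / 2 / scale
                rr = pspec.cluster_spread_nm / 2 / scale
                rad = rr * np.sqrt(rng.random(size))
                ang = rng.random(size) * 2 * np.pi
                pts = np.column_stack([ar + rad * np.sin(ang), ac + rad * np.cos(ang)])
                if size == 1:
                    pts = np.array([[ar, ac]])
                if pts[:, 0].min() < edge_px or pts[:, 0].max() > h - 1 - edge_px:
                    continue
                if pts[:, 1].min() < edge_px or pts[:, 1].max() > w - 1 - edge_px:
                    continue
                if size > 1:
                    dd = np.hypot(
                        pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
                    )
                    np.fill_diagonal(dd, np.inf)
                    if np.any(dd < radii_px[:, None] + radii_px[None, :]):
                        continue
                if not _far_enough(pts, radii_px):
                    continue
                for k in range(size):
                    placements.append({
                        "row": pts[k, 0], "col": pts[k, 1],
                        "diameter_nm": float(diam[k]),
                        "size_class": _SIZE_CLASSES[nominal],
                        "cluster_id": cluster_id,
                        "placement_class": (
                            {"1": "heterochromatin", "2": "euchromatin"}[str(target)]
                            if target is not None else "any"
                        ),
                    })
                    accepted_rc.append(pts[k])
                    accepted_rad.append(float(radii_px[k]))
                cluster_id += 1
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place a {size}-bead cluster after 100 attempts"
                )

    # ground truth (before rendering)
    rows = []
    for i, p in enumerate(placements):
        if np.isinf(sd_px).all():
            bd = np.inf
        else:
            r0, c0 = int(round(p["row"])), int(round(p["col"]))
            bd = float(sd_px[r0, c0]) * scale
        rows.append({
            "id": i,
            "x_nm": p["col"] * scale,
            "y_nm": p["row"] * scale,
            "diameter_nm": p["diameter_nm"],
            "size_class": p["size_class"],
            "cluster_id": p["cluster_id"],
            "boundary_distance_nm": bd,
            "placement_class": p["placement_class"],
        })
    truth_df = pd.DataFrame(rows, columns=_PARTICLE_COLS)

    # rendering
    g = spec.gray
    image = np.full((h, w), g.euchromatin, dtype=float)
    image[het] = g.heterochromatin
    image[ledd_mask] = g.ledd
    for p in placements:
        r_px = p["diameter_nm"] / 2 / scale
        cr, cc = p["row"], p["col"]
        r0, r1 = int(np.floor(cr - r_px - 2)), int(np.ceil(cr + r_px + 3))
        c0, c1 = int(np.floor(cc - r_px - 2)), int(np.ceil(cc + r_px + 3))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = np.hypot(yy - cr, xx - cc)
        cov = np.clip(r_px - dist + 0.5, 0.0, 1.0)  # anti-aliased disc coverage
        patch = image[r0:r1, c0:c1]
        image[r0:r1, c0:c1] = g.bead * cov + patch * (1 - cov)
    if spec.blur_sigma_nm > 0:
        image = gaussian_filter(image, sigma=spec.blur_sigma_nm / scale)
    if spec.noise_sigma > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    img = Micrograph(pixels=image, scale_nm_per_px=scale,
                     nucleus_mask=np.ones((h, w), dtype=bool))
    truth = GroundTruth(particles=truth_df, ledd_mask=ledd_mask,
                        chromatin_label=chromatin, seed=spec.seed)
    return img, truth


def generate_dataset(
    n_sections: int, spec: SceneSpec, condition: Optional[str] = None
) -> list[tuple[Micrograph, GroundTruth]]:
    """Generate independent sections with per-section seeds derived from the master seed.

    Two calls with the same master seed produce bitwise-identical datasets.
    """
    if n_sections < 1:
        raise ValidationError("n_sections must be >= 1")
    states = np.random.SeedSequence(spec.seed).generate_state(n_sections)
    out = []
    for i, s in enumerate(states):
        sec_spec = replace(spec, seed=int(s) & 0x7FFFFFFF)
        img, truth = generate_micrograph(sec_spec)
        truth.condition = condition
        truth.section_index = i
        out.append((img, truth))
    return out
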