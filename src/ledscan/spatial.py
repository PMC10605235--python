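"""Spatial partitioning around LEDD boundaries, bead clustering and summaries.

The nucleus is partitioned by the signed Euclidean distance to the nearest
LEDD boundary (negative inside any LEDD): an *inside* zone deeper than the
border half-width, a symmetric *border* band (default ±300 nm, closed
interval at the band edge), and *outside* beyond it. Outside distances are
further histogrammed into finer bands (default (0,100], (100,200], (200,300],
(300,400] nm, printed as "1-100 nm" etc.). Beads are grouped into clusters by
single-linkage at a center-to-center distance (default 50 nm, the span of two
beads bridged by antibody stacks), categorized 1-2 / 3-4 / >4 beads per
cluster, and clusters of at least 3 beads count as clustered lesions for the
zone percentages.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .chromatin import (
    LABEL_EXCLUDED,
    LABEL_NAMES,
    ChromatinMap,
)
from .errors import ValidationError
from .records import LEDDRegion, ParticleRecord

ZONE_EXCLUDED = 0
ZONE_INSIDE = 1
ZONE_BORDER = 2
ZONE_OUTSIDE = 3
ZONE_NAMES = {ZONE_INSIDE: "inside", ZONE_BORDER: "border", ZONE_OUTSIDE: "outside"}

CATEGORY_LABELS = ("1-2", "3-4", ">4")


def cluster_category(size: int) -> str:
    """Cluster size category: 1-2, 3-4 or >4 beads per cluster."""
    if size <= 2:
        return "1-2"
    if size <= 4:
        return "3-4"
    return ">4"


@dataclass
class RegionPartition:
    """Signed-distance field and zone labels relative to LEDD boundaries."""

    signed_distance_nm: np.ndarray
    zone_labels: np.ndarray
    band_edges_nm: tuple[float, ...]
    border_halfwidth_nm: float
    scale_nm_per_px: float
    no_ledds: bool

    @property
    def band_intervals(self) -> list[tuple[float, float]]:
        """Left-open, right-closed (lo, hi] intervals in nm.

        Edges like (1, 100, 200, ...) follow the printed integer labels, so
        the first interval opens at ``edges[0] - 1`` (i.e. (0, 100]).
        """
        e = list(self.band_edges_nm)
        lowers = [max(e[0] - 1.0, 0.0)] + e[1:-1]
        return list(zip(lowers, e[1:]))

    def band_label(self, index: int) -> str:
        lo, hi = self.band_intervals[index]
        return f"{int(lo) + 1}-{int(hi)} nm"

    def band_of(self, distance_nm: float) -> int:
        """Band index for a positive outside distance, or -1 when out of range."""
        if not np.isfinite(distance_nm) or distance_nm <= 0:
            return -1
        for i, (lo, hi) in enumerate(self.band_intervals):
            if lo < distance_nm <= hi:
                return i
        return -1

    def zone_name(self, code: int) -> Optional[str]:
        return ZONE_NAMES.get(int(code))


def build_partition(
    ledds: Sequence[LEDDRegion],
    shape: tuple[int, int],
    scale_nm_per_px: float,
    analysis_mask: Optional[np.ndarray] = None,
    border_halfwidth_nm: float = 300.0,
    band_edges_nm: Sequence[float] = (1, 100, 200, 300, 400),
) -> RegionPartition:
    """Euclidean signed-distance partition around the union of LEDDs.

    Zone is a pure function of the signed distance d: inside ⇔ d < -h,
    border ⇔ |d| ≤ h (closed at the tie), outside ⇔ d > h. With zero LEDDs
    every in-mask pixel is outside at distance +inf and the partition is
    flagged ``no_ledds``.
    """
    if border_halfwidth_nm <= 0:
        raise ValidationError("border_halfwidth_nm must be positive")
    edges = tuple(float(e) for e in band_edges_nm)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("band_edges_nm must be strictly increasing with >= 2 entries")

    union = np.zeros(shape, dtype=bool)
    for r in ledds:
        if r.mask is None:
            raise ValidationError(f"LEDD {r.id} has no full-frame mask")
        union |= r.mask

    if union.any():
        sd = np.where(
            union,
            -ndimage.distance_transform_edt(union),
            ndimage.distance_transform_edt(~union),
        ) * scale_nm_per_px
    else:
        sd = np.full(shape, np.inf)

    zones = np.full(shape, ZONE_OUTSIDE, dtype=np.uint8)
    zones[np.abs(sd) <= border_halfwidth_nm] = ZONE_BORDER
    zones[sd < -border_halfwidth_nm] = ZONE_INSIDE
    if analysis_mask is not None:
        zones[~analysis_mask] = ZONE_EXCLUDED

    return RegionPartition(
        signed_distance_nm=sd,
        zone_labels=zones,
        band_edges_nm=edges,
        border_halfwidth_nm=float(border_halfwidth_nm),
        scale_nm_per_px=float(scale_nm_per_px),
        no_ledds=not union.any(),
    )


def assign_particles(
    particles: Sequence[ParticleRecord],
    partition: RegionPartition,
    cmap: ChromatinMap,
) -> pd.DataFrame:
    """Per-particle zone / band / chromatin assignment by centroid pixel.

    Particles sitting on excluded pixels are dropped; the count is recorded in
    ``df.attrs['n_dropped_excluded']``. Row order follows particle id.
    """
    scale = partition.scale_nm_per_px
    h, w = partition.zone_labels.shape
    rows = []
    dropped = 0
    for p in particles:
        x, y = p.centroid_nm
        pr = min(max(int(round(y / scale)), 0), h - 1)
        pc = min(max(int(round(x / scale)), 0), w - 1)
        zone_code = int(partition.zone_labels[pr, pc])
        chrom_code = int(cmap.labels[pr, pc])
        if zone_code == ZONE_EXCLUDED or chrom_code == LABEL_EXCLUDED:
            dropped += 1
            continue
        sd = float(partition.signed_distance_nm[pr, pc])
        band_i = partition.band_of(sd)
        rows.append({
            "id": p.id,
            "x_nm": x,
            "y_nm": y,
            "size_class": p.size_class,
            "zone": ZONE_NAMES[zone_code],
            "band": partition.band_label(band_i) if band_i >= 0 else "",
            "chromatin": LABEL_NAMES[chrom_code],
            "signed_distance_nm": sd,
        })
    df = pd.DataFrame(
        rows,
        columns=["id", "x_nm", "y_nm", "size_class", "zone", "band",
                 "chromatin", "signed_distance_nm"],
    ).sort_values("id", kind="stable").reset_index(drop=True)
    df.attrs["n_dropped_excluded"] = dropped
    return df


@dataclass
class ClusterAssignment:
    """One single-linkage bead cluster.

    ``cluster_id`` is the minimum member particle id (deterministic);
    ``chromatin_class`` is the majority chromatin label of members (ties to
    the denser class); ``zone`` is the zone of the cluster centroid.
    """

    cluster_id: int
    member_ids: tuple[int, ...]
    size: int
    category: str
    centroid_nm: tuple[float, float]
    zone: Optional[str] = None
    chromatin_class: Optional[str] = None


def find_clusters(
    particles: Sequence[ParticleRecord],
    linkage_nm: float = 50.0,
    partition: Optional[RegionPartition] = None,
    cmap: Optional[ChromatinMap] = None,
) -> list[ClusterAssignment]:
    """Single-linkage clusters of the graph joining pairs within ``linkage_nm``.

    Clusters partition the particle set; ids are the minimum member particle
    id and output is sorted by cluster id.
    """
    if linkage_nm <= 0:
        raise ValidationError("linkage_nm must be positive")
    n = len(particles)
    if n == 0:
        return []
    xy = np.array([p.centroid_nm for p in particles], dtype=float)
    ids = np.array([p.id for p in particles], dtype=int)

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, j in cKDTree(xy).query_pairs(r=linkage_nm, output_type="ndarray"):
        union(int(i), int(j))

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for members in groups.values():
        mids = sorted(int(ids[m]) for m in members)
        centroid = xy[members].mean(axis=0)
        cl = ClusterAssignment(
            cluster_id=mids[0],
            member_ids=tuple(mids),
            size=len(mids),
            category=cluster_category(len(mids)),
            centroid_nm=(float(centroid[0]), float(centroid[1])),
        )
        if partition is not None:
            h, w = partition.zone_labels.shape
            pr = min(max(int(round(cl.centroid_nm[1] / partition.scale_nm_per_px)), 0), h - 1)
            pc = min(max(int(round(cl.centroid_nm[0] / partition.scale_nm_per_px)), 0), w - 1)
            cl.zone = partition.zone_name(partition.zone_labels[pr, pc])
        if cmap is not None:
            votes: dict[int, int] = {}
            h, w = cmap.labels.shape
            for m in members:
                pr = min(max(int(round(xy[m, 1] / cmap.scale_nm_per_px)), 0), h - 1)
                pc = min(max(int(round(xy[m, 0] / cmap.scale_nm_per_px)), 0), w - 1)
                code = int(cmap.labels[pr, pc])
                if code != LABEL_EXCLUDED:
                    votes[code] = votes.get(code, 0) + 1
            if votes:
                best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
                cl.chromatin_class = LABEL_NAMES[best]
        clusters.append(cl)
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def brute_force_clusters(xy: np.ndarray, linkage_nm: float) -> list[tuple[int, ...]]:
    """O(n²) transitive closure over the pairwise distance matrix (test oracle)."""
    n = len(xy)
    if n == 0:
        return []
    adj = (
        np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        <= linkage_nm
    )
    seen = np.zeros(n, dtype=bool)
    out = []
    for i in range(n):
        if seen[i]:
            continue
        frontier = {i}
        comp: set[int] = set()
        while frontier:
            k = frontier.pop()
            if k in comp:
                continue
            comp.add(k)
            frontier |= set(np.nonzero(adj[k])[0]) - comp
        seen[list(comp)] = True
        out.append(tuple(sorted(comp)))
    return sorted(out)


def cluster_zone_percentages(
    clusters: Iterable[ClusterAssignment], min_size: int = 3
) -> dict:
    """Percentage of qualifying clusters (size >= min_size) per zone.

    Percentages sum to 100 when at least one qualifying cluster exists;
    otherwise all zeros with ``empty=True``.
    """
    qual = [c for c in clusters if c.size >= min_size and c.zone is not None]
    n = len(qual)
    out = {"inside": 0.0, "border": 0.0, "outside": 0.0, "n_clusters": n, "empty": n == 0}
    if n:
        for zone in ("inside", "border", "outside"):
            out[zone] = 100.0 * sum(c.zone == zone for c in qual) / n
    return out


def band_density_profile(
    assignment: pd.DataFrame, partition: RegionPartition
) -> pd.DataFrame:
    """Particle density (particles/µm²) per outside distance band.

    Band areas come from the in-analysis pixels of the signed-distance field;
    particles beyond the last band edge are excluded from the profile (but
    remain in the assignment table).
    """
    if partition.no_ledds:
        raise ValidationError("band profile requires at least one LEDD")
    scale = partition.scale_nm_per_px
    sd = partition.signed_distance_nm
    valid = partition.zone_labels != ZONE_EXCLUDED
    dist = assignment["signed_distance_nm"].to_numpy(dtype=float) if len(assignment) else np.empty(0)
    rows = []
    for i, (lo, hi) in enumerate(partition.band_intervals):
        in_band = valid & (sd > lo) & (sd <= hi)
        area_um2 = float(in_band.sum()) * scale**2 * 1e-6
        count = int(np.sum((dist > lo) & (dist <= hi)))
        rows.append({
            "band": partition.band_label(i),
            "lo_nm": lo,
            "hi_nm": hi,
            "count": count,
            "area_um2": area_um2,
            "density_per_um2": count / area_um2 if area_um2 > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class DensityMap:
    """Gaussian-kernel particle density raster (particles/µm²)."""

    values: np.ndarray
    grid_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)

    @property
    def cell_area_um2(self) -> float:
        return (self.grid_nm * 1e-3) ** 2

    def integral(self) -> float:
        """Total particle count implied by the raster (sum × cell area)."""
        return float(self.values.sum() * self.cell_area_um2)


def density_heatmap(
    particles: Sequence[ParticleRecord],
    frame_shape_px: tuple[int, int],
    scale_nm_per_px: float,
    grid_nm: float = 100.0,
    kernel_bandwidth_nm: float = 150.0,
) -> DensityMap:
    """Gaussian-kernel density of particle centroids on a coarse grid.

    The raster integrates (sum × cell area) to the total particle count
    exactly; its purpose is visualization of cluster hot spots.
    """
    if grid_nm <= 0 or kernel_bandwidth_nm <= 0:
        raise ValidationError("grid and bandwidth must be positive")
    h_nm = frame_shape_px[0] * scale_nm_per_px
    w_nm = frame_shape_px[1] * scale_nm_per_px
    ny = max(1, int(np.ceil(h_nm / grid_nm)))
    nx = max(1, int(np.ceil(w_nm / grid_nm)))
    hist = np.zeros((ny, nx))
    for p in particles:
        x, y = p.centroid_nm
        iy = min(max(int(y // grid_nm), 0), ny - 1)
        ix = min(max(int(x // grid_nm), 0), nx - 1)
        hist[iy, ix] += 1
    smoothed = ndimage.gaussian_filter(hist, sigma=kernel_bandwidth_nm / grid_nm, mode="constant")
    total = smoothed.sum()
    n = hist.sum()
    if total > 0:
        smoothed *= n / total  # restore mass lost at the frame edge
    cell_area_um2 = (grid_nm * 1e-3) ** 2
    return DensityMap(values=smoothed / cell_area_um2, grid_nm=float(grid_nm))


@dataclass
class SpatialTable:
    """Per-particle assignments plus per-section aggregate metrics."""

    particles: pd.DataFrame
    clusters: list[ClusterAssignment]
    zone_percentages: dict
    band_profile: Optional[pd.DataFrame]
    section_id: int = 0
    condition: Optional[str] = None
    time_point: Optional[str] = None

    def metrics(self) -> dict[str, float]:
        """Flat per-section metric dictionary used by :func:`summarize_sections`."""
        df = self.particles
        m: dict[str, float] = {"n_particles": float(len(df))}
        for cls in ("6nm", "10nm"):
            m[f"n_particles_{cls}"] = float((df["size_class"] == cls).sum()) if len(df) else 0.0
        for chrom in ("heterochromatin", "euchromatin", "ledd"):
            m[f"n_particles_{chrom}"] = float((df["chromatin"] == chrom).sum()) if len(df) else 0.0
        # cluster-category percentages, overall and per chromatin class
        n_cl = len(self.clusters)
        for cat in CATEGORY_LABELS:
            key = f"cluster_pct_{cat}"
            m[key] = 100.0 * sum(c.category == cat for c in self.clusters) / n_cl if n_cl else 0.0
        for chrom in ("heterochromatin", "euchromatin"):
            sub = [c for c in self.clusters if c.chromatin_class == chrom]
            for cat in CATEGORY_LABELS:
                key = f"cluster_pct_{cat}_{chrom}"
                m[key] = 100.0 * sum(c.category == cat for c in sub) / len(sub) if sub else 0.0
        for zone in ("inside", "border", "outside"):
            m[f"zone_pct_{zone}"] = float(self.zone_percentages.get(zone, 0.0))
        if self.band_profile is not None:
            for row in self.band_profile.itertuples(index=False):
                m[f"band_density_{row.band}"] = float(row.density_per_um2)
        finite = df["signed_distance_nm"].replace([np.inf, -np.inf], np.nan).dropna() if len(df) else pd.Series(dtype=float)
        m["mean_abs_boundary_distance_nm"] = float(finite.abs().mean()) if len(finite) else float("nan")
        return m


def build_spatial_table(
    particles: Sequence[ParticleRecord],
    partition: RegionPartition,
    cmap: ChromatinMap,
    linkage_nm: float = 50.0,
    min_cluster_size: int = 3,
    section_id: int = 0,
    condition: Optional[str] = None,
    time_point: Optional[str] = None,
) -> SpatialTable:
    """Assign particles, form clusters and compute the per-section aggregates."""
    assignment = assign_particles(particles, partition, cmap)
    kept_ids = set(assignment["id"]) if len(assignment) else set()
    kept = [p for p in particles if p.id in kept_ids]
    clusters = find_clusters(kept, linkage_nm=linkage_nm, partition=partition, cmap=cmap)
    id_to_cluster = {m: c.cluster_id for c in clusters for m in c.member_ids}
    if len(assignment):
        assignment = assignment.assign(
            cluster_id=[id_to_cluster.get(i, -1) for i in assignment["id"]]
        )
    else:
        assignment["cluster_id"] = pd.Series(dtype=int)
    zones = cluster_zone_percentages(clusters, min_size=min_cluster_size)
    band = None if partition.no_ledds else band_density_profile(assignment, partition)
    return SpatialTable(
        particles=assignment,
        clusters=clusters,
        zone_percentages=zones,
        band_profile=band,
        section_id=section_id,
        condition=condition,
        time_point=time_point,
    )


def summarize_sections(tables: Sequence[SpatialTable]) -> pd.DataFrame:
    """Group means ± SE across sections for every per-section metric.

    Sections are grouped by (condition, time_point); SE = sd/√n over sections
    (NaN for n = 1). Returns a long table with one row per group × metric.
    """
    if not tables:
        raise ValidationError("at least one section table required")
    rows = []
    for t in tables:
        rec = {"condition": t.condition or "", "time_point": t.time_point or ""}
        rec.update(t.metrics())
        rows.append(rec)
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c not in ("condition", "time_point")]
    long = []
    for (cond, tp), grp in df.groupby(["condition", "time_point"], sort=True):
        for col in metric_cols:
            vals = grp[col].astype(float)
            valid = vals.dropna()
            n = len(valid)
            long.append({
                "condition": cond,
                "time_point": tp,
                "metric": col,
                "mean": float(valid.mean()) if n else float("nan"),
                "se": float(valid.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
                "n_sections": n,
            })
    return pd.DataFrame(long)
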