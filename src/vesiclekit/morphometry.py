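"""Per-vesicle geometry and population statistics.

Re-implements the quantitative segmentation analysis: the centroid of a
vesicle's surface point cloud estimates its center, the maximum distance from
that center is the maximum radius (reported without de-biasing; the positive
bias from surface noise and voxel snapping is documented, not corrected), and
the enclosed volume comes from the signed-tetrahedron (divergence-theorem)
sum over a closed triangle mesh, with the convex-hull volume as the
documented fallback for bare point clouds.

Population summaries report the median with a percentile-bootstrap 95%
confidence interval of the median, group differences as signed percent
differences, and an optional two-sided permutation test on medians — a
distribution-free replacement for parametric multiple-comparison tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull


class InputError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class VesicleMorphometry:
    """Size measures of one vesicle (all lengths nm, volume nm^3)."""

    vesicle_id: str
    centroid: tuple[float, float, float]
    max_radius: float
    max_diameter: float
    volume: float | None = None
    sphere_equivalent_radius: float | None = None
    strain: str | None = None


@dataclass(frozen=True)
class PopulationSummary:
    """Median and percentile-bootstrap 95% CI for one strain's measurements."""

    strain: str | None
    n: int
    median: float
    ci95: tuple[float, float]
    values: np.ndarray


def _as_points(surface_or_points) -> np.ndarray:
    pts = getattr(surface_or_points, "points", surface_or_points)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError("expected an (n, 3) array of coordinates")
    if not np.all(np.isfinite(pts)):
        raise InputError("coordinates must be finite")
    return pts


def centroid(points) -> np.ndarray:
    """Arithmetic mean of the surface points; estimates the vesicle center."""
    pts = _as_points(points)
    if pts.shape[0] < 1:
        raise InputError("centroid needs at least one point")
    return pts.mean(axis=0)


def max_radius(
    surface_or_points,
    voxel_size: float | None = None,
    coords_in_voxel_units: bool = False,
) -> float:
    """Maximum Euclidean distance from the centroid to any surface point (nm).

    If the coordinates are in voxel units, pass ``coords_in_voxel_units=True``
    with the voxel edge in nm; inputs already in nm pass through unscaled.
    """
    pts = _as_points(surface_or_points)
    if pts.shape[0] < 2:
        raise InputError("max_radius needs at least two points")
    if coords_in_voxel_units:
        if voxel_size is None:
            voxel_size = getattr(surface_or_points, "voxel_size", None)
        if not voxel_size or voxel_size <= 0:
            raise InputError("voxel-unit input requires a positive voxel_size in nm")
        pts = pts * voxel_size
    return float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())


def boundary_edge_count(faces: np.ndarray) -> int:
    """Number of directed edges without an opposing partner (0 for a closed,
    consistently oriented mesh)."""
    faces = np.asarray(faces, dtype=int)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    directed = {tuple(e) for e in edges.tolist()}
    if len(directed) != len(edges):
        raise GeometryError("mesh has duplicated directed edges (inconsistent orientation)")
    return sum(1 for a, b in directed if (b, a) not in directed)


def mesh_volume(surface, hull_fallback: bool = True) -> float:
    """Enclosed volume in nm^3.

    For a closed, consistently oriented triangle mesh: the absolute value of
    the signed-tetrahedron sum sum(det(a, b, c)) / 6 over its triangles.  For
    a bare point cloud (or with ``hull_fallback`` forced), the convex-hull
    volume of the points.
    """
    pts = _as_points(surface)
    faces = getattr(surface, "faces", None)
    if faces is not None:
        n_open = boundary_edge_count(faces)
        if n_open > 0:
            raise GeometryError(f"mesh is not closed: {n_open} boundary edges")
        a = pts[np.asarray(faces)[:, 0]]
        b = pts[np.asarray(faces)[:, 1]]
        c = pts[np.asarray(faces)[:, 2]]
        signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
        return float(abs(signed))
    if not hull_fallback:
        raise GeometryError("no faces present and hull fallback disabled")
    return float(ConvexHull(pts).volume)


def sphere_equivalent_radius(volume: float) -> float:
    """Radius of the sphere with the given volume: (3V / 4pi)^(1/3)."""
    if volume <= 0:
        raise InputError("volume must be > 0")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def measure_surface(surface, hull_fallback: bool = True) -> VesicleMorphometry:
    """All per-vesicle measures for one surface."""
    pts = _as_points(surface)
    c = centroid(pts)
    r = max_radius(pts)
    vol: float | None
    try:
        vol = mesh_volume(surface, hull_fallback=hull_fallback)
    except GeometryError:
        if getattr(surface, "faces", None) is not None:
            raise
        vol = None
    return VesicleMorphometry(
        vesicle_id=getattr(surface, "vesicle_id", ""),
        centroid=(float(c[0]), float(c[1]), float(c[2])),
        max_radius=r,
        max_diameter=2.0 * r,
        volume=vol,
        sphere_equivalent_radius=None if vol is None else sphere_equivalent_radius(vol),
        strain=getattr(surface, "strain", None),
    )


def measure_population(surfaces: Iterable, hull_fallback: bool = True) -> pd.DataFrame:
    """Per-vesicle measurement table (unit-suffixed column names)."""
    rows = []
    for s in surfaces:
        m = measure_surface(s, hull_fallback=hull_fallback)
        rows.append(
            {
                "vesicle_id": m.vesicle_id,
                "strain": m.strain,
                "centroid_x_nm": m.centroid[0],
                "centroid_y_nm": m.centroid[1],
                "centroid_z_nm": m.centroid[2],
                "max_radius_nm": m.max_radius,
                "max_diameter_nm": m.max_diameter,
                "volume_nm3": m.volume,
                "sphere_equivalent_radius_nm": m.sphere_equivalent_radius,
            }
        )
    if not rows:
        raise InputError("no surfaces to measure")
    return pd.DataFrame(rows)


def summarize_population(
    values: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    strain: str | None = None,
) -> PopulationSummary:
    """Median with a percentile-bootstrap 95% CI of the median.

    Resamples with replacement ``n_boot`` times and takes the 2.5/97.5
    percentiles of the bootstrap medians; deterministic for a fixed seed.
    Even-length medians use the midpoint convention.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise InputError("summarize_population needs at least one value")
    if n_boot < 100:
        raise InputError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boot_medians = np.median(vals[idx], axis=1)
    lo, hi = np.percentile(boot_medians, [2.5, 97.5])
    return PopulationSummary(
        strain=strain,
        n=int(vals.size),
        median=float(np.median(vals)),
        ci95=(float(lo), float(hi)),
        values=vals,
    )


def percent_difference(reference: float, other: float) -> float:
    """Signed percent difference 100 * (other - reference) / reference."""
    if reference <= 0:
        raise InputError("reference must be > 0")
    return 100.0 * (other - reference) / reference


def permutation_median_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in medians."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise InputError("both samples must be non-empty")
    observed = abs(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(np.median(perm[: a.size]) - np.median(perm[a.size:])) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def summarize_strains(
    per_vesicle: pd.DataFrame,
    value_column: str,
    reference_strain: str | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-strain summary table with optional percent difference vs reference."""
    if value_column not in per_vesicle.columns:
        raise InputError(f"no column {value_column!r} in the measurement table")
    summaries = {}
    for i, (strain, grp) in enumerate(per_vesicle.groupby("strain", sort=False)):
        vals = grp[value_column].dropna().to_numpy()
        summaries[strain] = summarize_population(
            vals, n_boot=n_boot, seed=seed + i, strain=strain
        )
    if reference_strain is not None and reference_strain not in summaries:
        raise InputError(f"reference strain {reference_strain!r} not in the table")
    rows = []
    for strain, s in summaries.items():
        pct = (
            percent_difference(summaries[reference_strain].median, s.median)
            if reference_strain is not None
            else np.nan
        )
        rows.append(
            {
                "strain": strain,
                "n": s.n,
                "median": s.median,
                "ci_low": s.ci95[0],
                "ci_high": s.ci95[1],
                "pct_diff_vs_reference": pct,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers (same dialects as written by the synthetic module)
# ---------------------------------------------------------------------------


def read_points_csv(path: str | Path, voxel_size: float | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    mapping = {}
    for want, aliases in {
        "vesicle_id": ("vesicle_id",),
        "x_nm": ("x_nm", "x"),
        "y_nm": ("y_nm", "y"),
        "z_nm": ("z_nm", "z"),
    }.items():
        for alias in aliases:
            if alias in cols:
                mapping[cols[alias]] = want
                break
        else:
            raise InputError(f"point CSV missing a {want} column")
    df = df.rename(columns=mapping)[["vesicle_id", "x_nm", "y_nm", "z_nm"]]
    bad = df[["x_nm", "y_nm", "z_nm"]].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:20]]  # +2: header and 1-based
        raise InputError(f"non-numeric coordinates on line(s) {lines}")
    if voxel_size:
        df[["x_nm", "y_nm", "z_nm"]] = df[["x_nm", "y_nm", "z_nm"]] * voxel_size
    return df
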