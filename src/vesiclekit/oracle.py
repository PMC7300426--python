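"""Brute-force Monte-Carlo oracles.

These deliberately simple estimators verify the analytic partition
coefficient and the signed-tetrahedron mesh volume by direct geometric
sampling, and provide an end-to-end parameter-recovery harness for the
synthetic strain presets.  Oracles are kept dumber than the code they check:
uniform-in-sphere sampling is plain cube rejection, and the inside test for
meshes is ray-crossing parity, with the ray direction drawn per point from
the six signed coordinate axes (axis-aligned rays permit a sorted
bounding-box sweep so a million parity tests run in seconds; together with
the random sample positions this dodges edge-grazing pathologies).  A point
lying on a face counts as inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .morphometry import GeometryError, InputError, boundary_edge_count, summarize_population

_ON_SURFACE_EPS = 1e-9


@dataclass(frozen=True)
class OracleResult:
    estimate: float
    n_samples: int
    standard_error: float
    seed: int


def mc_partition(r_cargo: float, R_av: float, n: int, seed: int = 0) -> OracleResult:
    """Estimate K by sampling cargo centers uniformly in the R_av sphere.

    Rejection sampling in the bounding cube; the estimate is the fraction of
    centers with |center| <= R_av - r_cargo, SE = sqrt(K(1-K)/n).
    """
    if R_av <= 0:
        raise InputError("R_av must be > 0")
    if r_cargo < 0:
        raise InputError("r_cargo must be >= 0")
    if n < 100:
        raise InputError("n must be >= 100")
    rng = np.random.default_rng(seed)
    accepted = 0
    hits = 0
    r_eff = R_av - r_cargo
    while accepted < n:
        batch = max(1024, int((n - accepted) * 6 / math.pi * 1.1))
        pts = rng.uniform(-R_av, R_av, size=(batch, 3))
        d2 = np.einsum("ij,ij->i", pts, pts)
        inside_sphere = d2 <= R_av * R_av
        d2 = d2[inside_sphere]
        take = min(d2.size, n - accepted)
        d2 = d2[:take]
        accepted += take
        if r_eff > 0:
            hits += int(np.count_nonzero(d2 <= r_eff * r_eff))
    k_hat = hits / n
    return OracleResult(
        estimate=float(k_hat),
        n_samples=n,
        standard_error=float(math.sqrt(k_hat * (1.0 - k_hat) / n)),
        seed=seed,
    )


def _axis_ray_parity(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray,
                     directions: np.ndarray, eps_scale: float) -> np.ndarray:
    """Inside/outside by ray-crossing parity along signed coordinate axes.

    ``directions`` holds one code in 0..5 per point: axis = code // 2,
    sign = +1 for even codes, -1 for odd.  For each of the six groups the
    coordinates are permuted (and possibly flipped) so the ray is +z; a sweep
    over triangles using an x-sorted point index confines each triangle's
    candidate set to its 2D bounding box.
    """
    n = points.shape[0]
    inside = np.zeros(n, dtype=bool)
    on_surface = np.zeros(n, dtype=bool)
    crossings = np.zeros(n, dtype=np.int64)
    tri = vertices[faces]  # (m, 3, 3)

    for code in range(6):
        group = np.flatnonzero(directions == code)
        if group.size == 0:
            continue
        axis = code // 2
        sign = 1.0 if code % 2 == 0 else -1.0
        order = [(axis + 1) % 3, (axis + 2) % 3, axis]
        p = points[group][:, order].copy()
        t = tri[:, :, order].copy()
        if sign < 0:
            p[:, 2] *= -1.0
            t[:, :, 2] *= -1.0

        sort_idx = np.argsort(p[:, 0], kind="stable")
        xs = p[sort_idx, 0]
        a2, b2, c2 = t[:, 0, :2], t[:, 1, :2], t[:, 2, :2]
        det = (b2[:, 0] - a2[:, 0]) * (c2[:, 1] - a2[:, 1]) - (
            b2[:, 1] - a2[:, 1]
        ) * (c2[:, 0] - a2[:, 0])
        tx_min = t[:, :, 0].min(axis=1)
        tx_max = t[:, :, 0].max(axis=1)
        ty_min = t[:, :, 1].min(axis=1)
        ty_max = t[:, :, 1].max(axis=1)

        for m in range(t.shape[0]):
            if det[m] == 0.0:  # degenerate projection: rays a.s. miss it
                continue
            i0 = np.searchsorted(xs, tx_min[m], side="left")
            i1 = np.searchsorted(xs, tx_max[m], side="right")
            if i0 >= i1:
                continue
            cand = sort_idx[i0:i1]
            py = p[cand, 1]
            cand = cand[(py >= ty_min[m]) & (py <= ty_max[m])]
            if cand.size == 0:
                continue
            dx = p[cand, 0] - a2[m, 0]
            dy = p[cand, 1] - a2[m, 1]
            w1 = ((c2[m, 1] - a2[m, 1]) * dx - (c2[m, 0] - a2[m, 0]) * dy) / det[m]
            w2 = ((a2[m, 1] - b2[m, 1]) * dx + (b2[m, 0] - a2[m, 0]) * dy) / det[m]
            hit = (w1 >= 0.0) & (w2 >= 0.0) & (w1 + w2 <= 1.0)
            if not np.any(hit):
                continue
            cand = cand[hit]
            z_tri = (
                t[m, 0, 2]
                + w1[hit] * (t[m, 1, 2] - t[m, 0, 2])
                + w2[hit] * (t[m, 2, 2] - t[m, 0, 2])
            )
            dz = z_tri - p[cand, 2]
            on = np.abs(dz) <= eps_scale
            if np.any(on):
                on_surface[group[cand[on]]] = True
            above = dz > eps_scale
            np.add.at(crossings, group[cand[above]], 1)

    inside = on_surface | (crossings % 2 == 1)
    return inside


def mc_mesh_volume(surface, n: int, seed: int = 0) -> OracleResult:
    """Estimate a closed mesh's volume by uniform box sampling + parity test."""
    if n < 1000:
        raise InputError("n must be >= 1000")
    vertices = np.asarray(surface.points, dtype=float)
    faces = getattr(surface, "faces", None)
    if faces is None:
        raise GeometryError("mc_mesh_volume needs a triangulated surface")
    faces = np.asarray(faces, dtype=int)
    n_open = boundary_edge_count(faces)
    if n_open > 0:
        raise GeometryError(f"mesh is not closed: {n_open} boundary edges")
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    extent = hi - lo
    if np.any(extent <= 0):
        raise GeometryError("degenerate (flat) mesh: zero-extent bounding box")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n, 3))
    dirs = rng.integers(0, 6, size=n)
    eps = _ON_SURFACE_EPS * float(extent.max())
    inside = _axis_ray_parity(pts, vertices, faces, dirs, eps)
    p_in = inside.mean()
    box = float(np.prod(extent))
    return OracleResult(
        estimate=float(box * p_in),
        n_samples=n,
        standard_error=float(box * math.sqrt(p_in * (1.0 - p_in) / n)),
        seed=seed,
    )


@dataclass(frozen=True)
class RecoveryReport:
    strain: str
    measure: str  # max_diameter | volume
    target: float
    estimate: float  # recovered population median
    ci95: tuple[float, float]
    n_vesicles: int
    passed: bool  # target inside the 95% bootstrap CI


def recover_parameters(
    preset,
    n_vesicles: int | None = None,
    seed: int = 0,
    n_boot: int = 2000,
) -> RecoveryReport:
    """Generate a population from a preset, measure it, compare to its target.

    The preset must carry ``target_measure``/``target_value`` (the built-in
    strain presets do).  The recovered median is compared against the target
    via its 95% percentile-bootstrap CI.
    """
    from dataclasses import replace

    from .morphometry import measure_population
    from .synthetic import generate_strain

    if preset.target_measure is None or preset.target_value is None:
        raise InputError("preset carries no recovery target")
    cfg = replace(
        preset,
        n_vesicles=n_vesicles or preset.n_vesicles,
        seed=seed if seed is not None else preset.seed,
    )
    surfaces = generate_strain(cfg)
    table = measure_population(surfaces)
    column = "max_diameter_nm" if cfg.target_measure == "max_diameter" else "volume_nm3"
    values = table[column].to_numpy()
    summary = summarize_population(values, n_boot=n_boot, seed=seed, strain=cfg.name)
    lo, hi = summary.ci95
    return RecoveryReport(
        strain=cfg.name,
        measure=cfg.target_measure,
        target=float(cfg.target_value),
        estimate=summary.median,
        ci95=summary.ci95,
        n_vesicles=cfg.n_vesicles,
        passed=bool(lo <= cfg.target_value <= hi),
    )
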