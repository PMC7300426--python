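"""Cargo occupancy and excluded-volume partitioning in COPII vesicles.

The vesicle is modeled as a sphere: subtracting the lipid bilayer thickness
from the vesicle radius gives the lumenal radius, and subtracting the
coat-selected cargo layer (the weighted mean diameter of the recruited cargo
species, each treated as a compact sphere) gives the available radius R_av
open to nonselective bulk flow.  A bulk-flow probe of radius r_cargo can
place its center only within R_eff = R_av - r_cargo, so its equilibrium
partition coefficient between vesicle and bulk is

    K = V_eff / V_av = (1 - r_cargo / R_av)^3,     clipped to 0 for r_cargo >= R_av.

Partitioning regimens: relaxed (R_av >> r_cargo; capture insensitive to
vesicle size), stringent (comparable scales; capture sensitive to small size
changes), excluded (r_cargo >= R_av; no capture).

Cargo radii derive from molecular weight by the compact-sphere scaling
r = c * M^(1/3) with c = 0.066 nm/Da^(1/3) (minimal unhydrated protein
sphere), or are supplied explicitly (e.g. a hydrodynamically determined
radius for the Cp bulk-flow marker).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


class FullyOccupiedError(ValueError):
    """The bilayer plus cargo layer leaves no lumenal space."""


DEFAULT_BILAYER_NM = 4.0
DEFAULT_MW_RADIUS_COEFF = 0.066  # nm * Da^(-1/3), compact unhydrated sphere
DEFAULT_RELAXED_RATIO = 10.0  # R_av/r_cargo at the relaxed/stringent boundary

# Probe cargoes discussed with the model: the inert fluid-phase marker Cp
# (explicit radius; the hydrodynamic computation is external to this package)
# and a Kar2/client chaperone complex treated as a ~1 MDa sphere.
DEFAULT_CP_RADIUS_NM = 2.0
KAR2_COMPLEX_MW_DA = 1.0e6

# Median vesicle volumes (nm^3) used to place strains on the model axis.
# Only the emp24del lst1del value is a measured median; the emp24del value is
# implied by the printed 21% volume reduction of the double mutant relative
# to it, and the WT value is an assumption (never measured) — comparisons
# referenced to WT are therefore model-assumption-dependent.
LST1EMP24_MEDIAN_VOLUME_NM3 = 31_493.0
EMP24_MEDIAN_VOLUME_NM3 = LST1EMP24_MEDIAN_VOLUME_NM3 / 0.79  # ~39,865
WT_ASSUMED_MEDIAN_VOLUME_NM3 = 38_300.0  # ASSUMED


@dataclass(frozen=True)
class ModelParams:
    bilayer_thickness: float = DEFAULT_BILAYER_NM  # nm
    mw_radius_coefficient: float = DEFAULT_MW_RADIUS_COEFF  # nm * Da^(-1/3)

    def __post_init__(self) -> None:
        if self.bilayer_thickness <= 0 or self.mw_radius_coefficient <= 0:
            raise InputError("model parameters must be positive")


@dataclass(frozen=True)
class CargoSpecies:
    """One cargo species: size from molecular weight or an explicit radius."""

    name: str
    mw: float | None = None  # Da
    radius: float | None = None  # nm; overrides mw when present
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mw is None and self.radius is None:
            raise InputError(f"cargo {self.name!r} needs a molecular weight or a radius")
        if self.mw is not None and self.mw <= 0:
            raise InputError(f"cargo {self.name!r}: mw must be > 0")
        if self.radius is not None and self.radius < 0:
            raise InputError(f"cargo {self.name!r}: radius must be >= 0")
        if self.fraction < 0:
            raise InputError(f"cargo {self.name!r}: fraction must be >= 0")

    def effective_radius(self, params: ModelParams) -> float:
        if self.radius is not None:
            return self.radius
        return radius_from_mw(self.mw, params)


@dataclass(frozen=True)
class CargoMix:
    """A mixture of cargo species; fractions are normalized to sum to 1."""

    species: tuple[CargoSpecies, ...]

    def __init__(self, species: Sequence[CargoSpecies]):
        species = tuple(species)
        if len(species) < 1:
            raise InputError("a cargo mix needs at least one species")
        total = sum(s.fraction for s in species)
        if total <= 0:
            raise InputError("cargo fractions must sum to a positive value")
        object.__setattr__(
            self,
            "species",
            tuple(replace(s, fraction=s.fraction / total) for s in species),
        )


@dataclass(frozen=True)
class VesicleOccupancy:
    vesicle_radius: float  # nm
    lumenal_radius: float  # nm, vesicle_radius - bilayer
    layer_thickness: float  # nm, cargo layer
    available_radius: float  # nm, R_av
    available_volume: float  # nm^3, V_av = 4/3 pi R_av^3


@dataclass(frozen=True)
class PartitionResult:
    r_cargo: float  # nm
    effective_radius: float  # nm, R_eff = max(0, R_av - r_cargo)
    effective_volume: float  # nm^3, V_eff
    K: float  # in [0, 1]
    regimen: str  # relaxed | stringent | excluded


@dataclass(frozen=True)
class KGrid:
    R_av_axis: np.ndarray  # nm
    r_cargo_axis: np.ndarray  # nm
    K_matrix: np.ndarray  # shape (len(r_cargo_axis), len(R_av_axis))
    regimen_matrix: np.ndarray  # same shape, labels
    relaxed_ratio_threshold: float = DEFAULT_RELAXED_RATIO

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (R_av_nm, r_cargo_nm, K, regimen)."""
        rows = []
        for i, r in enumerate(self.r_cargo_axis):
            for j, R in enumerate(self.R_av_axis):
                rows.append(
                    {
                        "R_av_nm": float(R),
                        "r_cargo_nm": float(r),
                        "K": float(self.K_matrix[i, j]),
                        "regimen": str(self.regimen_matrix[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def radius_from_mw(mw: float, params: ModelParams = ModelParams()) -> float:
    """Compact-sphere radius (nm) from molecular weight: c * M^(1/3)."""
    if mw is None or mw <= 0:
        raise InputError("molecular weight must be > 0")
    return params.mw_radius_coefficient * mw ** (1.0 / 3.0)


def cargo_layer_thickness(mix: CargoMix, params: ModelParams = ModelParams()) -> float:
    """Fraction-weighted mean cargo *diameter* (nm): the cargo layer."""
    return sum(s.fraction * 2.0 * s.effective_radius(params) for s in mix.species)


def occupancy(
    vesicle_radius: float,
    mix: CargoMix,
    params: ModelParams = ModelParams(),
) -> VesicleOccupancy:
    """Subtract bilayer and cargo layer from the vesicle radius.

    The vesicle radius may be supplied directly or derived upstream as the
    sphere-equivalent radius of a median vesicle volume.
    """
    if vesicle_radius <= 0:
        raise InputError("vesicle_radius must be > 0")
    layer = cargo_layer_thickness(mix, params)
    lumenal = vesicle_radius - params.bilayer_thickness
    r_av = lumenal - layer
    if r_av <= 0:
        raise FullyOccupiedError(
            "fully occupied vesicle: bilayer "
            f"({params.bilayer_thickness:g} nm) + cargo layer ({layer:.3g} nm) "
            f"exceed the vesicle radius {vesicle_radius:.3g} nm by {-r_av:.3g} nm"
        )
    return VesicleOccupancy(
        vesicle_radius=float(vesicle_radius),
        lumenal_radius=float(lumenal),
        layer_thickness=float(layer),
        available_radius=float(r_av),
        available_volume=4.0 / 3.0 * math.pi * float(r_av) ** 3,
    )


def classify_regimen(
    r_cargo: float,
    R_av: float,
    relaxed_ratio_threshold: float = DEFAULT_RELAXED_RATIO,
) -> str:
    """relaxed / stringent / excluded for one (cargo, available-radius) pair."""
    if R_av <= 0:
        raise InputError("R_av must be > 0")
    if r_cargo >= R_av:
        return "excluded"
    if r_cargo == 0 or R_av / r_cargo >= relaxed_ratio_threshold:
        return "relaxed"
    return "stringent"


def partition_coefficient(
    r_cargo: float,
    R_av: float,
    relaxed_ratio_threshold: float = DEFAULT_RELAXED_RATIO,
) -> PartitionResult:
    """K = (1 - r_cargo/R_av)^3, clipped to 0 when r_cargo >= R_av."""
    if R_av <= 0:
        raise InputError("R_av must be > 0")
    if r_cargo < 0:
        raise InputError("r_cargo must be >= 0")
    r_eff = max(0.0, R_av - r_cargo)
    k = (r_eff / R_av) ** 3
    return PartitionResult(
        r_cargo=float(r_cargo),
        effective_radius=float(r_eff),
        effective_volume=4.0 / 3.0 * math.pi * r_eff**3,
        K=float(k),
        regimen=classify_regimen(r_cargo, R_av, relaxed_ratio_threshold),
    )


def k_grid(
    R_av_axis: Sequence[float],
    r_cargo_axis: Sequence[float],
    relaxed_ratio_threshold: float = DEFAULT_RELAXED_RATIO,
) -> KGrid:
    """Evaluate K and the regimen label on a (R_av, r_cargo) grid."""
    R = np.asarray(R_av_axis, dtype=float)
    r = np.asarray(r_cargo_axis, dtype=float)
    for axis, label in ((R, "R_av"), (r, "r_cargo")):
        if axis.size == 0:
            raise InputError(f"{label} axis is empty")
        if np.any(axis <= 0):
            raise InputError(f"{label} axis must be strictly positive")
        if axis.size > 1 and np.any(np.diff(axis) <= 0):
            raise InputError(f"{label} axis must be strictly increasing")
    K = np.clip(1.0 - r[:, None] / R[None, :], 0.0, None) ** 3
    regimen = np.empty(K.shape, dtype=object)
    for i, rc in enumerate(r):
        for j, Rv in enumerate(R):
            regimen[i, j] = classify_regimen(rc, Rv, relaxed_ratio_threshold)
    return KGrid(
        R_av_axis=R,
        r_cargo_axis=r,
        K_matrix=K,
        regimen_matrix=regimen,
        relaxed_ratio_threshold=relaxed_ratio_threshold,
    )


def plot_k_grid(grid: KGrid, path=None):
    """Flat heat map of K over the grid (returns the matplotlib figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.R_av_axis, grid.r_cargo_axis, grid.K_matrix, shading="nearest")
    fig.colorbar(mesh, ax=ax, label="K")
    ax.set_xlabel("available radius R_av (nm)")
    ax.set_ylabel("cargo radius r_cargo (nm)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Built-in mixes/probes and strain comparison
# ---------------------------------------------------------------------------


def default_cargo_mixes() -> dict[str, CargoMix]:
    """Coat-selected cargo mixes per strain.

    WT: 25% p24/GPI-AP complexes (100 kD) + 75% average secretory cargo
    (50 kD).  Strains lacking Emp24 lose the p24/GPI-AP class and keep only
    the model cargo.
    """
    p24 = CargoSpecies(name="p24/GPI-AP", mw=100_000.0, fraction=0.25)
    model = CargoSpecies(name="model cargo", mw=50_000.0, fraction=0.75)
    model_only = CargoMix([CargoSpecies(name="model cargo", mw=50_000.0, fraction=1.0)])
    return {
        "WT": CargoMix([p24, model]),
        "emp24": model_only,
        "sec13emp24": model_only,
        "lst1emp24": model_only,
    }


def default_probe_cargoes() -> list[CargoSpecies]:
    return [
        CargoSpecies(name="Cp", radius=DEFAULT_CP_RADIUS_NM, fraction=0.0),
        CargoSpecies(name="Kar2 complex", mw=KAR2_COMPLEX_MW_DA, fraction=0.0),
    ]


def default_strain_median_volumes() -> dict[str, float]:
    """Median vesicle volumes (nm^3) for the model axis; WT is ASSUMED."""
    return {
        "WT": WT_ASSUMED_MEDIAN_VOLUME_NM3,
        "emp24": EMP24_MEDIAN_VOLUME_NM3,
        "lst1emp24": LST1EMP24_MEDIAN_VOLUME_NM3,
    }


@dataclass(frozen=True)
class StrainComparison:
    occupancy: pd.DataFrame  # strain, vesicle_radius_nm, R_av_nm, V_av_nm3, pct_vs_reference
    partition: pd.DataFrame  # strain, cargo, r_cargo_nm, K, regimen, pct_K_vs_reference
    reference: str
    relaxed_ratio_threshold: float


def compare_strains(
    strain_vesicle_radii: Mapping[str, float],
    strain_mixes: Mapping[str, CargoMix],
    probe_cargoes: Sequence[CargoSpecies],
    params: ModelParams = ModelParams(),
    reference: str = "WT",
    relaxed_ratio_threshold: float = DEFAULT_RELAXED_RATIO,
) -> StrainComparison:
    """Per-strain available space and per-(strain, probe) partitioning.

    Reports R_av, V_av and the percent change of V_av vs the reference
    strain, and for each probe cargo the partition coefficient K with its
    percent change vs the reference strain.
    """
    if reference not in strain_vesicle_radii or reference not in strain_mixes:
        raise InputError(f"reference strain {reference!r} missing from the inputs")
    occ = {
        strain: occupancy(radius, strain_mixes[strain], params)
        for strain, radius in strain_vesicle_radii.items()
        if strain in strain_mixes
    }
    missing = set(strain_vesicle_radii) - set(strain_mixes)
    if missing:
        raise InputError(f"no cargo mix for strain(s): {sorted(missing)}")

    ref_occ = occ[reference]
    occ_rows = []
    for strain, o in occ.items():
        occ_rows.append(
            {
                "strain": strain,
                "vesicle_radius_nm": o.vesicle_radius,
                "lumenal_radius_nm": o.lumenal_radius,
                "cargo_layer_nm": o.layer_thickness,
                "R_av_nm": o.available_radius,
                "V_av_nm3": o.available_volume,
                "pct_V_av_vs_reference": 100.0
                * (o.available_volume - ref_occ.available_volume)
                / ref_occ.available_volume,
            }
        )

    part_rows = []
    for probe in probe_cargoes:
        r_probe = probe.effective_radius(params)
        ref_part = partition_coefficient(
            r_probe, ref_occ.available_radius, relaxed_ratio_threshold
        )
        for strain, o in occ.items():
            p = partition_coefficient(r_probe, o.available_radius, relaxed_ratio_threshold)
            pct = (
                100.0 * (p.K - ref_part.K) / ref_part.K if ref_part.K > 0 else math.nan
            )
            part_rows.append(
                {
                    "strain": strain,
                    "cargo": probe.name,
                    "r_cargo_nm": r_probe,
                    "K": p.K,
                    "regimen": p.regimen,
                    "pct_K_vs_reference": pct,
                }
            )
    return StrainComparison(
        occupancy=pd.DataFrame(occ_rows),
        partition=pd.DataFrame(part_rows),
        reference=reference,
        relaxed_ratio_threshold=relaxed_ratio_threshold,
    )
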