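"""Excluded-volume occupancy and partitioning model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesiclekit.occupancy import (
    CargoMix,
    CargoSpecies,
    FullyOccupiedError,
    InputError,
    ModelParams,
    cargo_layer_thickness,
    classify_regimen,
    compare_strains,
    default_cargo_mixes,
    default_probe_cargoes,
    k_grid,
    occupancy,
    partition_coefficient,
    radius_from_mw,
)

PARAMS = ModelParams()


class TestCargoSizes:
    @pytest.mark.parametrize(
        "mw, expected",
        [(50_000.0, 2.431), (100_000.0, 3.063), (1_000_000.0, 6.600)],
    )
    def test_compact_sphere_radii(self, mw, expected):
        assert radius_from_mw(mw) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(InputError):
            radius_from_mw(0.0)

    def test_explicit_radius_overrides_mw(self):
        sp = CargoSpecies(name="x", mw=50_000.0, radius=1.0)
        assert sp.effective_radius(PARAMS) == 1.0

    def test_species_needs_size(self):
        with pytest.raises(InputError):
            CargoSpecies(name="sizeless")


class TestCargoLayer:
    def test_wt_mix_weighted_diameter(self):
        assert cargo_layer_thickness(default_cargo_mixes()["WT"]) == pytest.approx(
            5.18, abs=0.01
        )

    def test_model_cargo_only(self):
        assert cargo_layer_thickness(default_cargo_mixes()["emp24"]) == pytest.approx(
            4.86, abs=0.01
        )

    def test_explicit_radius_species(self):
        mix = CargoMix([CargoSpecies(name="r3", radius=3.0, fraction=1.0)])
        assert cargo_layer_thickness(mix) == pytest.approx(6.0)

    def test_fractions_normalized(self):
        a = CargoMix([CargoSpecies(name="a", radius=2.0, fraction=1.0),
                      CargoSpecies(name="b", radius=4.0, fraction=3.0)])
        b = CargoMix([CargoSpecies(name="a", radius=2.0, fraction=7.0),
                      CargoSpecies(name="b", radius=4.0, fraction=21.0)])
        assert cargo_layer_thickness(a) == pytest.approx(cargo_layer_thickness(b))

    def test_empty_mix_rejected(self):
        with pytest.raises(InputError):
            CargoMix([])


class TestOccupancy:
    def test_printed_median_chain(self):
        # sphere-equivalent radius of 31,493 nm^3 -> lumen -> R_av
        occ = occupancy(19.590, default_cargo_mixes()["emp24"])
        assert occ.lumenal_radius == pytest.approx(15.59, abs=0.01)
        assert occ.available_radius == pytest.approx(10.73, abs=0.01)
        assert occ.available_volume == pytest.approx(5.17e3, rel=0.01)

    def test_point_cargo_layer(self):
        mix = CargoMix([CargoSpecies(name="point", radius=0.0, fraction=1.0)])
        occ = occupancy(26.0, mix)
        assert occ.available_radius == pytest.approx(22.0)
        assert occ.available_volume == pytest.approx(4 / 3 * math.pi * 22**3)

    def test_fully_occupied_error_names_deficit(self):
        with pytest.raises(FullyOccupiedError, match="fully occupied"):
            occupancy(4.5, default_cargo_mixes()["WT"])

    def test_conservation_chain(self):
        occ = occupancy(26.0, default_cargo_mixes()["WT"])
        part = partition_coefficient(2.0, occ.available_radius)
        vesicle_volume = 4 / 3 * math.pi * occ.vesicle_radius**3
        lumen_volume = 4 / 3 * math.pi * occ.lumenal_radius**3
        assert (
            part.effective_volume
            <= occ.available_volume
            <= lumen_volume
            <= vesicle_volume
        )


class TestPartitionCoefficient:
    def test_point_particle(self):
        assert partition_coefficient(0.0, 10.0).K == 1.0

    def test_boundary_exclusion(self):
        assert partition_coefficient(10.0, 10.0).K == 0.0
        assert partition_coefficient(12.0, 10.0).K == 0.0
        assert partition_coefficient(12.0, 10.0).regimen == "excluded"

    def test_half_ratio(self):
        assert partition_coefficient(6.6, 13.2).K == pytest.approx(0.125)

    @given(
        r=st.floats(0.0, 30.0, allow_nan=False),
        R=st.floats(0.1, 30.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_k_always_in_unit_interval(self, r, R):
        res = partition_coefficient(r, R)
        assert 0.0 <= res.K <= 1.0
        assert res.effective_volume <= 4 / 3 * math.pi * R**3 * (1 + 1e-9)
        if r >= R:
            assert res.K == 0.0
        if res.K == 0.0:
            assert r >= R * (1 - 1e-12)

    def test_strict_monotonicity(self):
        rs = np.linspace(0.5, 9.5, 40)
        ks = [partition_coefficient(r, 10.0).K for r in rs]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        Rs = np.linspace(5.0, 50.0, 40)
        ks = [partition_coefficient(4.0, R).K for R in Rs]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_relative_sensitivity_greater_for_larger_cargo(self):
        # within the stringent regimen, |dK/K| under the same R_av change is
        # larger for the larger cargo
        r_small, r_big, R0, R1 = 2.0, 6.6, 12.0, 13.0
        rel = lambda r: abs(
            partition_coefficient(r, R1).K / partition_coefficient(r, R0).K - 1.0
        )
        assert classify_regimen(r_big, R0) == "stringent"
        assert rel(r_big) > rel(r_small)


class TestRegimen:
    @pytest.mark.parametrize(
        "r, R, expected",
        [(1.0, 100.0, "relaxed"), (12.0, 10.0, "excluded"), (6.0, 12.0, "stringent"),
         (0.0, 5.0, "relaxed"), (1.0, 10.0, "relaxed"), (1.01, 10.0, "stringent")],
    )
    def test_default_threshold(self, r, R, expected):
        assert classify_regimen(r, R) == expected

    def test_threshold_configurable(self):
        assert classify_regimen(2.0, 10.0, relaxed_ratio_threshold=5.0) == "relaxed"


class TestKGrid:
    def test_hand_evaluated_cells(self):
        grid = k_grid([10.0, 20.0], [5.0])
        np.testing.assert_allclose(grid.K_matrix, [[0.125, 0.421875]])

    def test_monotone_along_r_av(self):
        grid = k_grid(np.linspace(5, 30, 26), np.linspace(0.5, 8, 16))
        assert np.all(np.diff(grid.K_matrix, axis=1) >= 0)
        assert np.all((grid.K_matrix >= 0) & (grid.K_matrix <= 1))

    def test_long_format_round_trip(self):
        grid = k_grid([10.0, 20.0], [2.0, 5.0])
        df = grid.to_frame()
        assert len(df) == 4
        assert set(df.columns) == {"R_av_nm", "r_cargo_nm", "K", "regimen"}

    def test_bad_axes_rejected(self):
        with pytest.raises(InputError):
            k_grid([], [5.0])
        with pytest.raises(InputError):
            k_grid([10.0, 9.0], [5.0])
        with pytest.raises(InputError):
            k_grid([-1.0, 5.0], [5.0])


class TestCompareStrains:
    def setup_method(self):
        self.mixes = default_cargo_mixes()
        self.probes = default_probe_cargoes()

    def test_identical_strains_zero_changes(self):
        radii = {"WT": 20.0, "twin": 20.0}
        mixes = {"WT": self.mixes["WT"], "twin": self.mixes["WT"]}
        cmp = compare_strains(radii, mixes, self.probes, reference="WT")
        assert np.allclose(cmp.occupancy["pct_V_av_vs_reference"], 0.0)
        assert np.allclose(cmp.partition["pct_K_vs_reference"], 0.0)

    def test_thinner_cargo_layer_increases_available_volume(self):
        radii = {"WT": 20.9, "emp24": 20.9}  # common vesicle radius
        cmp = compare_strains(radii, self.mixes, self.probes, reference="WT")
        occ = cmp.occupancy.set_index("strain")
        assert occ.loc["emp24", "V_av_nm3"] > occ.loc["WT", "V_av_nm3"]
        assert occ.loc["emp24", "pct_V_av_vs_reference"] > 0

    def test_large_probe_more_sensitive_than_small(self):
        radii = {"WT": 20.91, "emp24": 21.19}
        cmp = compare_strains(radii, self.mixes, self.probes, reference="WT")
        part = cmp.partition.set_index(["cargo", "strain"])
        d_large = abs(part.loc[("Kar2 complex", "emp24"), "pct_K_vs_reference"])
        d_small = abs(part.loc[("Cp", "emp24"), "pct_K_vs_reference"])
        assert d_large > d_small

    def test_rescaled_fractions_leave_table_unchanged(self):
        scaled = CargoMix(
            [CargoSpecies(name="p24/GPI-AP", mw=100_000.0, fraction=2.5),
             CargoSpecies(name="model cargo", mw=50_000.0, fraction=7.5)]
        )
        radii = {"WT": 20.9, "emp24": 21.2}
        base = compare_strains(radii, self.mixes, self.probes, reference="WT")
        alt = compare_strains(
            radii, {**self.mixes, "WT": scaled}, self.probes, reference="WT"
        )
        np.testing.assert_allclose(
            base.occupancy["V_av_nm3"], alt.occupancy["V_av_nm3"]
        )

    def test_missing_reference_rejected(self):
        with pytest.raises(InputError):
            compare_strains({"emp24": 20.0}, self.mixes, self.probes, reference="WT")
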