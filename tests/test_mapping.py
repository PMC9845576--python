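"""Dual-isotope mapping: Rayleigh line, solver round-trips, N2 back-calculation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from n2osource.endmembers import (
    DoubleAdjustmentError,
    Endmember,
    ReductionLine,
    default_endmembers,
)
from n2osource.mapping import (
    MapResult,
    SingularGeometryError,
    estimate_n2_flux,
    forward_mix_red,
    forward_red_mix,
    map_sample,
    rayleigh_residual,
    solve_mix_red,
    solve_red_mix,
)

EPS = ReductionLine(eps_sp=-5.9, eps_o=-15.4)


class TestEndmemberAdjustment:
    def test_water_shift_denitrifiers_only(self):
        ems, _ = default_endmembers()
        adj = ems.adjust_for_water(-8.5)
        for p in ("bD", "fD", "nD"):
            assert adj[p].d18o == pytest.approx(ems[p].d18o - 8.5)
            assert adj[p].sp == ems[p].sp
        assert adj["Ni"].d18o == ems["Ni"].d18o

    def test_zero_water_identity(self):
        ems, _ = default_endmembers()
        adj = ems.adjust_for_water(0.0)
        assert all(adj[p].d18o == ems[p].d18o for p in ("bD", "fD", "nD", "Ni"))

    def test_double_adjustment_raises(self):
        ems, _ = default_endmembers()
        with pytest.raises(DoubleAdjustmentError):
            ems.adjust_for_water(-8.5).adjust_for_water(-8.5)

    def test_table_hash_tracks_content(self):
        ems, _ = default_endmembers()
        assert ems.table_hash != ems.adjust_for_water(-8.5).table_hash

    def test_reduction_line_invariants(self):
        assert EPS.slope > 0
        with pytest.raises(ValueError):
            ReductionLine(eps_sp=5.0, eps_o=-15.0)


class TestRayleigh:
    def test_identity_at_r_one(self):
        assert rayleigh_residual(-1.6, 9.0, EPS, 1.0) == (-1.6, 9.0)

    def test_ln_r_scaling(self):
        eps = ReductionLine(eps_sp=-5.0, eps_o=-15.0)
        sp, _ = rayleigh_residual(0.0, 0.0, eps, math.exp(-1.0))
        assert sp == pytest.approx(5.0, abs=1e-12)

    def test_path_slope_constant(self):
        for r in (0.9, 0.5, 0.1, 0.01):
            sp, o = rayleigh_residual(0.0, 0.0, EPS, r)
            assert sp / o == pytest.approx(EPS.slope, rel=1e-12)

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            rayleigh_residual(0.0, 0.0, EPS, 0.0)


BD = Endmember(-1.6, 3.5, 9.0, 4.6)
FD = Endmember(35.1, 3.1, 31.3, 4.0)
NI = Endmember(31.4, 4.2, 35.6, 5.0)


class TestSolvers:
    @pytest.mark.parametrize("minor", [FD, NI], ids=["fD", "Ni"])
    @pytest.mark.parametrize(
        "f, r", [(0.85, 0.09), (0.88, 0.11), (0.5, 0.5), (0.97, 0.02), (0.1, 0.9)]
    )
    def test_red_mix_round_trip(self, minor, f, r):
        sample = forward_red_mix(f, r, BD, minor, EPS)
        res = solve_red_mix(sample, BD, minor, EPS)
        assert res.f_bd == pytest.approx(f, abs=1e-6)
        assert res.r_n2o == pytest.approx(r, abs=1e-6)
        assert not res.flags

    @pytest.mark.parametrize("minor", [FD, NI], ids=["fD", "Ni"])
    @pytest.mark.parametrize(
        "f, r", [(0.88, 0.11), (0.85, 0.09), (0.3, 0.6), (0.99, 0.05)]
    )
    def test_mix_red_round_trip(self, minor, f, r):
        sample = forward_mix_red(f, r, BD, minor, EPS)
        res = solve_mix_red(sample, BD, minor, EPS)
        assert res.f_bd == pytest.approx(f, abs=1e-6)
        assert res.r_n2o == pytest.approx(r, abs=1e-6)
        assert not res.flags

    @given(
        st.floats(min_value=0.05, max_value=0.999),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_round_trip_property(self, f, r):
        sample = forward_red_mix(f, r, BD, FD, EPS)
        res = solve_red_mix(sample, BD, FD, EPS)
        # r is unconstrained when f -> 0; weight by identifiability
        assert res.f_bd == pytest.approx(f, abs=1e-5)
        if f > 0.1:
            assert res.r_n2o == pytest.approx(r, abs=1e-4)

    def test_pure_bd_limit(self):
        sample = rayleigh_residual(BD.sp, BD.d18o, EPS, 0.1)
        res = solve_red_mix(sample, BD, FD, EPS)
        assert res.f_bd == pytest.approx(1.0, abs=1e-9)
        assert res.r_n2o == pytest.approx(0.1, abs=1e-9)

    def test_pure_minor_degenerate(self):
        res = solve_red_mix((FD.sp, FD.d18o), BD, FD, EPS)
        assert res.f_bd == 0.0 and res.r_n2o == 1.0
        assert res.flags  # r unidentifiable

    def test_sample_on_mixing_segment(self):
        sp = 0.4 * BD.sp + 0.6 * FD.sp
        o = 0.4 * BD.d18o + 0.6 * FD.d18o
        res = solve_mix_red((sp, o), BD, FD, EPS)
        assert res.r_n2o == pytest.approx(1.0, abs=1e-9)
        assert res.f_bd == pytest.approx(0.4, abs=1e-9)

    def test_equal_endmembers_singular(self):
        with pytest.raises(SingularGeometryError):
            solve_mix_red((10.0, 10.0), BD, BD, EPS)

    def test_out_of_domain_clipped_and_flagged(self):
        # sample below the mixing segment in the anti-reduction direction
        sample = (BD.sp - 10.0, BD.d18o - 20.0)
        res = solve_mix_red(sample, BD, FD, EPS)
        assert res.flags
        assert 0.0 <= res.f_bd <= 1.0 and 0.0 < res.r_n2o <= 1.0

    def test_f_bd_is_case_independent(self):
        # both cases share the same linear relation for f, which is why
        # campaign tables report one f_bD per scenario across cases
        sample = forward_red_mix(0.8, 0.2, BD, FD, EPS)
        f_red = solve_red_mix(sample, BD, FD, EPS).f_bd
        f_mix = solve_mix_red(sample, BD, FD, EPS).f_bd
        assert f_red == pytest.approx(f_mix, abs=1e-9)


class TestN2Flux:
    def test_zero_at_r_one(self):
        res = MapResult("bD_fD", "red_mix", 0.9, 1.0)
        assert estimate_n2_flux(res, 1.7).n2_flux == 0.0

    def test_red_mix_only_bd_stream_reduced(self):
        res = MapResult("bD_fD", "red_mix", 0.85, 0.09)
        assert estimate_n2_flux(res, 1.7).n2_flux == pytest.approx(14.61, abs=0.01)

    def test_mix_red_whole_mixture_reduced(self):
        res = MapResult("bD_fD", "mix_red", 0.85, 0.13)
        assert estimate_n2_flux(res, 1.7).n2_flux == pytest.approx(11.38, abs=0.01)

    def test_monotonicity(self):
        n2 = [
            estimate_n2_flux(MapResult("s", "mix_red", 0.9, r), 1.0).n2_flux
            for r in (0.05, 0.1, 0.2, 0.5, 1.0)
        ]
        assert all(a > b for a, b in zip(n2, n2[1:]))
        n2f = [
            estimate_n2_flux(MapResult("s", "red_mix", f, 0.1), 1.0).n2_flux
            for f in (0.2, 0.5, 0.9)
        ]
        assert all(a < b for a, b in zip(n2f, n2f[1:]))

    def test_rejects_zero_r(self):
        with pytest.raises(ValueError):
            estimate_n2_flux(MapResult("s", "red_mix", 0.9, 0.0), 1.0)


class TestMapSample:
    def test_four_cells_per_sample(self, adjusted_endmembers):
        ems, eps = adjusted_endmembers
        sample = forward_red_mix(0.87, 0.1, ems["bD"], ems["fD"], eps)
        cells = map_sample(sample, ems, eps, n2o_flux=1.7)
        assert len(cells) == 4
        combos = {(c.result.scenario, c.result.case) for c in cells}
        assert combos == {
            ("bD_fD", "red_mix"), ("bD_fD", "mix_red"),
            ("bD_Ni", "red_mix"), ("bD_Ni", "mix_red"),
        }
        for c in cells:
            assert c.result.f_minor == pytest.approx(1.0 - c.result.f_bd)
            assert c.n2 is not None

    def test_requires_water_adjusted_table(self):
        ems, eps = default_endmembers()
        with pytest.raises(ValueError):
            map_sample((20.0, 40.0), ems, eps)

    def test_case_ordering_of_r(self, adjusted_endmembers):
        # a sample above the mixing segment: the mix_red r exceeds the
        # red_mix r (the whole mixture needs less reduction than the bD
        # stream alone), reproducing the campaign-table ordering
        ems, eps = adjusted_endmembers
        sample = forward_red_mix(0.85, 0.09, ems["bD"], ems["fD"], eps)
        cells = {(c.result.scenario, c.result.case): c.result
                 for c in map_sample(sample, ems, eps)}
        assert cells[("bD_fD", "mix_red")].r_n2o > cells[("bD_fD", "red_mix")].r_n2o

    def test_synthetic_campaign_recovery(self, adjusted_endmembers, rng):
        from n2osource.synthetic import TruthConfig, simulate_emitted_isotopes

        ems, eps = adjusted_endmembers
        truth = TruthConfig(f_bd=0.87, r_n2o=0.10)
        pts = simulate_emitted_isotopes(truth, 50, rng)
        f_all, r_all = [], []
        for sp, o in pts:
            for c in map_sample((sp, o), ems, eps):
                f_all.append(c.result.f_bd)
                if c.result.case == "red_mix":
                    r_all.append(c.result.r_n2o)
        assert np.mean(f_all) == pytest.approx(0.87, abs=0.05)
        assert np.mean(r_all) == pytest.approx(0.10, abs=0.02)
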