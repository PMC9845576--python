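"""15N tracing: two-pool inversion, mixing partition, flux split."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from n2osource.constants import A15_NATURAL
from n2osource.partitioning import (
    atmospheric_correction_fraction,
    emitted_atom_fraction,
    f_from_mixing,
    forward_two_pool,
    isotopologue_ratios,
    n_classes_from_ratios,
    nd_cnd_fraction,
    partition_flux,
    two_pool_from_ratios,
    two_pool_nonequilibrium,
)

A_BGD = 0.0036630


class TestTwoPoolInversion:
    def test_single_labeled_pool(self):
        res = two_pool_nonequilibrium(0.03, 0.03**2, A_BGD)
        assert res.ap == pytest.approx(0.03, abs=1e-12)
        assert res.x == pytest.approx(1.0, abs=1e-12)

    def test_worked_example(self):
        a_m, m2 = forward_two_pool(0.4, 0.03, A_BGD)
        res = two_pool_nonequilibrium(a_m, m2, A_BGD)
        assert res.ap == pytest.approx(0.03, abs=1e-10)
        assert res.x == pytest.approx(0.4, abs=1e-10)

    def test_no_label_below_detection(self):
        res = two_pool_nonequilibrium(A_BGD, A_BGD**2, A_BGD)
        assert res.below_detection

    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=0.004, max_value=0.11),
    )
    def test_exact_inverse_over_grid(self, x, ap):
        a_m, m2 = forward_two_pool(x, ap, A_BGD)
        res = two_pool_nonequilibrium(a_m, m2, A_BGD)
        assert res.ap == pytest.approx(ap, abs=1e-10)
        assert res.x == pytest.approx(x, abs=1e-10)


class TestIsotopologueRatios:
    @pytest.mark.parametrize("d18o", [-10.0, 0.0, 44.5, 90.0])
    def test_ratio_round_trip(self, d18o):
        a_m, m2 = forward_two_pool(0.35, 0.05, A_BGD)
        r45, r46 = isotopologue_ratios(a_m, m2, d18o)
        a_back, m2_back = n_classes_from_ratios(r45, r46, d18o)
        assert a_back == pytest.approx(a_m, abs=1e-14)
        assert m2_back == pytest.approx(m2, abs=1e-14)

    def test_natural_abundance_ratios_plausible(self):
        # 45R of tropospheric N2O is ~0.0077-0.0078 (2x 15R + 17R)
        r45, r46 = isotopologue_ratios(A15_NATURAL, A15_NATURAL**2, 44.5)
        assert r45 == pytest.approx(0.00778, abs=5e-5)
        assert r46 == pytest.approx(0.0021, abs=1e-4)

    def test_full_chain_from_ratios(self):
        a_m, m2 = forward_two_pool(0.6, 0.028, A_BGD)
        res = two_pool_from_ratios(*isotopologue_ratios(a_m, m2, 44.5), 44.5, A_BGD)
        assert res.ap == pytest.approx(0.028, abs=1e-10)
        assert res.x == pytest.approx(0.6, abs=1e-10)


class TestAtmosphericRescaling:
    def test_no_background(self):
        f, flags = atmospheric_correction_fraction(0.3, 600.0, 0.0)
        assert f == pytest.approx(0.3) and not flags

    def test_hand_arithmetic(self):
        f, _ = atmospheric_correction_fraction(0.3, 600.0, 300.0)
        assert f == pytest.approx(0.6)

    def test_zero_is_zero(self):
        f, _ = atmospheric_correction_fraction(0.0, 600.0, 300.0)
        assert f == 0.0

    def test_clip_and_flag(self):
        f, flags = atmospheric_correction_fraction(0.8, 400.0, 300.0)
        assert f == 1.0 and flags

    def test_emitted_atom_fraction_inverts_mixing(self):
        a_e, c_e, c_a = 0.02, 250.0, 300.0
        a_mix = (c_e * a_e + c_a * A15_NATURAL) / (c_e + c_a)
        back = emitted_atom_fraction(a_mix, c_e + c_a, A15_NATURAL, c_a)
        assert back == pytest.approx(a_e, abs=1e-14)


class TestMixingPartition:
    def test_endpoint_identities(self):
        assert f_from_mixing(0.05, 0.05, 0.002)[0] == pytest.approx(1.0)
        assert f_from_mixing(0.002, 0.05, 0.002)[0] == pytest.approx(0.0)

    def test_nh4_labeled_example(self):
        f, _ = f_from_mixing(0.02, 0.003663, 0.0659)
        assert f == pytest.approx(0.7375, abs=0.001)

    def test_brute_force_two_pool_mixture(self):
        a_no3, a_nh4, f_true = 0.0037, 0.0659, 0.42
        a_n2o = f_true * a_no3 + (1 - f_true) * a_nh4
        f, flags = f_from_mixing(a_n2o, a_no3, a_nh4)
        assert f == pytest.approx(f_true, abs=1e-12) and not flags

    def test_degenerate_pools(self):
        with pytest.raises(ValueError):
            f_from_mixing(0.01, 0.05, 0.05)

    def test_agreement_with_nonequilibrium_route(self):
        # single labeled pool: Eq-style mixing and the isotopologue
        # route must partition identically
        ap, x = 0.033, 0.55
        a_m, m2 = forward_two_pool(x, ap, A_BGD)
        res = two_pool_nonequilibrium(a_m, m2, A_BGD)
        f_mix, _ = f_from_mixing(a_m, res.ap, A_BGD)
        assert f_mix == pytest.approx(res.x, abs=1e-9)


class TestFluxPartition:
    def test_all_no3(self):
        p = partition_flux(1.0, 3.0)
        assert p.no3_derived_flux == 3.0 and p.nh4_derived_flux == 0.0

    def test_even_split(self):
        p = partition_flux(0.5, 2.0)
        assert p.no3_derived_flux == 1.0 and p.nh4_derived_flux == 1.0

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=50.0),
    )
    def test_components_sum_to_total(self, f, total):
        p = partition_flux(f, total)
        assert p.no3_derived_flux + p.nh4_derived_flux == pytest.approx(total)

    def test_synthetic_split_recovery(self, rng):
        from n2osource.synthetic import TruthConfig, simulate_label_dynamics

        truth = TruthConfig(label_form="NH4_15", f_pn2o=0.7)
        fs = []
        for _ in range(12):
            sim = simulate_label_dynamics(truth, rng)
            gas = sim.gas.iloc[0]
            pools = sim.pools[sim.pools["time_h"] == 4.0].iloc[0]
            a_no3 = A15_NATURAL + pools["no3_ape_pct"] / 100.0
            a_nh4 = A15_NATURAL + pools["nh4_ape_pct"] / 100.0
            a_emit = emitted_atom_fraction(
                gas["a15_mixture"], gas["conc_ppb"], A15_NATURAL, gas["ambient_ppb"]
            )
            fs.append(f_from_mixing(a_emit, a_no3, a_nh4)[0])
        assert np.mean(fs) == pytest.approx(0.7, abs=0.03)


class TestNdCndFraction:
    def test_zero_difference(self):
        assert nd_cnd_fraction(0.7, 0.7)[0] == 0.0

    def test_typical_difference(self):
        d, flags = nd_cnd_fraction(0.87, 0.68)
        assert d == pytest.approx(0.19, abs=1e-12) and not flags

    def test_negative_flagged(self):
        d, flags = nd_cnd_fraction(0.6, 0.8)
        assert d == pytest.approx(-0.2) and flags

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            nd_cnd_fraction(1.2, 0.5)
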