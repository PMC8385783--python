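import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pullpush import (
    EffectiveRates,
    Parameters,
    State,
    default_parameters,
    effective_rates,
    rhs,
    saturating_transfer,
)

BASELINE = effective_rates(Parameters(), "none", "post")


class TestParameters:
    def test_defaults_are_the_published_set(self):
        p = default_parameters()
        assert p.k_periin_psd == 0.001
        assert p.k_psd_periout == 0.004
        assert p.k_peri_endo == p.k_endo_peri == pytest.approx(1 / 50)
        assert p.k_ua_endo == p.k_endo_ua == pytest.approx(1 / 20)
        assert p.t_psd == 1.0
        assert p.t_ua == p.t_peri_in == p.t_peri_out == 0.2
        assert p.km2_kin == p.km2_pp == 0.1
        assert (p.k_kin, p.k_pp) == (0.25, 0.1)
        assert (p.f_ltp_kin, p.f_ltd_pp) == (1000.0, 400.0)
        assert p.gs_factors == (100.0, 10.0, 4.5)
        assert p.gq_factors == (10.0, 100.0, 2.0)
        assert (p.t_mod, p.t_ind, p.t_total) == (9.0, 2.0, 50.0)

    def test_enzyme_sources_pinned_to_relaxation_rates(self):
        p = Parameters(k_kin=0.5, k_pp=0.02)
        assert p.s_kin == 0.5 and p.s_pp == 0.02

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_psd": 0.0},
            {"t_peri_in": -0.1},
            {"k_periin_psd": -1e-3},
            {"km2_kin": 0.0},
            {"f_ltp_kin": 0.5},
            {"t_mod": -1.0},
            {"t_mod": 40.0, "t_ind": 20.0},
            {"w_ua": 1.5},
            {"tau_smooth": -0.1},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Parameters(**kwargs)


class TestSaturatingTransfer:
    @pytest.mark.parametrize(
        "a,km2,expected",
        [(0.0, 0.1, 0.0), (0.1, 0.1, pytest.approx(0.05)),
         (1e9, 0.1, pytest.approx(0.1, rel=1e-8))],
    )
    def test_known_values(self, a, km2, expected):
        assert saturating_transfer(a, km2) == expected

    def test_negative_occupancy_rejected(self):
        with pytest.raises(ValueError):
            saturating_transfer(-0.01, 0.1)
        with pytest.raises(ValueError):
            saturating_transfer(0.1, 0.0)

    @given(
        a1=st.floats(0, 100, allow_nan=False),
        a2=st.floats(0, 100, allow_nan=False),
        km2=st.floats(1e-3, 10, allow_nan=False),
    )
    def test_bounded_and_monotone(self, a1, a2, km2):
        f1, f2 = saturating_transfer(a1, km2), saturating_transfer(a2, km2)
        assert 0 <= f1 <= km2
        if a1 <= a2:
            assert f1 <= f2 + 1e-15


class TestEffectiveRates:
    def test_gs_scales_exocytic_rates_during_modulation(self):
        r = effective_rates(Parameters(), "gs", "modulation")
        assert r.endo_periin == pytest.approx(2.0)        # 0.02 * 100
        assert r.endo_periout == pytest.approx(0.2)       # 0.02 * 10
        assert r.endo_ua == pytest.approx(0.225)          # 0.05 * 4.5
        assert r.periin_endo == BASELINE.periin_endo      # endocytic side untouched

    def test_gq_scales_endocytic_rates_during_induction(self):
        r = effective_rates(Parameters(), "gq", "induction")
        assert r.periin_endo == pytest.approx(0.2)        # 0.02 * 10
        assert r.periout_endo == pytest.approx(2.0)       # 0.02 * 100
        assert r.ua_endo == pytest.approx(0.1)            # 0.05 * 2
        assert r.endo_periin == BASELINE.endo_periin

    def test_coactivation_applies_both_factor_sets(self):
        r = effective_rates(Parameters(), "gs+gq", "modulation")
        assert r.endo_periin == pytest.approx(2.0)
        assert r.periout_endo == pytest.approx(2.0)

    def test_no_agonist_equals_baseline_everywhere(self):
        for phase in ("modulation", "induction", "post"):
            assert effective_rates(Parameters(), "none", phase) == BASELINE

    def test_post_phase_reverts_to_baseline_for_any_agonist(self):
        for agonist in ("gs", "gq", "gs+gq"):
            assert effective_rates(Parameters(), agonist, "post") == BASELINE

    def test_psd_fluxes_never_modulated(self):
        for agonist in ("gs", "gq", "gs+gq"):
            r = effective_rates(Parameters(), agonist, "modulation")
            assert r.periin_psd == 0.001 and r.psd_periout == 0.004

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            effective_rates(Parameters(), "purple", "modulation")
        with pytest.raises(ValueError):
            effective_rates(Parameters(), "gs", "washout")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            EffectiveRates(0.001, 0.004, -0.02, 0.02, 0.02, 0.02, 0.05, 0.05)


occupancy_states = st.builds(
    State,
    a_psd=st.floats(0, 1, allow_nan=False),
    a_peri_in=st.floats(0, 0.2, allow_nan=False),
    a_peri_out=st.floats(0, 0.2, allow_nan=False),
    a_ua=st.floats(0, 0.2, allow_nan=False),
    kin=st.floats(0, 1000, allow_nan=False),
    pp=st.floats(0, 400, allow_nan=False),
)


class TestRhs:
    def test_enzyme_derivatives_from_printed_constants(self):
        p = Parameters()
        s = State(0.3, 0.1, 0.1, 0.1, kin=1000.0, pp=1.0)
        d = rhs(s, p, BASELINE)
        assert d.kin == pytest.approx(-249.75)  # -0.25*1000 + 0.25
        assert d.pp == 0.0                      # pp at rest stays put

    def test_resting_enzymes_are_stationary(self):
        d = rhs(State(0.3, 0.1, 0.1, 0.1, 1.0, 1.0), Parameters(), BASELINE)
        assert d.kin == 0.0 and d.pp == 0.0

    @given(s=occupancy_states)
    def test_psd_flux_antisymmetry(self, s):
        """Receptors leaving a peri pool through a PSD flux all land in the
        PSD: the membrane triplet only gains/loses via Endo exchange."""
        p = Parameters()
        d = rhs(s, p, BASELINE)
        triplet = d.a_peri_in + d.a_psd + d.a_peri_out
        endo_terms = (
            -BASELINE.periin_endo * s.a_peri_in
            + BASELINE.endo_periin * (p.t_peri_in - s.a_peri_in)
            - BASELINE.periout_endo * s.a_peri_out
            + BASELINE.endo_periout * (p.t_peri_out - s.a_peri_out)
        )
        assert triplet == pytest.approx(endo_terms, abs=1e-15)

    @given(s=occupancy_states)
    def test_derivative_points_inward_at_capacity_boundaries(self, s):
        from dataclasses import replace

        p = Parameters()
        caps = {"a_psd": p.t_psd, "a_peri_in": p.t_peri_in,
                "a_peri_out": p.t_peri_out, "a_ua": p.t_ua}
        for name, cap in caps.items():
            d_full = rhs(replace(s, **{name: cap}), p, BASELINE)
            assert getattr(d_full, name) <= 1e-15
            d_empty = rhs(replace(s, **{name: 0.0}), p, BASELINE)
            assert getattr(d_empty, name) >= -1e-15

    @given(s=occupancy_states)
    def test_enzyme_dynamics_autonomous(self, s):
        """Kinase/phosphatase relaxation ignores occupancies and agonists."""
        p = Parameters()
        for agonist in ("none", "gs", "gq", "gs+gq"):
            r = effective_rates(p, agonist, "modulation")
            d = rhs(s, p, r)
            assert d.kin == p.s_kin - p.k_kin * s.kin
            assert d.pp == p.s_pp - p.k_pp * s.pp

    def test_empty_membrane_only_fills_from_endo(self):
        p = Parameters()
        d = rhs(State(0.0, 0.0, 0.0, 0.0, 1.0, 1.0), p, BASELINE)
        assert d.a_psd == 0.0
        assert d.a_peri_in == pytest.approx(BASELINE.endo_periin * p.t_peri_in)
        assert d.a_ua == pytest.approx(BASELINE.endo_ua * p.t_ua)
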