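import numpy as np
import pytest

from hjsmc.currents import (STOICHIOMETRY, CurrentBreakdown, channel_current,
                            leak_current, nak_current, ncx_current, nernst,
                            total_ionic_current)
from hjsmc.fixtures import random_operating_points
from hjsmc.homeostasis import concentration_derivatives
from hjsmc.parameters import FARADAY, R_GAS, load_parameters
from hjsmc.state import initial_state


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst(1, 5.4, 5.4) == 0.0

    def test_doubling_valence_halves_magnitude(self):
        assert nernst(2, 1.0, 10.0) == pytest.approx(nernst(1, 1.0, 10.0) / 2)

    def test_potassium_closed_form(self, params):
        """E_K for the default ionic conditions against a direct
        RT/F ln(c_out/c_in) recomputation."""
        ki = params.initial["K_i"]
        expected = R_GAS * 310.0 / FARADAY * np.log(params.K_o / ki)
        assert nernst(1, ki, params.K_o, 310.0) == pytest.approx(
            expected, abs=1e-9)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            nernst(1, 0.0, 5.4)
        with pytest.raises(ValueError):
            nernst(0, 1.0, 1.0)


class TestChannelCurrent:
    def test_reversal_and_closed_channel(self):
        assert channel_current(2.0, 0.5, -85.0, -85.0) == 0.0
        assert channel_current(2.0, 0.0, 0.0, -85.0) == 0.0

    def test_linear_in_conductance(self):
        a = channel_current(1.0, 0.3, -40.0, -85.0)
        assert channel_current(2.0, 0.3, -40.0, -85.0) == pytest.approx(2 * a)


class TestLeak:
    def test_reverses_at_zero_millivolts(self, params):
        assert leak_current(0.0, params) == (0.0, 0.0)

    def test_inward_at_rest(self, params):
        na, k = leak_current(-60.0, params)
        assert na + k < 0

    def test_total_leak_at_least_45_fold_below_gkv(self, params):
        assert params.G_NaLeak + params.G_KLeak <= params.G_Kv / 45.0


class TestNaK:
    def test_zero_scale_gives_zero(self, params):
        p = params.with_overrides({"pumps": {"P_NaK": 0.0}})
        assert nak_current(-60.0, 10.0, 5.4, p) == 0.0

    def test_monotone_in_intracellular_sodium(self, params):
        vals = [nak_current(-60.0, na, 5.4, params)
                for na in np.linspace(1.0, 40.0, 50)]
        assert np.all(np.diff(vals) > 0)

    def test_positive_at_resting_conditions(self, params):
        assert nak_current(-60.0, 9.0, params.K_o, params) > 0


class TestNCX:
    def test_zero_scale_gives_zero(self, params):
        p = params.with_overrides({"pumps": {"k_NCX": 0.0}})
        assert ncx_current(-60.0, 9.0, 1e-4, p) == 0.0

    def test_raising_calcium_moves_toward_extrusion(self, params):
        """Ten-fold more free Ca2+ at fixed V, Na_i pushes the exchanger
        toward Ca2+-extrusion mode (more inward current)."""
        lo = ncx_current(-60.0, 9.0, 1e-4, params)
        hi = ncx_current(-60.0, 9.0, 1e-3, params)
        assert hi < lo

    def test_matches_independent_transcription(self, params):
        """The implementation against a separately written transcription of
        the ten Tusscher exchanger expression, on 20 random points."""
        nn = params.nak_ncx
        rtf = params.RTF
        pts = random_operating_points(seed=11, n=20)
        for _, row in pts.iterrows():
            v, nai, caf = row.V, row.Na_i, row.Ca_free
            g = nn["gamma"]
            num = (np.exp(g * v / rtf) * nai ** 3 * params.Ca_o
                   - np.exp((g - 1) * v / rtf) * params.Na_o ** 3 * caf
                   * nn["alpha_NCX"])
            den = ((nn["K_mNai"] ** 3 + params.Na_o ** 3)
                   * (nn["K_mCa"] + params.Ca_o)
                   * (1 + nn["k_sat"] * np.exp((g - 1) * v / rtf)))
            ref = params.k_NCX * num / den
            assert ncx_current(v, nai, caf, params) == pytest.approx(
                ref, rel=1e-10)


class TestTotalCurrent:
    def test_breakdown_sums_to_total(self, params):
        st = initial_state(params, V0=-55.0)
        cb = total_ionic_current(st, params)
        manual = (cb.I_CaL + cb.I_CaT + cb.I_Kv + cb.I_BK + cb.I_Na
                  + cb.I_NaK + cb.I_NCX + cb.I_NaLeak + cb.I_KLeak)
        assert cb.I_total == pytest.approx(manual, abs=1e-9)

    def test_all_scales_zero_gives_zero_total(self):
        p = load_parameters({"conductances": {
            "G_CaL": 1e-12, "G_CaT": 1e-12, "G_Kv": 1e-12, "G_BK": 1e-12,
            "G_Na": 1e-12, "G_NaLeak": 1e-14, "G_KLeak": 1e-14},
            "pumps": {"P_NaK": 0.0, "k_NCX": 0.0}})
        st = initial_state(p, V0=-60.0)
        assert abs(total_ionic_current(st, p).I_total) < 1e-9

    def test_component_functions_agree_with_breakdown(self, params):
        st = initial_state(params, V0=-60.0)
        cb = total_ionic_current(st, params)
        assert cb.I_NaK == pytest.approx(
            nak_current(st.V_m, st.Na_i, params.K_o, params), rel=1e-12)
        assert cb.I_NCX == pytest.approx(
            ncx_current(st.V_m, st.Na_i, st.free_calcium(params), params),
            rel=1e-12)
        assert (cb.I_NaLeak, cb.I_KLeak) == leak_current(st.V_m, params)


class TestChargeBookkeeping:
    def test_every_current_assigned_once_with_stated_stoichiometry(self):
        """Each species-carrying current appears in exactly one
        concentration ODE; the pump moves 3 Na+ out / 2 K+ in and the
        exchanger 3 Na+ in / 1 Ca2+ out per unit charge."""
        assert STOICHIOMETRY["I_NaK"] == {"Na": 3.0, "K": -2.0}
        assert STOICHIOMETRY["I_NCX"] == {"Na": 3.0, "Ca": -2.0}
        species_of = {"I_CaL": "Ca", "I_CaT": "Ca", "I_Kv": "K", "I_BK": "K",
                      "I_Na": "Na", "I_NaLeak": "Na", "I_KLeak": "K"}
        for name, sp in species_of.items():
            assert STOICHIOMETRY[name] == {sp: 1.0}

    @pytest.mark.parametrize("name", sorted(STOICHIOMETRY))
    def test_derivatives_implement_stoichiometry_table(self, params, name):
        """Unit current in one term must change each species' pool by
        exactly -factor/(z F V_c), matching the table entry."""
        kwargs = {k: 0.0 for k in STOICHIOMETRY}
        kwargs[name] = 1.0
        cb = CurrentBreakdown(**kwargs)
        dca, dna, dk = concentration_derivatives(cb, params)
        conv = 1e-15 / (params.F * params.V_c)
        got = {"Ca": dca / (conv / 2.0), "Na": dna / conv, "K": dk / conv}
        for sp, factor in STOICHIOMETRY[name].items():
            assert got[sp] == pytest.approx(-factor, rel=1e-12)
        for sp in set(got) - set(STOICHIOMETRY[name]):
            assert got[sp] == 0.0

    def test_junctional_current_enters_potassium_pool(self, params):
        cb = CurrentBreakdown(**{k: 0.0 for k in STOICHIOMETRY})
        dca, dna, dk = concentration_derivatives(cb, params, I_stim=1.0)
        conv = 1e-15 / (params.F * params.V_c)
        assert dk == pytest.approx(conv, rel=1e-12)
        assert dca == 0.0 and dna == 0.0
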