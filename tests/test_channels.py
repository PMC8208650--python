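"""Channel kinetics and membrane-derivative checks against hand oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetagate import channels as ch


# --- independent re-evaluation of the published rate functions -------------
# Written out long-hand on purpose: this block is the oracle the package
# implementation is compared against and must not share code with it.

def oracle_stellate_rates(v):
    am = -0.1 * (v + 23) / (math.exp(-0.1 * (v + 23)) - 1)
    bm = 4 * math.exp(-(v + 48) / 18)
    ah = 0.07 * math.exp(-(v + 37) / 20)
    bh = 1 / (math.exp(-0.1 * (v + 7)) + 1)
    an = -0.01 * (v + 27) / (math.exp(-0.1 * (v + 27)) - 1)
    bn = 0.125 * math.exp(-(v + 37) / 80)
    ms_inf = 1 / (1 + math.exp(-(v + 38) / 6.5))
    mhf_inf = 1 / (1 + math.exp((v + 79.2) / 9.78))
    tau_mhf = 0.51 / (math.exp((v - 1.7) / 10) + math.exp(-(v + 340) / 52)) + 1
    mhs_inf = (1 / (1 + math.exp((v + 2.83) / 15.9))) ** 58
    tau_mhs = 5.6 / (math.exp((v - 1.7) / 14) + math.exp(-(v + 260) / 43)) + 1
    return am, bm, ah, bh, an, bn, ms_inf, mhf_inf, tau_mhf, mhs_inf, tau_mhs


def oracle_interneuron_rates(v):
    am = 0.1 * (v + 35) / (1 - math.exp(-(v + 35) / 10))
    bm = 4 * math.exp(-(v + 60) / 18)
    ah = 0.07 * math.exp(-(v + 58) / 20)
    bh = 1 / (math.exp(-0.1 * (v + 28)) + 1)
    an = 0.01 * (v + 34) / (1 - math.exp(-0.1 * (v + 34)))
    bn = 0.125 * math.exp(-(v + 44) / 80)
    return am, bm, ah, bh, an, bn


class TestRateLandmarks:
    """Closed-form values at special voltages."""

    def test_stellate_alpha_m_removable_singularity(self):
        assert ch.stellate_alpha_m(-23.0) == pytest.approx(1.0)

    def test_persistent_na_midpoint(self):
        assert ch.stellate_ms_inf(-38.0) == pytest.approx(0.5)

    def test_fast_h_gate_midpoint(self):
        assert ch.stellate_mhf_inf(-79.2) == pytest.approx(0.5)

    def test_interneuron_alpha_m_removable_singularity(self):
        assert ch.interneuron_alpha_m(-35.0) == pytest.approx(1.0)

    def test_interneuron_alpha_h_at_minus58(self):
        assert ch.interneuron_alpha_h(-58.0) == pytest.approx(0.07)

    def test_interneuron_beta_n_at_minus44(self):
        assert ch.interneuron_beta_n(-44.0) == pytest.approx(0.125)

    @pytest.mark.parametrize("fn,v0", [
        (ch.stellate_alpha_m, -23.0),
        (ch.stellate_alpha_n, -27.0),
        (ch.interneuron_alpha_m, -35.0),
        (ch.interneuron_alpha_n, -34.0),
    ])
    def test_continuity_at_singularity(self, fn, v0):
        lim = fn(v0)
        assert abs(fn(v0 + 1e-6) - lim) < 1e-6
        assert abs(fn(v0 - 1e-6) - lim) < 1e-6


@pytest.mark.parametrize("v", [-60.0, -75.0, -40.0, -52.3])
def test_stellate_kinetics_match_hand_oracle(v):
    am, bm, ah, bh, an, bn, msi, mhfi, tmhf, mhsi, tmhs = oracle_stellate_rates(v)
    kin = ch.stellate_gating_kinetics(v)
    assert kin["m"].inf == pytest.approx(am / (am + bm), rel=1e-12)
    assert kin["m"].tau == pytest.approx(1 / (am + bm), rel=1e-12)
    assert kin["h"].inf == pytest.approx(ah / (ah + bh), rel=1e-12)
    assert kin["n"].tau == pytest.approx(1 / (an + bn), rel=1e-12)
    assert kin["ms"].inf == pytest.approx(msi, rel=1e-12)
    assert kin["ms"].tau == pytest.approx(0.15)
    assert kin["mhf"].inf == pytest.approx(mhfi, rel=1e-12)
    assert kin["mhf"].tau == pytest.approx(tmhf, rel=1e-12)
    assert kin["mhs"].inf == pytest.approx(mhsi, rel=1e-12)
    assert kin["mhs"].tau == pytest.approx(tmhs, rel=1e-12)


@pytest.mark.parametrize("v", [-60.0, -70.0, -45.0])
def test_interneuron_kinetics_match_hand_oracle(v):
    am, bm, ah, bh, an, bn = oracle_interneuron_rates(v)
    kin = ch.interneuron_gating_kinetics(v, phi=5.0)
    assert kin["m"].inf == pytest.approx(am / (am + bm), rel=1e-12)
    assert kin["h"].inf == pytest.approx(ah / (ah + bh), rel=1e-12)
    assert kin["h"].tau == pytest.approx(1 / (5.0 * (ah + bh)), rel=1e-12)
    assert kin["n"].tau == pytest.approx(1 / (5.0 * (an + bn)), rel=1e-12)


@settings(deadline=None, max_examples=200)
@given(st.floats(min_value=-120.0, max_value=60.0))
def test_gate_steady_states_bounded_and_taus_positive(v):
    for kin in (ch.stellate_gating_kinetics(v), ch.interneuron_gating_kinetics(v)):
        for gate in kin.values():
            assert 0.0 <= gate.inf <= 1.0
            assert 0.0 < gate.tau < math.inf


class TestStellateDerivative:
    def test_zero_everything_gives_zero_dv(self):
        p = ch.StellateParams(g_na=0, g_k=0, g_nap=0, g_h=0, g_leak=0)
        s = ch.StellateState(v=-60, m=0.1, h=0.9, n=0.2, ms=0.3, mhf=0.4, mhs=0.5)
        d = ch.stellate_membrane_derivative(s, p, ch.MembraneInputs())
        assert d.v == 0.0

    def test_na_currents_vanish_at_reversal(self):
        p = ch.StellateParams(g_k=0, g_h=0, g_leak=0)
        s = ch.StellateState(v=55.0, m=0.9, h=0.9, n=0.0, ms=0.9, mhf=0.0, mhs=0.0)
        d = ch.stellate_membrane_derivative(s, p, ch.MembraneInputs())
        assert d.v == 0.0

    def test_rejects_pulse_and_theta_terms(self):
        s = ch.StellateState(v=-60, m=0.1, h=0.9, n=0.2, ms=0.3, mhf=0.4, mhs=0.5)
        with pytest.raises(ValueError):
            ch.stellate_membrane_derivative(
                s, ch.StellateParams(), ch.MembraneInputs(i_theta=0.1)
            )

    def test_matches_term_by_term_oracle(self):
        v = -57.3
        s = ch.StellateState(v=v, m=0.21, h=0.77, n=0.15, ms=0.42, mhf=0.33, mhs=0.18)
        p = ch.StellateParams()
        inp = ch.MembraneInputs(i_ext=-2.7, i_syn=1.3, i_noise=-0.2)
        d = ch.stellate_membrane_derivative(s, p, inp)
        i_na = 52.0 * s.m ** 3 * s.h * (v - 55.0)
        i_k = 11.0 * s.n ** 4 * (v + 90.0)
        i_leak = 0.55 * (v + 65.0)
        i_h = 1.5 * (0.65 * s.mhf + 0.35 * s.mhs) * (v + 20.0)
        i_nap = 0.5 * s.ms * (v - 55.0)
        dv = -2.7 - i_na - i_k - i_leak - i_h - i_nap - 1.3 + 0.2
        assert d.v == pytest.approx(dv, rel=1e-12)
        am, bm, ah, bh, an, bn, msi, mhfi, tmhf, mhsi, tmhs = oracle_stellate_rates(v)
        assert d.m == pytest.approx(am * (1 - s.m) - bm * s.m, rel=1e-10)
        assert d.h == pytest.approx(ah * (1 - s.h) - bh * s.h, rel=1e-10)
        assert d.n == pytest.approx(an * (1 - s.n) - bn * s.n, rel=1e-10)
        assert d.ms == pytest.approx((msi - s.ms) / 0.15, rel=1e-10)
        assert d.mhf == pytest.approx((mhfi - s.mhf) / tmhf, rel=1e-10)
        assert d.mhs == pytest.approx((mhsi - s.mhs) / tmhs, rel=1e-10)


class TestInterneuronDerivative:
    def test_zero_everything_gives_zero_dv(self):
        p = ch.InterneuronParams(g_na=0, g_k=0, g_leak=0)
        s = ch.InterneuronState(v=-60, m=0.1, h=0.9, n=0.2)
        d = ch.interneuron_membrane_derivative(s, p, ch.MembraneInputs())
        assert d.v == 0.0

    def test_theta_enters_with_minus_sign(self):
        s = ch.InterneuronState(v=-60, m=0.1, h=0.8, n=0.2)
        p = ch.InterneuronParams()
        d0 = ch.interneuron_membrane_derivative(s, p, ch.MembraneInputs())
        d1 = ch.interneuron_membrane_derivative(s, p, ch.MembraneInputs(i_theta=0.5))
        assert d1.v < d0.v

    def test_matches_term_by_term_oracle(self):
        v = -62.1
        s = ch.InterneuronState(v=v, m=0.0, h=0.66, n=0.31)
        p = ch.InterneuronParams()
        inp = ch.MembraneInputs(i_ext=0.2, i_pulse=1.0, i_syn=0.4, i_noise=0.05, i_theta=-0.3)
        d = ch.interneuron_membrane_derivative(s, p, inp)
        am, bm, ah, bh, an, bn = oracle_interneuron_rates(v)
        m_inf = am / (am + bm)  # Na activation is slaved to voltage
        i_na = 35.0 * m_inf ** 3 * s.h * (v - 55.0)
        i_k = 9.0 * s.n ** 4 * (v + 90.0)
        i_leak = 0.1 * (v + 65.0)
        dv = 0.2 + 1.0 - i_na - i_k - i_leak - 0.4 - 0.05 + 0.3
        assert d.v == pytest.approx(dv, rel=1e-12)
        assert d.m == 0.0
        assert d.h == pytest.approx(5.0 * (ah * (1 - s.h) - bh * s.h), rel=1e-10)
        assert d.n == pytest.approx(5.0 * (an * (1 - s.n) - bn * s.n), rel=1e-10)


class TestIsolatedCellBehavior:
    """Single-cell phenomenology at the default constant drives."""

    def test_stellate_subthreshold_oscillation(self, single_stellate):
        from thetagate.engine import SimulationConfig, integrate
        from thetagate.synapses import StimulusProgram

        cfg = SimulationConfig(
            duration=2000.0, seed=0, v_init_low=-54.0, v_init_high=-54.0
        )
        res = integrate(single_stellate, StimulusProgram(), cfg)
        v = res.v[:, 0]
        assert len(res.spikes[0]) == 0
        assert v.max() < 0.0  # never crosses the spike threshold
        assert v.max() - v.min() > 0.5

    def test_interneuron_fires_tonically(self, single_interneuron):
        from thetagate.engine import SimulationConfig, integrate
        from thetagate.synapses import StimulusProgram

        cfg = SimulationConfig(duration=1000.0, seed=0)
        res = integrate(single_interneuron, StimulusProgram(), cfg)
        assert len(res.spikes[0]) > 0
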