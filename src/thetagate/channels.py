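"""Channel kinetics and single-compartment membrane equations.

Two cell types are modeled, both as single-compartment conductance-based
neurons:

* **Stellate cell** (MEC layer II): transient Na (m³h), delayed-rectifier K
  (n⁴), leak, a non-inactivating persistent Na current, and a
  hyperpolarization-activated cation current (h-current) with a fast and a
  slow gate mixed 0.65/0.35.  The persistent Na and h currents give the cell
  subthreshold membrane-potential oscillations and post-inhibitory rebound
  spiking.
* **Fast-spiking interneuron**: transient Na, delayed-rectifier K and leak,
  with the gate kinetics of the classic fast-spiking interneuron model
  (h and n accelerated by a temperature-like factor ``phi``).

All rate functions take the membrane potential in mV and return rates in
ms⁻¹; removable singularities of the x/(1−e^(−x)) forms are evaluated by
their series limits within ``SINGULARITY_HALFWIDTH`` of the singular point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

__all__ = [
    "StellateState",
    "InterneuronState",
    "StellateParams",
    "InterneuronParams",
    "MembraneInputs",
    "GateKinetics",
    "stellate_gating_kinetics",
    "interneuron_gating_kinetics",
    "stellate_membrane_derivative",
    "interneuron_membrane_derivative",
]

#: half-width of the series-limit branch around removable singularities
SINGULARITY_HALFWIDTH = 1e-7


# ---------------------------------------------------------------------------
# Rate functions.  Plain scalar functions so the same code objects can be
# numba-jitted by the integration kernels.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _xexprel(u: float) -> float:
    """u / (e^u - 1), continuous at u = 0 (value 1)."""
    if abs(u) < SINGULARITY_HALFWIDTH:
        return 1.0 - 0.5 * u
    return u / (math.exp(u) - 1.0)


@njit(cache=True)
def stellate_alpha_m(v: float) -> float:
    return _xexprel(-0.1 * (v + 23.0))


@njit(cache=True)
def stellate_beta_m(v: float) -> float:
    return 4.0 * math.exp(-(v + 48.0) / 18.0)


@njit(cache=True)
def stellate_alpha_h(v: float) -> float:
    return 0.07 * math.exp(-(v + 37.0) / 20.0)


@njit(cache=True)
def stellate_beta_h(v: float) -> float:
    return 1.0 / (math.exp(-0.1 * (v + 7.0)) + 1.0)


@njit(cache=True)
def stellate_alpha_n(v: float) -> float:
    return 0.1 * _xexprel(-0.1 * (v + 27.0))


@njit(cache=True)
def stellate_beta_n(v: float) -> float:
    return 0.125 * math.exp(-(v + 37.0) / 80.0)


@njit(cache=True)
def stellate_ms_inf(v: float) -> float:
    """Persistent-Na activation; sigmoid midpoint −38 mV, slope 6.5 mV."""
    return 1.0 / (1.0 + math.exp(-(v + 38.0) / 6.5))


@njit(cache=True)
def stellate_mhf_inf(v: float) -> float:
    """Fast h-current gate; opens on hyperpolarization (midpoint −79.2 mV)."""
    return 1.0 / (1.0 + math.exp((v + 79.2) / 9.78))


@njit(cache=True)
def stellate_tau_mhf(v: float) -> float:
    return 0.51 / (math.exp((v - 1.7) / 10.0) + math.exp(-(v + 340.0) / 52.0)) + 1.0


@njit(cache=True)
def stellate_mhs_inf(v: float) -> float:
    """Slow h-current gate: 58th power of a shallow sigmoid.

    The high power sharpens the shallow (15.9 mV) sigmoid into an effective
    activation curve centered near −75 mV, as in the source stellate model.
    """
    return (1.0 / (1.0 + math.exp((v + 2.83) / 15.9))) ** 58.0


@njit(cache=True)
def stellate_tau_mhs(v: float) -> float:
    return 5.6 / (math.exp((v - 1.7) / 14.0) + math.exp(-(v + 260.0) / 43.0)) + 1.0


@njit(cache=True)
def interneuron_alpha_m(v: float) -> float:
    # 0.1(v+35) / (1 - e^(-(v+35)/10)) = w/(1-e^-w) with w = (v+35)/10
    w = (v + 35.0) / 10.0
    return _xexprel(-w)  # w/(1-e^(-w)) == (-w)/(e^(-w)-1)


@njit(cache=True)
def interneuron_beta_m(v: float) -> float:
    return 4.0 * math.exp(-(v + 60.0) / 18.0)


@njit(cache=True)
def interneuron_alpha_h(v: float) -> float:
    return 0.07 * math.exp(-(v + 58.0) / 20.0)


@njit(cache=True)
def interneuron_beta_h(v: float) -> float:
    return 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)


@njit(cache=True)
def interneuron_alpha_n(v: float) -> float:
    return 0.1 * _xexprel(-0.1 * (v + 34.0))


@njit(cache=True)
def interneuron_beta_n(v: float) -> float:
    return 0.125 * math.exp(-(v + 44.0) / 80.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StellateState:
    """Membrane potential (mV) and gating variables of one stellate cell."""

    v: float
    m: float
    h: float
    n: float
    ms: float
    mhf: float
    mhs: float

    def validate(self) -> None:
        if not math.isfinite(self.v):
            raise ValueError("membrane potential must be finite")
        for name in ("m", "h", "n", "ms", "mhf", "mhs"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name}={x} outside [0, 1]")


@dataclass
class InterneuronState:
    """Membrane potential (mV) and gating variables of one interneuron."""

    v: float
    m: float
    h: float
    n: float

    def validate(self) -> None:
        if not math.isfinite(self.v):
            raise ValueError("membrane potential must be finite")
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name}={x} outside [0, 1]")


@dataclass
class StellateParams:
    """Stellate-cell membrane parameters (conductances mS/cm², reversals mV)."""

    c_m: float = 1.0
    g_na: float = 52.0
    g_k: float = 11.0
    g_nap: float = 0.5
    g_h: float = 1.5
    g_leak: float = 0.55
    e_na: float = 55.0
    e_k: float = -90.0
    e_h: float = -20.0
    e_leak: float = -65.0
    tau_ms: float = 0.15
    h_frac_fast: float = 0.65
    h_frac_slow: float = 0.35

    def validate(self) -> None:
        for name in ("g_na", "g_k", "g_nap", "g_h", "g_leak", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.h_frac_fast + self.h_frac_slow - 1.0) > 1e-12:
            raise ValueError("h-current mixing fractions must sum to 1")


@dataclass
class InterneuronParams:
    """Fast-spiking interneuron membrane parameters.

    ``phi`` is the temperature-like factor that accelerates the h and n
    gates and gives the model its fast-spiking character.
    """

    c_m: float = 1.0
    g_na: float = 35.0
    g_k: float = 9.0
    g_leak: float = 0.1
    e_na: float = 55.0
    e_k: float = -90.0
    e_leak: float = -65.0
    phi: float = 5.0

    def validate(self) -> None:
        for name in ("g_na", "g_k", "g_leak", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MembraneInputs:
    """External and network currents entering one cell's current balance.

    All in μA/cm².  ``i_pulse`` and ``i_theta`` only exist for interneurons;
    the stellate current balance has no such terms.
    """

    i_ext: float = 0.0
    i_pulse: float = 0.0
    i_syn: float = 0.0
    i_noise: float = 0.0
    i_theta: float = 0.0

    def validate(self) -> None:
        for name in ("i_ext", "i_pulse", "i_syn", "i_noise", "i_theta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GateKinetics:
    """(steady state, time constant ms) pair for one gating variable."""

    inf: float
    tau: float


def _ab_to_kin(alpha: float, beta: float) -> GateKinetics:
    s = alpha + beta
    return GateKinetics(inf=alpha / s, tau=1.0 / s)


def stellate_gating_kinetics(v: float) -> dict[str, GateKinetics]:
    """Steady states and time constants of all six stellate gates at ``v``."""
    if not math.isfinite(v):
        raise ValueError("membrane potential must be finite")
    return {
        "m": _ab_to_kin(stellate_alpha_m(v), stellate_beta_m(v)),
        "h": _ab_to_kin(stellate_alpha_h(v), stellate_beta_h(v)),
        "n": _ab_to_kin(stellate_alpha_n(v), stellate_beta_n(v)),
        "ms": GateKinetics(inf=stellate_ms_inf(v), tau=0.15),
        "mhf": GateKinetics(inf=stellate_mhf_inf(v), tau=stellate_tau_mhf(v)),
        "mhs": GateKinetics(inf=stellate_mhs_inf(v), tau=stellate_tau_mhs(v)),
    }


def interneuron_gating_kinetics(v: float, phi: float = 5.0) -> dict[str, GateKinetics]:
    """Steady states and time constants of the interneuron gates at ``v``.

    ``phi`` divides the h and n time constants (steady states unaffected).
    """
    if not math.isfinite(v):
        raise ValueError("membrane potential must be finite")
    kin = {
        "m": _ab_to_kin(interneuron_alpha_m(v), interneuron_beta_m(v)),
        "h": _ab_to_kin(interneuron_alpha_h(v), interneuron_beta_h(v)),
        "n": _ab_to_kin(interneuron_alpha_n(v), interneuron_beta_n(v)),
    }
    kin["h"].tau /= phi
    kin["n"].tau /= phi
    return kin


# ---------------------------------------------------------------------------
# Membrane derivatives
# ---------------------------------------------------------------------------

def stellate_membrane_derivative(
    state: StellateState, params: StellateParams, inputs: MembraneInputs
) -> StellateState:
    """Time derivative of a stellate cell's state.

    Current balance::

        C dV/dt = I_ext − I_Na − I_K − I_L − I_h − I_NaP − I_syn − I_noise

    Returns a :class:`StellateState` whose fields hold d/dt of the
    corresponding state fields (mV/ms for v, ms⁻¹ for gates).
    """
    state.validate()
    params.validate()
    inputs.validate()
    if inputs.i_pulse != 0.0 or inputs.i_theta != 0.0:
        raise ValueError("stellate current balance has no pulse or theta term")
    v = state.v
    i_na = params.g_na * state.m ** 3 * state.h * (v - params.e_na)
    i_k = params.g_k * state.n ** 4 * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    i_h = (
        params.g_h
        * (params.h_frac_fast * state.mhf + params.h_frac_slow * state.mhs)
        * (v - params.e_h)
    )
    i_nap = params.g_nap * state.ms * (v - params.e_na)
    dv = (
        inputs.i_ext - i_na - i_k - i_leak - i_h - i_nap
        - inputs.i_syn - inputs.i_noise
    ) / params.c_m
    return StellateState(
        v=dv,
        m=stellate_alpha_m(v) * (1.0 - state.m) - stellate_beta_m(v) * state.m,
        h=stellate_alpha_h(v) * (1.0 - state.h) - stellate_beta_h(v) * state.h,
        n=stellate_alpha_n(v) * (1.0 - state.n) - stellate_beta_n(v) * state.n,
        ms=(stellate_ms_inf(v) - state.ms) / params.tau_ms,
        mhf=(stellate_mhf_inf(v) - state.mhf) / stellate_tau_mhf(v),
        mhs=(stellate_mhs_inf(v) - state.mhs) / stellate_tau_mhs(v),
    )


def interneuron_m_inf(v: float) -> float:
    """Instantaneous Na activation of the fast-spiking interneuron.

    As in the source fast-spiking model, the Na activation gate is slaved to
    voltage (its kinetics are much faster than the other gates); the ``m``
    state field carries this value rather than an integrated variable.
    """
    a = interneuron_alpha_m(v)
    return a / (a + interneuron_beta_m(v))


def interneuron_membrane_derivative(
    state: InterneuronState, params: InterneuronParams, inputs: MembraneInputs
) -> InterneuronState:
    """Time derivative of an interneuron's state.

    Current balance::

        C dV/dt = I_ext + I_pulse − I_Na − I_K − I_L − I_syn − I_noise − I_θ

    The theta drive enters with a minus sign: a positive sinusoid
    hyperpolarizes, so the depolarized ("receptive") phase window is where
    the sinusoid is negative.  The Na activation m is instantaneous
    (m = m∞(v)); its reported derivative is identically zero.
    """
    state.validate()
    params.validate()
    inputs.validate()
    v = state.v
    i_na = params.g_na * interneuron_m_inf(v) ** 3 * state.h * (v - params.e_na)
    i_k = params.g_k * state.n ** 4 * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    dv = (
        inputs.i_ext + inputs.i_pulse - i_na - i_k - i_leak
        - inputs.i_syn - inputs.i_noise - inputs.i_theta
    ) / params.c_m
    phi = params.phi
    return InterneuronState(
        v=dv,
        m=0.0,
        h=phi * (interneuron_alpha_h(v) * (1.0 - state.h) - interneuron_beta_h(v) * state.h),
        n=phi * (interneuron_alpha_n(v) * (1.0 - state.n) - interneuron_beta_n(v) * state.n),
    )
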