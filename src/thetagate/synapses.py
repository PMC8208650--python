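"""Synapse model, theta drive, sequential pulse stimuli, conductance noise.

Chemical synapses are graded-release conductances: a single gating variable
``s`` per presynaptic cell opens at a rate proportional to a sigmoid of the
presynaptic voltage and closes at a constant rate.  The theta drive is a
sinusoidal conductance onto interneurons; because it enters the interneuron
current balance with a minus sign, interneurons are most excitable at the
*trough* of the sinusoid.  Sequential pulse trains model afferent sensory
drive visiting neighboring interneurons in successive theta cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseParams",
    "ThetaDrive",
    "PulseTrainSpec",
    "NoiseSpec",
    "StimulusProgram",
    "presynaptic_activation",
    "synapse_gate_derivative",
    "synaptic_current",
    "theta_current",
    "pulse_current",
    "pulse_schedule",
    "noise_current",
]


@dataclass
class SynapseParams:
    """Conductance, reversal and gate rate constants of one synapse class.

    Rates are in ms⁻¹ (the millisecond-scale gate dynamics fix the unit).
    """

    g_max: float
    e_rev: float
    alpha_s: float
    beta_s: float

    def validate(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")

    @classmethod
    def inhibitory(cls, g_max: float = 1.0) -> "SynapseParams":
        """GABAergic synapse: E_rev −80 mV, decay time constant ≈ 9 ms."""
        return cls(g_max=g_max, e_rev=-80.0, alpha_s=3.33, beta_s=0.11)

    @classmethod
    def excitatory(cls, g_max: float = 0.03) -> "SynapseParams":
        """AMPA-like synapse: E_rev 0 mV, decay time constant ≈ 3 ms."""
        return cls(g_max=g_max, e_rev=0.0, alpha_s=100.0, beta_s=0.33)


@dataclass
class ThetaDrive:
    """Sinusoidal conductance drive I_θ = A·sin(θ(t))·(V − V_th).

    For a fixed frequency θ(t) = 2πωt/1000 + φ (t in ms, ω in Hz).  With a
    sweep (``mod_amp_hz`` > 0) the instantaneous frequency is
    ω(t) = ω + mod_amp·sin(2πt/mod_period), and θ(t) is its phase-continuous
    integral.
    """

    amplitude: float = 0.04
    freq_hz: float = 8.0
    phase_offset: float = 0.0
    v_th: float = -80.0
    mod_amp_hz: float = 0.0
    mod_period_ms: float = 0.0

    def validate(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.freq_hz - abs(self.mod_amp_hz) <= 0:
            raise ValueError("instantaneous frequency must stay positive")
        if self.mod_amp_hz != 0.0 and self.mod_period_ms <= 0:
            raise ValueError("mod_period_ms required for swept drives")

    def phase(self, t: float) -> float:
        """Accumulated sinusoid argument at time ``t`` ms (not wrapped)."""
        ph = 2.0 * math.pi * self.freq_hz * t / 1000.0 + self.phase_offset
        if self.mod_amp_hz != 0.0:
            # integral of mod_amp*sin(2*pi*t/Tm) dt, converted Hz·ms → rad
            tm = self.mod_period_ms
            ph += (
                2.0 * math.pi * self.mod_amp_hz / 1000.0
                * (tm / (2.0 * math.pi))
                * (1.0 - math.cos(2.0 * math.pi * t / tm))
            )
        return ph

    def instantaneous_freq(self, t: float) -> float:
        f = self.freq_hz
        if self.mod_amp_hz != 0.0:
            f += self.mod_amp_hz * math.sin(2.0 * math.pi * t / self.mod_period_ms)
        return f


@dataclass
class PulseTrainSpec:
    """Periodic pulse train to interneuron ``neuron_index``.

    Onsets follow t_s = i·T + k·λ for k = 0, 1, …; each pulse lasts
    ``p_width`` ms, rising from ``p_low`` toward ``p_high`` with time
    constant ``tau_r`` and decaying back with ``tau_f``.  On a ring of N
    interneurons the revisit interval is λ = N·T so the pulse tours the
    whole ring before returning.
    """

    neuron_index: int = 0
    p_low: float = -0.05
    p_high: float = 1.0
    tau_r: float = 1.0
    tau_f: float = 2.0
    p_width: float = 40.0
    T: float = 125.0
    lambda_: float = 0.0  # 0 → single pulse (no revisits)
    t_offset: float = 0.0  # global shift of every onset (phase relative to theta)

    def validate(self) -> None:
        if self.p_width <= 0:
            raise ValueError("p_width must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.tau_r <= 0 or self.tau_f <= 0:
            raise ValueError("rise/fall time constants must be positive")

    def onsets(self, duration: float) -> np.ndarray:
        """All pulse onset times < ``duration`` (ms), sorted."""
        first = self.neuron_index * self.T + self.t_offset
        if self.lambda_ <= 0:
            out = [first] if first < duration else []
        else:
            out = []
            k = 0
            while first + k * self.lambda_ < duration:
                out.append(first + k * self.lambda_)
                k += 1
        return np.asarray(out, dtype=float)


@dataclass
class NoiseSpec:
    """Conductance noise g_amp·u·(v − e_rev), u ~ U(−1, 1).

    ``u`` is redrawn independently per cell every ``resample_ms`` (the noise
    correlation time).  The default amplitude makes the mean absolute noise
    current ≈ 10% of the 1 μA/cm² pulse amplitude at a typical 10 mV
    excursion from the −65 mV noise reversal.
    """

    g_amp: float = 0.02
    e_rev: float = -65.0
    resample_ms: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.g_amp < 0:
            raise ValueError("g_amp must be non-negative")
        if self.resample_ms <= 0:
            raise ValueError("resample_ms must be positive")


@dataclass
class StimulusProgram:
    """Everything that drives a network besides its constant currents."""

    theta: ThetaDrive | None = None
    pulses: list[PulseTrainSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(g_amp=0.0))

    def validate(self) -> None:
        if self.theta is not None:
            self.theta.validate()
        for p in self.pulses:
            p.validate()
        self.noise.validate()

    def to_config_text(self) -> str:
        """Serialize to a plain-text key-value format."""
        lines = []
        if self.theta is not None:
            th = self.theta
            lines.append(
                "theta amplitude=%g freq_hz=%g phase_offset=%g v_th=%g "
                "mod_amp_hz=%g mod_period_ms=%g"
                % (th.amplitude, th.freq_hz, th.phase_offset, th.v_th,
                   th.mod_amp_hz, th.mod_period_ms)
            )
        for p in self.pulses:
            lines.append(
                "pulse neuron=%d p_low=%g p_high=%g tau_r=%g tau_f=%g "
                "p_width=%g T=%g lambda=%g t_offset=%g"
                % (p.neuron_index, p.p_low, p.p_high, p.tau_r, p.tau_f,
                   p.p_width, p.T, p.lambda_, p.t_offset)
            )
        n = self.noise
        lines.append(
            "noise g_amp=%g e_rev=%g resample_ms=%g seed=%d"
            % (n.g_amp, n.e_rev, n.resample_ms, n.seed)
        )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Current / gate functions
# ---------------------------------------------------------------------------

def presynaptic_activation(v_pre: float) -> float:
    """Sigmoid of presynaptic voltage, F(v) = (1 + tanh(v/4))/2 ∈ (0, 1)."""
    if not math.isfinite(v_pre):
        raise ValueError("presynaptic voltage must be finite")
    return 0.5 * (1.0 + math.tanh(v_pre / 4.0))


def synapse_gate_derivative(s: float, v_pre: float, params: SynapseParams) -> float:
    """ds/dt = F(v_pre)·α_s·(1 − s) − β_s·s."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"synaptic gate s={s} outside [0, 1]")
    return presynaptic_activation(v_pre) * params.alpha_s * (1.0 - s) - params.beta_s * s


def synaptic_current(s: float, v_post: float, params: SynapseParams) -> float:
    """I_syn = g_max·s·(v_post − E_rev) in μA/cm²."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"synaptic gate s={s} outside [0, 1]")
    return params.g_max * s * (v_post - params.e_rev)


def theta_current(t: float, v: float, drive: ThetaDrive) -> float:
    """I_θ(t, v) = A·sin(θ(t))·(v − V_th) in μA/cm²."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return drive.amplitude * math.sin(drive.phase(t)) * (v - drive.v_th)


def pulse_schedule(
    i: int, k: int, T: float, lambda_: float, p_width: float
) -> tuple[float, float]:
    """(onset, offset) of the k-th pulse to interneuron i.

    onset = i·T + k·λ, offset = onset + p_width.
    """
    if i < 0 or k < 0:
        raise ValueError("neuron and repeat indices must be non-negative")
    onset = i * T + k * lambda_
    return onset, onset + p_width


def pulse_current(t: float, spec: PulseTrainSpec) -> float:
    """Pulse current at time ``t`` ms for one interneuron's train.

    Saturating exponential rise from ``p_low`` toward ``p_high`` during a
    pulse, exponential decay back to ``p_low`` after pulse offset;
    continuous at both segment boundaries.
    """
    spec.validate()
    first = spec.neuron_index * spec.T + spec.t_offset
    if t < first:
        return spec.p_low
    if spec.lambda_ > 0:
        k = int((t - first) // spec.lambda_)
        ts = first + k * spec.lambda_
    else:
        ts = first
    te = ts + spec.p_width
    if t < te:
        return spec.p_high + (spec.p_low - spec.p_high) * math.exp(-(t - ts) / spec.tau_r)
    p_end = spec.p_high + (spec.p_low - spec.p_high) * math.exp(-spec.p_width / spec.tau_r)
    return spec.p_low + (p_end - spec.p_low) * math.exp(-(t - te) / spec.tau_f)


def noise_current(t: float, v: float, spec: NoiseSpec, rng_seed: int | None = None) -> float:
    """Conductance-noise current g_amp·u·(v − e_rev) at time ``t``.

    ``u`` ~ U(−1, 1) is held constant within each resample interval and is a
    deterministic function of (seed, interval index), so the process is
    reproducible without integrating it sequentially.
    """
    spec.validate()
    if spec.g_amp == 0.0:
        return 0.0
    seed = spec.seed if rng_seed is None else rng_seed
    idx = int(t // spec.resample_ms)
    u = np.random.default_rng([seed, idx]).uniform(-1.0, 1.0)
    return spec.g_amp * u * (v - spec.e_rev)
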