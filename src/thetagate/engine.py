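"""Fixed-step integration of the coupled network, trials, spike detection.

The production integrator is forward Euler at dt = 0.01 ms (the scheme and
step used for all experiments); :func:`reference_integrate` provides a
classical 4th-order Runge–Kutta scheme at a finer step as a numerical
oracle for tests.  Trials share the topology and stimulus schedule and
differ only in their noise stream and initial conditions, both derived from
per-trial seeds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .channels import (
    InterneuronParams,
    StellateParams,
    interneuron_gating_kinetics,
    stellate_gating_kinetics,
)
from .network import NetworkSpec
from .synapses import StimulusProgram

__all__ = [
    "SimulationConfig",
    "TrialResult",
    "SpikeRaster",
    "SimulationDivergedError",
    "integrate",
    "reference_integrate",
    "run_trials",
    "detect_spikes",
]


class SimulationDivergedError(RuntimeError):
    """Raised when any membrane potential leaves the plausible range."""

    def __init__(self, t: float):
        super().__init__(f"membrane potential diverged at t = {t:.3f} ms")
        self.t = t


@dataclass
class SimulationConfig:
    """Integration and trial-management settings.

    ``record_stride`` thins the stored voltage traces (samples every
    ``record_stride``·dt ms); 0 disables trace recording.  Initial membrane
    potentials are drawn per cell from U(v_init_low, v_init_high) under the
    trial seed, with gates at their steady state for the drawn voltage —
    this desynchronizes symmetric motifs without biasing a winner.
    """

    duration: float = 1000.0
    dt: float = 0.01
    n_trials: int = 1
    seed: int = 0
    record_voltages: bool = True
    record_stride: int = 10
    v_init_low: float = -70.0
    v_init_high: float = -60.0
    spike_threshold: float = 0.0
    refractory: float = 2.0
    divergence_v: float = 200.0
    max_spike_rate_hz: float = 500.0
    stellate_params: StellateParams = field(default_factory=StellateParams)
    interneuron_params: InterneuronParams = field(default_factory=InterneuronParams)

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


@dataclass
class TrialResult:
    """Traces and spikes of one trial."""

    t: np.ndarray                 # recorded sample times (ms)
    v: np.ndarray                 # (n_samples, n_cells) voltages, stellates first
    spikes: list[np.ndarray]      # per-cell spike times (ms)
    clamp_count: int
    n_stellate: int
    n_interneuron: int


@dataclass
class SpikeRaster:
    """Per-neuron, per-trial spike-time lists on a common clock."""

    spikes: list[list[np.ndarray]]  # [trial][cell] -> spike times (ms)
    n_stellate: int
    n_interneuron: int
    duration: float
    dt: float

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def n_cells(self) -> int:
        return self.n_stellate + self.n_interneuron

    def cell_type(self, cell: int) -> str:
        return "stellate" if cell < self.n_stellate else "interneuron"

    def trains(self, cell: int) -> list[np.ndarray]:
        """Spike trains of one cell across all trials."""
        return [self.spikes[trial][cell] for trial in range(self.n_trials)]

    def to_table(self) -> str:
        """Columnar text: trial, neuron, cell_type, spike_time_ms."""
        buf = io.StringIO()
        buf.write("trial\tneuron\tcell_type\tspike_time_ms\n")
        for trial, cells in enumerate(self.spikes):
            for cell, times in enumerate(cells):
                kind = self.cell_type(cell)
                for t in times:
                    buf.write(f"{trial}\t{cell}\t{kind}\t{t:.4f}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_table())


# ---------------------------------------------------------------------------
# Packing helpers
# ---------------------------------------------------------------------------

def _pack_stellate_params(p: StellateParams) -> np.ndarray:
    p.validate()
    return np.array([
        p.c_m, p.g_na, p.g_k, p.g_nap, p.g_h, p.g_leak,
        p.e_na, p.e_k, p.e_h, p.e_leak, p.tau_ms, p.h_frac_fast, p.h_frac_slow,
    ])


def _pack_interneuron_params(p: InterneuronParams) -> np.ndarray:
    p.validate()
    return np.array([
        p.c_m, p.g_na, p.g_k, p.g_leak, p.e_na, p.e_k, p.e_leak, p.phi,
    ])


# synapse rate constants shared by every connection of a class (ms^-1)
_SYN = np.array([3.33, 0.11, 100.0, 0.33, -80.0, 0.0])


def _pack_theta(program: StimulusProgram) -> np.ndarray:
    th = program.theta
    if th is None:
        return np.zeros(6)
    th.validate()
    return np.array([
        th.amplitude, th.freq_hz, th.mod_amp_hz, th.mod_period_ms,
        th.phase_offset, th.v_th,
    ])


def _pack_pulses(program: StimulusProgram, n_i: int, duration: float):
    pulse_par = np.zeros((n_i, 5))
    has_pulse = np.zeros(n_i, dtype=np.uint8)
    onset_lists: list[np.ndarray] = [np.empty(0) for _ in range(n_i)]
    for spec in program.pulses:
        i = spec.neuron_index
        if not 0 <= i < n_i:
            raise ValueError(f"pulse targets interneuron {i} outside population")
        if has_pulse[i]:
            raise ValueError(f"interneuron {i} has more than one pulse train")
        spec.validate()
        has_pulse[i] = 1
        pulse_par[i] = (spec.p_low, spec.p_high, spec.tau_r, spec.tau_f, spec.p_width)
        onset_lists[i] = spec.onsets(duration)
    indptr = np.zeros(n_i + 1, dtype=np.int64)
    for i in range(n_i):
        indptr[i + 1] = indptr[i] + onset_lists[i].size
    data = np.concatenate(onset_lists) if indptr[-1] else np.empty(0)
    return pulse_par, has_pulse, data, indptr


def initial_state(
    network: NetworkSpec, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Packed initial state: random voltages, gates at steady state, s = 0."""
    n_s, n_i = network.n_stellate, network.n_interneuron
    y = np.zeros(7 * n_s + 4 * n_i + n_s + n_i)
    b = 7 * n_s
    vs = rng.uniform(config.v_init_low, config.v_init_high, size=n_s)
    vi = rng.uniform(config.v_init_low, config.v_init_high, size=n_i)
    for j in range(n_s):
        kin = stellate_gating_kinetics(vs[j])
        y[j] = vs[j]
        y[n_s + j] = kin["m"].inf
        y[2 * n_s + j] = kin["h"].inf
        y[3 * n_s + j] = kin["n"].inf
        y[4 * n_s + j] = kin["ms"].inf
        y[5 * n_s + j] = kin["mhf"].inf
        y[6 * n_s + j] = kin["mhs"].inf
    phi = config.interneuron_params.phi
    for i in range(n_i):
        kin = interneuron_gating_kinetics(vi[i], phi=phi)
        y[b + i] = vi[i]
        y[b + n_i + i] = kin["m"].inf
        y[b + 2 * n_i + i] = kin["h"].inf
        y[b + 3 * n_i + i] = kin["n"].inf
    return y


def _kernel_args(network: NetworkSpec, program: StimulusProgram, config: SimulationConfig):
    network.validate()
    program.validate()
    config.validate()
    n_s, n_i = network.n_stellate, network.n_interneuron
    pulse_par, has_pulse, onsets_data, onsets_indptr = _pack_pulses(
        program, n_i, config.duration
    )
    return dict(
        n_s=n_s,
        n_i=n_i,
        sp=_pack_stellate_params(config.stellate_params),
        ip=_pack_interneuron_params(config.interneuron_params),
        syn=_SYN,
        g_is=np.ascontiguousarray(network.w_ie.T),
        g_si=np.ascontiguousarray(network.w_ei.T),
        g_ii_t=np.ascontiguousarray(network.w_ii.T),
        iext_s=np.asarray(network.iext_s, dtype=float),
        iext_i=np.asarray(network.iext_i, dtype=float),
        th=_pack_theta(program),
        pulse_par=pulse_par,
        has_pulse=has_pulse,
        onsets_data=onsets_data,
        onsets_indptr=onsets_indptr,
    )


def _max_spikes(config: SimulationConfig) -> int:
    return int(config.duration / 1000.0 * config.max_spike_rate_hz) + 64


def _unpack_result(res, n_s, n_i, config) -> TrialResult:
    rec_t, rec_v, spikes, counts, clamp_count, diverged_at = res
    if diverged_at >= 0.0:
        raise SimulationDivergedError(diverged_at)
    trains = [np.sort(spikes[c, : counts[c]]) for c in range(n_s + n_i)]
    return TrialResult(
        t=rec_t,
        v=rec_v,
        spikes=trains,
        clamp_count=int(clamp_count),
        n_stellate=n_s,
        n_interneuron=n_i,
    )


def _trial_seeds(config: SimulationConfig, trial: int):
    ss = np.random.SeedSequence([int(config.seed), int(trial)])
    ic_seed, noise_seed = ss.generate_state(2)
    rng = np.random.default_rng(ic_seed)
    return rng, int(noise_seed % (2 ** 31))


def integrate(
    network: NetworkSpec,
    program: StimulusProgram,
    config: SimulationConfig,
    trial: int = 0,
    y0: np.ndarray | None = None,
) -> TrialResult:
    """One forward-Euler trial; identical seeds give bit-identical output.

    ``y0`` overrides the random initial-condition policy with an explicit
    packed state vector (as produced by :func:`initial_state`).
    """
    args = _kernel_args(network, program, config)
    rng, noise_seed = _trial_seeds(config, trial)
    if y0 is None:
        y0 = initial_state(network, config, rng)
    noise = program.noise
    resample_steps = max(1, int(round(noise.resample_ms / config.dt)))
    n_steps = int(round(config.duration / config.dt))
    stride = config.record_stride if config.record_voltages else 0
    res = _kernels.euler_run(
        y0, config.dt, n_steps,
        args["n_s"], args["n_i"], args["sp"], args["ip"], args["syn"],
        args["g_is"], args["g_si"], args["g_ii_t"],
        args["iext_s"], args["iext_i"], args["th"],
        args["pulse_par"], args["has_pulse"], args["onsets_data"], args["onsets_indptr"],
        noise_seed, resample_steps, noise.g_amp, noise.g_amp, noise.e_rev,
        stride, config.spike_threshold, config.refractory,
        _max_spikes(config), config.divergence_v,
    )
    return _unpack_result(res, args["n_s"], args["n_i"], config)


def reference_integrate(
    network: NetworkSpec,
    program: StimulusProgram,
    config: SimulationConfig,
    dt_ref: float = 0.001,
    trial: int = 0,
    y0: np.ndarray | None = None,
) -> TrialResult:
    """Noise-free 4th-order Runge–Kutta reference run (numerical oracle)."""
    if program.noise.g_amp != 0.0:
        raise ValueError("reference integrator is defined for noise-free programs")
    config = replace(config, dt=dt_ref)
    args = _kernel_args(network, program, config)
    rng, _ = _trial_seeds(config, trial)
    if y0 is None:
        y0 = initial_state(network, config, rng)
    n_steps = int(round(config.duration / dt_ref))
    stride = config.record_stride if config.record_voltages else 0
    res = _kernels.rk4_run(
        y0, dt_ref, n_steps,
        args["n_s"], args["n_i"], args["sp"], args["ip"], args["syn"],
        args["g_is"], args["g_si"], args["g_ii_t"],
        args["iext_s"], args["iext_i"], args["th"],
        args["pulse_par"], args["has_pulse"], args["onsets_data"], args["onsets_indptr"],
        stride, config.spike_threshold, config.refractory,
        _max_spikes(config), config.divergence_v,
    )
    return _unpack_result(res, args["n_s"], args["n_i"], config)


def run_trials(
    network: NetworkSpec, program: StimulusProgram, config: SimulationConfig
) -> SpikeRaster:
    """Run all trials; each re-seeds only noise and initial conditions."""
    all_spikes: list[list[np.ndarray]] = []
    for trial in range(config.n_trials):
        result = integrate(network, program, config, trial=trial)
        all_spikes.append(result.spikes)
    return SpikeRaster(
        spikes=all_spikes,
        n_stellate=network.n_stellate,
        n_interneuron=network.n_interneuron,
        duration=config.duration,
        dt=config.dt,
    )


def detect_spikes(
    v: np.ndarray,
    dt: float,
    threshold: float = 0.0,
    refractory: float = 2.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled voltage trace.

    Crossing times are linearly interpolated; crossings within the
    refractory window of the previous accepted spike are discarded.
    """
    v = np.asarray(v, dtype=float)
    idx = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    out: list[float] = []
    last = -np.inf
    for k in idx:
        tc = t0 + dt * (k + (threshold - v[k]) / (v[k + 1] - v[k]))
        if tc - last >= refractory:
            out.append(tc)
            last = tc
    return np.asarray(out)
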