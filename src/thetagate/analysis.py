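"""Spike-phase statistics, SPIKE-distance reliability, smoothed rate maps.

The reliability measure is the time-averaged SPIKE dissimilarity between the
spike trains a neuron produced on different noisy trials.  The dissimilarity
profile S(t) is built, at every t, from the timing differences between each
train's previous/following spikes and their nearest counterparts in the
other train, normalized by the local mean inter-spike interval; it is
piecewise linear between consecutive spikes of either train, so its time
average is computed here by exact trapezoidal integration of each segment
(no grid sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synapses import ThetaDrive

__all__ = [
    "PhaseAssignment",
    "ReliabilitySummary",
    "spike_phase",
    "phase_histogram",
    "spike_train_distance",
    "reliability",
    "rate_map",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseAssignment:
    """Spike phases in [0, 2π) relative to a periodic reference."""

    phases: np.ndarray
    cell_type: str = ""

    def validate(self) -> None:
        if self.phases.size and ((self.phases < 0) | (self.phases >= TWO_PI)).any():
            raise ValueError("phases must lie in [0, 2*pi)")


@dataclass
class ReliabilitySummary:
    """Mean pairwise spike-train distance per neuron, across trial pairs."""

    neuron_indices: np.ndarray
    mean_distance: np.ndarray
    condition: str = ""

    def median(self) -> float:
        return float(np.median(self.mean_distance))

    def to_table(self) -> str:
        lines = ["# neuron\tmean_spike_distance\tcondition"]
        for idx, d in zip(self.neuron_indices, self.mean_distance):
            lines.append(f"{idx}\t{d:.6f}\t{self.condition}")
        return "\n".join(lines) + "\n"


def spike_phase(t: float | np.ndarray, drive: ThetaDrive) -> float | np.ndarray:
    """Phase of the theta sinusoid argument at spike time(s) ``t``, mod 2π.

    The depolarized (receptive) window of the interneurons is where the
    sinusoid is negative, i.e. phases in (π, 2π), because the drive enters
    the interneuron current balance with a minus sign.
    """
    if np.isscalar(t):
        return drive.phase(float(t)) % TWO_PI
    return np.array([drive.phase(float(x)) for x in np.asarray(t, dtype=float)]) % TWO_PI


def circular_mean(phases: np.ndarray) -> tuple[float, float]:
    """(mean direction in [0, 2π), resultant length in [0, 1])."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return float("nan"), 0.0
    z = np.exp(1j * phases).mean()
    return float(np.angle(z) % TWO_PI), float(np.abs(z))


def phase_histogram(
    phases: np.ndarray, n_bins: int = 16
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Binned phase counts over [0, 2π) plus circular mean statistics.

    Returns (counts, bin_edges, circular_mean, resultant_length).
    """
    if n_bins < 4:
        raise ValueError("n_bins must be at least 4")
    phases = np.asarray(phases, dtype=float)
    counts, edges = np.histogram(phases, bins=n_bins, range=(0.0, TWO_PI))
    mean, r = circular_mean(phases)
    return counts, edges, mean, r


# ---------------------------------------------------------------------------
# SPIKE distance
# ---------------------------------------------------------------------------

def _with_aux(train: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Clip to the interval and add auxiliary spikes at both endpoints."""
    train = np.asarray(train, dtype=float)
    train = train[(train >= t0) & (train <= t1)]
    if train.size == 0 or train[0] > t0:
        train = np.concatenate(([t0], train))
    if train[-1] < t1:
        train = np.concatenate((train, [t1]))
    return train


def _nearest_dist(t: float, train: np.ndarray) -> float:
    i = np.searchsorted(train, t)
    best = np.inf
    if i < train.size:
        best = train[i] - t
    if i > 0:
        best = min(best, t - train[i - 1])
    return best


def _profile_value(
    t: float, tp_a: float, tf_a: float, dp_a: float, df_a: float,
    tp_b: float, tf_b: float, dp_b: float, df_b: float,
) -> float:
    """S(t) inside one segment, given the segment's corner quantities."""
    x_a = tf_a - tp_a
    x_b = tf_b - tp_b
    s_a = (dp_a * (tf_a - t) + df_a * (t - tp_a)) / x_a
    s_b = (dp_b * (tf_b - t) + df_b * (t - tp_b)) / x_b
    mean_isi = 0.5 * (x_a + x_b)
    return (s_a * x_b + s_b * x_a) / (2.0 * mean_isi ** 2)


def spike_train_distance(
    train_a: np.ndarray,
    train_b: np.ndarray,
    interval: tuple[float, float],
) -> float:
    """Time-averaged SPIKE dissimilarity between two trains, in [0, 1].

    Auxiliary spikes at the interval endpoints make the profile defined for
    empty and near-empty trains; a pair of identical trains (including two
    empty ones) has distance 0.  The profile is integrated exactly segment
    by segment (it is linear between consecutive spikes of either train).
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if t1 <= t0:
        raise ValueError("interval must have positive length")
    a = _with_aux(train_a, t0, t1)
    b = _with_aux(train_b, t0, t1)
    edges = np.union1d(a, b)
    total = 0.0
    for k in range(edges.size - 1):
        lo, hi = edges[k], edges[k + 1]
        if hi <= lo:
            continue
        # previous spike <= lo and following spike >= hi, per train
        tp_a = a[np.searchsorted(a, lo, side="right") - 1]
        tf_a = a[np.searchsorted(a, hi, side="left")]
        tp_b = b[np.searchsorted(b, lo, side="right") - 1]
        tf_b = b[np.searchsorted(b, hi, side="left")]
        dp_a = _nearest_dist(tp_a, b)
        df_a = _nearest_dist(tf_a, b)
        dp_b = _nearest_dist(tp_b, a)
        df_b = _nearest_dist(tf_b, a)
        s_lo = _profile_value(lo, tp_a, tf_a, dp_a, df_a, tp_b, tf_b, dp_b, df_b)
        s_hi = _profile_value(hi, tp_a, tf_a, dp_a, df_a, tp_b, tf_b, dp_b, df_b)
        total += 0.5 * (s_lo + s_hi) * (hi - lo)
    return total / (t1 - t0)


def reliability(
    raster,
    subset: np.ndarray | list[int],
    interval: tuple[float, float] | None = None,
    condition: str = "",
) -> ReliabilitySummary:
    """Mean pairwise SPIKE distance across trials, per neuron in ``subset``.

    ``raster`` is a :class:`~thetagate.engine.SpikeRaster` (or anything with
    ``trains(cell)`` and ``duration``).  Requires at least two trials.
    """
    if raster.n_trials < 2:
        raise ValueError("reliability needs at least 2 trials")
    if interval is None:
        interval = (0.0, raster.duration)
    subset = np.asarray(subset, dtype=int)
    means = np.empty(subset.size)
    for out_idx, cell in enumerate(subset):
        trains = raster.trains(int(cell))
        dists = []
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                dists.append(spike_train_distance(trains[i], trains[j], interval))
        means[out_idx] = float(np.mean(dists))
    return ReliabilitySummary(
        neuron_indices=subset, mean_distance=means, condition=condition
    )


def rate_map(
    trains: list[np.ndarray],
    sigma: float = 20.0,
    duration: float | None = None,
    bin_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate vs time, Gaussian-smoothed.

    Returns (bin centers ms, rate in spikes/ms).  The integral of the rate
    over the duration equals the mean spike count per trial (up to edge
    truncation of the kernel for spikes within ~4σ of the boundaries).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if duration is None:
        duration = max((float(tr[-1]) for tr in trains if len(tr)), default=0.0) + 4 * sigma
    n_bins = max(1, int(np.ceil(duration / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts = np.zeros(n_bins)
    for tr in trains:
        counts += np.histogram(tr, bins=edges)[0]
    density = counts / (len(trains) * bin_ms)  # spikes per ms, trial-averaged
    half = int(np.ceil(4 * sigma / bin_ms))
    x = np.arange(-half, half + 1) * bin_ms
    kernel = np.exp(-(x ** 2) / (2 * sigma ** 2))
    kernel /= kernel.sum()
    rate = np.convolve(density, kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate
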