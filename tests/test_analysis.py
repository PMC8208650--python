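"""Spike-train distance, reliability, phases and rate maps.

The SPIKE-distance implementation (exact piecewise integration) is checked
against an independent brute-force oracle that evaluates the dissimilarity
profile from its definition on a dense time grid and averages it.
"""

import numpy as np
import pytest

from thetagate.analysis import (
    circular_mean,
    phase_histogram,
    rate_map,
    reliability,
    spike_phase,
    spike_train_distance,
)
from thetagate.engine import SpikeRaster
from thetagate.experiments import generate_fixtures
from thetagate.synapses import ThetaDrive


# --- brute-force oracle ----------------------------------------------------

def grid_spike_distance(a, b, t0, t1, n_grid=20000):
    """Average of the dissimilarity profile sampled on a dense grid.

    Independent of the package implementation: nearest-spike searches are
    done per sample point directly from the definition.
    """
    def with_aux(tr):
        tr = np.asarray(tr, float)
        tr = tr[(tr >= t0) & (tr <= t1)]
        if tr.size == 0 or tr[0] > t0:
            tr = np.r_[t0, tr]
        if tr[-1] < t1:
            tr = np.r_[tr, t1]
        return tr

    a, b = with_aux(a), with_aux(b)
    ts = t0 + (np.arange(n_grid) + 0.5) * (t1 - t0) / n_grid
    vals = np.empty(n_grid)
    for k, t in enumerate(ts):
        def side(x, y):
            ip = np.searchsorted(x, t, side="right") - 1
            tp, tf = x[max(ip, 0)], x[min(ip + 1, x.size - 1)]
            if t < x[0]:
                tp = x[0]
            dp = np.min(np.abs(y - tp))
            df = np.min(np.abs(y - tf))
            xisi = tf - tp if tf > tp else np.inf
            s = (dp * (tf - t) + df * (t - tp)) / xisi if np.isfinite(xisi) else 0.0
            return s, (tf - tp if tf > tp else 0.0)

        s1, x1 = side(a, b)
        s2, x2 = side(b, a)
        if x1 == 0.0 or x2 == 0.0:
            vals[k] = 0.0
        else:
            vals[k] = (s1 * x2 + s2 * x1) / (2 * ((x1 + x2) / 2) ** 2)
    return vals.mean()


class TestSpikeDistance:
    def test_identical_trains_zero(self):
        tr = np.array([100.0, 250.0, 600.0])
        assert spike_train_distance(tr, tr, (0.0, 1000.0)) == 0.0

    def test_both_empty_zero(self):
        e = np.empty(0)
        assert spike_train_distance(e, e, (0.0, 1000.0)) == 0.0

    def test_symmetry(self):
        a = np.array([120.0, 480.0, 700.0])
        b = np.array([150.0, 500.0])
        d1 = spike_train_distance(a, b, (0.0, 1000.0))
        d2 = spike_train_distance(b, a, (0.0, 1000.0))
        assert d1 == pytest.approx(d2, abs=1e-14)
        assert d1 > 0

    def test_two_spike_toy_matches_grid_oracle(self):
        a, b = generate_fixtures("two_spike_toy")
        exact = spike_train_distance(a, b, (0.0, 1000.0))
        brute = grid_spike_distance(a, b, 0.0, 1000.0)
        assert exact == pytest.approx(brute, abs=1e-4)

    def test_random_pairs_match_grid_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            na, nb = rng.integers(0, 8, size=2)
            a = np.sort(rng.uniform(0, 1000, size=na))
            b = np.sort(rng.uniform(0, 1000, size=nb))
            exact = spike_train_distance(a, b, (0.0, 1000.0))
            brute = grid_spike_distance(a, b, 0.0, 1000.0)
            assert exact == pytest.approx(brute, abs=1e-4)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            a = np.sort(rng.uniform(0, 500, size=rng.integers(0, 20)))
            b = np.sort(rng.uniform(0, 500, size=rng.integers(0, 20)))
            d = spike_train_distance(a, b, (0.0, 500.0))
            assert 0.0 <= d <= 1.0


def _toy_raster(trains_by_trial):
    n_cells = len(trains_by_trial[0])
    return SpikeRaster(
        spikes=[[np.asarray(tr, float) for tr in trial] for trial in trains_by_trial],
        n_stellate=0, n_interneuron=n_cells, duration=1000.0, dt=0.01,
    )


class TestReliability:
    def test_identical_trials_zero(self):
        raster = _toy_raster([[[100.0, 300.0]], [[100.0, 300.0]], [[100.0, 300.0]]])
        rel = reliability(raster, [0])
        assert rel.mean_distance[0] == 0.0

    def test_two_trials_single_pair(self):
        a, b = [100.0, 300.0], [120.0, 280.0]
        raster = _toy_raster([[a], [b]])
        rel = reliability(raster, [0])
        direct = spike_train_distance(np.array(a), np.array(b), (0.0, 1000.0))
        assert rel.mean_distance[0] == pytest.approx(direct)

    def test_invariant_under_trial_relabeling(self):
        trials = [[[100.0 + 7 * k, 400.0 - 11 * k]] for k in range(4)]
        rel = reliability(_toy_raster(trials), [0])
        rel_perm = reliability(_toy_raster(trials[::-1]), [0])
        assert rel.mean_distance[0] == pytest.approx(rel_perm.mean_distance[0])

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            reliability(_toy_raster([[[1.0]]]), [0])

    def test_summary_table_is_columnar_text(self):
        raster = _toy_raster([[[100.0]], [[150.0]]])
        rel = reliability(raster, [0], condition="theta")
        lines = rel.to_table().splitlines()
        assert lines[0].startswith("#")
        idx, dist, cond = lines[1].split("\t")
        assert cond == "theta" and 0.0 <= float(dist) <= 1.0


class TestSpikePhase:
    def test_landmarks_at_8hz(self):
        d = ThetaDrive(freq_hz=8.0, phase_offset=0.0)
        assert spike_phase(0.0, d) == pytest.approx(0.0)
        assert spike_phase(125.0, d) == pytest.approx(0.0, abs=1e-9)
        assert spike_phase(62.5, d) == pytest.approx(np.pi)

    def test_histogram_counts_and_circular_mean(self):
        counts, edges, mean, r = phase_histogram(np.full(40, np.pi), n_bins=8)
        assert counts.sum() == 40
        assert mean == pytest.approx(np.pi)
        assert r == pytest.approx(1.0)

    def test_empty_histogram(self):
        counts, _, mean, r = phase_histogram(np.empty(0), n_bins=8)
        assert counts.sum() == 0
        assert r == 0.0

    def test_uniform_phases_have_small_resultant(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 2 * np.pi, size=10_000)
        _, _, _, r = phase_histogram(phases)
        assert r < 0.05

    def test_circular_mean_against_scipy(self):
        from scipy.stats import circmean

        rng = np.random.default_rng(4)
        phases = rng.vonmises(1.0, 2.0, size=500) % (2 * np.pi)
        mean, _ = circular_mean(phases)
        assert mean == pytest.approx(circmean(phases, high=2 * np.pi), abs=1e-9)

    def test_rejects_too_few_bins(self):
        with pytest.raises(ValueError):
            phase_histogram(np.array([0.1]), n_bins=2)


class TestRateMap:
    def test_no_spikes_all_zero(self):
        _, rate = rate_map([np.empty(0)], sigma=20.0, duration=1000.0)
        assert (rate == 0).all()

    def test_single_spike_unit_integral(self):
        centers, rate = rate_map([np.array([500.0])], sigma=20.0, duration=1000.0)
        assert np.argmax(rate) == pytest.approx(500, abs=2)
        assert np.trapezoid(rate, centers) == pytest.approx(1.0, abs=1e-3)

    def test_integral_equals_mean_count_per_trial(self):
        trains = [np.array([200.0, 600.0]), np.array([210.0, 590.0, 800.0])]
        centers, rate = rate_map(trains, sigma=15.0, duration=1000.0)
        assert np.trapezoid(rate, centers) == pytest.approx(2.5, abs=1e-2)

    def test_periodic_spikes_produce_periodic_peaks(self):
        period = 250.0
        trains = [np.arange(125.0, 2000.0, period)]
        centers, rate = rate_map(trains, sigma=10.0, duration=2000.0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(rate)
        assert np.allclose(np.diff(centers[peaks]), period, atol=2.0)
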