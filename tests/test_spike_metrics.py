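"""PSTH, epoch-rate, SDF and peak metrics against counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspmap import (
    SessionConfig,
    TrialRecord,
    align_to_touch,
    compute_epoch_rates,
    compute_psth,
    generate_session,
    net_normalized_activity,
    peak_activity,
    smooth_sdf,
)
from graspmap.spike_metrics import (
    EmptyConditionError,
    MissingTrialError,
    NeuronRecording,
    NonIncreasingNeuronError,
    Psth,
    gaussian_kernel,
)


def trial(tid, outcome="success", touch=10.0):
    return TrialRecord(tid, outcome, touch, (touch - 0.5, touch - 0.25, touch, touch + 0.25))


def neuron(spikes_by_trial):
    return NeuronRecording("n0", "r0", (2.5, 0.5), {
        k: np.asarray(v, dtype=float) for k, v in spikes_by_trial.items()
    })


class TestAlign:
    def test_subtracts_touch_time(self):
        aligned = align_to_touch(neuron({0: [10.0, 10.2]}), [trial(0)])
        np.testing.assert_allclose(aligned[0], [0.0, 0.2])

    def test_empty_trial_stays_empty(self):
        aligned = align_to_touch(neuron({0: []}), [trial(0)])
        assert aligned[0].size == 0

    def test_zero_offset_idempotent(self, rng):
        spikes = np.sort(rng.uniform(-1, 1, 20))
        t = TrialRecord(0, "success", 0.0, (-0.5, -0.25, 0.0, 0.25))
        once = align_to_touch(neuron({0: spikes}), [t])
        twice = align_to_touch(neuron({0: once[0]}), [t])
        np.testing.assert_array_equal(once[0], twice[0])

    def test_missing_trial_reports_ids(self):
        with pytest.raises(MissingTrialError, match=r"\[1\]"):
            align_to_touch(neuron({0: [], 1: []}), [trial(0)])


class TestPsth:
    def test_one_spike_per_trial_in_one_bin(self):
        trials = [trial(i) for i in range(7)]
        aligned = {i: np.array([0.01]) for i in range(7)}  # bin [0, 0.02)
        psth = compute_psth(aligned, trials)
        idx = np.searchsorted(psth.bin_edges, 0.01) - 1
        assert psth.mean_rate[idx] == pytest.approx(50.0)
        assert psth.mean_rate.sum() == pytest.approx(50.0)

    def test_homogeneous_poisson_flat(self, rng):
        trials = [trial(i) for i in range(500)]
        aligned = {
            i: np.sort(rng.uniform(-1.0, 0.3, rng.poisson(13)))
            for i in range(500)
        }
        psth = compute_psth(aligned, trials)
        se = np.sqrt(10.0 / (0.020 * 500))  # Poisson SE per bin
        assert np.all(np.abs(psth.mean_rate - 10.0) < 3 * se)

    def test_no_spikes_all_zero(self):
        psth = compute_psth({0: np.array([])}, [trial(0)])
        assert np.all(psth.mean_rate == 0)

    def test_empty_condition_raises(self):
        with pytest.raises(EmptyConditionError):
            compute_psth({0: np.array([])}, [trial(0)], condition="failure")

    def test_window_must_tile(self):
        with pytest.raises(ValueError, match="multiple"):
            compute_psth({0: np.array([])}, [trial(0)], window=(-1.0, 0.305))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_spike_count_conserved(self, seed):
        r = np.random.default_rng(seed)
        n_trials = int(r.integers(1, 6))
        trials = [trial(i) for i in range(n_trials)]
        aligned = {
            i: np.sort(r.uniform(-1.0, 0.3 - 1e-9, r.integers(0, 30)))
            for i in range(n_trials)
        }
        psth = compute_psth(aligned, trials)
        total = sum(len(v) for v in aligned.values())
        assert psth.mean_rate.sum() * 0.020 * n_trials == pytest.approx(total)


class TestEpochRates:
    def test_baseline_spikes_counted(self):
        er = compute_epoch_rates({0: np.array([-0.9, -0.8, -0.75])})
        np.testing.assert_allclose(er.rates[0], [10.0, 0.0, 0.0])

    def test_touch_spike_is_post_touch(self):
        er = compute_epoch_rates({0: np.array([0.0])})
        assert er.column("post")[0] == pytest.approx(1 / 0.3)
        assert er.column("pre")[0] == 0.0

    def test_epoch_rates_equal_psth_bin_average(self, rng):
        # consistency: each epoch covers exactly 15 PSTH bins
        trials = [trial(i) for i in range(20)]
        aligned = {
            i: np.sort(rng.uniform(-1.0, 0.3 - 1e-9, 25)) for i in range(20)
        }
        psth = compute_psth(aligned, trials)
        er = compute_epoch_rates(aligned)
        centers = psth.bin_centers
        for name, (lo, hi) in (("baseline", (-1.0, -0.7)), ("pre", (-0.3, 0.0)), ("post", (0.0, 0.3))):
            sel = (centers > lo) & (centers < hi)
            assert sel.sum() == 15
            assert psth.mean_rate[sel].mean() == pytest.approx(
                er.column(name).mean()
            )

    def test_pre_dominant_generator_ordering(self):
        trials, neurons, _ = generate_session(
            {"pre_dominant": 1}, SessionConfig(n_trials=200, seed=3)
        )
        er = compute_epoch_rates(align_to_touch(neurons[0], trials))
        assert er.column("pre").mean() > er.column("baseline").mean()


def brute_force_smooth(y, width):
    """Independent oracle: direct summation with edge renormalization."""
    k = gaussian_kernel(width)
    half = (width - 1) // 2
    out = np.zeros_like(y, dtype=float)
    for i in range(len(y)):
        num = den = 0.0
        for j, kj in enumerate(k):
            idx = i + j - half
            if 0 <= idx < len(y):
                num += kj * y[idx]
                den += kj
        out[i] = num / den
    return out


class TestSdf:
    def test_constant_preserved(self):
        psth = Psth(np.arange(66) * 0.02 - 1.0, np.full(65, 7.3), 10, "pooled")
        np.testing.assert_allclose(smooth_sdf(psth), 7.3)

    def test_impulse_becomes_symmetric_bell(self):
        y = np.zeros(65)
        y[32] = 50.0
        psth = Psth(np.arange(66) * 0.02 - 1.0, y, 10, "pooled")
        sdf = smooth_sdf(psth)
        assert sdf.sum() == pytest.approx(50.0)  # area conserved (interior)
        np.testing.assert_allclose(sdf[32 - 7 : 32], sdf[32 + 7 : 32 : -1])
        assert np.argmax(sdf) == 32

    def test_matches_brute_force_convolution(self, rng):
        y = rng.uniform(0, 30, 65)
        psth = Psth(np.arange(66) * 0.02 - 1.0, y, 10, "pooled")
        np.testing.assert_allclose(
            smooth_sdf(psth), brute_force_smooth(y, 15), atol=1e-12
        )

    def test_linear_and_positive(self, rng):
        a, b = rng.uniform(0, 10, 65), rng.uniform(0, 10, 65)
        pa = Psth(np.arange(66) * 0.02 - 1.0, a, 1, "pooled")
        pb = Psth(np.arange(66) * 0.02 - 1.0, b, 1, "pooled")
        pab = Psth(np.arange(66) * 0.02 - 1.0, 2 * a + b, 1, "pooled")
        np.testing.assert_allclose(
            smooth_sdf(pab), 2 * smooth_sdf(pa) + smooth_sdf(pb), atol=1e-10
        )
        assert np.all(smooth_sdf(pa) >= 0)

    def test_kernel_wider_than_signal(self):
        psth = Psth(np.arange(6) * 0.02, np.ones(5), 1, "pooled")
        with pytest.raises(ValueError, match="wider"):
            smooth_sdf(psth, kernel_width_bins=15)


class TestNetNormalizedActivity:
    def run_on_session(self, archetype, n_trials=300, seed=4):
        trials, neurons, _ = generate_session(
            {archetype: 1}, SessionConfig(n_trials=n_trials, seed=seed)
        )
        aligned = align_to_touch(neurons[0], trials)
        by_outcome = {
            o: {t.trial_id: aligned[t.trial_id] for t in trials if t.outcome == o}
            for o in ("success", "failure")
        }
        rates = {o: compute_epoch_rates(v) for o, v in by_outcome.items()}
        psth = {o: compute_psth(aligned, trials, condition=o) for o in rates}
        sdf = {o: smooth_sdf(psth[o]) for o in rates}
        return rates, sdf, psth["success"].bin_centers

    def test_flat_neuron_raises_exclusion(self):
        rates, sdf, centers = self.run_on_session("unmodulated")
        # force exactly-flat activity: a neuron pinned at its baseline can
        # never exceed the pooled baseline, so no [0, 1] scale exists
        level = np.mean([rates[o].rates.mean() for o in rates])
        flat = {o: np.full_like(sdf[o], level) for o in sdf}
        for o in flat:
            rates[o].rates[:] = level
        with pytest.raises(NonIncreasingNeuronError):
            net_normalized_activity(rates, flat, centers)

    def test_pre_dominant_ordering_and_range(self):
        rates, sdf, centers = self.run_on_session("pre_dominant")
        net = net_normalized_activity(rates, sdf, centers)
        for o in ("success", "failure"):
            assert net[(o, "pre")] > net[(o, "post")]
        assert all(0.0 <= v <= 1.05 for v in net.values())

    def test_requires_both_outcomes(self):
        rates, sdf, centers = self.run_on_session("pre_dominant")
        with pytest.raises(ValueError, match="both outcomes"):
            net_normalized_activity(
                {"success": rates["success"]}, {"success": sdf["success"]}, centers
            )


class TestPeak:
    def test_impulse_timing(self):
        sdf = np.zeros(65)
        sdf[10] = 3.0
        centers = np.arange(65) * 0.02 - 0.99
        pk = peak_activity(sdf, centers)
        assert pk.timing == pytest.approx(centers[10])
        assert pk.amplitude == 3.0

    def test_tie_reports_earliest(self):
        sdf = np.zeros(65)
        sdf[[10, 40]] = 3.0
        centers = np.arange(65) * 0.02 - 0.99
        assert peak_activity(sdf, centers).timing == pytest.approx(centers[10])

    def test_post_dominant_peak_recovered(self):
        trials, neurons, _ = generate_session(
            {"post_dominant": 1}, SessionConfig(n_trials=200, seed=5)
        )
        aligned = align_to_touch(neurons[0], trials)
        psth = compute_psth(aligned, trials)
        pk = peak_activity(smooth_sdf(psth), psth.bin_centers)
        assert abs(pk.timing - 0.15) <= 0.04
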