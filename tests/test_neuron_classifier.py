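"""Gate logic, outcome-dependence calibration and the label scheme."""

import numpy as np
import pytest

from graspmap import (
    SessionConfig,
    align_to_touch,
    classify_neuron,
    compute_epoch_rates,
    generate_session,
    modulation_gate,
    outcome_dependence_test,
    epoch_dominance,
    population_summary,
    subpopulation_anova,
    compare_phase_durations,
    compare_peak_activity,
)
from graspmap.neuron_classifier import NeuronLabel
from graspmap.spike_metrics import EpochRates
from graspmap.stats import tukey_rm_contrasts

LABELS = ("baseline", "pre", "post")


def rates_from(baseline, pre, post, rng, n=45, sd=1.0):
    data = np.column_stack(
        [rng.normal(m, sd, n) for m in (baseline, pre, post)]
    )
    return np.clip(data, 0, None)


class TestModulationGate:
    def test_pre_increase_flagged_increasing(self, rng):
        c = tukey_rm_contrasts(rates_from(5, 15, 5, rng), LABELS)
        assert modulation_gate(c) == "increasing"

    def test_post_decrease_only_flagged_decreasing(self, rng):
        c = tukey_rm_contrasts(rates_from(5, 5, 1, rng, sd=0.5), LABELS)
        assert modulation_gate(c) == "decreasing"

    def test_flat_unmodulated(self):
        data = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [3.0, 1.0, 2.0]])
        assert modulation_gate(tukey_rm_contrasts(data, LABELS)) == "unmodulated"


def epoch_rates(arr):
    arr = np.asarray(arr, dtype=float)
    return EpochRates(trial_ids=np.arange(len(arr)), rates=arr)


class TestOutcomeDependence:
    def test_label_swap_preserves_interaction(self, rng):
        s = rates_from(5, 10, 7, rng, n=30)
        f = rates_from(5, 6, 9, rng, n=15)
        res = outcome_dependence_test(epoch_rates(s), epoch_rates(f))
        swapped = outcome_dependence_test(epoch_rates(f), epoch_rates(s))
        assert res["interaction"].p == pytest.approx(swapped["interaction"].p)
        assert res["outcome"].p == pytest.approx(swapped["outcome"].p)

    def test_null_flag_rate_calibrated(self, rng):
        # under H0 the OR of two independent alpha-level tests fires at
        # ~1 - (1 - alpha)^2
        n_sim, flags = 400, 0
        for _ in range(n_sim):
            s = rates_from(5, 5, 5, rng, n=31)
            f = rates_from(5, 5, 5, rng, n=14)
            res = outcome_dependence_test(epoch_rates(s), epoch_rates(f))
            flags += res["outcome"].p < 0.05 or res["interaction"].p < 0.05
        expected = 1 - 0.95**2
        se = np.sqrt(expected * (1 - expected) / n_sim)
        assert abs(flags / n_sim - expected) < 3 * se

    def test_success_only_modulation_detected(self):
        hits, n_seeds = 0, 20
        for seed in range(n_seeds):
            trials, neurons, _ = generate_session(
                {"success_epoch_neutral": 1}, SessionConfig(n_trials=45, seed=seed)
            )
            aligned = align_to_touch(neurons[0], trials)
            by = {
                o: compute_epoch_rates(
                    {t.trial_id: aligned[t.trial_id] for t in trials if t.outcome == o}
                )
                for o in ("success", "failure")
            }
            res = outcome_dependence_test(by["success"], by["failure"])
            hits += res["outcome"].p < 0.05 or res["interaction"].p < 0.05
        assert hits >= 0.9 * n_seeds

    def test_single_outcome_rejected(self, rng):
        s = epoch_rates(rates_from(5, 5, 5, rng, n=2))
        with pytest.raises(ValueError, match="3 trials"):
            outcome_dependence_test(s, s)


class TestDominance:
    def test_equal_epochs_neutral(self):
        data = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [3.0, 1.0, 2.0]])
        assert epoch_dominance(tukey_rm_contrasts(data, LABELS)) == "neutral"

    def test_scale_invariance(self, rng):
        data = rates_from(5, 15, 5, rng)
        a = epoch_dominance(tukey_rm_contrasts(data, LABELS))
        b = epoch_dominance(tukey_rm_contrasts(data * 7.3, LABELS))
        assert a == b == "pre_dominant"


class TestClassifyNeuron:
    @pytest.mark.parametrize(
        "archetype,expected",
        [
            ("pre_dominant", ("outcome_independent", "pre_touch_dominant")),
            ("success_post_dominant", ("outcome_dependent", "success_post_touch_dominant")),
            ("decreasing", ("excluded_decreasing", "none")),
            ("failure_only", ("excluded_failure_only", "none")),
        ],
    )
    def test_archetype_routing(self, archetype, expected):
        trials, neurons, _ = generate_session(
            {archetype: 1}, SessionConfig(n_trials=45, seed=101)
        )
        lab = classify_neuron(neurons[0], trials)
        assert (lab.population, lab.subpopulation) == expected

    def test_evidence_records_p_values(self, small_session):
        trials, neurons, _ = small_session
        lab = classify_neuron(neurons[0], trials)
        assert all(0 <= r.p <= 1 for r in lab.evidence.values())
        assert "pooled_baseline_pre" in lab.evidence

    def test_label_invariants(self):
        with pytest.raises(ValueError):
            NeuronLabel("n0", "unmodulated", "pre_touch_dominant")
        with pytest.raises(ValueError):
            NeuronLabel("n0", "outcome_independent", "none")


class TestPopulationSummary:
    def make_label(self, i, pop, sub):
        net = {(o, e): 0.5 for o in ("success", "failure") for e in ("pre", "post")}
        return NeuronLabel(f"n{i}", pop, sub, net_activity=net)

    def test_small_category_flagged_not_analyzed(self):
        labels = [
            self.make_label(i, "outcome_independent", "epoch_neutral")
            for i in range(3)
        ] + [
            self.make_label(i + 3, "outcome_independent", "pre_touch_dominant")
            for i in range(5)
        ]
        df = population_summary(labels, min_category=4)
        row = df[df.subpopulation == "epoch_neutral"].iloc[0]
        assert row.n == 3 and not row.analyzed
        assert df[df.subpopulation == "pre_touch_dominant"].iloc[0].analyzed

    def test_counts_partition_input(self, small_session):
        trials, neurons, _ = small_session
        labels = [classify_neuron(n, trials) for n in neurons]
        df = population_summary(labels)
        assert df["n"].sum() == len(labels)

    def test_empty_input(self):
        df = population_summary([])
        assert df["n"].sum() == 0


class TestSubpopulationAnova:
    def test_df_error_52_for_14_neurons(self, rng):
        data = rng.normal(0.5, 0.1, (14, 4))
        res = subpopulation_anova(data)
        assert res["epoch"].df == (1.0, 52.0)

    def test_identical_values_flat(self):
        res = subpopulation_anova(np.full((6, 4), 0.4))
        assert all(
            r.statistic == pytest.approx(0.0)
            for k, r in res.items()
            if k in ("outcome", "epoch", "interaction")
        )

    def test_interaction_triggers_bonferroni(self, rng):
        data = rng.normal(0.3, 0.05, (20, 4))
        data[:, 0] += 0.6  # success-pre cell only
        res = subpopulation_anova(data)
        assert res["interaction"].p < 0.05
        assert any(k.startswith("bonferroni") for k in res)

    def test_no_interaction_runs_mann_whitney(self, rng):
        data = rng.normal(0.3, 0.05, (20, 4))
        res = subpopulation_anova(data)
        assert "mw_outcome" in res and "mw_epoch" in res


class TestBehavioralComparisons:
    def test_phase_durations_null_calibration(self):
        nonsig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trials, _, _ = generate_session(
                {"unmodulated": 1}, SessionConfig(n_trials=45, seed=seed)
            )
            res = compare_phase_durations(trials)
            nonsig += all(r.p > 0.05 for r in res.values())
        assert nonsig >= 0.7 * n_seeds  # ~0.86 expected for 3 joint tests

    def test_shifted_failure_durations_detected(self):
        trials, _, _ = generate_session(
            {"unmodulated": 1}, SessionConfig(n_trials=200, seed=3)
        )
        from graspmap import TrialRecord

        shifted = [
            t
            if t.outcome == "success"
            else TrialRecord(
                t.trial_id,
                t.outcome,
                t.touch_time,
                (
                    t.phase_boundaries[0] - 2.0,
                    t.phase_boundaries[1] - 1.0,
                    t.phase_boundaries[2],
                    t.phase_boundaries[3] + 1.0,
                ),
            )
            for t in trials
        ]
        res = compare_phase_durations(shifted)
        assert all(r.p < 0.05 for r in res.values())

    def test_identical_peaks_not_significant(self):
        labels = [
            NeuronLabel(
                f"n{i}",
                "outcome_independent",
                "pre_touch_dominant",
                peaks={"success": (10.0 + i, -0.1), "failure": (10.0 + i, -0.1)},
            )
            for i in range(8)
        ]
        res = compare_peak_activity(labels)
        assert res["amplitude"].p > 0.9
        assert res["timing"].p > 0.9

    def test_suppressed_failure_amplitude_detected(self, rng):
        labels = [
            NeuronLabel(
                f"n{i}",
                "outcome_dependent",
                "success_epoch_neutral",
                peaks={
                    "success": (rng.normal(20, 2), rng.normal(0.0, 0.05)),
                    "failure": (rng.normal(8, 2), rng.normal(0.0, 0.05)),
                },
            )
            for i in range(13)
        ]
        res = compare_peak_activity(labels)
        assert res["amplitude"].p < 0.05
        assert res["timing"].p > 0.05
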