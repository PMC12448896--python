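"""Two-level classification of grasping neurons by epoch and outcome.

Gate sequence per neuron:

1. One-way repeated-measures ANOVA over the three epoch rates (trials as
   subjects), Tukey post-hocs, and a modulation gate: the neuron must show
   a significant *increase* over baseline in at least one touch epoch.
   Significant decreases (with no increase) are excluded from the study;
   neurons increasing only in failed trials are likewise excluded.
2. A trial-level two-factor ANOVA (outcome x epoch on the per-trial pre-
   and post-touch rates) separates outcome-dependent neurons (outcome main
   effect or interaction significant) from outcome-independent ones.
3. Epoch dominance (Tukey pre-post contrast) assigns the subpopulation:
   pre-touch dominant / post-touch dominant / epoch-neutral, computed on
   pooled trials for outcome-independent neurons (requiring concordance
   across outcomes, discordance resolved by the pooled contrast) and on
   successful trials only for outcome-dependent neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .spike_metrics import (
    EpochRates,
    NeuronRecording,
    NonIncreasingNeuronError,
    Psth,
    TrialRecord,
    align_to_touch,
    compute_epoch_rates,
    compute_psth,
    net_normalized_activity,
    peak_activity,
    smooth_sdf,
)
from .stats import TestResult, mann_whitney, rm_anova, tukey_rm_contrasts, two_way_anova

__all__ = [
    "NeuronLabel",
    "modulation_gate",
    "outcome_dependence_test",
    "epoch_dominance",
    "classify_neuron",
    "classify_session",
    "population_summary",
    "subpopulation_anova",
    "compare_phase_durations",
    "compare_peak_activity",
]

POPULATIONS = (
    "outcome_independent",
    "outcome_dependent",
    "excluded_decreasing",
    "excluded_failure_only",
    "unmodulated",
)

EPOCH_LABELS = ("baseline", "pre", "post")


@dataclass
class NeuronLabel:
    neuron_id: str
    population: str
    subpopulation: str = "none"
    evidence: dict[str, TestResult] = field(default_factory=dict)
    net_activity: dict[tuple[str, str], float] | None = None
    peaks: dict[str, tuple[float, float]] | None = None  # outcome -> (amp, t)

    def __post_init__(self):
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        labelled = self.population in ("outcome_independent", "outcome_dependent")
        if labelled == (self.subpopulation == "none"):
            raise ValueError(
                "subpopulation must be set exactly for the two labelled populations"
            )


def modulation_gate(
    contrasts: dict[tuple[str, str], TestResult],
    alpha: float = 0.05,
    omnibus: TestResult | None = None,
) -> str:
    """Route a neuron by its Tukey baseline contrasts.

    increasing: any touch epoch significantly above baseline; decreasing:
    any significantly below and none above; unmodulated otherwise. When the
    omnibus epoch test is supplied, a non-significant omnibus short-
    circuits to unmodulated (post-hocs are only read after the omnibus).
    """
    if omnibus is not None and not omnibus.p < alpha:
        return "unmodulated"
    above = below = False
    for epoch in ("pre", "post"):
        r = contrasts[("baseline", epoch)]
        if r.p < alpha:
            # direction is sign(baseline - epoch): negative means epoch higher
            if r.direction < 0:
                above = True
            elif r.direction > 0:
                below = True
    if above:
        return "increasing"
    if below:
        return "decreasing"
    return "unmodulated"


def outcome_dependence_test(
    rates_success: EpochRates, rates_failure: EpochRates
) -> dict[str, TestResult]:
    """Trial-level outcome x epoch ANOVA on the pre/post-touch rates.

    Each trial contributes its pre- and post-touch rate; outcome varies
    between trials, epoch within. The neuron is flagged outcome-dependent
    when the outcome main effect or the interaction is significant.
    """
    if len(rates_success.trial_ids) < 3 or len(rates_failure.trial_ids) < 3:
        raise ValueError("need at least 3 trials per outcome")
    vals, outc, epoch = [], [], []
    for name, er in (("success", rates_success), ("failure", rates_failure)):
        for ep in ("pre", "post"):
            col = er.column(ep)
            vals.extend(col)
            outc.extend([name] * len(col))
            epoch.extend([ep] * len(col))
    return two_way_anova(
        np.array(vals), np.array(outc), np.array(epoch), names=("outcome", "epoch")
    )


def epoch_dominance(
    contrasts: dict[tuple[str, str], TestResult], alpha: float = 0.05
) -> str:
    """Pre/post dominance from the Tukey pre-post contrast."""
    r = contrasts[("pre", "post")]
    if r.p < alpha:
        return "pre_dominant" if r.direction > 0 else "post_dominant"
    return "neutral"


_SUBPOP_INDEPENDENT = {
    "pre_dominant": "pre_touch_dominant",
    "post_dominant": "post_touch_dominant",
    "neutral": "epoch_neutral",
}
_SUBPOP_DEPENDENT = {
    "pre_dominant": "success_pre_touch_dominant",
    "post_dominant": "success_post_touch_dominant",
    "neutral": "success_epoch_neutral",
}


def classify_neuron(
    recording: NeuronRecording,
    trials: list[TrialRecord],
    config: PipelineConfig | None = None,
) -> NeuronLabel:
    """Run the full gate sequence on one neuron."""
    config = config or PipelineConfig()
    alpha = config.alpha
    aligned = align_to_touch(recording, trials)
    by_outcome = {
        o: {t.trial_id: aligned[t.trial_id] for t in trials if t.outcome == o}
        for o in ("success", "failure")
    }
    if not by_outcome["success"] or not by_outcome["failure"]:
        raise ValueError("classification requires trials of both outcomes")

    evidence: dict[str, TestResult] = {}
    pooled_rates = compute_epoch_rates(aligned)
    evidence["rm_anova_pooled"] = rm_anova(pooled_rates.rates, "rm_anova_pooled")
    pooled_contrasts = tukey_rm_contrasts(pooled_rates.rates, EPOCH_LABELS)
    for key, r in pooled_contrasts.items():
        evidence[f"pooled_{key[0]}_{key[1]}"] = r

    rates = {o: compute_epoch_rates(by_outcome[o]) for o in ("success", "failure")}
    omnibus = {
        o: rm_anova(rates[o].rates, f"rm_anova_{o}") for o in ("success", "failure")
    }
    contrasts = {
        o: tukey_rm_contrasts(rates[o].rates, EPOCH_LABELS)
        for o in ("success", "failure")
    }
    for o in ("success", "failure"):
        evidence[f"rm_anova_{o}"] = omnibus[o]
        for key, r in contrasts[o].items():
            evidence[f"{o}_{key[0]}_{key[1]}"] = r

    gate = modulation_gate(pooled_contrasts, alpha, evidence["rm_anova_pooled"])
    if gate == "decreasing":
        return NeuronLabel(recording.neuron_id, "excluded_decreasing", evidence=evidence)
    success_gate = modulation_gate(contrasts["success"], alpha, omnibus["success"])
    failure_gate = modulation_gate(contrasts["failure"], alpha, omnibus["failure"])
    if gate == "unmodulated" and not (
        success_gate == "increasing" or failure_gate == "increasing"
    ):
        return NeuronLabel(recording.neuron_id, "unmodulated", evidence=evidence)
    if success_gate != "increasing" and failure_gate == "increasing":
        return NeuronLabel(
            recording.neuron_id, "excluded_failure_only", evidence=evidence
        )
    if gate == "unmodulated" and success_gate != "increasing":
        return NeuronLabel(recording.neuron_id, "unmodulated", evidence=evidence)

    dep = outcome_dependence_test(rates["success"], rates["failure"])
    for key, r in dep.items():
        evidence[f"two_way_{key}"] = r
    dependent = dep["outcome"].p < alpha or dep["interaction"].p < alpha

    # net normalized activity and peaks (for the summary tables)
    psth = {
        o: compute_psth(aligned, trials, bin_width=config.bin_width_s, condition=o)
        for o in ("success", "failure")
    }
    sdf = {o: smooth_sdf(psth[o], config.kernel_width_bins) for o in ("success", "failure")}
    centers = psth["success"].bin_centers
    try:
        net = net_normalized_activity(rates, sdf, centers)
    except NonIncreasingNeuronError:
        return NeuronLabel(recording.neuron_id, "excluded_decreasing", evidence=evidence)
    peaks = {
        o: (pk.amplitude, pk.timing)
        for o, pk in ((o, peak_activity(sdf[o], centers)) for o in ("success", "failure"))
    }

    if dependent:
        dom = epoch_dominance(contrasts["success"], alpha)
        sub = _SUBPOP_DEPENDENT[dom]
        pop = "outcome_dependent"
    else:
        doms = {o: epoch_dominance(contrasts[o], alpha) for o in ("success", "failure")}
        dom = (
            doms["success"]
            if doms["success"] == doms["failure"]
            else epoch_dominance(pooled_contrasts, alpha)
        )
        sub = _SUBPOP_INDEPENDENT[dom]
        pop = "outcome_independent"
    return NeuronLabel(
        recording.neuron_id, pop, sub, evidence=evidence, net_activity=net, peaks=peaks
    )


def classify_session(
    neurons: list[NeuronRecording],
    trials: list[TrialRecord],
    config: PipelineConfig | None = None,
) -> list[NeuronLabel]:
    return [classify_neuron(n, trials, config) for n in neurons]


def labels_to_table(labels: list[NeuronLabel]) -> pd.DataFrame:
    rows = []
    for lab in labels:
        row = {
            "neuron_id": lab.neuron_id,
            "population": lab.population,
            "subpopulation": lab.subpopulation,
        }
        for key, r in lab.evidence.items():
            row[f"p_{key}"] = r.p
        if lab.net_activity:
            for (o, ep), v in lab.net_activity.items():
                row[f"net_{o}_{ep}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def population_summary(
    labels: list[NeuronLabel], min_category: int = 4
) -> pd.DataFrame:
    """Subpopulation table: counts and mean +- SEM net normalized activity.

    Categories smaller than ``min_category`` are reported but flagged as
    not analyzed. Layout mirrors the classification-scheme table: one row
    per subpopulation with per-(outcome, epoch) activity columns.
    """
    rows = []
    order = [
        ("outcome_independent", "pre_touch_dominant"),
        ("outcome_independent", "post_touch_dominant"),
        ("outcome_independent", "epoch_neutral"),
        ("outcome_dependent", "success_pre_touch_dominant"),
        ("outcome_dependent", "success_post_touch_dominant"),
        ("outcome_dependent", "success_epoch_neutral"),
        ("unmodulated", "none"),
        ("excluded_decreasing", "none"),
        ("excluded_failure_only", "none"),
    ]
    for pop, sub in order:
        members = [l for l in labels if l.population == pop and l.subpopulation == sub]
        if not members and pop not in dict(order):
            continue
        row: dict = {
            "population": pop,
            "subpopulation": sub,
            "n": len(members),
            "analyzed": len(members) >= min_category and sub != "none",
        }
        acts = [m.net_activity for m in members if m.net_activity]
        for o in ("success", "failure"):
            for ep in ("pre", "post"):
                vals = np.array([a[(o, ep)] for a in acts]) if acts else np.array([])
                row[f"net_{o}_{ep}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"net_{o}_{ep}_sem"] = (
                    vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    assert df["n"].sum() == len(labels), "populations must partition the neurons"
    return df


def subpopulation_anova(
    net_by_neuron: np.ndarray, alpha: float = 0.05
) -> dict[str, TestResult]:
    """Outcome x epoch ANOVA with neurons as replicates.

    ``net_by_neuron`` is (n_neurons, 4) with columns (success-pre,
    success-post, failure-pre, failure-post); the error df is 4n - 4.
    When the interaction is significant the four cell means are compared
    pairwise with Bonferroni-corrected t tests, otherwise per-factor
    Mann-Whitney tests are run.
    """
    data = np.asarray(net_by_neuron, dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError("expected an (n_neurons, 4) table")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    n = data.shape[0]
    vals = data.ravel()
    outc = np.tile(["success", "success", "failure", "failure"], n)
    epoch = np.tile(["pre", "post", "pre", "post"], n)
    res = two_way_anova(vals, outc, epoch, names=("outcome", "epoch"))
    if res["interaction"].p < alpha:
        cells = {
            ("success", "pre"): data[:, 0],
            ("success", "post"): data[:, 1],
            ("failure", "pre"): data[:, 2],
            ("failure", "post"): data[:, 3],
        }
        keys = list(cells)
        pairs = [(keys[i], keys[j]) for i in range(4) for j in range(i + 1, 4)]
        from scipy import stats as sps

        for k1, k2 in pairs:
            t, p = sps.ttest_ind(cells[k1], cells[k2])
            res[f"bonferroni_{k1[0]}_{k1[1]}_vs_{k2[0]}_{k2[1]}"] = TestResult(
                "bonferroni_t",
                float(t),
                (float(2 * n - 2),),
                float(min(1.0, p * len(pairs))),
                int(np.sign(cells[k1].mean() - cells[k2].mean())),
            )
    else:
        res["mw_outcome"] = mann_whitney(
            data[:, :2].ravel(), data[:, 2:].ravel(), "mw_outcome"
        )
        res["mw_epoch"] = mann_whitney(
            data[:, [0, 2]].ravel(), data[:, [1, 3]].ravel(), "mw_epoch"
        )
    return res


def compare_phase_durations(trials: list[TrialRecord]) -> dict[str, TestResult]:
    """Mann-Whitney success-vs-failure comparison of the three phase durations."""
    by_outcome: dict[str, list] = {"success": [], "failure": []}
    for t in trials:
        by_outcome[t.outcome].append(t.phase_durations)
    if not by_outcome["success"] or not by_outcome["failure"]:
        raise ValueError("both outcomes required")
    succ = np.array(by_outcome["success"])
    fail = np.array(by_outcome["failure"])
    return {
        f"phase{i + 1}": mann_whitney(succ[:, i], fail[:, i], f"phase{i + 1}")
        for i in range(3)
    }


def compare_peak_activity(labels: list[NeuronLabel]) -> dict[str, TestResult]:
    """Success-vs-failure Mann-Whitney tests on peak amplitude and timing.

    ``labels`` is one subpopulation's worth of labelled neurons with peaks.
    """
    peaks = [l.peaks for l in labels if l.peaks]
    if len(peaks) < 2:
        raise ValueError("need at least 2 neurons with peaks per outcome")
    amp_s = np.array([p["success"][0] for p in peaks])
    amp_f = np.array([p["failure"][0] for p in peaks])
    t_s = np.array([p["success"][1] for p in peaks])
    t_f = np.array([p["failure"][1] for p in peaks])
    return {
        "amplitude": mann_whitney(amp_s, amp_f, "amplitude"),
        "timing": mann_whitney(t_s, t_f, "timing"),
    }
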