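"""Touch-aligned firing-rate metrics for single-unit grasping recordings.

The quantities defined here are the inputs to the neuron classification
scheme: per-trial epoch rates (baseline / pre-touch / post-touch, 300 ms
each), 20-ms peri-event time histograms, Gaussian-smoothed spike-density
functions, net normalized activity, and peak amplitude/timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ANALYSIS_WINDOW, EPOCHS

__all__ = [
    "TrialRecord",
    "NeuronRecording",
    "Psth",
    "EpochRates",
    "PeakActivity",
    "align_to_touch",
    "compute_psth",
    "compute_epoch_rates",
    "smooth_sdf",
    "net_normalized_activity",
    "peak_activity",
]


@dataclass(frozen=True)
class TrialRecord:
    """One grasping attempt.

    ``phase_boundaries`` holds four session-clock timestamps: paw lift,
    aperture pass, food touch, aperture re-pass. The third boundary is the
    touch time that all spike metrics align to.
    """

    trial_id: int
    outcome: str  # "success" | "failure"
    touch_time: float
    phase_boundaries: tuple[float, float, float, float]

    def __post_init__(self):
        if self.outcome not in ("success", "failure"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        b = self.phase_boundaries
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError(
                f"trial {self.trial_id}: phase boundaries must strictly increase"
            )
        if abs(b[2] - self.touch_time) > 1e-9:
            raise ValueError(
                f"trial {self.trial_id}: touch_time must equal third boundary"
            )

    @property
    def phase_durations(self) -> tuple[float, float, float]:
        b = self.phase_boundaries
        return (b[1] - b[0], b[2] - b[1], b[3] - b[2])


@dataclass
class NeuronRecording:
    """Spike times of one neuron across trials, plus its grid position.

    ``spikes`` maps trial_id -> sorted spike times on the session clock.
    ``position`` is (ML, AP) in bregma-relative mm.
    """

    neuron_id: str
    rat_id: str
    position: tuple[float, float]
    spikes: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class Psth:
    """Trial-averaged peri-touch histogram in spikes/s, 20-ms bins."""

    bin_edges: np.ndarray
    mean_rate: np.ndarray
    n_trials: int
    condition: str  # "success" | "failure" | "pooled"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class EpochRates:
    """Per-trial mean rates (spikes/s) in the three 300-ms epochs.

    ``rates`` is an (n_trials, 3) array with columns baseline, pre, post.
    """

    trial_ids: np.ndarray
    rates: np.ndarray
    columns: tuple[str, str, str] = ("baseline", "pre", "post")

    def column(self, name: str) -> np.ndarray:
        return self.rates[:, self.columns.index(name)]


@dataclass(frozen=True)
class PeakActivity:
    amplitude: float  # spikes/s (or normalized units)
    timing: float     # s relative to touch


class MissingTrialError(KeyError):
    pass


class EmptyConditionError(ValueError):
    pass


def align_to_touch(
    recording: NeuronRecording, trials: list[TrialRecord]
) -> dict[int, np.ndarray]:
    """Re-reference each trial's spike times to its food-touch time.

    Returns trial_id -> spike times in seconds relative to touch. Every
    trial_id present in the recording must have a TrialRecord.
    """
    touch = {t.trial_id: t.touch_time for t in trials}
    missing = sorted(set(recording.spikes) - set(touch))
    if missing:
        raise MissingTrialError(
            f"neuron {recording.neuron_id}: no TrialRecord for trials {missing}"
        )
    return {
        tid: np.asarray(st, dtype=float) - touch[tid]
        for tid, st in recording.spikes.items()
    }


def compute_psth(
    aligned: dict[int, np.ndarray],
    trials: list[TrialRecord],
    window: tuple[float, float] = ANALYSIS_WINDOW,
    bin_width: float = 0.020,
    condition: str = "pooled",
) -> Psth:
    """Bin touch-aligned spikes into a trial-averaged rate histogram.

    Bin value = total spikes in bin across the condition's trials divided by
    (n_trials x bin_width), in spikes/s.
    """
    n_bins = (window[1] - window[0]) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window must be a multiple of bin_width")
    n_bins = int(round(n_bins))
    if condition == "pooled":
        keep = [t.trial_id for t in trials]
    else:
        keep = [t.trial_id for t in trials if t.outcome == condition]
    keep = [tid for tid in keep if tid in aligned]
    if not keep:
        raise EmptyConditionError(f"no trials in condition {condition!r}")
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for tid in keep:
        counts += np.histogram(aligned[tid], bins=edges)[0]
    return Psth(
        bin_edges=edges,
        mean_rate=counts / (len(keep) * bin_width),
        n_trials=len(keep),
        condition=condition,
    )


def compute_epoch_rates(aligned: dict[int, np.ndarray]) -> EpochRates:
    """Per-trial mean rate in each 300-ms epoch (half-open intervals)."""
    tids = np.array(sorted(aligned))
    rates = np.zeros((len(tids), 3))
    for i, tid in enumerate(tids):
        st = aligned[tid]
        for j, name in enumerate(("baseline", "pre", "post")):
            lo, hi = EPOCHS[name]
            rates[i, j] = np.count_nonzero((st >= lo) & (st < hi)) / (hi - lo)
    return EpochRates(trial_ids=tids, rates=rates)


def gaussian_kernel(width_bins: int) -> np.ndarray:
    """Unit-area Gaussian kernel truncated to ``width_bins`` bins.

    The kernel SD is width/6 bins, so the truncated support covers +-3 SD.
    """
    if width_bins < 1:
        raise ValueError("kernel width must be >= 1 bin")
    sd = width_bins / 6.0
    half = (width_bins - 1) / 2.0
    x = np.arange(width_bins) - half
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def smooth_sdf(psth: Psth, kernel_width_bins: int = 15) -> np.ndarray:
    """Gaussian-smoothed spike-density function, same length as the PSTH.

    Edges are handled by renormalizing the overlapping kernel mass, so a
    constant input stays exactly constant.
    """
    y = psth.mean_rate
    if len(y) == 0:
        raise ValueError("empty PSTH")
    if kernel_width_bins > len(y):
        raise ValueError("kernel wider than signal")
    k = gaussian_kernel(kernel_width_bins)
    num = np.convolve(y, k, mode="same")
    den = np.convolve(np.ones_like(y), k, mode="same")
    return num / den


class NonIncreasingNeuronError(ValueError):
    """The neuron never rises above its pooled baseline; it cannot be put on
    the [0, 1] net-normalized-activity scale and is routed to exclusion."""


def net_normalized_activity(
    epoch_rates: dict[str, EpochRates],
    sdf: dict[str, np.ndarray],
    psth_bin_centers: np.ndarray,
) -> dict[tuple[str, str], float]:
    """Baseline-subtracted, peak-normalized epoch activity per (outcome, epoch).

    net = epoch mean rate - pooled baseline mean rate; the normalizer is the
    neuron's maximum baseline-subtracted smoothed SDF value across both
    outcomes over the analysis window. Negative values clip to 0.
    """
    if set(epoch_rates) != {"success", "failure"} or set(sdf) != {
        "success",
        "failure",
    }:
        raise ValueError("both outcomes required")
    pooled_baseline = np.concatenate(
        [epoch_rates[o].column("baseline") for o in ("success", "failure")]
    ).mean()
    in_window = (psth_bin_centers >= ANALYSIS_WINDOW[0]) & (
        psth_bin_centers <= ANALYSIS_WINDOW[1]
    )
    normalizer = max(
        float(np.max(sdf[o][in_window] - pooled_baseline)) for o in ("success", "failure")
    )
    if normalizer <= 0:
        raise NonIncreasingNeuronError(
            "SDF never exceeds pooled baseline; neuron routed to exclusion"
        )
    out: dict[tuple[str, str], float] = {}
    for o in ("success", "failure"):
        for epoch in ("pre", "post"):
            net = epoch_rates[o].column(epoch).mean() - pooled_baseline
            out[(o, epoch)] = max(0.0, net / normalizer)
    return out


def peak_activity(
    sdf: np.ndarray,
    bin_centers: np.ndarray,
    window: tuple[float, float] = ANALYSIS_WINDOW,
) -> PeakActivity:
    """Maximum SDF value and the center of the earliest bin attaining it."""
    if len(sdf) == 0:
        raise ValueError("empty SDF")
    mask = (bin_centers >= window[0]) & (bin_centers <= window[1])
    vals, times = sdf[mask], bin_centers[mask]
    idx = int(np.argmax(vals))  # argmax returns the earliest maximum
    return PeakActivity(amplitude=float(vals[idx]), timing=float(times[idx]))
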