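"""Synthetic recording sessions and ICMS kinematic datasets.

The generator emulates the statistical structure the downstream analysis
assumes — ~40-50 grasping trials per session at ~70% success, three task
phases of ~250 ms, inhomogeneous-Poisson neurons of nine rate archetypes on
a 4x8 electrode grid (0.5 mm pitch), and stimulation-evoked marker
trajectories per movement class over a breathing background — with known
ground truth so that recovery of labels and site calls can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ANALYSIS_WINDOW, EPOCHS
from .spike_metrics import NeuronRecording, TrialRecord

__all__ = [
    "GridSpec",
    "ArchetypeSpec",
    "SessionConfig",
    "IcmsLayout",
    "MarkerTrajectorySet",
    "ARCHETYPES",
    "EXPECTED_LABELS",
    "generate_session",
    "generate_icms_animal",
    "default_icms_layout",
]


@dataclass(frozen=True)
class GridSpec:
    """Bregma-relative electrode/penetration grid (mm)."""

    ml_range: tuple[float, float] = (2.5, 4.0)
    ap_range: tuple[float, float] = (0.5, 4.0)
    pitch: float = 0.5
    n_cols: int = 4   # ML
    n_rows: int = 8   # AP

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        for rng, n in ((self.ml_range, self.n_cols), (self.ap_range, self.n_rows)):
            span = rng[1] - rng[0]
            if abs(span - (n - 1) * self.pitch) > 1e-9:
                raise ValueError("gridpoints must tile the ranges exactly")

    @property
    def n_points(self) -> int:
        return self.n_cols * self.n_rows

    def gridpoints(self) -> np.ndarray:
        """(n_points, 2) array of (ML, AP) positions, ML-major order."""
        ml = self.ml_range[0] + self.pitch * np.arange(self.n_cols)
        ap = self.ap_range[0] + self.pitch * np.arange(self.n_rows)
        mm, aa = np.meshgrid(ml, ap, indexing="ij")
        return np.column_stack([mm.ravel(), aa.ravel()])


@dataclass(frozen=True)
class ArchetypeSpec:
    """Rate archetype: baseline rate times per-(outcome, epoch) gains.

    ``epoch_gains[outcome]`` maps "pre"/"post" to a multiplicative factor on
    the baseline rate for that epoch; the baseline epoch gain is always 1.
    Gains > 1 are realized as Gaussian bumps normalized so the epoch-mean
    rate equals ``baseline_rate * gain`` exactly; gains < 1 as peak-
    normalized dips (the rate never goes negative).
    """

    name: str
    baseline_rate: float = 5.0
    epoch_gains: dict[str, dict[str, float]] = field(default_factory=dict)
    peak_times: dict[str, float] = field(
        default_factory=lambda: {"pre": -0.15, "post": 0.15}
    )
    peak_width: float = 0.075  # Gaussian SD, s

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for gains in self.epoch_gains.values():
            if any(g < 0 for g in gains.values()):
                raise ValueError("gains must be >= 0")

    def gains(self, outcome: str) -> dict[str, float]:
        return self.epoch_gains.get(outcome, {"pre": 1.0, "post": 1.0})

    def rate(self, t: np.ndarray, outcome: str) -> np.ndarray:
        """Instantaneous rate (spikes/s) at touch-relative times ``t``."""
        g = np.ones_like(t, dtype=float)
        for epoch, gain in self.gains(outcome).items():
            if gain == 1.0:
                continue
            lo, hi = EPOCHS[epoch]
            c, sd = self.peak_times[epoch], self.peak_width
            bump = np.exp(-0.5 * ((t - c) / sd) ** 2)
            if gain > 1.0:
                # normalize so the epoch-average of the bump is 1
                mass = (
                    sd
                    * math.sqrt(2 * math.pi)
                    * 0.5
                    * (math.erf((hi - c) / (sd * math.sqrt(2)))
                       - math.erf((lo - c) / (sd * math.sqrt(2))))
                )
                bump = bump / (mass / (hi - lo))
            g += (gain - 1.0) * bump
        return self.baseline_rate * np.clip(g, 0.0, None)

    def max_rate(self, outcome: str) -> float:
        t = np.linspace(ANALYSIS_WINDOW[0] - 0.1, ANALYSIS_WINDOW[1] + 0.1, 2001)
        return float(self.rate(t, outcome).max())


def _gains(s_pre, s_post, f_pre, f_post):
    return {
        "success": {"pre": s_pre, "post": s_post},
        "failure": {"pre": f_pre, "post": f_post},
    }


#: The nine generator archetypes. Dominant epochs get a 4x gain, neutral
#: elevated epochs 3x; outcome-dependent archetypes modulate success trials
#: while failure trials are either mildly elevated in both epochs ("neutral
#: response") or at baseline ("silent response").
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "pre_dominant": ArchetypeSpec("pre_dominant", epoch_gains=_gains(4, 1, 4, 1)),
    "post_dominant": ArchetypeSpec("post_dominant", epoch_gains=_gains(1, 4, 1, 4)),
    "epoch_neutral": ArchetypeSpec("epoch_neutral", epoch_gains=_gains(3, 3, 3, 3)),
    "success_pre_dominant": ArchetypeSpec(
        "success_pre_dominant", epoch_gains=_gains(4, 1, 2, 2)
    ),
    "success_post_dominant": ArchetypeSpec(
        "success_post_dominant", epoch_gains=_gains(1, 4, 2, 2)
    ),
    "success_epoch_neutral": ArchetypeSpec(
        "success_epoch_neutral", epoch_gains=_gains(3, 3, 1, 1)
    ),
    "unmodulated": ArchetypeSpec("unmodulated", epoch_gains=_gains(1, 1, 1, 1)),
    "decreasing": ArchetypeSpec("decreasing", epoch_gains=_gains(0.2, 0.2, 0.2, 0.2)),
    "failure_only": ArchetypeSpec("failure_only", epoch_gains=_gains(1, 1, 4, 4)),
}

#: Ground-truth (population, subpopulation) label per archetype.
EXPECTED_LABELS: dict[str, tuple[str, str]] = {
    "pre_dominant": ("outcome_independent", "pre_touch_dominant"),
    "post_dominant": ("outcome_independent", "post_touch_dominant"),
    "epoch_neutral": ("outcome_independent", "epoch_neutral"),
    "success_pre_dominant": ("outcome_dependent", "success_pre_touch_dominant"),
    "success_post_dominant": ("outcome_dependent", "success_post_touch_dominant"),
    "success_epoch_neutral": ("outcome_dependent", "success_epoch_neutral"),
    "unmodulated": ("unmodulated", "none"),
    "decreasing": ("excluded_decreasing", "none"),
    "failure_only": ("excluded_failure_only", "none"),
}


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 45
    p_success: float = 0.7
    phase_means: tuple[float, float, float] = (0.25, 0.25, 0.25)
    phase_jitter_sd: float = 0.05
    iti_range: tuple[float, float] = (20.0, 30.0)
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_success < 1:
            raise ValueError(
                "p_success must be strictly between 0 and 1 "
                "(classification needs both outcomes)"
            )
        if any(m <= 0 for m in self.phase_means):
            raise ValueError("phase means must be positive")


class GridCapacityError(ValueError):
    pass


def _inhomogeneous_poisson(
    rng: np.random.Generator,
    arch: ArchetypeSpec,
    outcome: str,
    window: tuple[float, float],
) -> np.ndarray:
    """Spike times (rel. touch) by thinning a homogeneous bound process."""
    rmax = arch.max_rate(outcome)
    span = window[1] - window[0]
    n = rng.poisson(rmax * span)
    t = np.sort(rng.uniform(window[0], window[1], n))
    keep = rng.uniform(0, rmax, n) < arch.rate(t, outcome)
    return t[keep]


def generate_session(
    archetype_mix: dict[str, int],
    config: SessionConfig,
) -> tuple[list[TrialRecord], list[NeuronRecording], pd.DataFrame]:
    """Simulate one recording session.

    ``archetype_mix`` maps archetype name -> neuron count. Returns the trial
    records, the neuron recordings (placed on distinct gridpoints), and a
    ground-truth table (neuron_id, archetype, true population/subpopulation).
    """
    unknown = set(archetype_mix) - set(ARCHETYPES)
    if unknown:
        raise KeyError(f"unknown archetypes: {sorted(unknown)}")
    n_neurons = sum(archetype_mix.values())
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    if n_neurons > config.grid.n_points:
        raise GridCapacityError(
            f"{n_neurons} neurons exceed {config.grid.n_points} gridpoints"
        )
    rng = np.random.default_rng(config.seed)

    trials: list[TrialRecord] = []
    t_clock = 0.0
    for k in range(config.n_trials):
        t_clock += rng.uniform(*config.iti_range)
        outcome = "success" if rng.uniform() < config.p_success else "failure"
        durs = [
            max(0.05, rng.normal(m, config.phase_jitter_sd))
            for m in config.phase_means
        ]
        touch = t_clock
        trials.append(
            TrialRecord(
                trial_id=k,
                outcome=outcome,
                touch_time=touch,
                phase_boundaries=(
                    touch - durs[0] - durs[1],
                    touch - durs[1],
                    touch,
                    touch + durs[2],
                ),
            )
        )

    positions = config.grid.gridpoints()
    slots = rng.permutation(config.grid.n_points)[:n_neurons]
    window = (ANALYSIS_WINDOW[0] - 0.1, ANALYSIS_WINDOW[1] + 0.1)

    neurons: list[NeuronRecording] = []
    truth_rows = []
    i = 0
    for arch_name in sorted(archetype_mix):
        arch = ARCHETYPES[arch_name]
        for _ in range(archetype_mix[arch_name]):
            nid = f"n{i:03d}"
            spikes = {}
            for tr in trials:
                rel = _inhomogeneous_poisson(rng, arch, tr.outcome, window)
                spikes[tr.trial_id] = rel + tr.touch_time
            neurons.append(
                NeuronRecording(
                    neuron_id=nid,
                    rat_id="synthetic_rat",
                    position=tuple(positions[slots[i]]),
                    spikes=spikes,
                )
            )
            pop, sub = EXPECTED_LABELS[arch_name]
            truth_rows.append(
                {
                    "neuron_id": nid,
                    "archetype": arch_name,
                    "true_population": pop,
                    "true_subpopulation": sub,
                }
            )
            i += 1
    return trials, neurons, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# ICMS kinematics
# --------------------------------------------------------------------------

#: Mean evoked endpoint displacement (mm) of the wrist marker per proximal
#: class and of the paw (digit - wrist) component per distal class, in the
#: marker coordinate frame (x anterior, y lateral, z dorsal). Proximal means
#: are the observed class centroids of evoked rat forelimb movements; distal
#: means are placed well inside each class's decision region.
PROXIMAL_ENDPOINT_MEANS: dict[str, tuple[float, float, float]] = {
    "Abd": (5.08, 21.30, 24.22),
    "Add": (-3.83, -9.70, 4.42),
    "Ext": (18.17, 8.82, 12.73),
    "Rtr": (-10.13, 7.27, 17.01),
    "Elv": (1.17, 3.01, 10.92),
}

DISTAL_ENDPOINT_MEANS: dict[str, tuple[float, float, float]] = {
    "Opn": (9.48, 4.64, 9.11),
    "Clo": (-6.0, 2.0, 1.0),
    "Sup": (0.3, 0.5, 4.0),
}
#: Ocs is a two-phase movement: open to the first endpoint, close to the second.
OCS_PHASES: tuple[tuple[float, float, float], tuple[float, float, float]] = (
    (8.0, 3.0, 6.0),
    (-4.0, 3.0, 1.0),
)


@dataclass(frozen=True)
class IcmsLayout:
    """Ground-truth movement assignment per gridpoint.

    ``assignments`` maps gridpoint index (ML-major, matching
    ``GridSpec.gridpoints``) to a frozenset of class names, or to
    {"nonresponsive"} / {"sham"}.
    """

    assignments: dict[int, frozenset]
    endpoint_sd: float = 1.0        # mm, isotropic scatter around class means
    breathing_amplitude: float = 0.23  # mm, 1-Hz thoracic rhythm on z
    breathing_freq: float = 1.0     # Hz
    sensor_noise_sd: float = 0.05   # mm per axis per sample

    def __post_init__(self):
        valid = set(PROXIMAL_ENDPOINT_MEANS) | set(DISTAL_ENDPOINT_MEANS) | {
            "Ocs",
            "nonresponsive",
            "sham",
        }
        for idx, classes in self.assignments.items():
            bad = set(classes) - valid
            if bad:
                raise KeyError(f"gridpoint {idx}: unknown classes {sorted(bad)}")


@dataclass
class MarkerTrajectorySet:
    """Wrist and digit marker trajectories for all trials of one site.

    Trajectories are (n_trials, 200, 3) arrays in mm at 100 Hz over 2 s,
    origin at the marker's resting position; axes (x, y, z) = (anterior,
    lateral, dorsal).
    """

    site_id: str
    animal_id: str
    position: tuple[float, float]
    wrist: np.ndarray
    digit: np.ndarray
    current_ua: float = 100.0
    sham: bool = False

    def __post_init__(self):
        if self.wrist.shape != self.digit.shape:
            raise ValueError("wrist and digit trajectories must match in shape")


FS_HZ = 100.0
TRIAL_SAMPLES = 200
MOVEMENT_START_S = 0.1   # evoked movement begins ~100 ms after stimulus onset
MOVEMENT_DUR_S = 0.5     # matches the 500-ms stimulation train


def _minimum_jerk(t: np.ndarray, t0: float, dur: float) -> np.ndarray:
    """Minimum-jerk position profile rising 0 -> 1 over [t0, t0 + dur]."""
    s = np.clip((t - t0) / dur, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _site_trajectories(
    rng: np.random.Generator,
    classes: frozenset,
    layout: IcmsLayout,
    n_trials: int,
) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(TRIAL_SAMPLES) / FS_HZ
    wrist = np.zeros((n_trials, TRIAL_SAMPLES, 3))
    digit = np.zeros((n_trials, TRIAL_SAMPLES, 3))
    prox = [c for c in classes if c in PROXIMAL_ENDPOINT_MEANS]
    distal = [c for c in classes if c in ("Opn", "Clo", "Ocs", "Sup")]
    for k in range(n_trials):
        ramp = _minimum_jerk(t, MOVEMENT_START_S, MOVEMENT_DUR_S)
        if prox:
            target = np.sum(
                [
                    rng.normal(PROXIMAL_ENDPOINT_MEANS[c], layout.endpoint_sd)
                    for c in prox
                ],
                axis=0,
            )
            wrist[k] += ramp[:, None] * target
        comp = np.zeros((TRIAL_SAMPLES, 3))
        for c in distal:
            if c == "Ocs":
                open_t = rng.normal(OCS_PHASES[0], layout.endpoint_sd)
                close_t = rng.normal(OCS_PHASES[1], layout.endpoint_sd)
                half = MOVEMENT_DUR_S / 2
                r1 = _minimum_jerk(t, MOVEMENT_START_S, half)
                r2 = _minimum_jerk(t, MOVEMENT_START_S + half, half)
                comp += r1[:, None] * open_t + r2[:, None] * (close_t - open_t)
            else:
                target = rng.normal(DISTAL_ENDPOINT_MEANS[c], layout.endpoint_sd)
                comp += ramp[:, None] * target
        digit[k] = wrist[k] + comp
        # shared breathing rhythm (both markers ride the thorax) + sensor noise
        phase = rng.uniform(0, 2 * np.pi)
        breathing = layout.breathing_amplitude * np.sin(
            2 * np.pi * layout.breathing_freq * t + phase
        )
        wrist[k, :, 2] += breathing
        digit[k, :, 2] += breathing
        wrist[k] += rng.normal(0, layout.sensor_noise_sd, (TRIAL_SAMPLES, 3))
        digit[k] += rng.normal(0, layout.sensor_noise_sd, (TRIAL_SAMPLES, 3))
    return wrist, digit


def generate_icms_animal(
    layout: IcmsLayout,
    grid: GridSpec,
    n_trials_per_site: int = 3,
    seed: int = 0,
    animal_id: str = "synthetic_icms_rat",
) -> list[MarkerTrajectorySet]:
    """Simulate one ICMS mapping animal: one trajectory set per gridpoint."""
    missing = set(range(grid.n_points)) - set(layout.assignments)
    if missing:
        raise ValueError(f"layout does not cover gridpoints {sorted(missing)}")
    rng = np.random.default_rng(seed)
    positions = grid.gridpoints()
    sites = []
    for idx in range(grid.n_points):
        classes = frozenset(layout.assignments[idx])
        sham = "sham" in classes
        responsive_classes = classes - {"nonresponsive", "sham"}
        wrist, digit = _site_trajectories(
            rng, frozenset(responsive_classes), layout, n_trials_per_site
        )
        sites.append(
            MarkerTrajectorySet(
                site_id=f"{animal_id}_s{idx:02d}",
                animal_id=animal_id,
                position=tuple(positions[idx]),
                wrist=wrist,
                digit=digit,
                current_ua=0.0 if sham else 100.0,
                sham=sham,
            )
        )
    return sites


def default_icms_layout(
    grid: GridSpec,
    rng: np.random.Generator | None = None,
    endpoint_sd: float = 1.0,
) -> IcmsLayout:
    """A topographically coherent default assignment for one animal.

    Anterior rows carry extension + opening/closure territory, middle and
    posterior rows abduction + opening, with small adduction, retraction and
    supination patches; a few sites are non-responsive and two are sham.
    Each responsive site evokes its region's proximal class alone, its
    distal class alone, or the combination (roughly the observed 37/10/53%
    occurrence mix), so proximal and distal territories overlap without
    coinciding.
    """
    rng = rng or np.random.default_rng(0)
    assignments: dict[int, frozenset] = {}
    for idx, (ml, ap) in enumerate(grid.gridpoints()):
        if ap >= 3.0:  # anterior
            prox, dist = ("Ext", "Ocs") if ml < 3.5 else ("Add", "Clo")
        elif ap >= 1.5:  # middle
            prox, dist = "Abd", "Opn"
        else:  # posterior
            prox, dist = ("Abd", "Opn") if ml < 3.5 else ("Rtr", "Sup")
        u = rng.uniform()
        if u < 0.375:
            classes = {prox}
        elif u < 0.47:
            classes = {dist}
        else:
            classes = {prox, dist}
        assignments[idx] = frozenset(classes)
    # a scattered non-responsive fringe and two sham control sites
    shuffled = rng.permutation(grid.n_points)
    for idx in shuffled[:4]:
        assignments[int(idx)] = frozenset({"nonresponsive"})
    for idx in shuffled[4:6]:
        assignments[int(idx)] = frozenset({"sham"})
    return IcmsLayout(assignments=assignments, endpoint_sd=endpoint_sd)
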