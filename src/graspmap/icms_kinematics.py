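"""Classification of ICMS-evoked forelimb movements from 3D marker tracks.

A site's evoked movement is characterized from wrist and digit marker
trajectories (100 Hz, 2 s, origin at rest; x anterior, y lateral, z
dorsal). A trajectory counts as movement when it displaces >= 1 mm on at
least one axis (the movement cut-off, above the ~0.23 mm breathing
background). Proximal classes (Abd/Add/Ext/Rtr/Elv) are read from the
wrist endpoint, distal classes (Opn/Clo/Ocs/Sup) from the paw component
(digit minus wrist); proximal and distal calls are independent and may
combine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthgen import FS_HZ, MarkerTrajectorySet

__all__ = [
    "MovementCall",
    "passes_cutoff",
    "detect_onset_end",
    "paw_component",
    "classify_proximal",
    "classify_distal",
    "classify_site",
]


@dataclass
class MovementCall:
    site_id: str
    position: tuple[float, float]
    responsive: bool
    proximal_class: frozenset = field(default_factory=frozenset)
    distal_class: frozenset = field(default_factory=frozenset)
    onset: float | None = None
    end: float | None = None
    endpoint: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not self.responsive:
            if self.proximal_class or self.distal_class or self.onset is not None:
                raise ValueError("non-responsive call must carry no classes/onset")
        elif self.onset is not None and self.end is not None and not (
            self.onset < self.end
        ):
            raise ValueError("onset must precede end")


class NoMovementError(ValueError):
    pass


def passes_cutoff(trajectory: np.ndarray, cutoff_mm: float = 1.0) -> bool:
    """True iff max |displacement| >= cutoff on at least one axis (inclusive)."""
    traj = np.asarray(trajectory, dtype=float)
    return bool(np.any(np.abs(traj).max(axis=0) >= cutoff_mm))


def detect_onset_end(
    trajectory: np.ndarray,
    fs_hz: float = FS_HZ,
    speed_fraction: float = 0.05,
    search_window_s: float | None = 1.0,
    smooth_window: int = 0,
) -> tuple[float, float]:
    """Movement onset and end times (s) of one trajectory.

    Onset: first sample of the contiguous run of samples whose tangential
    speed (central differences) exceeds ``speed_fraction`` of the maximum
    speed and contains the speed maximum — identical to the first
    threshold crossing for a monotone speed rise, but robust to isolated
    pre-movement noise excursions. End: last sample at
    which the dominant-axis |displacement| attains its maximum, searched
    within ``search_window_s`` so that drift outlasting the stimulus or
    directed back to rest is ignored. ``smooth_window`` > 1 applies a
    moving average (edge-replicated) of that many samples before
    differentiation — off by default; differentiation amplifies sensor
    noise, so noisy tracks need a window wide enough that the residual
    speed noise stays below the onset threshold.
    """
    traj = np.asarray(trajectory, dtype=float)
    if smooth_window and smooth_window > 1:
        w = int(smooth_window)
        kernel = np.ones(w) / w
        padded = np.pad(traj, ((w, w), (0, 0)), mode="edge")
        traj = np.column_stack(
            [
                np.convolve(padded[:, i], kernel, mode="same")[w:-w]
                for i in range(traj.shape[1])
            ]
        )
    vel = np.gradient(traj, 1.0 / fs_hz, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    n = len(traj)
    if search_window_s is not None:
        n = min(n, int(round(search_window_s * fs_hz)) + 1)
    window = np.abs(traj[:n])
    dominant = int(np.argmax(window.max(axis=0)))
    disp = window[:, dominant]
    end_idx = int(np.max(np.nonzero(disp >= disp.max() - 1e-9)[0]))
    speed = speed[:n]
    vmax = speed.max()
    if vmax == 0:
        raise NoMovementError("zero maximum speed: no movement to time")
    # onset cannot postdate the end: anchor the supra-threshold run at the
    # speed maximum over the movement's course
    above = speed > speed_fraction * vmax
    onset_idx = int(np.argmax(speed[: end_idx + 1])) if end_idx > 0 else 0
    while onset_idx > 0 and above[onset_idx - 1]:
        onset_idx -= 1
    return onset_idx / fs_hz, end_idx / fs_hz


def paw_component(wrist: np.ndarray, digit: np.ndarray) -> np.ndarray:
    """Distal (paw) trajectory: digit marker minus wrist marker, pointwise."""
    wrist = np.asarray(wrist, dtype=float)
    digit = np.asarray(digit, dtype=float)
    if wrist.shape != digit.shape:
        raise ValueError("wrist and digit trajectories must have equal shape")
    return digit - wrist


def classify_proximal(
    endpoint: tuple[float, float, float] | np.ndarray,
    threshold_mm: float = 4.0,
    ratio: float = 0.15,
) -> str:
    """Proximal class of a wrist endpoint displacement (x, y, z) in mm.

    The dominant horizontal axis (larger of |x|, |y|; ties to x) decides
    between the Abd/Add (y) and Ext/Rtr (x) rules; Elv requires upward
    movement without a major horizontal shift. Returns "none" when no rule
    fires.
    """
    x, y, z = (float(v) for v in endpoint)
    if abs(y) > abs(x):  # y dominant
        if y > threshold_mm and y > ratio * abs(x) and z > 0:
            return "Abd"
        if y < -threshold_mm and abs(y) > ratio * abs(x) and z > 0:
            return "Add"
    else:  # x dominant (ties broken toward x)
        if x > threshold_mm and x > ratio * abs(y) and z > 0:
            return "Ext"
        if x < -threshold_mm and abs(x) > ratio * abs(y) and z > 0:
            return "Rtr"
    if z > threshold_mm and abs(x) < threshold_mm and abs(y) < threshold_mm:
        return "Elv"
    return "none"


def classify_distal(
    component: np.ndarray,
    cutoff_mm: float = 1.0,
    fs_hz: float = FS_HZ,
) -> str:
    """Distal class of a paw-component trajectory.

    An opening/closure sequence (Ocs) is a positive x excursion followed by
    a negative one, each exceeding the cut-off; otherwise the component
    endpoint (at its own detected end time) decides: Opn for digit opening
    (x and z positive), Clo for closure (x negative), Sup for wrist
    rotation without digit displacement (z positive, |x| sub-cutoff).
    """
    comp = np.asarray(component, dtype=float)
    if not passes_cutoff(comp, cutoff_mm):
        return "none"
    xs = comp[:, 0]
    imax = int(np.argmax(xs))
    if xs[imax] >= cutoff_mm and xs[imax:].min() <= -cutoff_mm:
        return "Ocs"
    _, end = detect_onset_end(comp, fs_hz=fs_hz)
    x, _, z = comp[int(round(end * fs_hz))]
    if x >= cutoff_mm and z > 0:
        return "Opn"
    if x <= -cutoff_mm:
        return "Clo"
    if z >= cutoff_mm and abs(x) < cutoff_mm:
        return "Sup"
    return "none"


def classify_site(
    site: MarkerTrajectorySet,
    cutoff_mm: float = 1.0,
    max_current_ua: float = 100.0,
    threshold_mm: float = 4.0,
    ratio: float = 0.15,
) -> MovementCall:
    """Average a site's trials and call its evoked movement classes.

    A site is responsive when at least one trial passes the movement
    cut-off at a recorded current <= ``max_current_ua`` and the site is not
    a sham. Onset/end times and the per-axis endpoint displacement are
    averaged over the trials that pass the cut-off; distal classification
    runs on the pointwise trial-averaged paw component so that the phase
    structure of opening/closure sequences survives averaging.
    """
    n_trials = site.wrist.shape[0]
    if n_trials < 1:
        raise ValueError("site has no trials")
    passing = [k for k in range(n_trials) if passes_cutoff(site.wrist[k], cutoff_mm)
               or passes_cutoff(paw_component(site.wrist[k], site.digit[k]), cutoff_mm)]
    moved = bool(passing)
    if site.sham:
        if moved:
            warnings.warn(
                f"sham site {site.site_id} shows supra-cutoff movement; "
                "check for uncontrolled influences",
                stacklevel=2,
            )
        return MovementCall(site.site_id, site.position, responsive=False)
    if not moved or site.current_ua > max_current_ua:
        return MovementCall(site.site_id, site.position, responsive=False)

    onsets, ends, endpoints = [], [], []
    for k in passing:
        # timing runs on a 5-sample-smoothed speed: raw differentiation of
        # sensor noise would swamp the 5%-of-max onset threshold
        track = (
            site.wrist[k]
            if passes_cutoff(site.wrist[k], cutoff_mm)
            else paw_component(site.wrist[k], site.digit[k])
        )
        onset, end = detect_onset_end(track, smooth_window=5)
        onsets.append(onset)
        ends.append(end)
        endpoints.append(site.wrist[k][int(round(end * FS_HZ))])
    endpoint = np.mean(endpoints, axis=0)

    proximal: set[str] = set()
    if passes_cutoff(np.mean([site.wrist[k] for k in passing], axis=0), cutoff_mm):
        call = classify_proximal(endpoint, threshold_mm, ratio)
        if call != "none":
            proximal.add(call)

    mean_component = np.mean(
        [paw_component(site.wrist[k], site.digit[k]) for k in passing], axis=0
    )
    distal: set[str] = set()
    dcall = classify_distal(mean_component, cutoff_mm)
    if dcall != "none":
        distal.add(dcall)

    return MovementCall(
        site_id=site.site_id,
        position=site.position,
        responsive=True,
        proximal_class=frozenset(proximal),
        distal_class=frozenset(distal),
        onset=float(np.mean(onsets)),
        end=float(np.mean(ends)),
        endpoint=tuple(float(v) for v in endpoint),
    )
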