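"""Delimited-text formats for sessions, trajectories and result tables.

All tables are TSV with a one-line schema header, preceded by ``#``
provenance comment lines (config hash + seed). Times are seconds on the
session clock; positions are bregma-relative mm.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .spike_metrics import NeuronRecording, TrialRecord
from .synthgen import FS_HZ, TRIAL_SAMPLES, MarkerTrajectorySet

__all__ = [
    "write_spike_table",
    "read_spike_table",
    "write_trajectory_table",
    "read_trajectory_table",
    "write_table",
]

SPIKE_COLUMNS = [
    "neuron_id", "rat_id", "ml_mm", "ap_mm", "trial_id", "outcome",
    "touch_time_s", "lift_s", "aperture_s", "touch_s", "repass_s", "spike_time_s",
]

TRAJECTORY_COLUMNS = [
    "site_id", "animal_id", "ml_mm", "ap_mm", "current_ua", "sham",
    "trial", "marker", "time_s", "x_mm", "y_mm", "z_mm",
]

VALID_OUTCOMES = {"success", "failure"}


class SchemaError(ValueError):
    pass


def _provenance(meta: dict | None) -> str:
    meta = meta or {}
    parts = [f"{k}={v}" for k, v in meta.items()]
    return "# graspmap " + " ".join(parts) if parts else "# graspmap"


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a result table as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(meta) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty input file")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def write_spike_table(
    trials: list[TrialRecord],
    neurons: list[NeuronRecording],
    path: str | Path,
    meta: dict | None = None,
) -> None:
    """One row per spike; (neuron, trial) pairs without spikes keep one row
    with an empty spike_time_s so the session round-trips exactly."""
    by_trial = {t.trial_id: t for t in trials}
    rows = []
    for nr in neurons:
        for tid in sorted(nr.spikes):
            tr = by_trial[tid]
            base = {
                "neuron_id": nr.neuron_id,
                "rat_id": nr.rat_id,
                "ml_mm": nr.position[0],
                "ap_mm": nr.position[1],
                "trial_id": tid,
                "outcome": tr.outcome,
                "touch_time_s": tr.touch_time,
                "lift_s": tr.phase_boundaries[0],
                "aperture_s": tr.phase_boundaries[1],
                "touch_s": tr.phase_boundaries[2],
                "repass_s": tr.phase_boundaries[3],
            }
            st = nr.spikes[tid]
            if len(st) == 0:
                rows.append({**base, "spike_time_s": np.nan})
            else:
                rows.extend({**base, "spike_time_s": s} for s in st)
    write_table(pd.DataFrame(rows, columns=SPIKE_COLUMNS), path, meta)


def read_spike_table(
    path: str | Path,
) -> tuple[list[TrialRecord], list[NeuronRecording]]:
    df = _read_tsv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df.loc[~df["outcome"].isin(VALID_OUTCOMES)]
    if not bad.empty:
        # +2: one schema header line and one provenance line precede the data
        lines = [int(i) + 3 for i in bad.index[:5]]
        raise SchemaError(
            f"{path}: unknown outcome token(s) {sorted(bad['outcome'].unique())} "
            f"at line(s) {lines}"
        )
    trials: dict[int, TrialRecord] = {}
    for tid, g in df.groupby("trial_id"):
        r = g.iloc[0]
        trials[int(tid)] = TrialRecord(
            trial_id=int(tid),
            outcome=str(r["outcome"]),
            touch_time=float(r["touch_time_s"]),
            phase_boundaries=(
                float(r["lift_s"]), float(r["aperture_s"]),
                float(r["touch_s"]), float(r["repass_s"]),
            ),
        )
    neurons = []
    for nid, g in df.groupby("neuron_id", sort=True):
        r = g.iloc[0]
        spikes: dict[int, np.ndarray] = {}
        for tid, gt in g.groupby("trial_id"):
            st = gt["spike_time_s"].dropna().to_numpy(dtype=float)
            if np.any(np.diff(st) < 0):
                warnings.warn(
                    f"{path}: unsorted spikes for neuron {nid} trial {tid}; sorting",
                    stacklevel=2,
                )
                st = np.sort(st)
            spikes[int(tid)] = st
        neurons.append(
            NeuronRecording(
                neuron_id=str(nid),
                rat_id=str(r["rat_id"]),
                position=(float(r["ml_mm"]), float(r["ap_mm"])),
                spikes=spikes,
            )
        )
    return sorted(trials.values(), key=lambda t: t.trial_id), neurons


def write_trajectory_table(
    sites: list[MarkerTrajectorySet], path: str | Path, meta: dict | None = None
) -> None:
    frames = []
    t = np.arange(TRIAL_SAMPLES) / FS_HZ
    for site in sites:
        for marker, arr in (("wrist", site.wrist), ("digit", site.digit)):
            n_trials = arr.shape[0]
            frames.append(
                pd.DataFrame(
                    {
                        "site_id": site.site_id,
                        "animal_id": site.animal_id,
                        "ml_mm": site.position[0],
                        "ap_mm": site.position[1],
                        "current_ua": site.current_ua,
                        "sham": int(site.sham),
                        "trial": np.repeat(np.arange(n_trials), TRIAL_SAMPLES),
                        "marker": marker,
                        "time_s": np.tile(t, n_trials),
                        "x_mm": arr[:, :, 0].ravel(),
                        "y_mm": arr[:, :, 1].ravel(),
                        "z_mm": arr[:, :, 2].ravel(),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)[TRAJECTORY_COLUMNS]
    write_table(df, path, meta)


def read_trajectory_table(
    path: str | Path, strict: bool = False
) -> list[MarkerTrajectorySet]:
    df = _read_tsv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["site_id", "trial", "marker", "time_s"])
    if dup.any():
        raise SchemaError(f"{path}: duplicated (site, trial, marker, time) rows")
    sites = []
    for sid, g in df.groupby("site_id", sort=True):
        markers = {}
        for marker in ("wrist", "digit"):
            gm = g[g["marker"] == marker]
            if gm.empty:
                raise SchemaError(f"{path}: site {sid} missing {marker} marker")
            trials = []
            for _, gt in gm.groupby("trial"):
                arr = gt.sort_values("time_s")[["x_mm", "y_mm", "z_mm"]].to_numpy()
                if len(arr) != TRIAL_SAMPLES:
                    msg = (
                        f"{path}: site {sid} {marker} has {len(arr)} samples, "
                        f"expected {TRIAL_SAMPLES}"
                    )
                    if strict:
                        raise SchemaError(msg)
                    warnings.warn(msg + "; padding with the nearest sample", stacklevel=2)
                    if len(arr) > TRIAL_SAMPLES:
                        arr = arr[:TRIAL_SAMPLES]
                    else:
                        pad = np.repeat(arr[-1:], TRIAL_SAMPLES - len(arr), axis=0)
                        arr = np.vstack([arr, pad])
                trials.append(arr)
            markers[marker] = np.stack(trials)
        r = g.iloc[0]
        sites.append(
            MarkerTrajectorySet(
                site_id=str(sid),
                animal_id=str(r["animal_id"]),
                position=(float(r["ml_mm"]), float(r["ap_mm"])),
                wrist=markers["wrist"],
                digit=markers["digit"],
                current_ua=float(r["current_ua"]),
                sham=bool(r["sham"]),
            )
        )
    return sites
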