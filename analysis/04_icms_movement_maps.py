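"""Call evoked movements per stimulation site and build the motor maps.

Classifies every site's trajectories (1-mm movement cut-off, wrist
endpoint rules for proximal classes, paw-component rules for distal
classes), scores the calls against ground truth, accumulates cumulative
frequency maps across the five animals, and writes each movement
representation (gridpoints evoked in >= 2 animals). Elevation is
classified but not mapped.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from graspmap import GridSpec, PipelineConfig
from graspmap.icms_kinematics import classify_site
from graspmap.io import read_trajectory_table, write_table
from graspmap.pipeline import map_movement_representations

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = PipelineConfig()
calls = []
for path in sorted(args.data.glob("icms_rat*.tsv")):
    for site in read_trajectory_table(path):
        calls.append(classify_site(site, cutoff_mm=cfg.movement_cutoff_mm,
                                   max_current_ua=cfg.max_current_ua,
                                   threshold_mm=cfg.proximal_threshold_mm,
                                   ratio=cfg.proximal_ratio))

df = pd.DataFrame(
    {
        "site_id": [c.site_id for c in calls],
        "ml_mm": [c.position[0] for c in calls],
        "ap_mm": [c.position[1] for c in calls],
        "responsive": [int(c.responsive) for c in calls],
        "proximal": ["+".join(sorted(c.proximal_class)) for c in calls],
        "distal": ["+".join(sorted(c.distal_class)) for c in calls],
    }
)
write_table(df, args.out / "site_calls.tsv")

truth = pd.read_csv(args.data / "ground_truth_sites.tsv", sep="\t", comment="#")
merged = df.merge(truth, on="site_id")
pred = merged.apply(
    lambda r: "+".join(sorted(filter(None, (r.proximal + "+" + r.distal).split("+"))))
    if r.responsive
    else "", axis=1,
)
true_responsive = ~merged.true_classes.isin(["nonresponsive", "sham"])
exact = ((pred == merged.true_classes.where(true_responsive, "")).mean())

n_resp = df.responsive.sum()
print(f"{n_resp}/{len(df)} sites responsive ({100 * n_resp / len(df):.0f}%)")
print(f"site-call exact recovery: {100 * exact:.1f}%")

grid = GridSpec()
reps = map_movement_representations(calls, grid, cfg)
mask_rows = []
for cls, rep in reps.items():
    print(f"{cls}: representation area {rep.area} gridpoints")
    for i, j in zip(*np.nonzero(rep.mask)):
        mask_rows.append({"class": cls, "ml_idx": int(i), "ap_idx": int(j)})
write_table(pd.DataFrame(mask_rows), args.out / "representation_masks.tsv")
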