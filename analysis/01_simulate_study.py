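"""Simulate the full synthetic study and write its input tables.

Five recording animals (32-channel arrays, ~45 grasping trials at ~70%
success, a mix of outcome-independent/-dependent/control neuron
archetypes) and five ICMS mapping animals (32 stimulation sites each,
three 2-s marker-trajectory trials per site, two sham sites per animal).
Ground-truth archetypes and site assignments are written alongside so
later steps can score themselves.
"""

import argparse
from pathlib import Path

import pandas as pd

from graspmap import PipelineConfig
from graspmap.io import write_spike_table, write_table, write_trajectory_table
from graspmap.pipeline import simulate_animals

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = PipelineConfig(seed=args.seed)
meta = {"config": cfg.config_hash(), "seed": cfg.seed}
grid, sessions, icms_animals = simulate_animals(cfg)

truths = []
for a, (trials, neurons, truth) in enumerate(sessions):
    write_spike_table(trials, neurons, args.out / f"session_rat{a}.tsv", meta)
    truths.append(truth)
    n_succ = sum(t.outcome == "success" for t in trials)
    print(
        f"recording rat {a}: {len(trials)} trials "
        f"({n_succ} successes), {len(neurons)} neurons"
    )
write_table(pd.concat(truths, ignore_index=True), args.out / "ground_truth_neurons.tsv", meta)

site_rows = []
for a, (layout, sites) in enumerate(icms_animals):
    write_trajectory_table(sites, args.out / f"icms_rat{a}.tsv", meta)
    for idx, site in enumerate(sites):
        site_rows.append(
            {
                "site_id": site.site_id,
                "true_classes": "+".join(sorted(layout.assignments[idx])),
            }
        )
    n_sham = sum(s.sham for s in sites)
    print(f"ICMS rat {a}: {len(sites)} sites ({n_sham} sham)")
write_table(pd.DataFrame(site_rows), args.out / "ground_truth_sites.tsv", meta)
print(f"tables written under {args.out}")
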