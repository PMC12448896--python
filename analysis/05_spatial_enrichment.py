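"""Test whether neuron classes cluster inside movement representations.

Overlays the classified neuron positions on the ICMS-derived
representation borders: a chi-square (with Cramer's V) asks whether the
outcome-independent/outcome-dependent proportions differ across
representations, and a Monte Carlo uniform-placement null gives each
(class, representation) density a two-tailed empirical p.
"""

import argparse
from pathlib import Path

import pandas as pd

from graspmap import GridSpec, PipelineConfig, Representation
from graspmap.io import read_spike_table, write_table
from graspmap.neuron_classifier import classify_session, labels_to_table
from graspmap.spatial_enrichment import enrichment_analysis

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = PipelineConfig(seed=args.seed)
grid = GridSpec()

positions, labels = {}, []
for path in sorted(args.data.glob("session_rat*.tsv")):
    trials, neurons = read_spike_table(path)
    labels.extend(classify_session(neurons, trials))
    positions.update({n.neuron_id: n.position for n in neurons})
table = labels_to_table(labels)

masks = pd.read_csv(args.out / "representation_masks.tsv", sep="\t", comment="#")
reps = []
for cls, g in masks.groupby("class"):
    import numpy as np

    mask = np.zeros((grid.n_cols, grid.n_rows), dtype=bool)
    mask[g.ml_idx, g.ap_idx] = True
    reps.append(Representation(cls, grid, mask))

positions_by_class = {
    pop: [positions[nid] for nid in table[table.population == pop].neuron_id]
    for pop in ("outcome_independent", "outcome_dependent")
}

rows = []
for group, classes in (
    ("proximal", {"Abd", "Add", "Ext", "Rtr"}),
    ("distal", {"Opn", "Clo", "Ocs", "Sup"}),
):
    group_reps = [r for r in reps if r.movement_class in classes]
    res = enrichment_analysis(
        positions_by_class, group_reps, grid, n_sim=cfg.n_sim, seed=cfg.seed
    )
    er = next(iter(res.values()))
    print(
        f"{group}: chi2({er.df}) = {er.chi2:.2f}, p = {er.p:.4f}, "
        f"V = {er.cramers_v:.4f}"
    )
    for cls, r in res.items():
        per = r.per_representation.copy()
        per.insert(0, "neuron_class", cls)
        per.insert(0, "group", group)
        rows.append(per)
        for _, row in per.iterrows():
            flag = " *" if row.p_empirical < 0.05 else ""
            print(
                f"  {cls:>20s} in {row.representation}: density "
                f"{row.observed_density:.3f} vs null {row.null_mean:.3f} "
                f"(p = {row.p_empirical:.4f}){flag}"
            )

write_table(pd.concat(rows, ignore_index=True), args.out / "enrichment_report.tsv")
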