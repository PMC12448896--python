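"""End-to-end pipeline: simulate -> metrics -> classify -> map -> enrich.

Runs the whole analysis on synthetic multi-animal data (or on tables read
from disk) and writes a reproducible report bundle: neuron label table,
classification-scheme summary, ICMS site calls, representation masks and
the enrichment report. Every output carries the config hash and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MAPPED_PROXIMAL_CLASSES, PipelineConfig
from .cortical_maps import Representation, build_frequency_map, representation_mask
from .icms_kinematics import MovementCall, classify_site
from .io import write_table
from .neuron_classifier import (
    NeuronLabel,
    classify_session,
    compare_phase_durations,
    labels_to_table,
    population_summary,
)
from .spatial_enrichment import enrichment_analysis
from .synthgen import (
    GridSpec,
    MarkerTrajectorySet,
    SessionConfig,
    default_icms_layout,
    generate_icms_animal,
    generate_session,
)

log = logging.getLogger("graspmap")

#: Archetype mix emulating one recorded animal's worth of neuron types.
DEFAULT_ARCHETYPE_MIX = {
    "pre_dominant": 3,
    "post_dominant": 4,
    "epoch_neutral": 1,
    "success_pre_dominant": 2,
    "success_post_dominant": 2,
    "success_epoch_neutral": 3,
    "unmodulated": 1,
}


@dataclass
class ReportBundle:
    labels: list[NeuronLabel]
    label_table: pd.DataFrame
    summary: pd.DataFrame
    phase_tests: dict
    site_calls: list[MovementCall]
    representations: dict[str, Representation]
    enrichment: dict
    enrichment_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_animals(
    config: PipelineConfig,
    n_recording_animals: int = 5,
    n_icms_animals: int = 5,
    archetype_mix: dict[str, int] | None = None,
):
    """Synthetic study: recording sessions and ICMS animals on one grid."""
    grid = GridSpec()
    mix = archetype_mix or DEFAULT_ARCHETYPE_MIX
    sessions = []
    for a in range(n_recording_animals):
        sc = SessionConfig(grid=grid, seed=config.seed * 1000 + a)
        trials, neurons, truth = generate_session(mix, sc)
        for n in neurons:
            n.rat_id = f"rec_rat{a}"
            n.neuron_id = f"r{a}_{n.neuron_id}"
        truth["neuron_id"] = [f"r{a}_{nid}" for nid in truth["neuron_id"]]
        sessions.append((trials, neurons, truth))
    icms_animals = []
    for a in range(n_icms_animals):
        rng = np.random.default_rng(config.seed * 2000 + a)
        layout = default_icms_layout(grid, rng)
        sites = generate_icms_animal(
            layout, grid, seed=config.seed * 3000 + a, animal_id=f"icms_rat{a}"
        )
        icms_animals.append((layout, sites))
    return grid, sessions, icms_animals


def map_movement_representations(
    site_calls: list[MovementCall],
    grid: GridSpec,
    config: PipelineConfig,
) -> dict[str, Representation]:
    """Frequency map + border per mapped movement class (Elv excluded)."""
    reps: dict[str, Representation] = {}
    classes = list(MAPPED_PROXIMAL_CLASSES) + ["Opn", "Clo", "Ocs", "Sup"]
    for cls in classes:
        positions = [
            c.position
            for c in site_calls
            if c.responsive and (cls in c.proximal_class or cls in c.distal_class)
        ]
        fmap = build_frequency_map(positions, grid, label=cls)
        reps[cls] = representation_mask(
            fmap, config.representation_threshold, config.strict_representation
        )
    return reps


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    simulate: bool = True,
    n_recording_animals: int = 5,
    n_icms_animals: int = 5,
) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    config = config or PipelineConfig()
    if not simulate:
        raise NotImplementedError(
            "file-driven runs go through io.read_spike_table / "
            "io.read_trajectory_table and the stage functions directly"
        )
    meta = {"config": config.config_hash(), "seed": config.seed}
    grid, sessions, icms_animals = simulate_animals(
        config, n_recording_animals, n_icms_animals
    )

    labels: list[NeuronLabel] = []
    positions: dict[str, tuple[float, float]] = {}
    phase_tests = {}
    for a, (trials, neurons, _) in enumerate(sessions):
        session_labels = classify_session(neurons, trials, config)
        labels.extend(session_labels)
        positions.update({n.neuron_id: n.position for n in neurons})
        phase_tests[f"rec_rat{a}"] = compare_phase_durations(trials)
        for lab in session_labels:
            log.info(
                "neuron %s -> %s/%s", lab.neuron_id, lab.population, lab.subpopulation
            )
    label_table = labels_to_table(labels)
    summary = population_summary(labels, config.min_category)

    site_calls: list[MovementCall] = []
    for _, sites in icms_animals:
        for site in sites:
            site_calls.append(
                classify_site(
                    site,
                    cutoff_mm=config.movement_cutoff_mm,
                    max_current_ua=config.max_current_ua,
                    threshold_mm=config.proximal_threshold_mm,
                    ratio=config.proximal_ratio,
                )
            )
    representations = map_movement_representations(site_calls, grid, config)

    positions_by_class = {
        cls: [
            positions[l.neuron_id] for l in labels if l.population == cls
        ]
        for cls in ("outcome_independent", "outcome_dependent")
    }
    usable = {k: v for k, v in representations.items() if v.area > 0}
    proximal_reps = [usable[c] for c in MAPPED_PROXIMAL_CLASSES if c in usable]
    distal_reps = [usable[c] for c in ("Opn", "Clo", "Ocs", "Sup") if c in usable]
    enrichment = {}
    rows = []
    for group_name, reps in (("proximal", proximal_reps), ("distal", distal_reps)):
        if not reps:
            continue
        res = enrichment_analysis(
            positions_by_class, reps, grid, n_sim=config.n_sim, seed=config.seed
        )
        enrichment[group_name] = res
        for cls, er in res.items():
            per = er.per_representation.copy()
            per.insert(0, "neuron_class", cls)
            per.insert(0, "group", group_name)
            per["chi2"] = er.chi2
            per["chi2_p"] = er.p
            per["cramers_v"] = er.cramers_v
            rows.append(per)
    enrichment_table = (
        pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    )

    bundle = ReportBundle(
        labels=labels,
        label_table=label_table,
        summary=summary,
        phase_tests=phase_tests,
        site_calls=site_calls,
        representations=representations,
        enrichment=enrichment,
        enrichment_table=enrichment_table,
    )

    if out_dir is not None:
        out = Path(out_dir)
        write_table(label_table, out / "neuron_labels.tsv", meta)
        write_table(summary, out / "classification_summary.tsv", meta)
        calls_df = pd.DataFrame(
            {
                "site_id": [c.site_id for c in site_calls],
                "ml_mm": [c.position[0] for c in site_calls],
                "ap_mm": [c.position[1] for c in site_calls],
                "responsive": [int(c.responsive) for c in site_calls],
                "proximal": ["+".join(sorted(c.proximal_class)) for c in site_calls],
                "distal": ["+".join(sorted(c.distal_class)) for c in site_calls],
            }
        )
        write_table(calls_df, out / "site_calls.tsv", meta)
        masks = pd.concat(
            [
                pd.DataFrame(
                    {
                        "class": cls,
                        "ml_idx": np.nonzero(rep.mask)[0],
                        "ap_idx": np.nonzero(rep.mask)[1],
                    }
                )
                for cls, rep in representations.items()
                if rep.area > 0
            ],
            ignore_index=True,
        )
        write_table(masks, out / "representation_masks.tsv", meta)
        write_table(enrichment_table, out / "enrichment_report.tsv", meta)
    return bundle
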