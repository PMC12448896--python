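# graspmap

Analysis pipeline for single-unit activity in rat primary motor cortex (M1)
during successful and failed grasping, and for the relation between
outcome-coding neurons and the cortical motor map.

The scientific question: when a rat reaches through a slit to grasp a food
pellet, some layer-V M1 neurons fire the same way whether the grasp succeeds
or fails (*outcome-independent*), while others change their discharge with
the outcome (*outcome-dependent*). Are these two classes differently placed
with respect to the complex-movement representations that long-duration
intracortical microstimulation (ICMS) reveals in the same cortex?

The package implements every stage of that analysis as a tested library,
with a synthetic-data generator standing in for the unavailable recordings:

1. **Spike metrics** — spike trains aligned to food touch; 20-ms PSTHs;
   per-trial mean rates in three 300-ms epochs (baseline −1000…−700 ms,
   pre-touch −300…0 ms, post-touch 0…+300 ms); spike-density functions by
   Gaussian-kernel smoothing (15-bin support); net normalized activity
   (baseline-subtracted epoch rate over the neuron's peak
   baseline-subtracted SDF, clipped to ≥ 0); peak amplitude and timing.
2. **Neuron classification** — a one-way repeated-measures ANOVA over
   epochs (trials as subjects) gates task-modulated neurons; Tukey
   post-hocs route them (significant increase over baseline required;
   decreasing and failure-only neurons are excluded); a trial-level
   outcome × epoch ANOVA separates outcome-dependent from
   outcome-independent neurons; the Tukey pre-vs-post contrast assigns the
   subpopulation (pre-touch dominant / post-touch dominant / epoch-neutral,
   success-side only for outcome-dependent neurons).
3. **ICMS kinematics** — evoked forelimb movements are classified from
   wrist and digit marker trajectories (100 Hz, 2 s): a 1-mm displacement
   cut-off, onset at 5% of peak tangential speed, end at the last
   attainment of maximal displacement, endpoint rules for the proximal
   classes (Abd/Add/Ext/Rtr/Elv) and paw-component (digit − wrist) rules
   for the distal classes (Opn/Clo/Ocs/Sup).
4. **Cortical maps** — bregma-relative cumulative frequency maps on the
   0.5-mm grid; a movement representation is the set of gridpoints where a
   class was evoked in ≥ 2 of 5 animals.
5. **Spatial enrichment** — Pearson χ² with Cramér's
   V = √(χ²/(N·(min(r,c)−1))) over the class × representation table, and a
   Monte Carlo uniform-placement null for the neuron density inside each
   representation with a two-tailed empirical
   p = (1 + #{|d − mean| ≥ |d_obs − mean|}) / (1 + n_sim).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py --seed 0
python analysis/02_behavior_and_metrics.py
python analysis/03_classify_neurons.py
python analysis/04_icms_movement_maps.py
python analysis/05_spatial_enrichment.py --seed 0
```

At seed 0 the classification step prints:

```
           population               subpopulation  n  analyzed
  outcome_independent          pre_touch_dominant 12      True
  outcome_independent         post_touch_dominant 19      True
  outcome_independent               epoch_neutral  5      True
    outcome_dependent  success_pre_touch_dominant 13      True
    outcome_dependent success_post_touch_dominant 11      True
    outcome_dependent       success_epoch_neutral 17      True
          unmodulated                        none  3     False
excluded_decreasing                          none  0     False
excluded_failure_only                        none  0     False

exact label recovery vs ground truth: 92.5%
```

i.e. of 80 simulated neurons, 92.5% receive exactly their ground-truth
population and subpopulation; the success-epoch-neutral subpopulation shows
the expected success-vs-failure peak-amplitude difference (U = 280.0,
p < 0.0001) while the outcome-independent post-touch-dominant one does not
(p = 0.70). The mapping step recovers 99.4% of site calls (sham sites are
always non-responsive), and the enrichment step reports, per movement
representation, the observed neuron density against its Monte Carlo null —
with uniformly placed synthetic neurons, none of the eight representations
is significantly enriched, as it should be.

The same stages are available as a CLI (`graspmap simulate|metrics|
classify|icms-classify|map|enrich|report`, each accepting `--config` and
`--seed`) and as one call, `graspmap.pipeline.run_pipeline`.

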