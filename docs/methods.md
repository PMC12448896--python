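# Methods

This note documents the models, statistical procedures and numerical
choices behind `graspmap`, and what the synthetic-data generator does and
does not emulate.

## Task structure and epochs

A trial is one grasping attempt with four event timestamps: paw lift,
aperture pass, food touch, aperture re-pass. The three phases these bound
last ~250 ms each. All spike metrics are computed relative to food touch
over the window [−1000, +300] ms, partitioned into three 300-ms epochs:
baseline [−1000, −700), pre-touch [−300, 0) and post-touch [0, +300) ms.
Intervals are half-open with t = 0 belonging to post-touch: touch initiates
the post phase. Spikes outside the window are ignored.

## Firing-rate metrics

* **PSTH**: spikes binned at 20 ms and averaged over trials; bin value =
  total spikes / (n_trials × bin width), in spikes/s. The 300-ms epochs
  cover exactly 15 bins each, and epoch rates equal the PSTH bin average
  over those bins (a tested consistency identity).
* **Spike-density function**: the PSTH convolved with a unit-area Gaussian
  kernel of 15-bin total support. "Width 15 bins" is read as support, with
  SD = 15/6 bins ≈ 50 ms; reading it as a 15-bin SD (300 ms) would flatten
  the epoch structure the classification depends on. Edges renormalize the
  truncated kernel mass so a constant signal stays constant.
* **Net normalized activity**: per (outcome, epoch ∈ {pre, post}),
  (epoch mean rate − pooled baseline mean) / normalizer, clipped below at
  0, where the normalizer is the neuron's maximum baseline-subtracted SDF
  value across both outcomes. The pooled (both-outcome) baseline gives each
  neuron a single reference scale. A neuron whose SDF never exceeds its
  baseline has no such scale and is routed to the excluded-decreasing
  population. No published algebraic definition exists for this quantity;
  this reconstruction is constrained by its reported [0, 1] range and
  behaves as expected on the generator (a pre-dominant neuron at the
  defaults scores ≈ 0.7 pre vs ≈ 0.1 post).
* **Peak activity**: maximum SDF value and the center of the earliest bin
  attaining it (ties break to the earliest).

## Neuron classification

Gates run in sequence, all at α = 0.05, no correction across neurons:

1. **Task modulation**: one-way repeated-measures ANOVA over the three
   epoch rates with trials as subjects, F with df (2, 2(n−1)). A
   non-significant omnibus ends classification (unmodulated). The
   decomposition is authored directly (sum-of-squares identities) and is
   cross-checked against pingouin to 1e−8 in F.
2. **Direction**: Tukey HSD over the three epoch means using the
   repeated-measures error term (studentized range, df = 2(n−1)). A
   significant increase of a touch epoch over baseline is required;
   neurons with only decreases are excluded (the population is reported
   but not analyzed), and neurons increasing only in failed trials are
   excluded as failure-only. On discrete low-count data this directional
   stage is deliberately more conservative than the omnibus: simulation at
   the generator defaults gives an omnibus type-I rate of ≈ 4.7% and a
   full-route rate of ≈ 3.1%.
3. **Outcome dependence**: a two-factor (outcome × epoch) ANOVA on the
   per-trial pre- and post-touch rates (Type II sums of squares on
   trial × epoch observations; cross-checked against statsmodels). The
   neuron is outcome-dependent when the outcome main effect or the
   interaction is significant. Under the null this OR-rule fires at
   1 − (1 − α)² ≈ 9.75%, which the calibration test asserts. The per-neuron
   rule is a reconstruction: the published scheme defines the two classes
   behaviorally but not the per-neuron statistic.
4. **Subpopulation**: the Tukey pre-vs-post contrast assigns pre-touch
   dominant / post-touch dominant / epoch-neutral. Outcome-independent
   neurons must be concordant across outcomes; discordant cases resolve by
   the pooled-trials contrast (a single label is required).
   Outcome-dependent neurons are labelled from successful trials only.

Subpopulation-level statistics use neurons as replicates in a 2 × 2
(outcome × epoch) ANOVA, error df = 4n − 4, with Bonferroni-corrected
pairwise t tests after a significant interaction and Mann–Whitney tests
per factor otherwise. Mann–Whitney is exact when the combined sample is
≤ 20 without ties (verified against full enumeration), and the
tie-corrected normal approximation otherwise.

## ICMS movement classification

Marker trajectories (wrist and digit, 100 Hz, 2 s, origin at rest; x
anterior, y lateral, z dorsal) pass the movement cut-off when displacement
reaches ≥ 1 mm on at least one axis (inclusive); the breathing background
(0.23 mm) stays well below it. Onset is where tangential speed (central
differences) exceeds 5% of its maximum — implemented as the start of the
supra-threshold run containing the speed maximum over the movement's
course, which equals the first crossing for clean monotone rises but does
not latch onto isolated pre-movement noise. End is the last sample
attaining maximal displacement on the dominant axis, searched within a
1-s window so drift outlasting the stimulus or returning to rest is
ignored. Differentiation amplifies tracking noise (0.1-mm white noise at
100 Hz gives ≈ 12 mm/s speed noise, above the ≈ 4.4 mm/s onset threshold
of a typical evoked movement), so site-level timing uses a 5-sample
moving average before differentiation — the smallest window for which the
tolerance study keeps onset within 30 ms of the clean profile; raw
central differences remain the default for clean tracks.

Proximal classes are read from the wrist endpoint: the dominant horizontal
axis (larger of |x|, |y|; ties to x, a fixed arbitrary rule) selects
between the y rules (Abd: y > 4 mm, y > 0.15|x|, z > 0; Add mirrored) and
the x rules (Ext: x > 4 mm, x > 0.15|y|, z > 0; Rtr mirrored); Elv
requires z > 4 mm with both horizontal axes below 4 mm. Exactly one
proximal label can fire per endpoint. Distal classes are read from the paw
component (digit − wrist): an opening/closure sequence is a positive x
excursion followed by a negative one, each beyond the 1-mm cut-off (the
cut-off is reused; no separate threshold is defined); otherwise the
component endpoint decides — Opn (x ≥ 1 mm and z > 0), Clo (x ≤ −1 mm),
Sup (z ≥ 1 mm with |x| < 1 mm, the strict reading of rotation without
digit displacement). A site is responsive when at least one of its trials
passes the cut-off at ≤ 100 μA and it is not a sham; endpoints, onsets
and ends average over the passing trials, and the distal call runs on the
pointwise trial-averaged component so the Ocs phase structure survives
averaging. A sham site with supra-cutoff movement raises an integrity
warning.

## Maps and enrichment

Positions snap to the nearest gridpoint of the 4 × 8, 0.5-mm grid
(half-pitch ties toward the smaller ML then AP index; > half-pitch
off-grid is an error). A representation is the set of gridpoints whose
cumulative count reaches 2 (inclusive by default; a strict > variant is a
config option — the two readings of "at least 2 of 5 animals" vs "larger
than two" cannot be distinguished from the text). Elevation is classified
but never mapped. The interpolated contour field (Gaussian, σ = one
pitch, mass-conserving padding) is for plotting only; every statistic uses
raw counts and masks.

The class × representation χ² is Pearson's without continuity correction;
Cramér's V = √(χ²/(N(min(r,c)−1))). The Monte Carlo null places the
observed number of neurons independently and uniformly on the gridpoints
(with replacement), records the density inside the representation, and the
two-tailed p measures absolute deviation from the null mean with an
add-one correction so p is never 0 (tail-doubling is available as an
alternative convention). Neurons under overlapping representations count
in each; area is measured in gridpoints (the 0.25-mm² cell area cancels).
Default n_sim = 10,000; the calibration studies use 2,000.

## Synthetic-data generator

The generator emulates the study's conditions: sessions of 45 trials at
p(success) = 0.7 (i.i.d. outcomes; no serial correlation is modeled),
phase durations ~250 ± 50 ms drawn from one law for both outcomes, and up
to 32 neurons on distinct gridpoints. Neurons are inhomogeneous-Poisson
with rate = baseline × a smooth gain profile: Gaussian bumps (SD 75 ms)
centered at −150 ms (pre) and +150 ms (post). For gains > 1 the bump is
normalized so the epoch-mean rate equals baseline × gain exactly (making
epoch-rate recovery testable against a counting oracle); for gains < 1 a
peak-normalized dip keeps the rate non-negative. Defaults: baseline
5 spikes/s, dominant-epoch gain 4×, neutral-elevated gain 3× in both
epochs — large enough to recover at 45 trials, small enough to be
physiological; these effect sizes are engineering choices, no per-archetype
values are published. Nine archetypes cover the scheme: three
outcome-independent (gains equal across outcomes), three
outcome-dependent (success-side gains with a mild 2× "neutral response"
or baseline "silent response" in failure), plus unmodulated, decreasing
(0.2×) and failure-only controls so every exclusion filter is exercised.

ICMS sites ramp (minimum-jerk, onset 100 ms after stimulus, 500 ms
duration matching the train) to an endpoint drawn around the class mean
(SD 1 mm), then hold; the digit marker adds the distal component, two-phase
for Ocs. Both markers ride a shared 1-Hz breathing sinusoid of 0.23 mm on
z plus 0.05-mm sensor noise. The proximal endpoint means are the observed
class centroids of evoked movements; the distal defaults are synthetic
values placed well inside each class's decision region, because the
published distal centroids are expressed in joint coordinates and do not
satisfy the marker-frame rules (e.g. a closure centroid with positive x).
The default per-animal layout assigns coherent territories (extension +
open/closure anteriorly, abduction + opening centrally/posteriorly, small
adduction/retraction/supination patches) with each responsive site
evoking its proximal class alone, its distal class alone, or both at
roughly the observed 37/10/53% mix, plus ~4 non-responsive and 2 sham
sites.

What passing tests on this generator do **not** show about real data: no
bursting or refractoriness (epoch counts are exactly Poisson), no
trial-history effects, no electrode drift or sorting errors, no
correlated noise between neurons, and ICMS endpoint scatter is isotropic
Gaussian rather than biomechanically structured. Recovery rates measured
here (≈ 94% labels, ≈ 99% site calls) are upper bounds for such effects.

## Calibration studies and problem sizes

The validation studies are sized to run comfortably on one CPU: label
recovery uses 20 repeated studies of 60 modulated neurons (10 per
archetype, split over two 32-channel sessions); gate calibration uses
1,000 unmodulated neurons; Monte Carlo calibration uses 500 replicates at
n_sim = 2,000 with 300 uniformly placed neurons and a 16-gridpoint mask —
enough neurons that the discrete density statistic has many support
points, without which a KS test against the uniform would measure
discreteness rather than miscalibration.

## Known limitations

* The per-neuron outcome-dependence rule and the net-normalized-activity
  formula are documented reconstructions; alternative readings would
  change individual labels but not the pipeline's structure.
* The trial-level outcome × epoch ANOVA treats the two epoch observations
  of a trial as independent; a mixed model would respect the pairing but
  is not identifiable from the published degrees of freedom.
* Monte Carlo p-values are discrete; with few neurons or a tiny mask the
  two-tailed p is conservative near 1.
* File-driven pipeline runs go through the io readers and stage functions;
  `run_pipeline` itself always simulates.
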