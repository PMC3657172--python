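# Methods

This note documents the statistical conventions, the synthetic-observer
model, the defaults that matter, and the choices made where the design was
genuinely open.

## Paradigm and scheduling

All schedules are generated from a seed through `numpy.random.Generator`
(PCG64); a seed plus the generator calls fully determines a schedule, and
writing the same schedule twice produces byte-identical files.

Object stimuli are parameter records, not images. A stimulus is the triple
(inner shape id, outer shape id, fill id) plus a rotation drawn uniformly
on [15°, 165°] *per object* (matches share the feature triple, not the
rotation — "same" is defined on features). Shape ids are allocated from an
incrementing counter, which enforces trial uniqueness by construction; the
mapping from shape id to repeating low-level "segments" (below) is the only
place shape identity carries content. Filler stimuli use disjoint shape,
fill and segment namespaces, making them perceptually unrelated to the
ambiguity conditions by construction.

Counterbalancing of the differing feature on high-ambiguity nonmatch
trials is exact within block: n nonmatch trials get ⌊n/3⌋ of each feature,
remainders assigned to randomly chosen features (so 36 → 12/12/12 and
44 → 15/15/14), then shuffled. The fMRI variant draws the number of
3-nonmatch miniblocks m uniformly from 0–18, uses m 1-nonmatch and
36 − 2m 2-nonmatch miniblocks (every admissible composition keeps 72
nonmatch / 36 match with ≥ 1 nonmatch per miniblock), and shuffles;
ordering miniblocks for fMRI contrast efficiency is out of scope. Size
trials jitter each square by ±10 px per axis, redrawn until the offsets
differ on both axes (the jitter magnitude is this package's choice; only
its purpose — misaligned edges — is constrained by the design).

Display timing (15 s response deadline; 5.75 s fMRI trial length) is
recorded as schedule metadata only: the package neither renders stimuli
nor collects human responses.

## Same-different signal detection

The differencing model is the default because it is the standard model
for roving same-different designs with trial-unique stimuli; the
independence-observer model is provided as an alternative (it caps the
false-alarm rate at 0.5 and the hit rate at Φ(c), and rejects inputs
beyond those bounds). Which model the field's published analyses used is
usually not stated; analyses here should report the model name, which the
result objects carry.

Numerics: the criterion k is recovered in closed form from the
false-alarm equation (k ≥ 0 on the absolute-difference axis); d′ is then
solved by Brent's method on [0, upper] with xtol 1e−9, the bracket upper
bound doubled until the forward model exceeds the target hit rate. At
hit = fa the solver is bypassed and d′ = 0 exactly. For hit < fa the two
rates swap roles and the result is negated, making d′ antisymmetric under
rate exchange. Rates of exactly 0 or 1 are rejected with a pointer to the
half-trial correction, which is applied only when a raw rate is perfect.

Reaction-time summaries use the median over correct trials by default
(mean selectable): the underlying RT generator is lognormal, and medians
are robust to its tail.

## Single-case and group statistics

Crawford's modified t treats the control sample as data, not parameters:
t = (x − m̄)/(s·√((n+1)/n)) with df = n − 1 keeps the type-I error at the
nominal level for control samples as small as the n = 8 used throughout.
One-tailed p values are taken in the deficit direction (lower score), so a
patient above the control mean reports p > 0.5 as-is; difficulty analyses
on control tables are two-tailed. A planned contrast with all
per-participant values exactly zero reports t = 0 (p = 0.5 one-tailed)
rather than an error; zero variance around a nonzero mean is an error,
since no finite t exists.

Group equivalence uses a closed-form balanced mixed ANOVA (group between,
condition within; group tested against subjects-within-groups, condition
and interaction against the subject × condition residual). It is written
directly in numpy so that calibration simulations over 10⁴ replicates run
in seconds; the test suite cross-checks it against pingouin's
`mixed_anova` on the same data. With one condition the design collapses to
a two-sample t test.

## Gaze metrics

The within:between statistic is the quotient of the two per-trial-averaged
ratios, not the average of per-trial quotients — with per-trial saccade
counts as low as 3–10 the latter is badly behaved. Trials with no counted
saccades are skipped; if no between-item saccade occurs anywhere the
quotient is undefined and the error object carries both component
averages so pipelines can report rather than crash.

Open conventions and their defaults:

* **Trials used** — nonmatch trials only (on a match trial the two stimuli
  are identical, so the trial has no ambiguity level); `trials="all"`
  is available.
* **Out-of-frame fixations** — excluded from W, B and T (so W + B = T);
  an `assign-nearest-frame` policy is available. Frame boundaries are
  inclusive; the 8 px gap belongs to neither frame.
* **Error and timeout trials** — retained.

A velocity-threshold fixation detector is included for raw samples; it is
a plain threshold-and-merge detector for simulated or pre-cleaned data,
not a re-implementation of any eye-tracker vendor's event parser.

## The synthetic observer

The observer implements a representational-hierarchical interference
mechanism. The functional form is this package's construction; the
parameters below are generative ground truth, not estimates of any
empirical quantity.

**Representation.** Each shape id maps deterministically to 4 of 16 shared
segment ids (fillers: 4 of a disjoint 16). An interference state carries a
trace vector per feature channel. Processing a trial adds 1 to each
segment of both presented shapes and a calibrated deposit to the presented
fills (scaled so all three channels accumulate load at the same expected
rate), then multiplies all traces by the decay ρ. A channel's *load* on a
trial is the trace mass similar to the current stimuli: the mean trace
over the presented shapes' segments, and the mean over the fill namespace
(the 8 fills repeat exactly, so fill interference is pool-wide).

**Noise law.** Feature-channel comparison noise is
sd = σ_f · (1 + λ · max(0, load − θ)). The capacity threshold θ encodes
that posterior feature banks absorb interference up to a point and degrade
once their capacity is exceeded; with the defaults below the load of a
consecutive high-ambiguity block crosses θ after roughly 25–35 trials,
while the every-third-trial schedule keeps the load below θ indefinitely
(steady-state load scales with deposit·ρ/(1−ρ) for consecutive trials but
with ρ³ between relevant trials when two fillers intervene).

**Decision.** Channel evidence is |δ + ε| (δ = 1 if the feature differs,
0 otherwise). An intact observer adds a conjunction channel (δ = 1 on any
nonmatch) whose noise ignores trace load. Channels combine by reliability
weighting (weight 1/sd²; the conjunction channel gets conj_weight/sd² —
its representation is assumed higher-fidelity than a single feature), so
an intact observer automatically shifts onto the conjunction channel as
feature channels degrade, which is what keeps control performance flat
under interference. The response is "different" if combined evidence
exceeds a criterion that (a) initializes at the analytic midpoint of the
observer's own expected match vs nonmatch evidence at zero load — what a
practice block with feedback establishes — and (b) drifts toward the
running mean evidence at rate α per trial, per stimulus class, modelling
an observer who knows the 50/50 base rate and recalibrates as their
evidence scale shifts. Size trials use a single side-difference channel
(|Δside|/16 px) and do not touch the trace: size interference is not part
of the mechanism being modelled, mirroring the empirical finding that the
decline is specific to the object conditions.

**Defaults** (one block, used everywhere):

| parameter | default | meaning |
|---|---|---|
| σ_f (`feature_noise_sd`) | 0.3 | baseline feature noise, signal units |
| σ_c (`conj_noise_sd`) | 0.45 | conjunction-channel noise |
| `conj_weight` | 8 | reliability multiplier of the conjunction channel |
| λ (`interference_gain`) | 2.0 | noise growth per unit above-capacity load |
| ρ (`trace_decay`) | 0.975 | per-trial trace retention |
| θ (`capacity_threshold`) | 10 | cost-free load per channel |
| α (`criterion_adapt_rate`) | 0.2 | criterion drift rate |

σ_f, σ_c and conj_weight were chosen so intact and lesioned observers are
comparably accurate at zero load (d′ ≈ 3–3.5, off the half-trial-correction
ceiling); λ, ρ and θ were tuned once so the simulated interference dynamics
reproduce the qualitative ordering the paradigm is designed around —
lesioned decline confined to the second half of a consecutive
high-ambiguity block, intact observers flat, rescue under every-third-trial
scheduling — and are documented as such, not presented as estimates. The
RT model (lognormal, slower near-criterion) is decorative pipeline
plumbing and carries no scientific claims.

**What the generator does and does not emulate.** It reproduces the
design's logic: accumulating similarity-driven interference, its
dependence on schedule structure, and the protective role of conjunctive
coding. It does not emulate real patients' heterogeneity, lapses,
fatigue, learning, stimulus-specific perceptual structure, or realistic
RT distributions — so green tests show the *analysis chain* behaves
correctly and the *mechanism* produces the documented pattern, not that
real patient data would.

The gaze generator is a two-state Markov process: the eye stays on the
current item with probability p per transition, positions uniform within
the frame (50 px margin). (Within/Total)Av is then a consistent estimator
of p, which the recovery tests exploit (at 72 trials × 200 fixations the
binomial standard error is ≈ 0.004, well inside the ±0.02 band checked).

## Problem sizes

Simulation-based checks use: 200 seeded runs for the interference
pattern; 2 × 10⁵ replicates for the Crawford null calibration (Monte-Carlo
SE ≈ 0.0005 against the ±0.005 acceptance band); 10⁴ replicates for the
mixed-ANOVA type-I calibration; 10³ random sequences for the gaze
classifier oracle and 10³ random rate pairs for the d′ inversion oracle.
These sizes put Monte-Carlo error well below every tolerance they are
checked against while keeping the full suite under a few minutes.

## Known limitations

* The differencing/independence choice cannot be validated against
  published patient d′ values (raw data not public); both models are
  provided and results are labelled.
* The balanced mixed ANOVA requires complete, equal-size groups;
  unbalanced designs are rejected rather than approximated.
* The capacity-threshold noise law is one of many forms consistent with a
  verbal interference account; conclusions from the synthetic observer are
  qualitative (orderings), never quantitative fits.
* Schedules model stimulus identity abstractly; anything that depends on
  actual image content (e.g. low-level saliency effects on gaze) is out of
  scope.
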