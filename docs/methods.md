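# Methods

`taskcpca` implements a constrained principal component analysis (CPCA)
workflow for event-related task fMRI at the parcel level, together with
the inferential machinery that typically surrounds it: bootstrap
significance of spatial loadings, multilevel growth models of
event-locked response curves, peak-score/behaviour association with
FDR control, and alignment of activation maps with structural
difference maps against spatial-autocorrelation-preserving surrogate
maps.  This note records the model, its assumptions, the defaults, the
numerical choices, and what the synthetic-data experiments do and do
not establish.

## The decomposition

Let `Z_i` be subject `i`'s parcellated BOLD run (volumes × regions),
per-region z-scored (zero-variance regions are centred only; the
standardisation is recorded and can be disabled).  The FIR design
`G_i` contains one indicator column per (event type, post-event lag):
acquisition `k` falls in lag bin `j` of a trial with onset `t0` iff
`k·TR − t0 ∈ [j·TR, (j+1)·TR)`.  With the default 18-s window at TR
3 s there are six lags and six event types (threat / non-threat ×
correct / incorrect / non-response), hence 36 columns.  Reported lag
times are bin midpoints (1.5, …, 16.5 s), so response peaks land on
half-TR offsets (4.5, 7.5, 10.5, 13.5 s).  Event types with no trials
keep their all-zero columns for cross-subject alignment; fitting uses
the pseudoinverse and logs rank deficiency.

The constrained step keeps the design-explainable part,
`Ẑ_i = G_i G_i⁺ Z_i`; the residual is orthogonal to the design's
column space by construction.  The `Ẑ_i` are stacked across subjects
and decomposed with one SVD, giving group spatial loadings `V` (right
singular vectors) and subject score blocks (rows of `U·diag(d)`), i.e.
one spatial solution for the cohort with subject-specific temporal
weights.  Variance explained is `d_k²/Σd²`.  Sign ambiguity is fixed
by flipping each loading column so its largest-|value| entry is
positive, which makes output deterministic across platforms.

Retention uses a scree-elbow criterion: the cumulative-variance curve
over the leading 20 components is normalised to the unit square and
the retained count maximises the perpendicular distance to the chord
joining its endpoints.  An explicit override is honoured (a fixed
six-component solution is used throughout the validation experiments,
where the ground truth has six modes).

A component whose loadings share one sign over more than 90% of
regions is interpreted as a global signal fluctuation, labelled PC0,
and excluded from reporting; the remaining components are re-indexed
PC1..PC(K−1) in variance order.

Back-regressing each subject's retained scores onto the same FIR
basis gives the event-locked mean score at each lag per event type
(the response curves).  There is no baseline column: curves are
relative to the inter-trial baseline absorbed by standardisation.
Event types absent for a subject are marked missing, never zero.

## Inference on loadings

Subjects are resampled with replacement, the group decomposition is
refitted per replicate at the reference rank, and replicate components
are aligned to the reference by greedy maximal-|correlation| matching
with sign flips (ties broken by component order).  Each region is
tested with the normal-approximation z ratio (loading / bootstrap SE,
two-sided); the analytic ratio makes thresholds such as p < 1e-4
reachable at a few hundred replicates, which a percentile bootstrap
cannot do.  Default 500 replicates; replicate failures are dropped and
logged, more than 10% failing is an error.

The stimulus-independence null multiplies every region's
positive-frequency Fourier coefficients by the *same* random unit
phases, preserving per-region power spectra and all cross-spectral
magnitudes (hence zero-lag spatial covariance) while destroying
event-locking.

## Growth models

For one component, the estimated score at each lag of the four
response event types (non-responses excluded) is modelled with a
linear mixed-effects model.  Time is expressed in seconds at the bin
midpoints and centred at the window midpoint before raising to powers
(raw, non-orthogonalised polynomials keep the coefficients
interpretable while centring tames collinearity).  Mandatory
covariates — age, sex, total brain volume, mean framewise
displacement, handedness, group — are never dropped by selection
(constant columns, e.g. an all-right-handed subsample, are
unidentifiable next to the intercept and are removed with a log
entry).  Continuous covariates are centred.

The random structure reflects the nesting of the data: a subject
random intercept plus a nested subject × event-type intercept, and
optionally a random time slope.  The nested term matters: per-subject
curve estimates share FIR-regression noise across cells, and without
it the likelihood-ratio tests for stimulus/response terms are
anticonservative (admission rates of 15–20% at a nominal 5% on
phase-randomized surrogates; about 5–7% with the term included).
Boundary fits with a slope variance below 0.1% of the residual
variance, or a singular random covariance, trigger a logged refit
without the slope.

Selection is forward stepwise over a hierarchy-respecting ladder:
time polynomials in increasing degree (stopping at the first
non-significant degree), then stimulus/response indicators, their
interactions with the admitted time terms, and finally group
interactions.  A candidate is admitted when the ML likelihood-ratio
test against the current model is significant at the selection alpha
(default 0.05, chi-squared with 1 df; 2 df for the random slope).
Interactions are only eligible once their main effects are present
(group, being mandatory, is always available); ladders violating this
are rejected.  The final model is refit by REML.  Reported per-term
tests use the normal approximation with residual-convention degrees of
freedom (n_obs − n_fixed); exact small-sample df conventions are not a
goal.

## Brain–behaviour association

The peak score per (subject, component, response event) is the signed
value at the lag maximising |estimate| (earliest lag on ties; a
signed-maximum convention is also available).  Cells estimated from
fewer than three trials are treated as missing: a 6-point curve
estimated from one or two trials is noise-dominated and its
"peak" is an extreme-value artefact, so those subjects drop out of the
affected model only — mirroring per-model missingness.  Accuracy is
rank-transformed (average ranks on ties), and each of the 20
(component × event) models regresses the rank on the standardised peak
plus the five adjustment covariates by OLS, reporting a standardised
beta.  Benjamini–Hochberg FDR is applied over exactly the 20-cell
case-group family; control-group and group-interaction analyses are
reported separately without joint correction.

## Structural alignment

The alignment statistic is the mean absolute value (MAV) of a cortical
difference map (thickness or surface area) within a component's
suprathreshold cortical regions.  Null maps preserve the empirical
map's value distribution exactly and its spatial autocorrelation
approximately: a random permutation of the map is smoothed with
distance-based exponential kernels over a grid of correlation lengths,
the length whose variogram best matches the original is selected, and
the original values are re-assigned by rank of the smoothed field.
This variogram-matched permutation engine needs only parcel centroid
coordinates, not surface geometry; a sphere-rotation engine would be a
natural extension where surfaces are available.  p-values use the +1
correction, `p = (1 + #{null ≥ observed}) / (n_perm + 1)`, so p never
equals 0; BH-FDR runs over the full family (default six components ×
two metrics; note the q floor `family / (n_perm + 1)` — 500
permutations leave room below q = 0.05, 100 do not).

## The synthetic cohort generator

The generator emulates a fast event-related emotion-identification
protocol: 60 stimuli of 5.5 s, ISI jittered in 0.5–18.5 s, 10.5-minute
run, TR 3 s (210 volumes), 214 regions (200 cortical + 14
subcortical).  ISIs are drawn uniformly and affinely rescaled
(anchored at the lower bound) so the run duration is matched exactly;
one ISI follows every trial, giving a 5.0-s mean ISI at the default
geometry.  Onsets are snapped to the acquisition grid by default so
that curve placement and FIR binning agree exactly; sub-bin onset
jitter is available but smears the planted curves across lag bins.

The planted model has six components: a global near-uniform mode and
five bipolar modes with disjoint 32-region supports (hence exactly
orthogonal maps, with zero-mean values orthogonal to the uniform
mode).  Each component's curve set is rank-1 over the event × lag
grid — a signed event-weight vector times a lag profile — emulating an
early task-general response, a delayed error-dominant response, a
correct/incorrect antiphase response, an early error-dominant salience
response, and a biphasic early-negative/late-positive response.
Because the decomposition can only identify modes whose score time
courses are uncorrelated under the task's trial-overlap structure, the
curve set is made exactly orthonormal in the metric of the expected
centred-and-projected FIR Gram matrix (estimated once by Monte Carlo
over default schedules with fixed internal seeds), via the polar
factor closest to the designed shapes.  Component energies decrease
with index so the planted order matches the variance order.

Case-group ("22q-like") modifications: the delayed error-dominant
component is attenuated (scale 0.55), and the biphasic component's
case curve replaces most of the late peak with an early one (a 0.35 /
0.85 mixture of the control direction and an early profile,
orthogonalised against the other components so the group difference
does not bleed across modes).

Per-subject amplitudes have a shared component gain (SD 0.3) plus
event-type-specific variation (SD 0.3).  Accuracy is the group base
rate (0.729 cases / 0.909 controls) plus the planted coupling applied
to the subject's amplitude matrix (default: 0.2 per incorrect event on
the delayed error-dominant component) plus N(0, 0.05) noise, clipped
to [0.02, 0.98]; response classes are then sampled per trial from the
subject's own accuracy (incorrect:non-response split 0.7:0.3).  At
these rates a case subject has roughly five incorrect trials per
stimulus class, which is what limits per-cell peak precision — hence
the minimum-trial rule above and the two-cohort design of the
behaviour-recovery experiment.  Region noise is AR(1) (coefficient
0.3, unit innovation SD); at the default signal scale the task signal
is roughly 20–30% of total variance per subject.

Structural maps are Gaussian fields with exponential spatial
covariance (default correlation length 25 mm) over synthetic
hemispheric-shell centroids; an effect `effect_size × |loadings|` of a
chosen component is added to the surface-area map only.

What the generator does **not** emulate: voxel-level structure and
registration error, haemodynamic nonlinearity and undershoot,
low-frequency drift and physiological noise, region-specific noise
levels, spatially correlated BOLD noise beyond the planted components,
and non-orthogonal ground-truth modes.  Passing recovery tests
therefore show the estimators are correct and calibrated under the
model's own assumptions at realistic sizes — not that the assumptions
hold in real BOLD data.

## Validation experiment sizes

The validation battery (`taskcpca.validation`, run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: exact
deconvolution on 10 noiseless subjects; variance partition on two
temporally disjoint components (exact 80/20); recovery on a
116-subject cohort (all planted-map cosines ≥ 0.95 after Hungarian
matching, global mode flagged); bootstrap calibration on three
32-subject cohorts × 200 replicates (984 null-region p-values);
surrogate-null growth selection on a 12-subject cohort; selection
consistency over 25 replicates of 40 subjects (cubic time +
group × time² generating model); behaviour recovery on two 116-subject
cohorts and 200 null replicates of the 20-cell family; MAV calibration
over 200 null maps of 120 regions × 100 permutations and recovery at
500 permutations; and oracle equivalences (pooled OLS, brute-force
BH, design-residual orthogonality).

## Known limitations

- The z-ratio bootstrap is mildly anticonservative at small cohort
  sizes (false-positive rates near 0.06 at n = 32 subjects); it
  approaches the nominal level as subjects grow.
- Peak extraction by max-|·| is an extreme-value statistic; with few
  trials its magnitude correlates with estimation noise, which both
  motivates the minimum-trial rule and caps the attainable
  brain-behaviour detection power at realistic error rates.
- The elbow criterion is a heuristic; the retained count should be
  overridden when the truth or a protocol dictates it.
- The growth-model term tests use normal approximations; very small
  cohorts deserve a parametric-bootstrap LRT instead.
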