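# Methods

## Feature extraction

A spectrum's base peak (most intense fragment) defines relative
intensities. Fragments with relative intensity ≥ 10% (inclusive) are
ranked by descending intensity — ties break by lower *m/z*, then input
order, so matrices are reproducible — and the top three fill the fragment
slots. Neutral losses are `|reference − fragment m/z|`.

Two reference conventions exist in practice. Taken literally against the
base peak, the top-ranked fragment *is* the base peak, so its neutral loss
is identically zero: an informationless constant column that autoscaling
must reject. `extract_features` therefore defaults to the base-peak
reference for fidelity at the single-spectrum level, while the pipeline
(`RunConfig`) defaults to the precursor reference — the usual chemical
convention — so that all eight modeled variables carry variance. A third
variant (`include_base_peak=False`) uses the base peak as reference only
and fills the slots with the next most intense fragments. All three are
tested.

Analytes with fewer than three surviving fragments keep the remaining
slots *flagged missing* rather than zero-filled; imputation is an explicit
later step (`mean_impute` by default, `zero_fill` for sparse
high-collision-energy matrices where absent signals are genuinely null).
Retention times are minutes everywhere (MGF `RTINSECONDS` is divided by 60
at parse time); *m/z* values are used unrounded.

Monoisotopic masses for fragment annotation come from the IUPAC atomic
mass table (via pyteomics), summed over elements with no electron-mass
correction; the ~0.55 mDa electron deficit of a cation is below the
0.5 mDa annotation tolerance used here.

## Autoscaling, partitioning, PCA diagnostics

Autoscaling centers each column and divides by its n−1 standard deviation;
constant columns raise an error naming the column. The Kennard-Stone split
seeds with the two mutually farthest samples (Euclidean distance in the
scaled space) and grows the training set by maximin selection; the first
⌈0.75·n⌉ picks train. Every tie breaks to the lowest row index, so the
partition is fully deterministic. An absolute training-set size can be
given instead of a fraction (useful when replicating a published split
whose size was reported directly, since ⌈·⌉ rounding need not reproduce
it).

PCA is computed by SVD of the autoscaled matrix. Eigenvalues are the score
variances s²ₐ/(n−1); each loading vector is signed so its largest-magnitude
element is positive (stable loading plots). Diagnostics per sample:
T² = Σₐ t²ₐ/λₐ (Mahalanobis score distance) and Q = ‖x − tPᵀ‖² (squared
orthogonal residual).

Critical limits at confidence 1−α (default α = 0.05):

* T²: A(n−1)/(n−A) · F₁₋α(A, n−A).
* Q: moment-matched scaled chi-squared — with m, v the training-Q mean and
  variance, Q_crit = (v/2m) · χ²₁₋α(2m²/v); if v = 0 (rank-exhausted
  model) Q_crit = m. This form stays usable at the very small per-class n
  of screening panels (down to 4). The Jackson–Mudholkar limit from the
  discarded eigenvalue spectrum is available as an alternative
  (`q_limit_method="jackson_mudholkar"`).

The influence table flags a sample as an outlier iff T² or Q exceeds its
limit.

## SIMCA

Each class with ≥ 4 analytes gets its own PCA model with class-local
autoscaling (global scaling available by flag); smaller classes are not
modeled but still serve as non-target samples. Classification is
independent per class — a sample may be accepted by zero, one, or several
models.

**Acceptance rule.** Default `combined_chi2`: rescale the two distances by
their training means, c = N_h·T²/T²₀ + N_q·Q/Q₀, with N_h = 2·mean²/var
and N_q likewise moment-estimated from the training distances, and accept
when c ≤ χ²₁₋α(N_h + N_q). The reported distance is d = √c with threshold
√χ²₁₋α, so "accepted ⇔ d ≤ d_threshold" holds everywhere (prediction,
validation counts, Coomans quadrants use this one definition). When a
class model exhausts the data rank, Q ≡ 0 and the Q term is dropped
(N_q = 0); a strictly positive Q then maps to certain rejection.
Alternative `box_rule`: accept iff T² ≤ T²_crit and Q ≤ Q_crit, reported
as d = max(T²/T²_crit, Q/Q_crit) with threshold 1. The combined rule was
chosen as default because it produces a single smooth acceptance boundary
and calibrates close to the nominal level on Gaussian classes (measured
acceptance ≈ 0.94–0.95 at α = 0.05; the chi-squared moment approximation
is slightly conservative at small training n).

**Component selection.** Candidate counts A = 1…A_max are scored by
cross-validated efficiency √(sensitivity × specificity): folds are five
contiguous venetian-blind cancellation groups over rows sorted by analyte
id when the class has ≥ 8 analytes, else leave-one-out (deterministic, no
seed). Per fold, a model fit on the remaining class rows scores held-out
class rows (pooled into CV sensitivity) and all non-target training rows
(fold specificities, averaged). The smallest A attaining the maximum
efficiency wins. At the small class sizes typical of screening panels,
CV sensitivities are coarse fractions that tie frequently, which is
exactly when this parsimony tie-break matters. A_max is capped at
min(smallest fold-training size − 1, 8). The four-analyte floor applies to
the class, not to fold sub-fits.

**Validation.** For class c: TP/FN from true-c samples accepted/rejected
by c's model, FP/TN from non-c samples; sensitivity TP/(TP+FN),
specificity TN/(TN+FP), efficiency their geometric mean. Classes absent
from an evaluation set get NaN sensitivity rather than a fabricated value.
Train- and test-set reports are computed and labeled separately.

Models serialize to JSON with full numeric state (means, sds, loadings,
eigenvalues, limits, rule, alpha), so predictions are bit-reproducible
across sessions.

## Synthetic panels

`generate_panel` draws, per analyte: precursor and retention time
uniformly within the class template's windows; one fragment per retained
characteristic loss at precursor − loss with Gaussian m/z jitter
(sd 0.003 Th, a realistic HRMS mass-accuracy scale); rank-patterned
relative intensities (base weights 1.0/0.65/0.40 times a gamma multiplier
with relative spread 1/√concentration, concentration 40); one to three
nuisance fragments below the 10% threshold; and independent fragment
dropout (probability 0.05, with per-loss occurrence probabilities 1.0 /
0.95 / 0.85 in the default templates). A single NumPy generator stream
makes a (templates, sizes, seed) triple bit-reproducible.

The default panel names the nine modeled drug classes with their study
sizes (17, 22, 18, 17, 4, 17, 5, 4, 6) plus seventeen minor classes of
2–3 analytes (49 records) that exercise the below-floor exclusion path,
for 159 records total. All template values are invented: the generator
reproduces the statistical shape of a screening panel — class-clustered
features, shared-scaffold overlap (`overlapping_templates`), small-n
classes, missing fragments — not fragmentation chemistry, isotope
envelopes, or retention-time/structure relationships. Passing tests
therefore demonstrate the correctness and calibration of the chemometric
machinery on data with the declared structure, not instrument-level
performance on real seizures.

`well_separated_templates` is the idealized variant (every loss always
present, no dropout) used by calibration and end-to-end recovery tests:
fragment dropout shifts lower-ranked fragments into vacated slots and
splits a class into sub-clusters, which would confound properties whose
premise is one tight cluster per class.

## Problem sizes and numerical choices

* Control-limit and acceptance calibrations use n = 2000 Gaussian training
  samples (binomial noise ±1% at the 95% level); end-to-end recovery uses
  balanced panels of 40 analytes per class so per-class rates resolve to
  2.5%; component recovery uses 20 replicates of 20-sample rank-2 classes.
* Degenerate denominators (zero Q limit or Q scale after rank exhaustion)
  map a ~zero numerator to 0 and an appreciable one to +∞, never NaN.
* Ranking ties, Kennard-Stone ties and CV fold assignment are all resolved
  deterministically; the only randomness in the package is the synthetic
  generator, which requires an explicit seed.
* The ≥ comparison at the 10% intensity threshold is inclusive.

## Known limitations

* The combined chi-squared acceptance is an approximation; its acceptance
  rate runs ~0.5–1.5% below nominal for small training sets.
* CV-efficiency component selection is only weakly identified when
  non-target classes are far away in every direction (any A then gives
  specificity 1); its selection consistency was verified in the regime
  where the non-target class breaks the tie.
* The Kennard-Stone split is unstratified, as in the original protocol: a
  four-analyte class can fall below the modeling floor in the training
  partition, in which case it is (correctly) not modeled.
* Feature extraction assumes centroided peak lists; profile data,
  centroiding, lock-mass correction, adduct and isotope handling, and
  spectral-library similarity search are out of scope.
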