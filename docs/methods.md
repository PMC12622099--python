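# Methods

## The model

A brain-age model is a regression `f : features → age` fitted **only on
healthy controls**, so that its errors on clinical groups can be read as
disease-related deviation rather than refitted-away signal. The pipeline is
a per-feature standardiser followed by a regressor (ordinary least squares,
ridge with penalty α, or an RBF support-vector regressor), fitted under
k-fold cross-validation with shuffled, seeded fold assignment. Defaults:
5 folds, ridge α = 1.0, SVR C = 1.0 / ε = 0.1 — all exposed in
configuration; the defaults are the common small-tabular-data settings and
matter little for the linear models because the feature sets are low
dimensional.

Two numbers summarise a fit:

* **Uncorrected MAE** — the mean |out-of-fold prediction − age| over all
  controls, computed strictly before any bias correction. Every control has
  exactly one out-of-fold prediction; scaler statistics come from the
  training folds only.
* **Bias-correction coefficients** — regression to the mean compresses
  predictions toward the training-age mean, so raw deltas correlate
  negatively with age. The default correction fits `ŷ ≈ a·y + b` by OLS on
  the pooled out-of-fold control predictions and inverts,
  `ŷc = (ŷ − b)/a`, `δ = ŷc − y`. An alternative ("delta on age": fit
  `ŷ − y ≈ α·y + β` and subtract) is available behind a config switch. Both
  zero the delta-age slope exactly on the fitting sample — an algebraic
  identity of OLS, which the tests verify numerically.

Choices the underlying procedure leaves open, resolved here:

* The correction is fitted on **out-of-fold** control predictions (in-sample
  predictions would be optimistic about the model's compression).
* Non-control groups are scored with a pipeline **refit on all controls**
  (rather than averaging per-fold models), then corrected with the
  oof-fitted coefficients. Controls themselves are always scored
  out-of-fold.
* `a = 0` (a model entirely uninformative about age) makes the inverse
  correction undefined and raises rather than returning infinities.

## Mutual-information ranking

Features are ranked by MI in nats, estimated with the
Kraskov–Stögbauer–Grassberger k-nearest-neighbour family (continuous target
for age; the continuous–discrete variant for binary labels), k = 3
neighbours by default. The estimator adds a tiny seeded jitter to break
sample ties; negative raw estimates are clamped to zero, constant features
score exactly zero. Exact score ties are broken by ascending feature name so
a ranking never depends on CSV column order. MI is computed on raw feature
scales — the estimator is invariant to per-variable monotone transforms
(tested with exp).

The label-criterion MI uses only subjects of the two compared groups; the
age-criterion MI uses all subjects by default (config: controls only). Set
k of the nested sweep contains the k top-ranked features. Feature sets are
treated as *sets* downstream: the design matrix always uses the cohort's
declared column order, so when two orderings converge on the same set
(always at k = p) they produce bit-identical fits.

## Classification of deltas (and features)

Any per-subject representation is evaluated the same way: stratified k-fold
CV (class ratios preserved per fold), random undersampling of the majority
class **within each training fold** down to the minority count, per-fold
standardisation on the undersampled training data, an effectively
unpenalised logistic model (C = 10⁶, configurable), and AUC from predicted
probabilities on the untouched test fold. Reported as mean ± sd across
folds; a repeat-seed mode (default 5 seeds) adds across-seed dispersion.
Comparisons that must be paired — the four-input augmentation table
(features / features+age / delta / features+delta) and the per-k
model-kind comparison — share identical fold assignments and undersampling
draws, so differences reflect the input representation, not split noise.

A constant input yields AUC 0.5 with a warning rather than an error; each
class must contribute at least one subject per fold.

## Seeds

One master seed fans out to stage seeds via
`derive_seed(master, *stage_path)` (a CRC-salted `SeedSequence`), so any
stage is reproducible in isolation and no two stages share a stream. The
ordering criterion is deliberately **not** part of the seed path: at equal
k both orderings use the same folds, which is what makes their metrics
coincide exactly at the full feature set.

## The synthetic cohort

Restricted clinical data cannot ship with the package, so the generator
emulates the structure such cohorts exhibit. Default study conditions:
CN 300, MCI 300, AD 100, sMCI 120, pMCI 50 (870 subjects), ages uniform on
55–90 years. Feature value = intercept + slope·age + group offset + shared
latent (volumes only) + Gaussian noise:

* **Ten volumetric features** (grey matter … accumbens): age slopes
  0.008–0.035 per year against noise sd 0.15 (age correlations ≈ 0.4–0.9,
  grey matter strongest), small diagnostic offsets (≤ 1 noise sd), and a
  shared standard-normal latent (loading 0.08) inducing the collinearity
  real volumetric panels show. Cerebrospinal fluid increases with age;
  volumes decrease.
* **Six cognitive scores** (MMSE … executive function): large
  CN → MCI → AD offsets (1.6–2.4 noise sd for AD), with sMCI ≈ pMCI at
  baseline — both groups present as MCI when first seen. Age slopes are
  weak but *detectable* (age correlations 0.14–0.20, a factor 5–10 below
  the volumes). This calibration matters: if the cognitive age slope is
  statistically invisible at n = 300 controls (coefficient t ≈ 1), the
  control-trained regressor cannot resolve even the sign of its
  coefficient, and the resulting delta collapses to chance-level
  discrimination in a large fraction of draws — a degenerate regime rather
  than the "weak age signal, strong disease signal" one being modelled.
  With t ≈ 3 the single-cognitive-feature model still predicts age poorly
  (MAE ≈ 8 years vs ≈ 3.5 for the top volume) while its delta classifies
  CN vs AD well, which is the regime of interest.

Ages are uniform for simplicity (a Gaussian option exists); scores are
continuous without floor/ceiling truncation, since the models treat them as
continuous inputs. All parameters are stand-ins — no attempt is made to
match any real cohort's covariance, site effects or longitudinal
structure — so passing tests demonstrate that the *machinery* behaves
correctly under planted structure, not that any real-data effect size is
reproduced.

## Problem sizes and numerical choices

The oracle checks run at the sizes where their closed forms are sharp:
MI on bivariate Gaussians at n = 2000 (±0.05 nats of −½ln(1−ρ²)),
single-feature MAE at n = 1000 against σ√(2/π), binormal AUC at n = 2000
against Φ(d/√2), bias-correction slope at n = 1000. Planted-structure
rates (ranking recovery, k=1 trade-off) use 20 independent 870-subject
cohorts. A full 16-feature progression run (2 orderings × 16 sets ×
5 folds) takes a few seconds; the complete model-comparison sweep under a
minute.

Degenerate inputs are errors, not silent fixes: missing feature values are
rejected rather than imputed (the data model assumes complete baseline
visits), duplicate subject ids and non-positive ages are rejected, zero age
variance makes the bias correction undefined, and a cohort whose subjects
disagree on the feature set cannot be constructed.

## Known limitations

* Deltas are a one-dimensional projection: signal orthogonal to the age
  axis is discarded by construction, which is why a direct logistic model
  on the features can dominate delta-based classification (the package
  reproduces this on cohorts where the diagnostic feature has no age
  slope).
* The bias correction is linear; nonlinear age trends in prediction error
  are out of scope.
* The generator's planted effects are linear-Gaussian; it does not emulate
  bounded test scores, site effects, missingness or label noise, so
  robustness to those must be assessed on real data.
* MI rankings carry no significance testing; near-tied features can swap
  ranks between draws (the nested-set curves make this visible rather than
  hiding it).
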