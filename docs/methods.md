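# Methods

This note documents the models, numerical choices and known limitations of
`spectrastack`: what each stage computes, which parameters matter, what the
synthetic data generator does and does not emulate, and where the design was
genuinely open.

## Spectra and preprocessing

A `SpectraSet` holds an `n_samples x n_channels` absorbance matrix on a
strictly increasing wavelength grid in nm (default span 900.7592–1674.9758,
the effective range of a 900–1700 nm grating spectrometer with ~10 nm
optical resolution). Replicate scans are averaged arithmetically; class-mean
spectra are arithmetic means per class.

Four preprocessing operators address the standard NIR nuisances:

* **Savitzky–Golay (SG)** smoothing and differentiation: windowed
  least-squares polynomial fit evaluated at the window centre. Defaults
  window = 9 channels, polynomial order 1 (so plain smoothing is a 9-point
  moving average, and any degree-1 spectrum is a fixed point). Derivatives
  are taken with respect to channel index, not nm — the dominant
  chemometrics convention, and the only one that is well defined on
  non-uniform grids without interpolation; grid spacing is never consulted.
  Edge policy: the window polynomial is evaluated at off-centre positions
  for the first and last (window−1)/2 channels, so the channel count never
  changes (`scipy.signal.savgol_filter(mode="interp")`).
* **SNV**: per-spectrum centring and scaling to unit standard deviation
  (sample sd, divisor n−1; the divisor is invisible to downstream
  classifiers up to a constant but is fixed for reproducibility). Constant
  spectra are rejected by name.
* **MSC**: each spectrum is regressed on a reference spectrum by ordinary
  least squares, `x ≈ a + b·ref`, and corrected to `(x − a)/b`. The
  reference is the column mean of the *training* spectra; correcting with a
  reference fitted on all data (the common preprocess-before-split
  convention in the applied literature) is available behind the
  `msc_on_all` flag but is not the default, because it leaks test
  information into training. Samples with |b| < 1e−12 are rejected.
* **FD**: the SG first derivative (order 1, window 9 by default); additive
  baselines map to zero exactly.

Chains (`sg+msc`, `sg+snv`, `sg+fd`) always run SG first. A chain carries
fitted state only through its MSC step; `fit` returns a frozen copy so the
same unfitted template can be refitted per cross-validation fold.

## Feature extraction

All three extractors produce a centring vector plus a `d x q` projection
matrix; classifiers never know which extractor produced their features.

**PCA** retains the smallest q whose cumulative explained-variance ratio
reaches a target, default 0.993; an explicit component count overrides.
Eigenvector signs follow the largest-magnitude-entry-positive convention so
outputs are reproducible across platforms.

**PCA+LDA** reduces to `min(n_train − C, 15)` principal components by
default before classical Fisher LDA (generalized eigenvectors of the
between/within scatter pair), guarding the within-class scatter against
ill-conditioning; it returns at most C−1 directions composed into a single
map.

**OLDA** computes orthonormal discriminant directions that remain defined
when the within-class scatter is singular. With centred data factor
H_t (total scatter S_t = H_t H_tᵀ) and between-class factor H_b: a reduced
SVD H_t = U Σ Vᵀ (rank t at relative tolerance 1e−10) whitens the problem,
B = Σ⁻¹Uᵀ H_b is decomposed as B = P Ω Qᵀ, the uncorrelated-LDA map is
X_q = U Σ⁻¹ P_q for the q ≤ C−1 directions with Ω above tolerance, and the
OLDA basis G is the orthonormal Q-factor of X_q. The Ω entries are cosines
of principal angles (bounded by 1), so an absolute floor of 1e−8 on Ω₁
doubles as the degeneracy check for equal class means. In the nonsingular
regime the G-span coincides with classical LDA's; the projected
between/within trace ratio equals the sum of the top C−1 generalized
eigenvalues, which the tests verify against a direct eigensolver.

## Classifiers

Four weak learners behind one contract (`fit(spec, X, y, seed)` /
`predict`), all deterministic given training data and seed:

* **KNN** (default K = 3, Euclidean): implemented here because the
  tie-break rules are part of the contract — vote ties are broken by the
  smaller mean neighbour distance, then the lower class index; and the
  neighbourhood includes *every* training point tied with the K-th
  distance, so predictions are a function of the geometry rather than of
  training row order (with integer-valued meta-features, exact distance
  ties are the norm, and truncating at K would silently select neighbours
  by row position). Features are standardized with training statistics:
  distance voting across features of arbitrary scale is meaningless, and
  extracted spectral features can span many orders of magnitude.
* **Gaussian NB**: per-class, per-feature Gaussians with a variance floor,
  default 1e−9 × the largest feature variance; with floor 0 a zero
  within-class variance raises an error naming the class and feature —
  the exact failure mode that disqualifies NB as a stacking
  meta-classifier over label-encoded meta-features. Inputs are
  standardized per feature first; Gaussian NB is exactly equivariant under
  per-feature affine maps, so this costs nothing statistically while
  keeping the relative floor meaningful when features differ in scale by
  orders of magnitude. Ties resolve to the lower class index.
* **Decision tree**: scikit-learn's CART with gini impurity, unlimited
  depth, fixed `random_state` for determinism. Inputs are standardized:
  trees are scale-free in exact arithmetic, and standardization restores
  that invariance where absolute split-threshold constants in the backend
  would otherwise treat very small-scale features as constant. Impurity
  ties resolve by the backend's seeded order rather than by the
  lowest-feature-index rule; determinism is what matters downstream.
* **SVM**: scikit-learn's SVC, linear kernel and C = 1 by default
  (conservative, reproducible; RBF available by config), one-vs-one
  multiclass, wrapped in a standardizer because margin penalties are not
  scale-invariant.

Hyperparameter defaults beyond K = 3 are package choices, selected for
determinism and plain behaviour rather than tuned performance.

## Stacking

A stack is 2 or 3 distinct base families plus a meta family that is neither
among the bases nor NB. Meta-features are the bases' *out-of-fold* predicted
class labels: stratified k-fold inside the training set, each base trained
on k−1 folds predicts the held-out fold, so every training sample
contributes exactly one row produced by models that never saw it. The meta
classifier trains on those label columns; label encoding is the default
(one-hot and per-class probabilities would also be possible, but the
zero-variance NB failure that motivates the meta exclusion is exact only
for labels). At prediction time the bases are refitted on the full training
set (standard stacked-generalization practice; serving the fold models and
majority-voting them was evaluated and performed indistinguishably). The
inner fold count defaults to the surrounding evaluation's k (5 standalone);
the inner fold seed derives deterministically from (outer seed, repeat,
fold).

For the default pool {KNN, tree, SVM, NB} the enumeration yields 9 two-base
and 3 three-base combinations in a fixed published order (`stacking1` …
`stacking12`); arbitrary pools are enumerated lexicographically.

## Evaluation harness

`repeated_cv` runs repeated stratified k-fold cross-validation. Within a
fold, the preprocessing chain, the extractor and all classifiers are fitted
on the training rows only. A repeat's accuracy is the unweighted mean of
its fold accuracies (folds are near-equal under stratification); the grand
mean and the across-repeat standard deviation are reported in percent,
rounded only at the reporting layer. Fold assignments derive
deterministically from (seed, k, repeat), so every model evaluated at the
same (k, repeat) sees identical partitions and comparisons are paired; a
per-repeat fold digest is stored so pairing can be asserted. The full grid
(4 singles + 12 stacks) × (PCA, PCA+LDA, OLDA) × k ∈ {2, 5, 8} at 10
repeats on the default 400 × 228 synthetic dataset runs in roughly a minute
on one CPU; base-classifier out-of-fold columns are computed once per fold
and shared by all stacking configurations, which is bit-identical to
fitting each stack independently because inner fold assignments depend only
on the labels, the inner k and the derived seed.

## Synthetic data generator

No real wolfberry spectra are deposited, so the generator supplies data
with the statistical structure the pipeline assumes. Per sample i of
class c:

```
A_i(λ) = m_i · [ base(λ) + Σ_comp conc_i,comp · g_comp(λ) + r_i(λ) ]
         + o_i + s_i · t(λ) + ε_i(λ)
```

* `g_comp`: Gaussian bands for six components, centred inside their
  published absorption ranges — protein 1010/25 nm, polysaccharide
  1200/40, flavonoid 1200/18, phenol 1425/20, moisture 1445/35, carotenoid
  1660/12 (centre/sd); widths are generator defaults.
* `conc`: truncated-normal draws (at 0) from the class profile, optionally
  with within-class correlations (a general covariance per class is
  supported). Moisture dominates every profile, so each class-mean
  spectrum peaks between 1400 and 1500 nm. Class contrasts ride on the
  minor components: the "ZY"-like class is phenol-rich, "DH"-like
  carotenoid-rich, "WW"-like depleted, and "BY"/"YM" are deliberate
  near-duplicates separated only by a modest flavonoid/phenol offset.
  Within-class relative sds: moisture 0.10, polysaccharide 0.08, protein
  0.05, minor discriminative components 0.02 — the dominant variance is
  deliberately non-discriminative, as in real dried-fruit spectra where
  drying state swamps cultivar chemistry.
* scatter: multiplicative `m_i ~ N(1, 0.08)`, offset `o_i ~ N(0, 0.02)`,
  baseline tilt `s_i ~ N(0, 0.01)` with `t` the normalized wavelength —
  exactly the distortion family MSC/SNV exist to remove.
  `strong_scatter_config()` is the scatter stress condition (0.25 / 0.15 /
  0.08) used to demonstrate how much correction recovers; beyond
  multiplicative sd ≈ 0.3 MSC itself destabilizes (near-zero slopes), so
  the stress stays at 0.25.
* `r_i`: a smooth structured residual field — sample-to-sample texture and
  matrix chemistry that no finite component list captures — built on the
  first K = n_channels/3 cosine modes (one mode per ~10 nm resolution
  element) with 1/k power decay, pointwise sd 0.012 (about three times the
  high-band noise level). Its mode weights are normalized analytically so
  the pointwise sd is exact.
* `ε_i`: heteroscedastic instrument noise, sd 0.004 below 1440 nm and 3×
  above, projected onto the same K smooth modes (an optically band-limited
  instrument cannot record spectrally white noise) and renormalized so the
  channel-wise sd stays at the nominal level.

Seeding is hierarchical: one global seed spawns a child seed per sample, so
any subset of samples is reproducible independently of generation order.

What the generator reproduces, and what it does not: it matches the
qualitative facts reported for the real data — the 1440 nm moisture peak,
higher noise above 1440 nm, a confusable class pair, preprocessing rescuing
scatter-corrupted spectra, and supervised whitening (OLDA) outperforming
variance-ranked projections because discriminant information sits in
low-variance directions. It does not reproduce instrument drift,
temperature effects, Beer–Lambert nonlinearity, or the error structure of
any particular spectrometer, and absolute accuracies on it are not
comparable to accuracies on real wolfberry spectra — only orderings and
mechanisms are. One published pattern the synthetic conditions do *not*
replicate is the strongest stacking combination exceeding every single
classifier under leakage-safe per-fold extraction: with all bases reading
the same four extracted coordinates their errors are strongly correlated,
and a label-encoded meta-learner lands within about two points of its best
base rather than above the best single cell. The gap traces to the
protocol: the extractor is fitted on the whole fold-training set, so
out-of-fold meta-features are optimistic relative to test-time base
behaviour, and the meta-classifier's trust calibration inherits that bias.
Whole-dataset ("global") extraction — common in the applied literature and
available in this package behind an explicit flag — removes the gap by
making the problem near-separable for bases and meta alike.

## Numerical choices

* Rank decisions in OLDA use a relative singular-value cutoff of 1e−10;
  the Ω spectrum additionally carries an absolute 1e−8 floor (its entries
  are bounded by 1).
* Explained-variance ties in PCA keep the stable SVD order.
* MSC rejects |slope| < 1e−12; SNV rejects zero-variance spectra; both
  errors name the offending sample.
* Accuracies are aggregated at full precision and rounded to two decimals
  only in reports.
* Seeds below 2³¹ everywhere; child seeds derive via `SeedSequence`.

## Limitations

* The CSV reader expects dense numeric grids; missing values are rejected
  rather than imputed, and instrument binary formats (JCAMP-DX, SPC) are
  out of scope.
* LDA-family extractors cap at C−1 directions; with 5 classes every
  classifier downstream works in 4 dimensions.
* The harness assumes balanced-ish classes (stratified folds require the
  smallest class to hold at least k samples).
* Statistical significance testing between pipeline variants is not
  implemented; the harness reports means, spreads and confusion matrices.
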