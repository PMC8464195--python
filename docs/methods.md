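# Methods

`honeychem` implements a chemometric screening pipeline for sugar-syrup
adulteration of honey based on high-performance thin-layer chromatography
(HPTLC) profiles. A sample is described by (i) four quantified sugars
(fructose, glucose, maltose, sucrose) and (ii) organic-extract band profiles
— peak-height intensities (AU, normalised to [0, 1]) at retardation-factor
(Rf) positions — recorded under four imaging conditions: 254 nm and 366 nm
before derivatisation (`R254`, `R366`) and transmittance white light / 366 nm
after derivatisation (`TW_D`, `R366_D`).

## Study design and the synthetic generator

The design is the 68-sample adulteration panel: two honeys (Manuka `MAN`,
Jarrah `JAR`), six syrups (rice `RIC`, corn `COR`, golden `GOL`, treacle
`TRE`, glucose `GLU`, maple `MAP`), and all 60 blends of one honey with one
syrup at 10, 20, 30, 40 and 50 % (w/w).

The generator's product templates encode the compositional contrasts that
drive every downstream analysis:

* **Honeys** are fructose/glucose dominated (MAN ≈ 950/800, JAR ≈ 1150/550
  on the study's 0–2,000 quantification scale) with trace maltose and no
  quantifiable sucrose. The two honeys differ in their fructose/glucose
  ratio — Jarrah is the textbook high-fructose, slow-crystallising honey —
  and carry rich, mutually disjoint organic fingerprints (11 bands each
  across the four channels, AU 0.28–0.90).
* **Starch syrups** (`RIC`, `COR`, `GLU`) are maltose-rich with mutually
  similar sugar spectra (all are glucose/maltose hydrolysates), which makes
  them hard to tell apart from sugar data alone, especially at low blend
  levels.
* **Cane/maple syrups** (`GOL`, `TRE`, `MAP`) are sucrose-rich. Maple syrup
  additionally carries its signifying marker band at Rf 0.41 in the
  derivatised 366 nm channel.
* **Syrup organic extracts** have no major bands; each syrup carries two
  minor bands (AU ≈ 0.3, mostly in the derivatised white-light channel).
  This choice reconciles two observations about such studies: extract
  fingerprints of syrups look empty next to honey fingerprints, yet
  organic-profile classifiers resolve *which* syrup adulterates a blend far
  better than chance — which is only possible if the extracts contribute
  some distinctive, if faint, signal.

Blending is linear in mass fraction for sugars and band intensities (union
of band positions), so adulteration dilutes honey bands by (1 − fraction)
while maltose or sucrose rises proportionally. Measurement noise is
multiplicative truncated-Gaussian, CV 5 % per sugar and per band by default
(`noise_scale` rescales all CVs; 0 gives the exact mixing rule). A sugar
with mean zero therefore stays exactly zero — honeys never show spurious
sucrose, mirroring "below limit of quantification" data. Band *positions*
are never jittered by the generator; run-to-run Rf drift belongs to the
augmentation model, which keeps generator output grid-alignable and makes
augmentation effects attributable.

## Feature matrix

Only bands inside the analytical window Rf 0.05–0.60 are modelled; the
window is closed at both ends so boundary bands are kept. Band intensities
are resampled onto a fixed per-channel Rf grid (nearest grid point,
colliding bands keep the maximum AU), and the four sugar columns are
appended. The default grid step is 0.005 (111 points per channel, 448
columns) — a desk-scale default; the step is a configurable knob, and the
classifier evaluation uses 0.002 (276 points per channel, 1,108 columns) to
work at the ~1,250-feature scale such studies typically deposit.
Standardisation is per-column min–max scaling to [0, 1] (constant columns
map to 0), with scaling parameters retained for exact inversion. A single
[0, 1] range is used for everything because the band intensities already
live there and the neural classifier expects inputs on that scale.

## Augmentation model

Each augmented copy of a sample perturbs

1. every band's Rf by a uniform draw in ±0.0173 (the drift figure names a
   bound, and uniform is the maximum-entropy choice given a bound;
   configurable), applied at band level and then re-gridded — matching the
   physics of between-run drift rather than shifting whole grid columns;
2. every band's AU by Gaussian noise with SD = 1.25 × that channel's SD,
   where the channel SD is computed over **all** of the channel's matrix
   cells across all samples (the only SD the protocol describes
   computing). Noise applies to band values — the AU values that exist —
   not to empty grid cells, which represent "no band detected";
3. every sugar by Gaussian noise with SD = 5 % of its value.

All perturbed values are truncated at zero (not resampled, preserving the
independence of draws). With the default replication counts — 50 outer ×
21 inner, originals kept — a 68-row matrix becomes 50·21·68 + 68 = 71,468
rows. The inner factor 21 is exposed as `inner_repeats` without further
interpretation; only the product of the two counts is meaningful here.
Augmentation is performed on the raw matrix and the result re-standardised
(noise moves values off the [0, 1] span); both orders are supported.

## Unsupervised suite

* **Hierarchical clustering**: Euclidean distance, average linkage by
  default (scipy's UPGMA agglomeration); the full merge tree is reported
  and can be cut at a height or a cluster count. Tests verify the tree
  against a brute-force implementation that recomputes all mean pairwise
  inter-cluster distances at every step.
* **k-means**: k-means++ seeding, 25 restarts by default (a single solution
  is reported, so restarts stabilise it); quality is summarised as
  between_SS/total_SS = 1 − within_SS/total_SS about the grand centroid.
  The elbow selects k by maximum perpendicular distance between the
  within-SS curve and the chord joining its endpoints, ties toward the
  smallest k (a perfectly linear curve yields k = 1).
* **DBSCAN**: non-core, non-reachable points are labelled noise (id −1).
  Rows are canonically lexsorted before clustering so the border-point
  assignment does not depend on input row order. When no `eps` is given
  the pipeline uses the median distance to the `minPts`-th nearest
  neighbour — a standard k-distance heuristic; the appropriate `eps` is
  scale-dependent, so published values for one feature space do not
  transfer to another.
* **PCA**: full-SVD decomposition of the column-centred matrix;
  per-component explained-variance fractions are validated against an
  independent covariance eigendecomposition.

## PCR / PLS regression

Each sugar is predicted from all other columns (its own column excluded;
the other three sugars included by default, with a flag to exclude). The
component count is the argmin of RMSECV — out-of-fold squared residuals
pooled over 10 shuffled folds, fitted on k−1 folds each time — with ties
broken toward fewer components for parsimony (too many latent components
destabilises the model). Hold-out evaluation uses a 70/30 split (stratified
when class sizes allow; the 68-sample design has singleton classes, so it
falls back to a plain shuffle), with all centring learned on the training
partition only — a dedicated test asserts the fitted centring equals the
train-partition mean. Because it is genuinely ambiguous whether published
RMSE/R² tables refer to training or test partitions, reports carry both:
`rmse`/`r2_train` (training) and `rmsep`/`r2` (test). PLS is the
single-response NIPALS iteration with deflation (scikit-learn's
implementation); PCR regresses the response on leading principal-component
scores.

## Neural classifier

A fully-connected network maps a feature row to a distribution over the 68
sample classes: two rectifier hidden layers (128, 64 by default), inverted
dropout 0.2, softmax output, cross-entropy loss (optional label
smoothing), Adam updates with cosine learning-rate annealing from 2·10⁻³,
mini-batches of 256. A held-back slice (10 %) of each training fold drives
early stopping; the best-validation-loss weights are restored. Training is
deterministic under a seed, and constant input columns (never-occupied
grid positions) are dropped at fit time as a pure speed optimisation.

Because the augmentation drifts every band by up to ±0.0173 Rf, a band's
intensity wanders across neighbouring grid columns between copies of the
same class — a sparse position-coding that a plain dense network learns
slowly and imperfectly. The classifier therefore offers a fixed (unlearned)
max-pooling input stage: each channel's grid columns are reduced to the
maximum over consecutive windows of `organic_pool_cells` cells (sugar
columns pass through), making the representation largely drift-invariant
before the first weight layer, exactly as pooling front-ends are used on
spectra elsewhere. The stage is off by default; evaluation runs use a
5-cell window (0.010 Rf, about half the drift bound) on the 0.002 grid,
which in our benchmarks lifts the combined-feature accuracy by about one
percentage point toward its analytical ceiling and roughly halves training
time.

Evaluation is stratified k-fold (6 folds) over the augmented matrix,
separately for three feature sets — the 4 sugar columns, all organic grid
columns, and both combined — reporting per-fold held-out accuracy, the
fold mean, and a pooled confusion matrix. Because augmentation gives every
class identical multiplicity, no class weighting is needed. Note that
augmented copies of the same source sample occur on both sides of each
fold split; the evaluation characterises recognition of the 68 products
under simulated run-to-run variability, not generalisation to new hives or
brands.

### Problem sizes used in tests and the acceptance script

The full 71,468-row augmentation is exercised for its arithmetic (it runs
in a few seconds); model evaluation uses a reduced replication
(`outer_repeats=10`, 14,348 rows) at the 0.002 grid step, with 100-epoch
training — sizes chosen so a complete three-seed evaluation is a desk-scale
run. Property tests use small fixtures (6–12 points) where brute-force
enumeration is exact.

## Known limitations

* Synthetic templates are stand-ins: no absolute sugar or band values for
  the real products are published, so the generator reproduces the
  *qualitative* contrasts (which sugar dominates where, who carries which
  bands) on the stated 0–2,000 dynamic range, not any product's true
  composition. Clustering ratios, explained-variance percentages and R²
  values computed on synthetic data are therefore structural analogues,
  not reproductions of any particular dataset's numbers.
* The generator draws independent noise per cell; real densitometry has
  correlated baseline drift, band-shape changes and detector saturation,
  none of which are modelled. Passing tests show the pipeline's numerics
  and protocol are correct, not that real plates will achieve the same
  accuracies.
* The augmentation noise model is exactly the drift + calibrated-Gaussian
  scheme described above; it does not learn variability from replicate
  plates.
* DBSCAN `eps` has no dimensionless default; the k-distance heuristic is a
  starting point, not an optimised setting.
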