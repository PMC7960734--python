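# Methods

This note documents the models, estimators, defaults and design choices in
`remitpredict`, and what the synthetic benchmarks do and do not show about
real data.

## The prediction problem

Subjects meet DSM-5 AUD criteria at a first visit; years later they are
either *continued* (still meet criteria) or *remitted* (no criteria except
craving for ≥ 12 months). The task is to predict the visit-2 label from
visit-1 features only. Groups are balanced by construction and analyzed
within sex × ancestry strata after 1:1 age matching, so the chance level is
50 % and age/sex/ancestry cannot act as shortcuts.

## EEG coherence features

**Estimator.** Magnitude-squared coherence from Welch cross-spectra: the
signal is cut into `segment_length` (default 2 s) windows with `overlap`
(default 50 %), each segment is mean-detrended and Hann-windowed, and the
segment FFTs of all ROIs are combined into per-frequency cross-spectral
matrices in one pass (equivalent to `scipy.signal.coherence` per pair, which
the tests verify to machine precision, but without recomputing FFTs for each
of the C(68,2) pairs). A band feature is the arithmetic mean of per-bin MSC
over the in-band bins of the half-open band [low, high); the alternative —
coherence of band-summed spectra — was rejected because it weights bins by
power and is less robust to bin counts.

**Bands.** theta 4–8, alpha 8–12, beta 12–30, gamma 30–60 Hz (half-open,
disjoint; gamma capped below 60 Hz exclusive). 68 ROIs × 4 bands give
4·C(68,2) = 9112 features named `ROIa-ROIb@band` in band-major,
upper-triangle order.

**Known estimator properties.** For independent signals the Welch MSC has a
positive small-sample bias ≈ 1/K_eff (K_eff = effective number of
overlapping segments): ≈ 0.006 at 240 s / 2 s segments. The tests check that
this bias floor shrinks monotonically with segment count.

**Source space is an input, not a computation.** The module starts from ROI
time series; no inverse modelling is performed (an optional EDF reader
ingests raw multichannel recordings but does not localize them).

## Synthetic signal construction

For a pair with target band MSC γ², three independent unit-variance
band-limited noises s, e₁, e₂ with identical (brick-wall) in-band spectra
are mixed as

    x = a·s + √(1−a²)·e₁ ,  y = a·s + √(1−a²)·e₂ .

At every in-band frequency S_xy = a²P and S_xx = S_yy = P, so MSC = a⁴, and
the mixing weight realizing the target is a = γ²^¼ (derivation repeated in
the code). Unplanted pairs get independent noise in every band. Each ROI's
full signal is the sum of one such component per band.

**Interaction to be aware of:** Welch windowing leaks a band's power ~1 bin
past its edge. A band with a high-power lower neighbor (alpha, below which
theta has 4.5× beta's per-Hz power) inherits one contaminated first bin,
which depresses estimates most visibly at extreme targets (unit-target alpha
estimates ≈ 0.89 rather than 1.0; theta and gamma are ≈ 0.99/0.98).
Closed-form benchmark checks therefore use theta, whose band start (4 Hz)
has no simulated neighbor below it. This is a property of the
estimator/synthesis pair at brick-wall band edges, not an error in either.

## Synthetic genetics

Dosages are built from two thresholded latent-Gaussian haplotypes per
subject. Within an LD block all SNPs share one allele frequency (drawn
uniformly from [0.1, 0.5] per block) and an equicorrelated latent structure;
the latent correlation is solved numerically (bivariate normal CDF +
Brent's method) so that the *dosage* r² matches the requested `block_r2`.
Blocks span < 500 kb and sit 1 Mb apart on one chromosome, so cross-block
pairs fall outside the clumping window and are uncorrelated. `block_r2 = 1`
requires equal allele frequencies within the block and is rejected
otherwise. This targets controllable clumping behaviour, not
population-genetic realism: no recombination maps, no family structure
(deliberately, although the motivating cohort is family-based), no
mutation/drift model.

Causal SNPs shift the log-odds of remission per dosage unit. Because
generation is label-first, label-conditional genotypes are drawn by
rejection sampling against the logistic model P(label | dosages), which
preserves the LD process exactly (conditioning SNP-by-SNP would break it).
Summary statistics give causal SNPs their stated effect sign and a small
p-value (log-uniform 1e-10..1e-6); null SNPs get N(0, 0.05) betas and
uniform p.

## Demographics

Each binary covariate (married, employed, eight medication indicators) has a
base rate in the continued group (married 0.45, employed 0.60, medications
0.10) and an odds ratio applied to the remitted group. Ages are drawn for
both groups from one normal distribution (mean 30.7, sd 9.4 years) truncated
at 18 — matching the study population's reported age summary; note the
truncation raises the realized mean to ≈ 32.4. Sex and self-reported
ancestry are drawn independently of the label (p_male = p_EA = 0.6).

## PRS

* Weight = sign(β)·(−log10 p). The weight magnitude follows the "negative
  log of the p value" convention; the sign of β is applied because a
  signless weight discards effect direction and makes the score's sign
  meaningless. Base 10 vs natural log only rescales columns, which
  Z-standardization removes.
* Thresholding is strict (p < t), matching the printed "p < 0.0001" style.
* Clumping removes at r² ≥ threshold (boundary inclusive), window measured
  index-to-candidate in bp on the same chromosome; ties on p break by
  (chr, pos, id) for determinism. SNPs absent from the reference panel
  cannot be clumped and are retained with a warning.
* Missing dosages are mean-imputed per SNP before scoring so score scales
  stay comparable across subjects. Genotype QC (call rate, HWE) is assumed
  done upstream.
* Any number of phenotype score families is supported by passing one
  summary-statistics table per phenotype (`prs_feature_block`); the package
  does not hard-code a phenotype count.

## Ancestry

PCA standardizes each SNP by mean 2f and sd √(2f(1−f)) (monomorphic SNPs
dropped and counted), eigendecomposes the subject covariance, and fixes
signs so each PC's largest-magnitude coordinate is positive. EA/AA
assignment is 2-means (k-means++, fixed seed) on PC1/PC2; clusters are named
by majority self-report, with proportion ties broken toward the larger
cluster. A degeneracy warning fires when the center separation is < 2× the
within-cluster RMS (a single Gaussian blob split in half sits at ≈ 1.4).
How the original analysis dichotomized PCs is not stated; clustering is this
package's choice and is recorded as such.

## Cohort assembly

Age matching is greedy nearest-neighbor 1:1 without replacement: candidate
cross-group pairs ordered by (|Δage|, id, id), pairs beyond the caliper
(default 2 years) dropped. Whether the original analysis matched pairwise or
only group-wise is unstated; greedy pairwise matching guarantees the group
means differ by at most the caliper. Missing values are handled by listwise
deletion per model feature set (no imputation of EEG/demographic features),
which reproduces the "different subject subsets per feature set" behaviour.
Z-normalization supports transform-with-given-statistics so CV folds can be
normalized without touching held-out rows.

## Classifier

* **LASSO:** squared-error loss on the ±1-coded label (the canonical
  Tibshirani formulation with the class label as response), solved by
  scikit-learn's coordinate descent. Penalty grid: 100 log-spaced values
  from λ_max = max_j |x_jᵀ(y−ȳ)|/n down to 1e-3·λ_max; chosen by 10-fold CV
  on held-out squared error, ties to the larger (sparser) λ; the 1-SE rule
  is not applied. The final fit is solved to tol 1e-8 and satisfies the KKT
  conditions to < 1e-6 (tested); the CV path search uses the standard 1e-4
  tolerance since only the loss ranking matters there. Whether the original
  LASSO was Gaussian or logistic is unstated; the Gaussian reading is
  implemented, and the nested/paper_faithful split covers the other open
  protocol question (selection inside vs before CV).
* **SVM:** hinge + L2 in the dual (liblinear), C from 10 log-spaced values
  in [1e-3, 1e3] by inner 5-fold stratified CV on accuracy, ties to the
  smaller C; refit on all rows at the chosen C. liblinear augments the
  intercept as a penalized feature; the local-optimality test uses that
  exact objective.
* **Folds:** stratified (class proportions preserved) even though groups
  are balanced — it guards small strata and changes nothing otherwise.
  Every ModelResult records all seeds for exact replay; result JSONs carry
  no timestamps so reruns are byte-identical.
* **Metrics:** positive class = remitted. A rate whose denominator is empty
  is reported as missing (None / rendered "—"), never as 0. AUC uses
  midranks (ties get half credit) on continuous decision scores.
* **Model comparison** is a paired two-sided t test on per-repeat mean
  accuracies. Repeat-level pairing reuses the same subjects, so the test is
  anti-conservative; the result carries that caveat explicitly. (The
  original comparison procedure is not publicly described; this is a
  declared stand-in.)
* An empty LASSO selection is signalled distinctly; the CV driver falls
  back to the full feature set with a warning rather than failing, which on
  null data keeps both modes runnable.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: coherence oracle at 50 subjects × 240 s × 256 Hz per target;
clumping replay on 1000 random ≤ 12-SNP instances; KKT checks on 100 random
200×200 designs; null-cohort CV at n = 200 (full multimodal table, 8 ROIs,
60 s signals); planted-feature recovery at n = 400 with 5008 features
(8 planted at standardized difference 0.8); leakage demonstration at
n = 100 with 5000 noise features. The heavy nested-CV runs use reduced
search settings (3-fold/30-alpha LASSO path, 7-point C grid) — these are
exposed parameters of `fit_lasso_cv`/`train_svm`; library defaults remain
10 folds / 100 alphas / 10-point grid as stated above.

## What the synthetic benchmarks do and do not show

They validate the *machinery*: estimator correctness against closed forms,
procedure agreement with brute-force replays, honest null behaviour,
recovery of planted effects, and the quantitative cost of selection leakage.
They do not validate *biology*: the generator has no volume conduction,
artifacts, 1/f background or non-stationarity in its signals, no family
structure or realistic LD decay in its genotypes, and effect sizes are
chosen for testability (the study effect sizes are unknown). Accuracy
achieved on synthetic cohorts therefore says nothing about achievable
accuracy on real cohorts; chance-level results on permuted labels and the
leakage margin, by contrast, are properties of the protocol itself and do
transfer.

## Known limitations

* `paper_faithful` mode is intentionally optimistically biased; it exists
  for protocol fidelity and comparison, not for reporting generalization.
* The repeat-level model comparison inflates significance; treat its
  p-values as descriptive.
* Band-edge leakage couples adjacent synthetic bands slightly (see above).
* VCF output round-trips integer dosages only; fractional dosages travel
  via the TSV format.
* k = 2 ancestry clustering only; more populations need a different
  assignment step.
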