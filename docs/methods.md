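# Methods

This note records the models, parameter choices, numerical conventions
and known limitations of the package. It documents *how* the pipeline
computes what it computes; all empirical numbers referenced here are
produced by the test suite or `scripts/acceptance.py`.

## Synthetic cohort generator

The generator exists so that every downstream stage can be tested
against known ground truth. It emulates the statistical structure the
analysis assumes, not the full physiology of the heart.

**Waveforms.** Each 8-lead median beat (leads I, II, V1–V6; 400 Hz;
1.2 s window centred on the R fiducial) is a per-lead sum of four
Gaussian lobes on fixed slots in normalized QRS time u = t/QRSd, slots at
u = ±0.35 and ±0.12 with width σ_u = 0.11, plus a lower-amplitude
discordant T wave (0.22 mV, sign opposite the terminal QRS deflection)
and a small P wave (0.08 mV). Slot amplitudes are class templates:

* *LBBB-like* — QS complexes in V1–V2, broad notched R in I/V5/V6
  (notch deepens with severity);
* *RBBB-like* — rsR′ in V1, broad slurred S in I/V6;
* *NSIVCD-like* — broad fractionated mid-amplitude complexes.

A small per-lead timing stagger (±0.02·QRSd) emulates the activation
wavefront crossing the leads and prevents synchronized zero-crossings.
The slot geometry was chosen so the 10%-of-peak crossing of the smoothed
multi-lead energy envelope lands at the nominal QRS duration: measured
width equals the requested duration to within ±10 ms over the
122–180 ms range, monotonically. Rhythm strips repeat the beat at the
requested heart rate with multiplicative RR jitter (2% default) and
additive white noise (0.02 mV default).

**Severity.** A single continuous latent, `severity` ∈ [0, 1] (uniform),
is the ground-truth risk axis: it deepens notching/fractionation,
lengthens the QRS (122 + 50·severity ms ± 4 ms noise, clipped at
121–180), raises QTc, and drives all outcome models. Downstream
acceptance checks ask the pipeline to rediscover this axis.

**Outcomes.** Nonfatal event times are exponential with hazard
h_e·exp(β·severity) (defaults h_e = 1/3000 per day, β = 0.7); death is
an independent exponential competing event (1/4000 per day); censoring
is independent exponential (1/1400 per day — roughly the 1400-day median
follow-up typical of such secondary-care cohorts) capped administratively
at 2000 days. These closed forms give analytic targets for the
event-fraction and parameter-recovery tests. Prevalent disease is
logistic in severity (intercept −1.5, slope 1.5). A CRT subset (40% of
eligible LBBB records by default) carries pre/post echo pairs whose
responder status is logistic in standardized severity (intercept 0.2,
slope −0.7) — severity standing in for tree dimension 1 — and the echo
pairs are constructed to be exactly consistent with the drawn responder
status across all three endpoints. 15% of records are made ineligible
(narrow QRS or a pacing/CIED/CHB flag) so the selection gate is
exercised.

**What the generator does not emulate** (hence what passing tests do not
show about real data): genuine 12-lead physiology and axis behaviour,
arrhythmia and ectopy, baseline wander and electrode artifacts,
non-proportional hazards, informative censoring, and — importantly —
intrinsic dimensionality: the Gaussian-lobe beats have roughly six
degrees of freedom, so even very small latent spaces reconstruct them
almost perfectly (a 2-dim VAE reaches r ≈ 0.97). Tests that would
discriminate latent-capacity effects on real ECGs are therefore not
meaningful here and are not asserted.

## Preprocessing

Zero-phase (forward–backward) third-order Butterworth bandpass
0.5–100 Hz plus an IIR notch (Q = 30) at 60 Hz; polyphase resampling to
400 Hz. Zero-phase filtering is used so the R fiducial does not shift.
R peaks are detected on lead II from a 50 ms smoothed energy envelope
with a 300 ms refractory distance and a two-stage height gate (discard
peaks below 5% of the largest, then below 25% of the median of the
survivors) — the two stages make detection robust to both small noise
bumps and a single high-amplitude artifact. The median-beat window is
1.2 s centred on the fiducial (configurable); records with fewer than 3
complete beats are flagged and excluded with a logged count.

QRS duration is measured as the width of the contiguous run, containing
the maximum, where the 20 ms-smoothed multi-lead *energy* envelope
(mean of squared leads) exceeds 10% of its peak. Squaring keeps ST/T
deflections (≤ 0.25 of QRS amplitude ⇒ ≤ 6% of peak energy) below
threshold, so the measurement does not bleed into the T wave.

Broad-QRS selection keeps records with QRS strictly > 120 ms and all of
paced/CIED/CHB flags false, and emits a per-rule exclusion table
(first-failing-rule attribution, mirroring a selection flow chart).

## Variational autoencoder

A 1-D convolutional VAE implemented directly in numpy (conv via
im2col/einsum, manual backpropagation verified against finite
differences to ~1e-10 relative error, Adam, fully seeded — training is
bitwise reproducible). Encoder: `n_blocks` blocks of stride-2 same-pad
convolution (kernel 5) + ReLU, then dense heads for the posterior mean
and log-variance (clipped to ±10); decoder mirrors it with ×2
nearest-neighbour upsampling + convolution, linear output. Defaults:
51 latent dimensions, 6 blocks, channels (16, 24, 32, 48, 64, 64),
input length 128 samples (beats are polyphase-resampled to this length;
~120k parameters at the defaults — a desk-scale architecture).

Loss = per-beat sum-of-squares reconstruction + KL against N(0, I),
KL weight 0.05 annealed linearly over the first third of the epochs
(avoids posterior collapse on small data). Inputs are standardized per
lead with training-set statistics stored in the model artifact and
re-applied at inference. `encode` returns the posterior mean, so
encoding is deterministic. Training aborts with a seeded diagnostic on a
non-finite loss.

Problem sizes: the reconstruction check trains on 1600 beats for 30
epochs and evaluates the held-out 400 (median Pearson r ≥ 0.9 required;
measured ≈ 0.99), and compares the broad-QRS subset against the full
held-out set with a Mann–Whitney test (indistinguishable, p > 0.01).

## Tree embedding

The objective and block updates are:

* **B-step:** minimum spanning tree over squared centroid distances —
  Kruskal with edges sorted by (weight, i, j), so ties break by stable
  index order;
* **R-step:** row softmax of −d²/σ (computed via logsumexp; with the
  default σ = 1e-3 assignments are effectively hard);
* **(W, Z, Y)-step:** closed-form joint solve — a K×K SPD system, a
  d×d symmetric eigendecomposition for the top-2 basis, then the
  centroid system ((λ/γ)L + Γ)Y = RᵀZ.

Each step exactly minimizes its block, so the objective (evaluated once
per iteration with R at its optimum via logsumexp) is monotone
non-increasing; the suite asserts this with 1e-9 relative slack, plus
connectivity/acyclicity of B each fit. At K = N and σ → 0 the learned
backbone provably reduces to the MST of the embedded points, and the
suite checks equality against an independent exhaustive Kruskal.

Defaults: K = 2000 centroids, λ = 5N/K, σ = 1e-3, γ = 10, max 20
iterations, relative tolerance 1e-3, centroid initialization by seeded
sampling of distinct rows, PCA initialization of (W, Z). K is clamped to
N with a warning.

**Input normalization** is a documented choice with two modes.
`per-feature` (default) z-scores each column — right for latent features
whose scales are not comparable. `global` centers columns and divides by
one pooled scale, preserving relative variances — right when features
are already commensurate, because z-scoring commensurate features
inflates low-variance noise directions: on a 3-armed star benchmark
(600 points in 10-D, noise SD 0.05) z-scoring inflates the seven
pure-noise coordinates twenty-fold and caps every centroid-based
partition at ARI ≈ 0.72 regardless of the clustering method, while the
scale-preserving mode recovers the arms at median ARI ≈ 0.82.

**Branches and phenogroups.** Branch points are nodes of degree ≥ 3;
sub-branches are maximal paths between branch points/leaves (an exact
edge partition; branch-point nodes take the lowest-indexed incident
branch for determinism); samples inherit the sub-branch of their
argmax-assignment centroid. Merging to phenogroups (default 6) is Ward
agglomerative clustering of sub-branch mean embedding coordinates,
constrained by sub-branch adjacency so merged groups stay contiguous on
the tree whenever adjacency permits. The tree center is the centroid
nearest the grand mean of the embedding (configurable); global
pseudotime is geodesic distance along the tree (Euclidean edge lengths)
from the center to the sample's centroid plus the sample's offset;
branch pseudotime starts from the branch's node nearest the center.

**Stability** refits the tree on bootstrap resamples and reports the
median and IQR of the ARI between reference and resample phenogroups on
the samples present in both. The bootstrap ARI is data-dependent; on the
well-separated star it is ≈ 0.83 (10 resamples).

## External projection

Two independent XGBoost regressors (300 trees, depth 5, learning rate
0.1, seeded) map the 51 features to each tree coordinate, trained on a
75:25 split of the reference cohort with validation R²/MAE recorded.
Raw predictions are snapped to the nearest point on any tree edge —
orthogonal projection onto each segment clamped to its endpoints,
minimized over edges; the suite verifies exact agreement with a
brute-force oracle. This nearest-point-on-tree snap is our reading of a
"distance-estimating" mapping onto a learned trajectory; the procedure
it paraphrases is not published in enough detail to reproduce verbatim,
so the snap contract is documented here as an interpretation.
Phenogroups come from a k-NN vote among reference samples in coordinate
space (k by stratified 10-fold CV over 1–200 on macro F1, grid truncated
with a warning when folds cannot support it; ties break by smallest mean
distance to the tied class). Projection never refits or reclusters the
tree, and the pipeline asserts the tree artifact hash is unchanged after
external cohorts are processed.

## Outcome models

Design matrices are patsy-built; categorical covariates are dummy-coded,
phenogroup against a configurable reference group (default group 4, the
central/average group in the published taxonomy this mirrors).
Singular designs and separation raise explicit errors — never silent
coefficients. Complete-case analysis per model with dropped-row counts
recorded. Logistic/linear fits via statsmodels; Cox via lifelines with
Newton precision 1e-10.

**Fine–Gray.** Subjects with the competing event are kept in the
subdistribution risk set after their event time with weight G(t)/G(T_i),
G the Kaplan–Meier survivor of the censoring distribution, piecewise
constant between subsequent event times (the standard `finegray`-style
counting-process expansion); the expanded, weighted data are fit by
weighted Cox partial likelihood. With no competing events the expansion
is the identity, and the suite asserts agreement with the plain Cox fit
to 1e-6 (measured ≈ 1e-7 or exact). The proportional-hazards assumption
is deliberately not tested; hazard ratios are read as averages over
follow-up.

**Risk surfaces** fit Cox (fatal) or Fine–Gray (nonfatal) on
(dim1, dim2, pseudotime) and return each sample's cumulative incidence
at a horizon (default: median follow-up), via the Breslow baseline:
CIF(t) = 1 − exp(−H₀(t)·exp(lp)). Probabilities are bounded and monotone
in the horizon by construction. Recovery of the generator's severity
axis through the full waveform → VAE → tree → risk-surface chain is
checked on a single-class cohort, where the embedding's leading axes
align with severity (on a mixed cohort the two embedding dimensions are
spent separating the three morphology classes and severity is nearly
orthogonal to them — the recovery question is only well-posed where its
premise, "severity correlates with dimension 1", holds). With 1500
records (~480 events) the measured Spearman correlation between
predicted risk and severity is 0.8–0.9 across seeds.

**Moran's I** uses row-standardized k-NN weights (k = 8 by default) on
the embedding coordinates; with row-standardized weights the statistic
reduces to Σᵢ zᵢ·mean(z_neighbours)/Σ z², the analytic null mean is
−1/(N−1), and significance comes from a two-sided permutation test.

**Explainability** runs one-vs-rest elastic-net logistic regressions of
the standardized latent features on each phenogroup (saga solver,
penalty strength and L1 mixing by 5-fold CV), reporting the top 3
features by |coefficient|.

**Prognostic comparison** fits both Cox models once on identical rows
and bootstraps Harrell's C-index by resampling rows with fixed
coefficients (mean ± SD per model; the bootstrap quantifies sampling
uncertainty of the concordance, not refitting variability). Goodness of
fit is compared with a Vuong-type z on per-event-subject Breslow
log-partial-likelihood contributions — a named construction suitable for
non-nested models, used because the exact variant of the published
"partial likelihood ratio test" for non-nested Cox models is not
specified anywhere we could follow.

**Multiple testing**: Benjamini–Hochberg q-values, pooled across the
supplied result tables.

## CRT analysis

Endpoints are pure functions of the echo pair: LVEF responder =
post − pre ≥ 10 percentage points (absolute; we use ≥, the boundary
convention being unstated in the source literature); LVESD/LVESV
responder = relative decrease ≥ 15%. A missing pre or post value leaves
the endpoint undefined (excluded from models, never "no response"); a
zero pre-value for a relative endpoint is an error. Echo-to-ECG linkage
takes the nearest echo within ±60 days, ties to the earlier echo; one
echo may serve several ECGs. Response models are logistic in the tree
variables, adjusted for age, sex and QRS duration, restricted to
LBBB-labelled records by default.

## Pipeline

One YAML config drives generate → preprocess → VAE → tree → projection →
outcomes → CRT; every stochastic stage has an explicit seed, and the
manifest records the config, per-stage row counts, artifact hashes and
timings. External cohorts are only projected, never refit (enforced by
hash comparison). When phenogroups align with morphology classes on
small cohorts the fully adjusted design can be collinear; the pipeline
then falls back to the morphology-omitting covariate set (the standard
sensitivity analysis for this situation) and records which set was used.
Artifacts are plain text: waveform CSVs, delimited tables, JSON
manifests, and a documented tree directory (edge list, centroid and
sample tables, basis, hyperparameters, objective trace).

Smoke scale for tests: 600-record derivation cohort, K = 60 centroids,
a 4-block VAE — the full pipeline runs in well under a minute on one
CPU; the acceptance script's larger computations (2000-beat VAE,
20×5000 Cox recovery, 1500-record risk surface) finish in a few minutes.

## Known limitations

* The synthetic beats are far more compressible than real ECGs; VAE
  capacity comparisons are not meaningful on them (see above).
* The bootstrap-stability ARI and the phenogroup count are
  data-dependent; the published values for the clinical cohorts are not
  reproducible from synthetic data and are not targeted.
* The Fine–Gray implementation assumes censoring independent of
  covariates (Kaplan–Meier censoring weights, not covariate-adjusted).
* Trees are fit in 2 embedding dimensions; higher dimensions are
  configurable but untested.
* The exact merging procedure, VAE architecture details and k-NN
  protocol of the study this mirrors are not public; the defaults here
  are documented independent choices.
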