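# Methods

`hyperbrain` embeds functional brain networks in hyperbolic space and
reads hierarchical organization off the embedding geometry. This note
records the model, the numerical choices, and what the synthetic
generators do and do not emulate.

## Connectivity: phase locking value

Band-limited ROI time series are turned into connectivity by the phase
locking value (PLV). Per epoch, each signal is band-passed with a
zero-phase 4th-order Butterworth filter (default 8–12 Hz) and its
instantaneous phase taken as the analytic-signal angle. For a source
pair, the per-epoch PLV is the modulus of the time-averaged unit phasor
of the phase difference,

    PLV = | (1/T) Σ_t exp(-j (φ_A(t) − φ_B(t))) |,

with the modulus applied **per source pair per epoch** and then averaged
across epochs and across all source pairs belonging to the two ROIs.
Averaging moduli across epochs (rather than concatenating epochs) is
standard practice and reduces bias from non-stationarity. The first and
last 5% of samples of every epoch are excluded from the average to
suppress filter edge transients.

Thresholding uses a strictly-greater comparison (ties at the threshold
excluded); the default threshold 0.329 retains roughly 20% of edges on
PLV matrices in the typical resting-state range. Continuous
edge-probability targets are the min–max scaled off-diagonal PLV values,
scaled per matrix so every graph's targets span [0, 1]; the unit
self-PLV diagonal is excluded from scaling and never becomes an edge.

Estimator caveat: PLV is positively biased at small effective sample
counts. After band-passing to a 4 Hz band the number of independent
samples per epoch is roughly bandwidth × epoch length, so the null level
for 4 s epochs is ≈ 0.2 and drops with longer epochs. Tests that probe
the null use long epochs for that reason.

## Poincaré-ball geometry

All hyperbolic operations live in the Poincaré ball of curvature
K < 0, parameterized by c = |K|; the ball radius is 1/√c and the
distance from the origin (the **hyperbolic radius**, the package's
hierarchy metric) is (2/√c)·artanh(√c‖x‖). Distances follow the
standard conformal convention whose c → 0 limit is **twice** the
Euclidean distance. Exp/log maps at the origin and at arbitrary base
points, Möbius addition, and the Möbius matrix–vector product
exp₀(W·log₀(x)) follow the usual gyrovector formulas.

Numerics: points are kept strictly inside the ball by rescaling any
vector with √c‖x‖ ≥ 1 − ε (ε = 1e−5); artanh arguments are clamped to
1 − 1e−10, tanh arguments to 15, and direction denominators floored at
1e−15. These guards cap the representable radius at about
2·artanh(1 − 1e−5) ≈ 24.4 / √c, far beyond anything training produces.

**Fréchet mean.** The weighted Karcher mean is computed by fixed-point
iteration on the tangent space at the current estimate,
μ ← exp_μ(τ Σᵢ wᵢ log_μ(xᵢ)), initialized at the input point with the
smallest weighted objective. The naive full step (τ = 1) can oscillate
when the points are widely spread — the gradient-Lipschitz constant of
the squared-distance objective grows with the spread in negative
curvature — so the standalone solver (tolerance 1e−6 on the tangent
step, max 200 iterations, warning plus best iterate on non-convergence)
halves the step whenever the objective would increase, and the
**in-layer aggregation** uses a fixed schedule of 8 damped steps
(τ = 0.5) so the computation stays smooth, deterministic and
autodiff-friendly. The standalone solver matches a multi-start
Nelder–Mead oracle to < 1e−6 in objective on random instances.

## The hyperbolic graph convolutional encoder

Two layers (one-hot input → hidden width 6 → output dimension D). Each
layer, acting in the ball of its input curvature:

1. feature transform  h = (W ⊗ x) ⊕ b,
2. Fréchet aggregation over the node's neighbors **including itself**,
   unweighted,
3. SELU (α ≈ 1.6733, λ ≈ 1.0507) applied through the tangent space,
   mapping from the input- to the output-curvature ball.

One-hot features are lifted into the ball by a scaled exp₀. The lift
scale is 1.0: a unit-scale lift keeps the first layer's inputs
well-conditioned through the tanh-saturating maps, and a much smaller
scale measurably underfits (several-fold higher training loss on every
fixture tried).

**Parameterization and optimization.** Weights are Euclidean; biases are
stored as tangent vectors at the origin and exp-mapped every forward
pass, so optimizer updates can never leave the ball; curvature is
learned as K = −softplus(κ_raw) (initialized at K = −1, frozen in
"fixed" mode), strictly negative by construction. With every parameter
Euclidean in these coordinates, Adam (lr 0.02, 100 epochs, one graph per
step, seed-shuffled order) is the Riemannian-aware update for this
model. Gradients come from a small reverse-mode autodiff engine written
for this package; analytic gradients agree with central finite
differences to better than 1e−6 relative on full models.

**Decoder and loss.** Edge probabilities use the Fermi–Dirac function
p(i,j) = 1 / (exp((d(xᵢ,xⱼ)² − r)/t) + 1) with r = 2, t = 1 (inflection
at d² = r, steepness 1/t). Training minimizes the mean squared error
between decoded probabilities and the min–max scaled PLV targets over
the off-diagonal upper triangle — a continuous reconstruction objective
that retains the information the binary thresholding discards. The
decoder distance is computed in the Möbius-addition form, which is
smooth at coincident points.

**Radius gauge.** The reconstruction loss depends only on pairwise
distances, so embeddings are identified only up to a hyperbolic
isometry and the raw distance-to-origin is not a well-defined statistic.
`embed()` therefore fixes the gauge by Möbius-translating each
embedding's Fréchet mean to the origin before radii are computed (the
flat GCN subtracts the arithmetic mean). This makes radii comparable
across subjects and sessions; without it, group comparisons of mean
radius pick up arbitrary whole-cloud translations.

**Baselines.** The flat GCN shares the architecture with exp/log maps
replaced by identities, aggregation by the arithmetic mean over
N(i) ∪ {i}, and Euclidean decoder distance; at zero edges it reduces to
a per-node MLP. The shallow Poincaré embedding optimizes free per-node
coordinates in the unit ball against the same Fermi–Dirac + MSE
objective (for comparability with the encoders) using Riemannian
gradient scaling ((1 − c‖x‖²)/2)² with ball projection, a 10-epoch
burn-in at a tenth of the learning rate, defaults lr 0.3 and 300
epochs. It is transductive: it must be refitted for every graph and
cannot use node features.

## Evaluation

**Link prediction.** MAP is the mean over nodes (with ≥ 1 true
neighbor) of the average precision of the node's true neighbors among
all other nodes ranked by decoded score, ties broken deterministically
by node index. Cross-validation folds partition **subjects**, never
sessions, so a participant's pre and post graphs share a fold. The
inductive models train per fold and score held-out graphs' full
adjacency; the shallow baseline is fitted on each held-out graph.

**Classification.** Three feature sets per subject (pre-intervention
session only): the 4005 strictly-lower-triangle PLV values (row-major,
90 ROIs), the 8 subnetwork mean radii, or their 4013-wide
concatenation. An RBF-kernel SVM (γ = 0.1, C = 10) with stratified
5-fold CV produces pooled out-of-fold predictions; macro F1 is computed
from predicted labels and AUC-ROC from decision-function scores.

**Subnetworks.** Radii are averaged within eight functional
subnetworks, reported in the fixed order pDMN, aDMN, DAN, FPN, VN, VAN,
SN, SMN (sizes 10/6/6/10/10/14/10/2 of the 90 AAL ROIs; 22 ROIs
unassigned and excluded). The bundled assignment
(`data/subnetworks_aal90.tsv`) maps each AAL region to the functionally
closest subnetwork and is deliberately an editable file: functional
parcellations differ across studies, and any two-column TSV can replace
it.

## Synthetic generators

The generators provide inputs with the statistical structure the method
assumes — scale-free, hierarchically organized networks and
phase-locked band-limited oscillations — so every stage is testable
without recordings. They emulate that structure only: no volume
conduction or source leakage, no 1/f background or artifacts, no
realistic head geometry. Passing tests demonstrate that the pipeline
recovers structure it is designed for, not MEG-level realism.

* **Balanced trees** (depth labels retained) — the canonical hierarchy.
* **Hyperbolic random graphs**: n nodes in a hyperbolic disk of radius
  R (radial density ∝ eʳ, uniform angles), connected when their native
  hyperbolic distance is below R; planted radii stored for recovery
  tests. Default R = 4.5 gives ≈ 20% density — the thresholded-PLV
  regime — with hub-dominated degree tails across n from tens to
  hundreds. Edge targets are the min–max scaled positive part of R − d.
* **Phase-locked signals**: coupled blocks share a 10 Hz base
  oscillator (plus slow Brownian drift and a block-specific frequency
  offset spread over ±1.5 Hz so distinct blocks decorrelate); each
  non-driver member adds a phase offset with exact von Mises marginal,
  κ solved from I₁(κ)/I₀(κ) = target by bisection. The offset varies in
  time as a copula-mapped sum of 0.5–2 Hz sinusoids — inside the
  modulation band an 8–12 Hz filter transmits — so the construction
  survives the analysis pipeline. The constructed phases (returned in
  `meta['true_phases']`) realize driver–member targets to within
  estimator error (≈ 0.03 with long epochs); pipeline-measured PLV runs
  about +0.05 high because filtering still removes the fastest jitter
  components. Amplitude noise sd 0.05.
* **Cohorts**: one disk geometry defines the cohort's base
  connectivity, PLV(i,j) = 0.15 + 0.5·sigmoid((R_c − d)/2) with R_c set
  at the 20th percentile of pairwise distances (shifted by the sigmoid's
  inverse) so the 0.329 threshold retains ≈ 20% of edges. Subjects add
  symmetric Gaussian jitter (sd 0.05), sessions differ by sd 0.02
  jitter, ages are uniform in 65–80, and the "SCD" group gains δ
  (default 0.2) on every within-target-subnetwork pair — denser DAN
  wiring that the embedding expresses as a lower (more central) DAN
  radius. Group sizes default to 20/20, matching a small clinical
  cohort.

All generators are pure functions of their parameters and a seed.

## Problem sizes in tests and the acceptance script

The test and acceptance runs use deliberately desk-scale sizes chosen as
the package's own defaults: 60-node graphs with 6-subject cohorts for
the link-prediction ordering, 100-node graphs for hierarchy recovery,
20-vs-20 cohorts at 90 ROIs with a 40-epoch encoder trained on four
subjects for the planted-effect analyses, and five-fold subject-aware CV
wherever folds are used. The 40-epoch setting sits on the flat part of
the training-loss curve for the 4-graph cohort training set.

## Known limitations

* Aggregation is the unweighted Fréchet mean (self included); no
  attention weighting.
* Only origin-based tangent operations are used between layers; there
  is no parallel transport between arbitrary base points.
* The min–max probability targets are per-matrix, so a global
  connectivity offset between subjects is normalized away by design.
* Group-level inferential statistics (repeated-measures ANCOVA, FDR,
  correlations with cognitive scores) are out of scope; the package
  exports the radii tables such analyses consume.
* The one-hot input convention ties a trained encoder to a fixed,
  consistently ordered ROI set; inductive inference applies to new
  graphs over the same ROI atlas.
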