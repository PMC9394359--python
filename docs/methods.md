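# Methods

## Design construction

A face-centered central composite design over k numeric factors consists of
the 2^k factorial corners (coded ±1), 2k axial points at ±α with α = 1 (so
axial runs sit on the faces of the cube and no factor leaves its range), and
n₀ replicated center runs. Categorical factors are crossed with the numeric
block: every combination of categorical levels receives its own full block,
multiplying all space-type counts. For the reference factor space (k = 4,
n₀ = 6, one two-level categorical) this gives 60 runs: 32 factorial, 16
axial, 12 center.

Coding is linear: coded = (actual − midpoint) / half-range, so the range low
maps to −1 and the high to +1. Two-level categorical factors are coded −1/+1
in level-list order (`trainlm` → −1, `traingdm` → +1); this sign convention
is what makes the two center-point predictions split as β₀ − β_E and
β₀ + β_E. Neuron and epoch counts are declared integer factors and are
rounded after decoding; the other numeric factors stay continuous. Rows are
emitted in a canonical deterministic order (categorical levels outermost;
factorial, axial, center within a block) because the least-squares fit is
order-invariant and stable ordering simplifies comparison; an optional
shuffle seed randomizes run order for physical experiments where time trends
matter.

## Surface model and ANOVA

The response model is the full quadratic in coded levels: intercept, all
linear terms, all two-factor interactions, and squared terms for numeric
factors only (a ±1 contrast squared is constant, so categorical squares do
not exist). For 4 numeric + 1 two-level categorical factor that is 20
parameters. The response is transformed before fitting; the default is the
natural log (Box-Cox λ = 0), appropriate for an MSE-type response spanning
orders of magnitude. A profile-likelihood scan over λ ∈ {−1, 0, 0.5, 1} is
available (`rsm.scan_transform`, using the geometric-mean Jacobian scaling to
make residual sums comparable across λ); on the packaged reference responses
it marginally prefers λ = −1 over λ = 0, but the pipeline default remains
the log, the conventional choice for error-variance responses.

Per-term sums of squares are partial (Type III): the SS of a term is the
increase in residual SS when that single term is removed. The face-centered
CCD is not orthogonal in its quadratic columns, so partial and sequential
(Type I) SS differ there; both are implemented and agree on the mutually
orthogonal linear/interaction columns, which is used as a cross-check. F
ratios use the residual mean square. Pure error pools the within-group SS of
replicate groups — runs with identical actual settings, i.e. the n₀ center
runs per categorical level (10 df in the reference design) — and lack of fit
is the remainder of the residual; when replicates are absent the lack-of-fit
test is reported as undefined rather than raising. Predicted R² uses PRESS
computed from leverages, PRESS = Σ (eᵢ/(1−hᵢᵢ))². Adequate precision is
(max ŷ − min ŷ) / sqrt(p·MS_res/n) with p the parameter count and n the run
count — the standard average-prediction-variance definition. p-values below
1e-4 are rendered `<0.0001` in the text report.

The optimum is located per categorical level by a dense grid over the coded
cube (step 0.05) followed by bounded L-BFGS-B polish; the constrained
quadratic can attain its optimum on the cube boundary, which rules out the
closed-form stationary point. The search is deterministic.

## Network and trainers

The network is a single hidden layer of hyperbolic-tangent-sigmoid units
with a linear output: ŷ = w_out·tanh(W_in x + b_h) + b_out. Initialization
is a seeded Nguyen-Widrow-style scheme (uniform weights row-scaled to
0.7·n_hidden^(1/n_inputs), biases spread over the active region), so
identical seeds give identical networks.

`train_gdm` is full-batch gradient descent with momentum,
Δw(t) = mc·Δw(t−1) − lr·∇E, on the mean-squared-error surface; a config flag
switches to the (1−mc)-scaled gradient step some toolboxes use. Divergence
to a non-finite error raises a typed exception carrying the epoch.
`train_lm` is Levenberg–Marquardt on the Jacobian of per-sample residuals:
solve (JᵀJ + μI)Δ = −Jᵀe, accept only error-decreasing steps (μ ÷ 10 on
accept, × 10 on reject), with μ₀ = 1e−3 and a 1e10 ceiling — standard
damping defaults. LM ignores the learning-rate and momentum settings; they
remain part of a configuration because the hyperparameter design varies them
across both algorithms, and the flatness of LM rows along B and C is itself
informative in the fitted surface. Early stopping on a validation set is
deliberately not used inside a run: the epoch budget is one of the factors
under study.

Two advisory capacity bounds are reported (never enforced): hidden units ≤
2·inputs + 1, and ≤ training samples / (inputs + 1). Practitioners routinely
exceed the first; violations warn.

## Cross-validation

A campaign fixes one split plan: a seeded 60/40 random holdout, with the
training indices cut into 3 near-equal folds (contiguous blocks of a seeded
shuffle). MSE_CV of a configuration is the mean over fold rotations of the
validation-fold MSE after training on the other folds. One plan is shared by
all configurations of a campaign, which removes split noise from
between-configuration comparisons. Normalization (min-max to [0, 1]) is
refit on the learning folds of each rotation — strictly no leakage; a leaky
mode that normalizes once on all data is available for comparison, since
normalize-before-split is a common shortcut. Error metrics are computed on
the normalized scale (consistent with MSE_CV magnitudes of order 0.01–1); a
flag restores original units. Per-fold training seeds derive from the
configuration seed and fold index, and in campaigns each design row gets its
own seed derived from the campaign seed — replicate center runs then carry
genuine run-to-run initialization variation, which is exactly the pure error
the ANOVA needs. Diverged or stalled training contributes an infinite fold
MSE instead of aborting the sweep.

## Synthetic SMBR generator

The generator emulates the *structure* of pilot-plant filtration data, not
any particular plant. Pump voltage follows piecewise-constant random steps
(magnitudes over roughly [0.5, 3] V, dwell 120–400 s); operation cycles
120 s permeation / 30 s relaxation; airflow steps within 6–8 SLPM. Fouling
is a resistance-in-series model: demanded flux is proportional to pump
voltage (25 L m⁻² h⁻¹ per volt), TMP = J_demand·(R_m + R_f) capped at
270 mbar, flux J = TMP/(R_m + R_f); the fouling resistance grows as
dR_f/dt = a·J during permeation (a = 1e−4) and relaxes as dR_f/dt = −b·R_f
during the aerated pause (b = 0.01 s⁻¹, scaled by relative airflow). This is
the simplest mechanism that yields the qualitative signatures of such data —
step response, slow flux decline under sustained demand, partial recovery
after relaxation — with Gaussian flux noise (sd 1 L m⁻² h⁻¹, giving held-out
correlations around 0.99 for a well-fitted model) and 1 Hz sampling (4000
samples ≈ 66 min). Defaults: membrane area 0.35 m², clean resistance 1 mbar
per flux unit.

What the generator does *not* emulate: sludge biology, cake-layer
compressibility, backwash hydraulics, sensor drift, or the partial
observability of real fouling state. In particular, during unclipped
operation the flux is close to a deterministic function of pump voltage
alone, so the learning problem is easier than a real plant's; campaign-level
tests on synthetic data therefore demonstrate that the machinery is correct
and the signal is learnable, not that real-plant accuracy figures transfer.

## Campaigns

The designed campaign executes: split → build the CCD → score all 60 rows by
MSE_CV → fit the log-scale quadratic → ANOVA → minimize the surface → decode
(rounding the neuron and epoch counts) → retrain on the full training split
→ test. Gradient-descent runs at aggressive corners of the design can blow
up; on the normalized scale their MSE is astronomically large or infinite,
which would let a few runs dominate a log-scale fit, so responses are capped
at 1e3 (far above any converged normalized MSE) and capped rows are flagged
in the evaluation log.

The OVAT baseline sweeps neurons (1–30), then learning rate (0.1–1.0 in ten
steps), then momentum (ten steps topping out at 0.95, since unit momentum
makes the update non-contractive), then epochs (100–1000), holding unswept
parameters at grid midpoints (lr 0.5, momentum 0.5, epochs 500) and fixing
each stage's argmin — 60 evaluations per algorithm. Tie-breaks go to the
earlier grid point.

`epoch_scale` multiplies every configured epoch budget (minimum one epoch),
letting an entire campaign run at reduced computational scale; run counts,
determinism and the selection logic are unaffected by the scale. The test
suite exercises campaigns on a 900-sample synthetic dataset at
epoch_scale = 0.05; the packaged-fixture reproduction always runs at full
fidelity since it involves no training.

## Numerical notes and limitations

* Fits use `numpy.linalg.lstsq`; rank deficiency raises a typed error naming
  the aliased terms via the SVD null space.
* The reference-fixture refit reproduces the published coefficients to
  ≤ 1e−4 and the ANOVA statistics to ≤ 4e−3 (the residual discrepancy is the
  4-decimal rounding of the published responses).
* Model fitting supports two-level categorical factors; multi-level
  categoricals are accepted by the design builder but would need dummy
  coding in the model, which is out of scope.
* The flux-volume relation J = v/(A·t) is exposed as a utility for working
  with volumetric records; the generator operates directly in flux units.
* Surface-optimum selection trusts the quadratic approximation; when the
  true response is multimodal in a factor the decoded optimum should be
  re-evaluated (the campaign does retrain and test it, and reports both the
  continuous and rounded settings).
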