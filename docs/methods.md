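# Methods

## Scope and data model

The pipeline starts from frame-wise tissue time-activity curves (TACs) and
well-counter blood samples; image reconstruction and VOI delineation are out
of scope. All times are minutes, all activities kBq/ml, assumed
decay-corrected to the start of the first scan. Tissue density is taken as
1 g/ml, so kBq/ml ≡ kBq/g and ppm means µg(¹⁰B)/g(tissue). Frames are
timestamped at their midpoints.

The reference acquisition is a whole-body protocol of seven 455 s frames
separated by 45.5 s gaps (midpoints 3.79–53.8 min) with blood samples at
0.5, 1, 3, 5, 10, 20, 30 and 50 min plus a pre-injection background row
that is stored but excluded from every fit.

## Input function

Plasma samples are metabolite-corrected by the parent fraction
`1 − m(t)`, with the metabolite fraction `m` linearly interpolated between
its measurement times (defaults: 2.324% at 20 min, 3.966% at 50 min) and
held constant outside the measured range — the measured fractions are few
and stable, so constant extrapolation is the conservative choice.

The clearance phase (from the peak sample onward) is fitted with
`A₁e^{−λ₁t} + A₂e^{−λ₂t}` by bounded nonlinear least squares; a
deterministic multi-start over log-spaced (λ₁, λ₂) pairs with
linear-least-squares amplitude initialization guards against local minima
(no randomness anywhere in the fit). Failures raise an error carrying the
per-start diagnostics.

Between samples the curve is evaluated, by default, from the fitted
bi-exponential (rescaled by one factor to pass through the last sample),
with a linear ramp from (0, 0) to the model value at the peak time. This
*model interpolation* is how sparse plasma curves are conventionally
smoothed; piecewise-linear chords over an 8-sample grid overestimate the
convex clearance curve by ~6% in ∫Cp and would bias every Vt estimate down
by the same amount. A `"linear"` mode (piecewise-linear in-window,
model-extrapolated beyond) is retained as an option. In both modes the
running integral ∫₀ᵗCp is computed in closed form (exact trapezoid on
linear pieces, analytic bi-exponential integral), so no quadrature error
enters the graphical-analysis regressors.

## Graphical Vt estimation

All three models are ordinary least squares over the frames at/after t\*,
unweighted (the upstream software's weighting scheme is not published, and
the comparison metrics only need ordering). The regression domain is the
transformed ordinate for the Logan plot and C(T) itself for MA1/MA2, and
goodness of fit is computed in that same domain per model.

Tissue integrals use a *frame-aware* rule: a frame value is the time
average of C over the frame, so it contributes exactly value × duration;
gaps and the half-frame up to the midpoint are filled assuming local
linearity. A midpoint trapezoid with a (0, 0) triangle — also provided as
the generic `cumulative_integral`, which builds the MA2 double integrals —
loses ~3.6% of the early integral on 455 s frames and would violate the 3%
recovery target. MA2's Vt is −γ₁/γ₂ (from γ₁ = (k₂/k₄)V, γ₂ = −k₂/k₄);
note that other software parameterizes γ₁…γ₄ differently, so individual
coefficients (γ₃, γ₄≈K₁) may not match across tools even when Vt does.

t\* for Logan/MA1 is the smallest frame midpoint whose refit keeps the
maximum relative deviation |fitted − observed|/|fitted| within 1% (7
candidates only; no continuous search). If none qualifies, the latest
feasible candidate is returned flagged `converged=False`. MA2 uses a fixed
t\* of 20 min by default (configurable, including 0).

Every fit reports a delta-method standard error of Vt from the OLS
coefficient covariance. Quality control rejects a fit when Vt is
non-positive/non-finite or its relative SE exceeds 50% — the conventional
%SE cutoff for non-identifiable kinetic parameters. A sign flip of γ₂
(flagged "unphysical") does *not* by itself reject: under near-collinearity
γ₁ and γ₂ flip together while their ratio stays well determined. Vt
estimates are invariant to a common rescaling of tissue and plasma
(activity units cancel).

## Model selection

AIC uses the least-squares form `n·ln(SSR/n) + 2p` without small-sample
correction (with n = 5 frames and p = 4, the AICc denominator vanishes;
requesting it raises). Reduced χ² defaults its σ to the fit's own Sy.x,
which makes it exactly 1 — supply the simulator's true σ for a meaningful
value; published χ² magnitudes depend on unknown weighting and are treated
as ordering information only. Ranking is AIC ascending with Sy.x and then
|χ²−1| as tie-breaks, a deterministic total order.

## Synthetic studies

The generator states a complete world rather than tunable noise dials:

* plasma: linear rise over 0.5 min to the peak, then
  `A₁e^{−λ₁t} + A₂e^{−λ₂t}` with A₁ = 60 kBq/ml, λ₁ = 0.30 /min (realistic
  early bolus clearance) and A₂ = 9.293 kBq/ml, λ₂ = 0.0149 /min — the slow
  phase is pinned by the reported plasma boron levels (14.9 ppm at 1 h,
  6.1 ppm at 2 h ⇒ 3.83 kBq/ml at 60 min and a 1 h→2 h ratio of 2.44);
* measured plasma includes metabolites (parent / parent fraction) so the
  correction step is exercised end to end; whole blood is plasma divided by
  1.31, the reported plasma/whole-blood boron ratio; blood samples carry no
  noise (well-counter precision ≫ frame noise);
* organs: eleven sets of two-tissue rate constants whose closed-form
  Vt = (K₁/k₂)(1 + k₃/k₄) equals the reported MA2 means (0.94 pancreas …
  0.16 lung). The brain uses slow constants (k₂ = 0.062, k₃ = 0.07,
  k₄ = 0.042 /min) so its TAC peaks inside frame 5 (~34–41 min), the
  late-peaking pattern characteristic of that region; all other organs wash
  out from the first frames;
* tissue curves are the exact convolution of the piecewise input with the
  two eigenmodes of the compartment system (a brute-force stiff ODE
  integrator serves as an independent oracle in tests, agreeing to ~1e-9);
  frame values are within-frame time averages; noise is multiplicative
  Gaussian truncated at zero, CV 5% by default, fully reproducible under a
  seed.

What a green test on this world does establish: estimator correctness,
bias behavior under frame averaging and multiplicative noise, and the
AIC-based preference for MA2. What it does not: real-data effects absent
from the generator — partial volume, motion, VOI heterogeneity, blood
sample measurement error, subject-to-subject kinetic variability.

## Study orchestration

`run_study` accepts one or more subjects (file paths or in-memory objects),
fits all requested models per VOI, records per-model failures without
aborting the study, selects the best reliable model per organ, and
aggregates across subjects as unweighted mean ± sample (n−1) SD,
QC-rejected fits excluded. The boron table contains one row per organ
(selected model's Vt), a plasma row (V ≡ 1) and a whole-blood row (V ≡ 1 on
a separate uncorrected whole-blood extrapolation), sorted by descending
concentration. `report_tables` writes the three CSV tables, the run log and
a JSON manifest with a configuration hash; identical inputs produce
byte-identical outputs.

## Known limitations

* With a decaying input the late-time ratio C/Cp converges to
  Σwⱼ/(θⱼ−λ₂), not to Vt; the two agree within 1% only for fast
  equilibration (θ ≫ λ₂). The simulator self-consistency check therefore
  uses a fast one-tissue organ.
* The MA2 Vt is a coefficient ratio whose denominator can approach zero on
  5 points with 4 parameters; at 5% frame noise its replicate mean is
  heavy-tailed. Quality control stabilizes the fast organs (<0.5% residual
  bias), but for the slow-kinetics brain ~30–45% of noisy fits are rejected
  and the surviving mean can still wander by several percent between seed
  batches.
* On coarse 7-frame data the Logan and MA1 estimates differ at the ~1e-3
  level from discretization; their algebraic equivalence (1e-6) is only
  observable on finely sampled, exactly linear data.
* MA1's variance advantage over the Logan plot reported in the multilinear-
  analysis literature does not materialize on this 7-frame schedule: the
  two spreads are comparable at CV 5–20%, though MA1's mean stays within 5%
  of truth.
* Multi-subject aggregation multiplies mean Vt by mean plasma ppm, which is
  not identical to averaging per-subject products when both vary.
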