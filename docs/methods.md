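# Methods

## Models

Assimilation demand is empirical throughout: the non-rectangular
hyperbola (NRH) in a CO₂ driver *C*,

ω A² − (CE·(C − Γ) + A_SAT)·A + A_SAT·CE·(C − Γ) = 0,

of which only the lower root is physical (A = 0 at C = Γ, initial slope
CE, asymptote A_SAT). Units follow field convention: A and A_SAT in
µmol m⁻² s⁻¹, C and Γ in µmol mol⁻¹, CE in mol m⁻² s⁻¹ (so CE·C products
deliberately mix mol and µmol), conductances in mol m⁻² s⁻¹, ω
dimensionless in (0, 1]. The same curve fitted against Cᵢ or against
Cₘ = Cᵢ − A/g_M gives the Ci-based and Cm-based parameter sets; Γ is the
curve's x-intercept on either basis. The light response of gross
assimilation uses the identical quadratic with PPFD as driver, initial
quantum yield Y(CO₂)_LL and asymptote GA_SAT.

Quadratics are solved in the (−b − √disc)/(2a) lower-root form; when the
leading coefficient falls below 10⁻¹⁰ the linear root −c/b is used
instead, which is exactly the rectangular-hyperbola limit of the NRH as
ω → 0 (tested for continuity at ω = 10⁻⁷). ω = 1 (the Blackman limit,
A = min(CE·(C − Γ), A_SAT)) needs no special casing but is exactly flat
past the kink, so monotonicity is only non-strict there.

Coupling the Cm-based demand curve to the series diffusion supply
Cₘ = C_a − A/g_tot, g_tot = g_S·g_M/(g_S + g_M), gives

(ω + CE·r)·A² − [CE·(C_a − Γ) + A_SAT·(1 + CE·r)]·A + A_SAT·CE·(C_a − Γ) = 0,

with r = 1/g_tot. The lower root agrees with an independent bracketing
solve of the fixed point A = f(C_a − A·r) to 10⁻⁸ relative on 1000 random
parameter draws (test suite), and reduces to the uncoupled curve to
within 10⁻⁶ µmol m⁻² s⁻¹ when both conductances reach the default
"arbitrarily high" sentinel of 10⁶ mol m⁻² s⁻¹.

### Flattening

A treated plant's curve is estimated from its single operational point
(C_op, A_op) by holding ω, Γ and the ratio µ = A_SAT/CE fixed and solving
the NRH for CE (positive branch). Mechanistically fixing µ corresponds to
fixing the ratio of electron transport to maximum carboxylation; the
`mu` argument accepts a measured ratio where available. One algebraic
fact worth recording: the inner radicand
(C − Γ + µ)² − 4ωµ(C − Γ) is non-negative for every ω ≤ 1, so any
positive operational point is reachable by some member of the family —
the "unreachable point" error can only fire on an out-of-range curvature.

### Mechanistic conversion

`mechanistic_to_empirical` maps literature parameters onto the NRH:
CE = V_MAX/K (carboxylase maximum rate over its O₂-adjusted
Michaelis–Menten constant), A_SAT = J/4 − R_L for C₃ or J_ATP/5.5 − R_L
for C₄, ω defaulting to the conventional 0.7, Γ supplied by the caller.
For a closer conversion, `synthesize_curve` evaluates a source model on
10–15 dummy driver values and `fit_nrh` refits them; the round trip
reproduces converted parameters within 1% (tested).

## The transition engine

A state is a named, complete input map for one registered model (`nrh`,
`coupled`, `light`); a transition is ≥ 2 states sharing a model, with K
intervals per leg (default K = 1000, following the convention of the
finite-interval contribution literature). Inputs scale linearly between
adjacent states. Per interval the marginal contribution of input *a* is
the forward difference ξ(a) = f(a at k+1, b at k) − f(all at k); the
alternate form ξ′ (others held at k+1) is exposed for convergence
demonstrations only — the two agree as K grows (tested: the gap shrinks
by > 100× from K = 4 to K = 1000).

Summation runs k = 0 … K−1 per leg. With a single changing input the
forward differences telescope, so Ξ equals the overall change to machine
precision for any K; with several inputs the first-order decomposition
leaves a closure residual Σ_a Ξ(a) − ΔΩ that is reported on every table,
logged at INFO, and shrinks monotonically as K doubles (tested 4 → 4096).
ρ = Ξ/ΔΩ and L = Ξ/Ω_end are stored as explicit `None` with defined-ness
flags when ΔΩ = 0 or Ω_end = 0 — never silent NaN. Iteration order over
input names is irrelevant by construction (each ξ depends only on the
interpolated paths); a bit-for-bit invariance test enforces this.

### Paths for barrier lifting

Lifting a conductance to 10⁶ mol m⁻² s⁻¹ along a *linear-in-conductance*
path concentrates essentially the entire response into the first
interval (after one step of width 10³ the supply is already unrestricted),
leaving a closure error that no K can reduce. A `Transition` therefore
accepts a `reciprocal` tuple naming inputs to interpolate linearly in
their reciprocal; `diffusional_limitation` uses it for g_S and g_M.
Resistance is the additive series coordinate of the diffusion pathway, so
this is still a linear input path — in the physically meaningful
variable. With it, the diffusional example closes to 4 × 10⁻⁴ µmol m⁻² s⁻¹
at K = 1000 and the limitation matches the closed form
(A_pot − A_op)/A_pot. Finite-to-finite transitions (e.g. the treatment
contribution analysis) keep plain linear conductance paths.

### Control coefficients

`sensitivity` and `elasticity` evaluate S = ξ/Δa and η = Δln f/Δln a at a
state; `control_analysis` perturbs each input by a relative increment
i = 10⁻⁴ (the conventional value) and reports S, η and each input's share
of the summed marginal response (shares sum to 1 by construction). η
satisfies η = S·a/f to 4 decimals at that increment (tested). Published
*averages* of S and η exist for this example (113 µmol mol⁻¹ and 0.5 for
g_S), but the set of intervals they average over is not identified in the
source; the engine therefore reports the full per-interval series and the
point values (S = 104, η = 0.476 at the healthy operational state) and
leaves averaging to the caller.

## Fitting

`fit_nrh`/`fit_light` use bounded trust-region least squares (scipy),
plain unweighted loss. Initial guesses come from the data: Γ from linear
interpolation of the sign change in A, CE from the slope of the two
lowest-driver points, A_SAT from 1.05·max(A), ω = 0.7; bounds are
A_SAT ∈ (0, 10·max A], CE ∈ (0, 10], ω ∈ (0, 1], Γ ∈ [0, lowest
positive-A driver]. Three jittered restarts run on non-convergence and
the result carries a `converged` flag rather than failing silently. Γ and
ω can be fixed, mirroring the flattening assumptions. Curves need ≥ 5
distinct driver values; duplicated drivers and flat curves are rejected.
Whether ω should be fitted freely per basis or fixed is left to the
caller — both options are exposed because fitted data sets differ on it.

## Bundled example data and what tests do (and do not) show

The fixture transcribes a published synthetic two-plant dataset: 9-point
A/Cᵢ curves (Cᵢ = 24 … 420 µmol mol⁻¹), derived A/Cₘ curves, operational
points (13.9, 200) and (11, 220) at C_a = 420, g_M = 0.35/0.25, printed
operational g_S = 0.063/0.055, and four fitted parameter sets. The
healthy A/Cᵢ column is noiseless output of its parameter set rounded to
three significant figures, which makes it a complete oracle for the
fit → transition → metrics pipeline. Two transcription quirks are kept
verbatim and tested around: the Cₘ entries at Cᵢ = 210 sit ~3 µmol mol⁻¹
below Cᵢ − A/g_M (every other row agrees within ±1), and the treated A
column is not noiseless output of its *rounded* parameters (deviations up
to 0.11 µmol m⁻² s⁻¹).

The synthetic generator (`synthesize_curve`) produces exact model values
plus i.i.d. Gaussian noise, deterministic per seed. Real gas-exchange
data additionally carry correlated drift, leak artefacts and
heteroscedastic IRGA noise; passing tests demonstrate correctness of the
estimators and the engine, not robustness to instrument pathology.

Two engine results deliberately differ from published rounded figures,
both documented in the acceptance tests: (i) in the single
healthy → treated contribution analysis the published stomatal/diffusional
split (−0.5/−0.9) does not reconcile with its own published endpoint
change (the printed components sum to −2.6 against a −2.9 ΔA); the
engine's split (−0.75/−1.11) closes against the data exactly, and the
mesophyll and biochemical components agree with print. (ii) The
single-transition and two-tier variants of the stomatal/non-stomatal
analysis share end states, so their *total* limitation is identical to
closure precision, but the split between the parts shifts by the
interaction term (0.205 vs 0.234 for L(g_S) here, ~14% — within the ±20%
scale generally quoted for path-dependent alternatives). Users comparing
variants should report which one they used.

## Known limitations

No temperature responses, no full mechanistic C₃/C₄ models, no
triose-phosphate limitation, no rapid-ramp A/Cᵢ correction, no
fluorescence/isotope estimation of g_M, and no uncertainty propagation
from fitted parameters into the restriction metrics. Input paths between
states are linear (or linear-in-reciprocal); time-resolved, non-linear
trajectories are out of scope.
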