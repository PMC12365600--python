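# Methods

This note records the statistical conventions `lipidmix` implements, the
defaults it ships, and the places where a design decision was genuinely
open — in the spirit of the methods documentation of statsmodels or
msprime: what the code assumes, not a results section.

## The modeling problem

An LNP formulation is a point on the 4-component mixture simplex: molar
fractions of helper phospholipid (DSPC, `A`), ionizable lipid (SM-102,
`B`), cholesterol (`C`) and PEG-lipid (DMG-PEG2000, `D`) with
`A+B+C+D = 1` and box bounds per component (defaults: A 0.05–0.40,
B 0.15–0.65, C 0.15–0.65, D 0.01–0.10; the built-in 16-run design respects
these). Measured responses per run are encapsulation efficiency (%, in
(0, 100]), Z-average diameter (nm, > 0) and nMFI (median fluorescence of
treated cells over untreated control, > 0, dimensionless).

Because the proportions sum to one, polynomial models use the Scheffé
canonical form: no intercept, linear blending terms `βᵢxᵢ` and binary
blending terms `βᵢⱼxᵢxⱼ`. The linear terms span the constant, which has two
consequences used throughout: R²-type statistics are computed against the
*mean-corrected* total sum of squares even though the model matrix has no
intercept column, and "hierarchy" reduces to keeping all linear terms in
every model.

## Design construction

The I-criterion is `tr((XᵀX)⁻¹M)` with `M = E[f(x)f(x)ᵀ]` over the feasible
region — the region-averaged scaled prediction variance. `M` is estimated
by Monte Carlo over uniform feasible points (default 100 000; the q=2
linear case agrees with the closed-form integrals to well under 2% at that
size). Uniform sampling is rejection from the flat Dirichlet; if the
acceptance rate falls below 1e-4 the sampler aborts with advice rather than
spinning (hit-and-run would be the next tool, not included).

Candidate sets are classical: extreme vertices (fix q−1 components at bound
combinations, solve the fill component, keep feasible), all edge midpoints,
the vertex centroid and a configurable number of uniform interior points.
Exchange is Fedorov-style: from each random start, try every
(design point, candidate) swap, accept the best improvement, stop when the
relative gain drops below 1e-8; ties break toward the lowest candidate
index so a seed fully determines the output. Replicated candidate points
are allowed — on tiny problems the exchange provably attains the brute-force
optimum over candidate *multisets*, and tests check exactly that.
Design identity with any particular software's 15-run layout is not a goal;
designs are judged by criterion value and feasibility, and the built-in
15-run design is shipped as data for the downstream stages.

## Transform choice

Models are fitted on the plain power scale `t = y^λ` (`ln y` at λ = 0) —
the scale on which the built-in fitted equations are stated. The
Jacobian-normalized form `z(λ) = (y^λ − 1)/(λ g^{λ−1})` (`g` the geometric
mean) is used only inside the profile-likelihood scan, where it makes
`−(n/2)·ln(SSE_λ/n)` comparable across λ and the whole curve invariant (up
to an additive constant) to rescaling `y`.

The confidence interval for λ is the set of grid points within a
log-likelihood cut of the maximum. The default cut is the exact Gaussian
small-sample calibration `(n/2)·ln(1 + t²(α/2, ν)/ν)` with `ν = n − rank(X)`
— equivalent to the familiar `SSE(λ) ≤ SSE(λ̂)(1 + t²/ν)` interval that
response-surface software draws on its Box–Cox plot. The asymptotic
`χ²₁(0.95)/2` cut is available (`ci_method="chisq"`) but is anti-conservative
at mixture-screen sizes: with 15 runs and 5–8 coefficients its true coverage
measurably drops below the nominal level, while the t-calibrated cut holds
it (the test suite checks ≥90% empirical coverage at the built-in noise
levels). The scanned λ is snapped to the nearest *convenient* exponent
(−2, −1.5, −1, −0.5, 0, 0.5, 1, 2) inside the CI; if none is inside, the
nearest convenient value is used with a warning. With only 15 runs the CI
spans roughly two λ-units, so the snapped value legitimately scatters over
neighbouring convenient exponents across replicate screens — the tests
assert CI coverage and neighbourhood recovery, not exact recovery.

λ = 0 is natural log, and responses must be strictly positive wherever
λ ≤ 0 or fractional; zeros are rejected, never offset, to avoid silent bias.

## Fitting and adequacy

`fit_scheffe` is OLS of the transformed response on the Scheffé matrix
(statsmodels under the hood; rank deficiency raises rather than silently
pseudo-inverting). Rows flagged as validation are excluded before fitting,
so the hold-out run MS can never leak into training, and
`holdout_validation` refuses any run id it has seen in training.

On the transformed scale, with `p` coefficients and `n` runs:

- `R² = 1 − SSE/SST`, `adjR² = 1 − (SSE/(n−p))/(SST/(n−1))`, SST
  mean-corrected (see above);
- `PRESS = Σ (eᵢ/(1−hᵢᵢ))²`, `predR² = 1 − PRESS/SST`; a leverage of
  exactly 1 makes PRESS undefined and is flagged, other statistics are
  still returned; the shortcut is tested against explicit leave-one-out
  refits to 1e-10;
- `CV% = 100·√MSE/t̄`;
- adequate precision `= (max ŷ − min ŷ)/√(p·MSE/n)` over the design
  points. The formula for this statistic is a convention (the name is
  standard, the definition is rarely printed); this is the common
  signal-to-noise form.

Adequacy flags: `adjR² − predR² < 0.2` (over-fit screen) and adequate
precision `> 4`.

Each run enters as a single value; replicate-level variance modeling is out
of scope, and if runs were measured in triplicate the table handed to the
fitter is expected to carry the means.

## Term selection

Sequential (type-I) SS starts from the grand-mean model so the increments
plus the final residual telescope exactly to the corrected SST; a term that
adds no rank (the fourth linear term after three, on a mixture) is a
zero-df, zero-SS step rather than an error. The F tests in the table are
descriptive ordering aids only — selection is driven purely by BIC, in the
Gaussian profile form `n·ln(SSE/n) + k·ln n` with `k` the coefficient
count.

Forward selection starts from the mandatory terms (default: all linear
blending terms, which also enforces hierarchy), adds the largest-BIC-drop
candidate until none helps. Backward elimination starts from the full
candidate model (feasible at n = 15 for the 10-term quadratic) and removes
the most-helpful-to-drop term. When both directions are run, the lower BIC
wins and exact ties favor fewer terms. An exhaustive enumerator over all
hierarchy-valid subsets (≤ 2²⁰) is provided as the verification oracle.

Two numerical conventions worth knowing:

- BIC comparisons floor SSE at `1e-12·SST`. On noiseless data the SSE of a
  correct model is rounding dust whose logarithm fluctuates by more than
  the `ln n` penalty; the floor makes all essentially-perfect models tie on
  likelihood and resolve on parsimony.
- BIC at n = 15 is a *liberal* gatekeeper: a spurious interaction enters
  whenever the best of the six candidates absorbs more than
  `1 − 15^{−1/15} ≈ 16.5%` of the residual SSE, which pure noise achieves
  in a majority of screens. That is a property of BIC at this sample size,
  not of the search — the tests therefore verify that stepwise lands on the
  exhaustive BIC optimum, not that it stays minimal under noise.

## Desirability optimization

Goals follow Derringer–Suich: one-sided ramps for maximize/minimize with
exponent `w` (weight), a two-sided ramp for target, an indicator for
in-range; overall `D = (Π dᵢ^rᵢ)^{1/Σrᵢ}` with integer importances 1–5.
Desirability is always evaluated on raw-scale predictions, so the direction
flip of a negative transform exponent (larger nMFI = smaller `Y^{−1.5}`)
cannot invert a goal; a transformed prediction with no raw image simply
scores zero at that point.

The search space is the feasible sub-simplex of the non-fixed components
(fixed components, e.g. SM-102 at 0.65 and DMG-PEG2000 at 0.01 for a
storage-stability series, are pinned exactly). Seeding evaluates a
candidate set of the sub-region; the best `n_starts` (default 50) seeds
launch Nelder–Mead in the (k−1)-coordinate parameterization, and every
evaluated point is first projected onto the box-constrained simplex by a
bisection water-filling step, so all reported candidates are feasible to
1e-9. Seed points stay in the final pool, hence the reported optimum is
never worse than any seed; on toy problems the result matches a dense grid
within 1e-3 in D. Default goals for the built-in study: maximize
encapsulation (L=40, T=95, w=2, r=3) and maximize nMFI (L=1, T=3, r=5);
the diameter model is excluded from the default objective — its fits are
the least stable of the three — but remains selectable.

## Synthetic data

The generator treats the built-in fitted models as ground truth and places
Gaussian noise on the *transformed* scale — the scale the whole analysis
assumes the noise lives on — at the published residual SDs (14.31 for
encapsulation on the identity scale, 1.56 for √diameter, 0.0961 for
nMFI^{−1.5}), then maps back through the inverse power. Draws whose raw
image is impossible (encapsulation outside (0, 100], diameter or nMFI not
positive) are redrawn and counted, making the marginals explicit truncated
normals; `truncate=False` disables the window for studies (unbiasedness,
refit-distribution checks) that assume plain Gaussian noise. At the default
noise levels the redraw rate is below 1% for diameter and nMFI; for
encapsulation several design points sit within one to two SDs of the 100%
ceiling, so a few percent of draws are redrawn there — visible in the
logged counts, and the reason coefficient-unbiasedness checks use the
untruncated mode.

What the generator deliberately does *not* emulate: replicate-level
flow-cytometry or DLS measurement error, inter-batch variation, PDI/zeta
responses, and any storage-time drift. Passing tests therefore demonstrate
that the pipeline recovers what it assumes — models on transformed scales
with homoscedastic Gaussian noise at the published magnitudes — not that
real screens satisfy those assumptions.

A note on reproducing printed summary statistics: refitting the five-term
nMFI model to synthetic screens at its published σ yields a median R² close
to the published value, and median adequate precision for all three models
clears the >4 rule (this is what `scripts/acceptance.py` recomputes). The
published adequate-precision values themselves are substantially higher
than the generating surfaces imply — the fitted spread of the encapsulation
equation over the design is ≈43 while the printed statistic would require
≈124 at the printed σ — so those particular numbers are not recoverable
from the printed models under any seed; the per-refit `>4` rule holds in
most but not ≥95% of refits for the two noisier responses.

## Problem sizes and runtime

Defaults are sized for a laptop core: 1e5 Monte-Carlo points for moment
matrices (2% accuracy on the analytic toy case), 200–500 synthetic refits
for distributional checks, 50 multistarts for optimization, 200-seed
coverage studies for the Box–Cox CI. The full test suite runs in well under
a minute; the acceptance script in a few seconds.

## Known limitations

- No blocking, split-plot or mixture-process designs; no lack-of-fit or
  replicate augmentation heuristics.
- Outlier handling stops at leverage; no studentized-residual diagnostics.
- Selection offers BIC only (no AICc, cross-validation or shrinkage).
- The optimizer reports local optima from multistart; it does not
  enumerate a Pareto front or propagate model uncertainty into D.
- Percent/proportion auto-detection in design files uses a hard 1% row-sum
  gate and refuses mixed files rather than guessing per row.
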