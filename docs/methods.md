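# Methods

## The microscopic model

Cells occupy sites of a 2D lattice (l = width × height sites, at most
one cell per site; periodic boundaries by default, a fixed mode
truncates neighborhoods at the edges). Time advances in steps of Δt
(default 1), and rates are interpreted as per-step event probabilities:
λ·Δt, δ·Δt, m·Δt must each lie in [0, 1]. One step sweeps all live
cells in a freshly shuffled order; for each cell, in order:

1. **Migration** with probability m·Δt: the cell moves to a uniformly
   chosen empty site of its migration neighborhood (or of the entire
   lattice for the `global` neighborhood). If no empty site exists, it
   stays; the event is not re-drawn.
2. **Birth** with probability λ·Δt: a daughter is placed on a uniformly
   chosen empty site of the birth neighborhood. If the neighborhood is
   completely occupied the attempt is *blocked* and logged — this is the
   contact-inhibition mechanism.
3. **Death** with probability δ·Δt, attempted only if no successful
   birth occurred for this cell this step (the flowchart convention; a
   `death_mode="independent"` flag decouples it for sensitivity
   analysis).

Daughters born during a sweep join the shuffled list from the next step
(no within-step cascades). A migrating cell may still divide in the
same step (the checks are sequential). All randomness flows through one
`numpy` Generator per simulation in a fixed draw order — shuffle, then
per cell: migration uniform, site choice, birth uniform, site choice,
death uniform, each drawn only when its rate is positive — so a (seed,
parameters, initial state) triple reproduces a trajectory bit for bit.
Empty-site choices are uniform over the empty neighborhood sites
enumerated in the neighborhood's fixed offset order. The sweep is
compiled with numba; semantics are defined entirely by that single
kernel.

Neighborhood presets: Von Neumann (ω = 4), Moore (ω = 8), second-order
Von Neumann (ω = 12), second-order Moore (ω = 24), plus `global`
(= all other sites).

## Occupancy theory

The blocked-birth probability E[ℙ(ω|n)] is the bridge from the
microscopic rule to mean-field laws:

- **Well-mixed (hypergeometric)**: with cells placed uniformly at
  random, the number of occupied neighbor sites of a focal cell is
  hypergeometric — ℙ(x|n) = C(ω,x)·C(l−ω−1, n−1−x)/C(l−1, n−1) — and
  the blocked probability is its value at x = ω. Binomials are
  evaluated in log space (`gammaln`), so l up to ~10⁶ is safe. The
  mean-field simplification (n/l)^ω is exposed separately, with the
  intermediate ((n−1)/(l−1))^ω behind a `shifted` flag; the (n/l)^ω
  form is canonical.
- **Radial**: a compact cluster in d dimensions has interior fraction
  (1 − n^(−1/d))^d, first order 1 − d·n^(−1/d). The Taylor form is
  clamped to [0, 1] because it goes negative precisely at the small n
  where it is invalid.
- **Fractal**: shares the first-order radial blocked probability; the
  fractal dimension D enters the growth law only.
- **Indicator** (ω = l−1): blocked = 𝟙[n ≥ l], which equals the
  hypergeometric value exactly and yields exponential growth until
  saturation — not logistic growth.

## Growth laws and their validity

`growth_laws` implements the right-hand sides and solutions of the
eight law variants (see README table; plus the second-order expansions
u̇ = λu(1 − u^ω̄(1 + ½σ_ω²(ln u)²)) − δu and
u̇ = −λu(ω̄ ln u + ½(σ_ω² + ω̄²)(ln u)²) − δu). Parameters: λ, δ per
unit time; ω̄ > 0 the mean birth-neighborhood size (need not be an
integer); σ_ω ≥ 0 its standard deviation; d ∈ {2, 3}; fractal dimension
d−1 < D ≤ d with prefactor a > 0. Radial and fractal laws are
integrated in cell count n (their canonical form); density versions are
the n/l rescaling.

Numerics: `solve` uses LSODA at rtol 1e-10 / atol 1e-13. The
generalized-logistic and Gompertz laws also have closed forms (Bernoulli
substitution v = u^(−ω) and w = ln u respectively), which the solver
tests verify by substitution and the fitting pipeline uses for speed and
a smooth objective. The indicator law is handled analytically so growth
halts exactly at u = 1. ε = 1e-30 guards divisions by |ln u| at u = 1.

The two "≫" validity conditions are operationalized as margin ratios
with a configurable threshold (default 10×): the generalized-logistic
condition 2 ≫ σ_ω²(ln u)², and the Gompertz condition
2ω̄/(σ_ω² + ω̄²) ≫ |ln u| — the unique reading under which dropping the
(ln u)² term of the second-order expansion is justified (the margin-≥10
region indeed bounds the term's contribution below 10%, which is
tested). Consequently the second-order forms are only growth laws
inside their validity region; started far below it they can decrease,
which is expected behavior of the expansion, not a bug.

## Spatial statistics

`count_blocked` counts occupied sites whose entire neighborhood is
occupied, via convolution ("wrap" for periodic, zero-padded with
truncated per-site neighborhood sizes for fixed boundaries);
`surface_cells` = n − blocked. The empirical blocked fraction supports
two denominators: lattice size l (the convention of published
lattice-wide estimates) and population n (the per-cell quantity the
theory predicts); they differ by the factor n/l and both are reported
by the CLI rather than silently merged.

The boundary set is defined as occupied cells with ≥ 1 empty
first-order Von Neumann neighbor, independent of the dynamics' birth
neighborhood, so boundary geometry does not depend on the simulated ω.
The fractal dimension is box counting on that set: 8 log-spaced box
sizes from 2 to min(width, height)/6, least-squares slope of
log N(s) vs log s, with the fit R² reported. The scale cap keeps the
coarsest boxes out of the saturated regime and the non-dyadic ladder
averages grid-alignment artifacts; the estimator was calibrated on a
rasterized disc (D = 0.945) and square (D = 1.015) of known dimension
1. It needs ≥ 3 usable scales (lattices ⪆ 20 on a side) and ≥ 2
boundary cells; box-counting on clusters below ~500 cells undersamples
the boundary and reads low, so growth-curve analyses should start once
the cluster passes that size.

## Fitting and model selection

`fit_growth_law` minimizes squared residuals between observed densities
and the law's trajectory started from u(t₀) = the first observation
(trajectory matching, mirroring how confluency curves are used; the
initial condition is pinned, not fitted). λ and ω are searched in
log₁₀ space over bounds λ ∈ [10⁻³, 10], ω ∈ [10⁻³, 50] (δ ∈ [0, 0.1]
when free) from 16 seeded Latin-hypercube starts, refined with
trust-region least squares; the lowest-RSS converged run wins, making
the fit deterministic given its options. δ can be fixed (commonly 0 or
the known simulation value); densities below 10⁻⁶ are clipped with a
logged warning before Gompertz fitting (ln u must exist). Confluency is
standardized to [0, 1] fractions.

AIC uses the least-squares convention n·ln(RSS/n) + 2k with k the free
ODE parameters; a Gaussian-likelihood convention (adds constants and
counts the noise variance) is available behind a flag since fitting
tools differ. The Gompertz/generalized-logistic comparison reports both
the normalized ratio AIC_G/AIC_GL and ΔAIC; AIC is negative for
small-RSS fits, where the ratio's "> 1 means Gompertz better" reading
inverts, so nonpositive-AIC cases are flagged and ΔAIC is the safe
statistic. The two summary regressions are ordinary least squares:
normalized AIC against log₁₀ initial confluence ("log-linear scale"
read as linear response vs log predictor) with per-line slopes, and
ln ω̂ against ln λ̂ with per-group slopes (slope −1, intercept ln C
when the data obey λω = C).

## Synthetic data

`make_invitro_like` emulates a time-lapse confluency panel: each of 7
default lines draws ω log-uniformly from [0.5, 24] and sets λ = C/ω on
the C = 0.1 hyperbola (echoing the observed λ–ω anticorrelation across
real lines and the line-to-line spread of effective neighborhood
sizes); each series integrates the chosen law from its initial
confluence over 50 uniform time points spanning growth to ≈95%
saturation (a typical time-lapse density), then applies multiplicative
log-normal noise (sd 0.02 — confluency measurement noise scales with
the signal; an additive mode exists behind a flag). The cadence,
replicate structure and noise level are stated assumptions of the
generator, not reconstructions of any particular instrument.

`make_abm_dataset` is the in silico analogue: well-mixed ABM runs
(global migration, m·Δt = 1, random-confluence seeding, λ = C/ω with
C = 0.1 and δ = 0.001 by default) over grids of initial confluence and
preset ω, each run long enough (twice the exponential-phase estimate)
to reach saturation. Both generators are exactly reproducible from
their seed.

What the generators do *not* emulate: measurement cadence drift,
plate-edge effects, cell-size or shape heterogeneity, adhesion-driven
clumping, and lag phases. Passing tests therefore demonstrate that the
pipeline recovers the governing law and its parameters under the
model's own assumptions — not that any particular real cell line obeys
them.

## Competition model

Two density-law subpopulations compete for the same space through the
*total* density U = u₁ + u₂ in the inhibition term:

- generalized logistic: u̇ᵢ = λᵢuᵢ(1 − U^ωᵢ) − δᵢuᵢ
- Gompertz: u̇ᵢ = −λᵢωᵢuᵢ ln U − δᵢuᵢ

Total-density coupling is an interpretation (the superposition is ad
hoc): it is the choice under which total confluence grows monotonically
while the subpopulations compete, and it reduces exactly to the
single-population law when one density vanishes. For Gompertz the
coupling uses ln U (not a per-population carrying term) for the same
single-population-limit reason. Outcomes are classified from the final
state of an LSODA integration (rtol 1e-9): subpopulation 2 is extinct
below u_ext = 10⁻⁶, has taken over if u₁ ends below it, else
coexistence; a converged flag reports whether relative drift over the
final 10% of the horizon is below 10⁻⁸. The invasion-boundary scan
classifies a (λ₂, ω₂) grid; with a common death rate each ω₂ column has
a single threshold λ₂*(ω₂), non-increasing in ω₂ — a larger birth
neighborhood buys tolerance for a lower birth rate. Reference study
conditions used in the tests: λ₁ = 0.1, ω₁ = 4, δ = 0.01,
u₁(0) = u₂(0) = 0.01, horizon 10⁴ — the death rate is set high enough
that extinction and takeover resolve within the horizon. The
Gompertz-region-contains-generalized-logistic comparison is stated for
the invader-with-larger-neighborhood regime (ω₂ ≥ ω₁); for ω₂ < ω₁ the
ordering reverses slightly.

## Problem sizes and numerical conventions

Default analysis scales, chosen so every check runs comfortably on one
CPU: well-mixed runs on 64² lattices (the hypergeometric comparison has
sub-percent mean-field bias there), radial and fractal cluster runs on
256² with single-seed initialization, 10-replicate ensembles for
fitted-parameter summaries, and a 4 × 8 (ω₂ × λ₂) competition grid.
The ensemble-mean ABM density is compared against the *discrete-time*
mean-field map u' = u + λΔt·u(1 − u^ω) at the simulator's own Δt: the
continuous ODE is the Δt → 0 limit, and at λΔt = 0.1 the pure
time-discretization gap (per-step factor 1.1 vs e^0.1) reaches ~12%
over a growth phase, an order larger than the ~2% spatial-correlation
residual the comparison is meant to expose.

## Known limitations

- 2D lattices only; no Gillespie (exact-event) mode, nutrient fields,
  adhesion, or off-lattice mechanics.
- The ABM blocked fraction deviates from the hypergeometric model when
  migration is slow relative to birth (persistent mother–daughter
  correlations); the well-mixed comparisons hold in the m·Δt = 1,
  λ ≪ m regime.
- Box-counting dimension is scale-range dependent; values are
  comparable within this package's ladder but not directly against
  estimators with other ranges.
- AIC ratios are sign-fragile for near-perfect fits; use ΔAIC when the
  flag is raised.
- The fitted ω̂ is an effective contact-inhibition parameter, not a
  count of physical neighbors; on noisy data it correlates strongly
  with λ̂ along the λω = C ridge, so the product is estimated much
  more precisely than either factor.
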