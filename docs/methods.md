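# Methods

## Model

The package predicts the clonogenic surviving fraction of cells treated
with a radiosensitizing drug (4-methylumbelliferone, 4-MU) and X-rays as
the product of three independent factors.

**Drug-only survival.** A four-parameter log-logistic
S_P(c) = S_Pmin + (S_Pmax − S_Pmin)/(1 + (c/ED50)^r_P) with S_Pmax
fixed at 1, so untreated cells have unit survival. The numerator is the
standard (max − min) range; with the packaged parameter values
(S_Pmin = 3·10⁻⁴) any alternative reading of the range changes S_P by
less than 6·10⁻⁴ anywhere. The zero-concentration value is taken as the
continuous limit S_Pmax (the power-law expression is indeterminate at
c = 0).

**Targeted kill.** −ln S_T = (α₀ + γβ₀)D + Fβ₀D², the
microdosimetric-kinetic linear-quadratic form. γ is the
frequency-mean specific energy per event for a unit-density spherical
domain, γ = 4ȳ_D/(ρπd²) ≈ 0.20397·y_D/d² with y_D in keV/μm and d in
μm; for y_D = 4.683 and d = 1.0 this gives 0.9553 Gy, within 0.15% of
the tabulated 0.954 Gy that the packaged fixture carries verbatim (the
fixture keeps the tabulated value so downstream numbers reproduce
exactly). The Lea-Catcheside factor
F = 2[(a+c)T + e^−(a+c)T − 1]/((a+c)T)² accounts for sublethal-damage
repair at rate (a+c) (h⁻¹) during a delivery of duration T; it is
evaluated with a second-order series below (a+c)T < 10⁻⁶ to avoid
cancellation, and equals 1 exactly at T = 0.

**Non-targeted kill.** −ln S_NT = δ(c)·(1 − p)p with
p = e^{−(α_b+γβ_b)D − β_b D²} the probability that no cell-killing
signal was activated. The ceiling δ follows an increasing log-logistic
in concentration from δ_min to δ_max, sharing ED50 with the
pharmacology term (a structural assumption of the model, enforced by
construction). Since (1−p)p ≤ ¼, bystander kill saturates at δ/4 —
reached where the activation exponent equals ln 2 — making it an
intermediate-dose effect.

**Exposure conventions.** Internal time is hours and dose rate Gy/h;
the CLI and CSV dialect accept Gy/min (the experimental machine rate,
1.0 Gy/min = 60 Gy/h) and convert. By default an exposure's duration is
dose/dose_rate, so F < 1 even for "acute" survival-curve points
(F ≈ 0.95 for 4 Gy at 1 Gy/min); an explicit `acute=True` forces the
T → 0 limit F = 1. Both conventions are exposed everywhere because the
original analysis does not state which it used; isoeffect results are
reported in both.

## Fractionation

For n identical fractions of d Gy at 24 h intervals, lethal lesions add:
−ln(S_T S_NT) over the course is n times the single-fraction value.
This assumes complete sublethal-damage repair between fractions (24 h ≫
1/(a+c) ≈ 27 min), no proliferation, constant drug level over the
course (δ and S_P held at their concentration values, S_P applied once
per course as a growth-arrest effect, not per fraction).

Because course log-kill is exactly linear in n, the isoeffect fraction
count for a target survival S_c is solved in closed form,
n* = [ln S_P(c) − ln S_c]/λ with λ the per-fraction lesion yield —
exact, so the inverse relation holds to round-off; an iterative
bracketing solve would add nothing. A target at or above the drug-only
survival raises an explicit error (no positive dose is needed). The
ceiling ⌈n*⌉ and its total dose are reported alongside for
integer-fraction scheduling.

## Fitting

**Likelihood.** Gaussian on ln SF. Clonogenic surviving fractions are
ratios spanning decades with approximately multiplicative error, so the
log scale is the natural homoscedastic scale. Per-point standard
deviations come from reported errors by the delta method
(σ_ln = se/SF) when every observation has one; otherwise a single
common σ is profiled out analytically (both reduce parameter
estimation to weighted least squares on log residuals). A fixed-σ mode
exists for analytic tests. The profiled variance is floored at 10⁻²⁴
so noise-free data yield a finite objective.

**Search.** 11 free parameters (S_Pmin, ED50, r_P, α₀, β₀, a+c, α_b,
β_b, δ_min, δ_max, r_δ); S_Pmax = 1 and γ are fixed. Seeded
Latin-hypercube samples over a box (by default a factor of 3 either
side of a reference set; a+c pinned to the literature prior interval
2.18–2.23 h⁻¹) start bounded trust-region least-squares refinements
(scipy `least_squares`, TRF, x-scaled by box widths, tolerances
10⁻¹⁴). Restarts are ranked by exact NLL with ties broken by lowest
restart index, so results are bit-reproducible given (data, config,
seed). A derivative-free polish (Powell) was tried first and could not
reach the optimum reliably on this 11-dimensional surface (errors of
tens of percent on noise-free data); since the MLE is a least-squares
problem in every error mode, the trust-region solver is the appropriate
tool. Standard errors are √diag of the inverse numerical Hessian of
the NLL at the optimum (central differences); an optional random-walk
Metropolis sampler over the same bounded box is provided for posterior
uncertainty but is not the default path.

**Fit quality.** The size-adjusted determination coefficient
R² = 1 − [Σ(exp−cal)²/(n−m−1)]/[Σ(exp−⟨exp⟩)²/(n−1)], computed on the
linear survival scale.

**Identifiability of the 37-point design.** The emulated design has
only three nonzero dose levels (2, 4, 10 Gy). On such a design the
model possesses an almost exact ridge: the affine family
δ′(c) = a·δ(c) + b preserves the sigmoid's functional form (same r_δ
and shared ED50), a proportional rescaling of the activation curve
g(D) = (1−p)p can match three dose points via (α_b, β_b), and the
leftover b·g(D) at three doses is absorbed by (α₀, β₀, a+c). In
practice a parameter set with α₀ off by 3.4%, a+c by 1.3% and δ_min by
2.6% reproduces all 37 noise-free log-survivals to 2·10⁻¹⁵. Individual
recovery of every parameter from this design is therefore not a
guaranteed property of any optimizer; what is identifiable — and
tested — is reproduction of the data to numerical precision and tight
recovery of ED50, r_P, S_Pmin and the bystander activation
coefficients. At 10% noise the quasi-ridge widens: the total linear
kill coefficient α₀ + γβ₀ shows median errors near 30% across
replicates (fixing a+c does not cure it, so the culprit is the
targeted-vs-bystander low-dose trade-off, not repair-rate freedom).
This is consistent with the large published fitting errors on α₀
(±53% relative) and β_b (±56%). Users fitting richer designs should
add dose levels between 4 and 10 Gy, where the bystander term turns
over while the LQ term keeps curving.

## Synthetic data

The generator evaluates the model at each design condition and applies
mean-corrected multiplicative lognormal noise
(factor e^{σZ − σ²/2}, σ² = ln(1+cv²)), clipping into (0, 1]; cv
defaults to 0.1, a typical replicate-level spread for clonogenic
assays. Reported per-point standard errors are cv·SF. Draws are keyed
by (seed, condition index) sub-streams, so datasets are reproducible
and a design extension reproduces its prefix.

The packaged 37-condition design reconstructs the published experiment
as 12 drug-only concentrations (0–500 μM) + the 4×3 dose-response grid
(0/2/4/10 Gy × 0/80/100 μM) + 13 concentrations at 4 Gy (including 20
and 200 μM). Only the three sub-experiments, their ranges and the
37-point total are documented in the source; the per-part counts are a
labelled reconstruction. What a green test on synthetic data
establishes is internal consistency (generator → fitter → statistics);
it does not establish that real assay error is lognormal with constant
cv, nor that plating-efficiency normalization artifacts are absent.

## Numerical choices

* All survival arithmetic in log space; products of factors never
  underflow even at n ≈ 40 fractions of 10 Gy.
* Sigmoids evaluated via exp/log with the c = 0 limit handled exactly
  (δ → δ_min, S_P → S_Pmax).
* 1 − p computed as −expm1(−e) to preserve precision at small doses.
* Isoeffect ⌈n*⌉ computed with a 10⁻¹² slack so an exact integer
  solution is not bumped up by representation error.

## Known limitations

* No proliferation/repopulation between fractions, no inter-fraction
  repair carry-over, no drug washout: course predictions are
  conservative for protracted schedules.
* γ is an input (from upstream microdosimetric simulation), not
  computed from beam spectra.
* The isoeffect doses computed from the published rounded parameter
  means do not exactly reproduce the published course doses; δ(80 μM)
  in particular sits on the steep flank of the r_δ ≈ 8.8 sigmoid, where
  rounding of ED50/r_δ moves the prediction by tens of percent.
  Both protraction conventions are reported rather than tuned.
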