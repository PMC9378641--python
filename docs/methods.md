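# Methods

## The attribution framework

Each bulk land carbon pool is treated as a single box,

    dC/dt = INPUT − C/τ,

where τ is the bulk turnover time. Specialised to the two pools the
package analyses:

    dCv/dt = NPP − Cv/τ_v          (vegetation)
    dCs/dt = f_vs − Cs/τ_s         (soil system = soil + litter + CWD)

Annual diagnostics are computed from model output alone:

    τ_v  = Cv / (NPP − ΔCv)
    τ_s  = Cs / Rh
    f_vs = ΔCs + Rh

with ΔC the backward annual difference (forward at the first year).
Non-positive denominators are flagged missing (NaN), never clamped:
clamping would silently bias every downstream term.

Assuming ΔC ≈ 0 relative to the fluxes gives the steady-state
approximation Ĉ = input·τ. The change in Ĉ between a reference year
(default 1959) and an end year (default 2020) splits exactly into

    input term        Δinput · τ_ref
    turnover term     input_ref · Δτ
    interaction term  Δinput · Δτ

whose sum is ΔĈ = input_end·τ_end − input_ref·τ_ref. Because the
steady-state, single-box view does not capture the actual simulated
change ΔC, the residual δ = ΔC − ΔĈ is redistributed over the three
terms in proportion to their absolute magnitudes, so the adjusted terms
sum to ΔC exactly. When all three terms are zero the whole residual is
assigned to the input term — the only degenerate rule that preserves the
sum identity without inventing a turnover signal.

Endpoint values are single-year by default (the equations taken
literally); an optional centred averaging window (`endpoint_window`) is
provided because single-year endpoints are volatile under interannual
noise. The window changes the terms but never the sum identities.

## Driver decomposition

With the factorial scenario set — S0 (all forcings fixed/recycled), S1
(+CO2), S2 (+climate), S3 (+land use) — driver components telescope:

    CO2 = S1−S0,  CLIM = S2−S1+S0,  LULCC = S3−S2,  ALL = S3.

The CLIM combination is implemented literally as S2−S1+S0 (S0 re-added),
which is what makes the three components telescope exactly to S3.
Per-driver process terms are computed by attributing each scenario
independently and telescoping the term tables. This construction was a
genuinely open design choice (one could instead attribute differenced
diagnostics); it is the only one that guarantees both closure identities
simultaneously — within each driver the adjusted terms sum to that
driver's ΔC, and drivers sum term-by-term to ALL.

A land-use forcing artefact around 1960 is handled by replacing the
1959–1961 values of the LULCC component with the mean of the 1958 and
1962 values. The correction is applied to the S3−S2 difference series
(where the artefact lives) by default; it is idempotent and touches only
the three named years, and it intentionally breaks telescoping closure
inside that window.

## Uncertainty

Ensemble summaries are mean ± sample standard deviation (n−1; the
ensembles of interest are small, so the sample convention is used
throughout). The spread of ΔĈ is decomposed one factor at a time over
the four factors (baseline input, Δinput, baseline turnover, Δturnover):
for each factor, ΔĈ is recomputed per model with that model's own factor
value and the multi-model mean of the other three, and the standard
deviation of the results is that factor's contribution. The substitution
is applied in the factor's own slot of the bilinear form, including its
slot in the interaction term. The one-at-a-time ΔĈ is not δ-adjusted:
the decomposition addresses the steady-state estimate itself. Identical
inputs are reported as exactly zero spread rather than the round-off
residual of a mean subtraction.

Model agreement masks count the majority sign fraction
max(#positive, #negative)/n, with zeros counting toward n but toward
neither sign (a conservative choice that stipples all-zero cells);
stippling marks fractions below 0.8.

## The toy ensemble

The synthetic generator emulates a TRENDY-style multi-model ensemble:
one vegetation pool, an optional litter pool and one soil pool per
model, run from an analytic pre-industrial steady state under shared
forcing with per-model structural parameters.

Forcing (defaults): years 1901–2020; CO2 a monotone quadratic ramp from
280 to 415 ppm; temperature anomaly a linear trend of 0.01 K yr⁻¹ from
1921 plus shared Gaussian noise of σ = 0.1 K (noise lives only in the
climate forcing and is shared across models, mirroring common-forcing /
different-structure ensembles); agricultural fraction piecewise-linear
through 0.15 (1901), 0.25 (1960), 0.30 (2020). The recycled-climate
variant used by S0/S1 tiles the first 20 years of the anomaly series,
which are trend-free by construction.

Model structure: NPP = npp0·[(1−f_ag)+f_ag·ρ_ag]·(1+β ln(CO2/CO2_ref))·
(1+γ·T); vegetation turnover blends natural and agricultural values by
area, τ_v_eff = (1−f_ag)·τ_v,nat + f_ag·τ_v,ag; land clearing removes
λ_lu·max(Δf_ag,0) of the standing biomass, a fraction p_atm straight to
the atmosphere, the rest into the soil system; soil turnover responds to
warming as τ_s = τ_s0·q10^(−T/10); a litter pool (turnover τ_lit) passes
a fraction ε_lit of its outflux to the soil and respires the rest.

Numerics: annual steps (Δt = 1 yr) with backward-Euler pool decay — the
outflux of year t is evaluated on the end-of-year stock reported for
year t, with the clearing flux evaluated on the start-of-year stock.
Stocks are reported as end-of-year values and fluxes as within-year
totals, so mass balance ΔCv+ΔClit+ΔCs = NPP − Rh − p_atm·E_lu = NBP
holds to machine precision every year, and the diagnosed τ equals the
prescribed τ exactly on single-pool configurations (this self-consistency
between the reported stock/flux pairs and the C/outflux diagnostic is
the reason for the implicit scheme; an explicit scheme leaves an O(Δt)
gap between the two). Spin-up is replaced by closed-form initialisation,
so the S0 control carries no drift. A pool driven negative aborts with a
diagnostic rather than being clipped.

Default parameter ranges (uniform, independent per model): npp0 ∈
[45, 65] PgC yr⁻¹, β ∈ [0.3, 0.7], γ ∈ [−0.02, 0.02] K⁻¹, τ_v,nat ∈
[8, 25] yr, τ_v,ag ∈ [1, 4] yr, τ_lit ∈ [2, 6] yr, τ_s0 ∈ [15, 40] yr,
q10 ∈ [1.5, 2.5], ρ_ag ∈ [0.5, 0.9], ε_lit ∈ [0.3, 0.7], λ_lu ∈
[0.5, 1.5], p_atm ∈ [0.4, 0.8]. These produce an 18-model ensemble
whose net stock changes, driver splits and spread have a realistic
qualitative character (vegetation gains of a few tens of PgC dominated
by the CO2 input term, partially offset by land-use losses; a recent
decadal net sink around 1.5 PgC yr⁻¹). Pool-availability flags are
sampled with P(litter) = 0.85, P(CWD | litter) = 0.3,
P(litter-inside-soil | litter) = 0.2; CWD and the inside-soil convention
only exist for models with a litter system, since a three-pool toy has
no other donor flux for them. When a model reports CWD, 30 % of the
litter pool is labelled cCWD (a reporting split; the dynamics have one
litter pool).

What the toy does and does not emulate: it reproduces the structural
features the attribution method keys on — heterogeneous baselines and
sensitivities, factorial scenario nesting, mass-conserving budgets,
litter/CWD availability differences, and false-priming (rising inputs
shift soil-system mass toward the fast litter pool and lower the
diagnosed aggregate τ_s with pool-level rates fixed). It has no spatial
structure (regional series are fixed shares of the global one, which
makes regional-linearity checks exact by construction), no nitrogen
cycle, fire, permafrost or demography, no sub-annual dynamics, and no
intent to emulate any particular named model. Passing tests therefore
demonstrate the correctness and the closure properties of the
attribution machinery, not the realism of any particular DGVM.

The S0-steadiness checks run under noise-free forcing (σ = 0): with
shared climate noise and γ ≠ 0 a recycled-climate control legitimately
fluctuates at the per-mille level, which is a property of the forcing,
not of the numerics the check targets.

## Presentation operators

Time-series smoothing is an order-4 (piecewise-cubic) penalized
smoothing spline with a second-derivative penalty: smoothing → 0
interpolates, smoothing → ∞ tends to the ordinary least-squares line;
the penalty defaults to generalized cross-validation. "Order 4 = cubic"
is the standard B-spline convention; a quartic-piece option (order 5)
exists for the other reading. Local regression is a tricube-weighted
local linear fit over the span-nearest neighbours (local linear rather
than quadratic — the conservative default). Period statistics are simple
means and OLS slopes versus year; acceleration is operationalised as the
OLS slope over the later period. Driver-dominance composites map each
driver's share of the total absolute change to a colour channel
(CLIM → red, CO2 → green, LULCC → blue) with alpha = min(1, |net|/scale);
the channels are invariant to common rescaling and sum to one wherever
any driver acts.

Default problem sizes — 18 models × 4 scenarios × 120 forcing years —
run the whole pipeline in a few seconds; they are the ensemble size and
study period the analysis is designed around.

## Known limitations

- Bulk two-pool attribution cannot separate false-priming from true
  turnover change; the soil turnover term mixes both by construction.
- The vegetation turnover time in the toy responds only to land use, so
  climate-driven τ_v signals are absent from the synthetic ground truth.
- The proportional δ-adjustment is an assumption, not an identity: it
  preserves sums but allocates the steady-state mismatch by term
  magnitude, which is only one defensible convention.
- Regional aggregation before diagnosis (the default) and per-cell
  diagnosis followed by aggregation are not equivalent for nonlinear
  diagnostics like τ; the package computes diagnostics on whatever
  series it is handed.
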