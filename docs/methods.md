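# Methods

## Model

A *B. thuringiensis* batch culture is described by four concentration
variables: biomass `X`, poly-β-hydroxybutyrate `PHB`, dipicolinic acid `DPA`
(the endospore proxy) and Cry protein, all in g/L against hours since
inoculation. Production of each compound is an asymmetric Gompertz sigmoid
`G(t; A, μ, t_c) = A·exp(−exp(−μ(t − t_c)))`; `t_c` is the inflection time,
where the curve passes `A/e` and the slope peaks at `μA/e`. Biomass and PHB
carry additional consumption terms coupled through constant yield
coefficients:

- `X(t) = G_x(t) − DPA(t)/Y_DPA/X` — vegetative cells are consumed as
  endospores (measured by DPA) form;
- `PHB(t) = G_p(t) − DPA(t)/Y_DPA/PHB − Cry(t)/Y_Cry/PHB` — PHB is the carbon
  and energy source for the two parallel sporulation products;
- `DPA(t) = G_d(t)` and `Cry(t) = G_c(t)` are plain sigmoids.

The model is algebraic (no substrate state variable, no ODEs): each curve is
an explicit function of time, and the coupling is through shared terms, not
through dynamics.

**Negativity.** The two-term expressions are not positivity-constrained: with
realistic parameter sets the biomass and PHB expressions go below zero late
in the culture (all cells sporulated, all PHB spent). Evaluation functions
default to the faithful unclamped equations; an opt-in clamp reports
negatives as 0 and flags the affected points. The clamped form is what an
assay would measure and is what the data generator uses.

## Synthetic data generator

The generator emulates the validation study's design. Defaults:

| quantity | default | rationale |
|---|---|---|
| sampling grid | 0–20 h every 2 h | batch cultures sampled every 2 h to ~85–90% endospore release |
| noise | multiplicative Gaussian, sd 5% | concentrations span two orders of magnitude (biomass ~13 g/L vs DPA ~0.16 g/L); additive noise of any single scale would drown the small compounds. Assay noise magnitudes are not reported; 5% is a declared assumption of typical wet-chemistry scatter |
| replicates averaged | biomass 1, DPA 2, PHB 4, Cry 4 | the study's counting/duplicate/quadruplicate assay structure |
| detection limits (g/L) | biomass 0.01, PHB 0.05, DPA 0.01, Cry 0.02 | chosen so the published "not detected" windows reproduce under F1–F4 (PHB absent ≤ 6 h; DPA/Cry absent ≤ 10–14 h) |

Per time point, `replicates` draws `value·(1+ε)` are averaged, negatives are
clamped to 0, and averages below the compound's detection limit are recorded
as exactly 0 and flagged censored (averaging precedes censoring, as in the
assays). Identical seeds give bitwise-identical series; per-fermentation
seeds are spawned from the study seed via `numpy.random.SeedSequence`.

What the generator does **not** emulate: substrate depletion, pH/dissolved-
oxygen excursions, autocorrelated drift, assay-specific bias, or endospore
counts as a channel separate from DPA. Passing recovery tests therefore shows
the estimator works when the model family and noise model are correct — not
that the model is correct for any particular real culture.

## Estimation

Parameters are estimated by nonlinear minimum sum of squares between
predicted and measured concentrations, using scipy's damped trust-region
least-squares (`least_squares`, TRF) with non-negativity bounds on
asymptotes, rates and yields; critical times are unbounded. Tolerances
default to 1e−8 (step and residual), 1000 function evaluations; the package
default seed for anything stochastic is 20141114.

**Observation model.** Residuals compare the observation to the *reported*
model value: raw predictions are clamped at 0 and, when the series carries
known detection limits, values below a compound's limit are reported as 0 —
the same operator the assay applies to the true concentration. Without this,
censored points included as zeros drag fitted curves below their detection
window and bias asymptotes low. Censored points can instead be dropped
entirely (`censoring_policy="exclude"`), at the cost of losing the early
time anchors.

**Staged strategy** (default) exploits the model's triangular structure:
(1) DPA and Cry are fitted as independent sigmoids; (2) the biomass triple
and `Y_DPA/X` are fitted with the fitted DPA curve inserted; (3) the PHB
triple, `Y_DPA/PHB` and `Y_Cry/PHB` are fitted with both fitted curves
inserted. **Joint strategy** refines all fifteen parameters in a single
least-squares problem initialized from the staged solution; because the
optimizer is monotone in cost, the joint total SSE never exceeds the staged
one.

**Initialization** (data-driven, per sigmoid): asymptote ← maximum observed
value; critical time ← midpoint of the steepest finite-difference interval;
rate ← `e·max_slope/asymptote` (from the Gompertz max-slope identity
`slope_max = μA/e`); yields ← ratio of terminal product to terminal consumed
amount, with fixed fallbacks when the consumed estimate degenerates.

**Degenerate inputs.** Series need ≥ 4 finite, non-constant observations per
fitted compound; a failing stage (e.g. constant-zero Cry) is recorded by
name, leaves a flat-zero placeholder curve, and marks the result
non-converged while the remaining stages complete.

## Identifiability at the study's sampling density

On a 2-h grid over 20 h the biomass block (triple + `Y_DPA/X`) and the DPA
triple are well identified in all four bundled parameter sets, and the PHB
and Cry triples are identified wherever the curve substantially completes
within the horizon (F2–F4). Two structural limits remain, verified by
simulation at the default design:

- **PHB-consumption yields.** The PHB series offers only ~4 informative
  (uncensored, unclamped) points against the five parameters of its
  equation, and the DPA and Cry consumption terms are nearly collinear over
  the observed window. Many (`G_p`, `Y_DPA/PHB`, `Y_Cry/PHB`) combinations
  reach indistinguishable SSE at R² ≈ 0.99, so these yields scatter over
  tens of percent and are not meaningfully recoverable from a single
  fermentation at this sampling density.
- **F1's Cry block.** With `μ_c = 0.20 1/h` and `t_cc = 14.9 h` the F1 Cry
  curve reaches only ~70% of its asymptote by 20 h; the asymptote is an
  extrapolation and its estimate is biased low by several percent.

Fit *quality* is unaffected (every compound fit stays above R² 0.90 —
typically ≥ 0.97); the limits concern parameter interpretation, not curve
description. Recovery tests assert the identifiable set.

## Derived analyses

- **Unit conversion:** counts → biomass via 2.3 pg per cell
  (`count · 2.3×10⁻¹² g · 10³ cm³/L`).
- **Percent dry weight:** `100·compound_max/biomass_max`.
- **Phase timing:** culture phases are reported as closed-form onset times
  `t = t_c − ln(−ln f)/μ` of the production sigmoids at onset fraction
  `f = 0.05` (5% of asymptote): biomass onset ends the lag phase, PHB onset
  ends vegetative growth, DPA onset marks sporulation. The 5% fraction is a
  reproducible stand-in for the descriptive phase calls made from data; it
  places the F1–F4 onsets inside the observed 3±1 h / 7±1 h windows, and the
  three boundaries are ordered for all four presets. At `f = 1/e` the onset
  reduces to the critical time.
- **Stoichiometric yield ceiling:** with every substrate carbon routed to
  biomass and no CO₂, the maximum biomass-per-substrate yield is the ratio
  of C-mol masses — 24.626/30.026 ≈ 0.820 g/g for generic biomass
  CH₁.₈O₀.₅N₀.₂ on glucose (CH₂O per C-mol), using IUPAC atomic masses
  rounded to 3 decimals (declared once in `fermentation_analysis`). Measured
  yields above a supplied ceiling are classified `exceeds` (the bound is
  closed): an aerobic culture reporting more biomass per gram of glucose
  than the carbon balance allows was not glucose-limited.
- **Cross-fermentation analyses:** series from heterogeneous sources are
  made comparable by max-scaling each compound to [0, 1] (per-series
  division by the compound maximum; idempotent; an optional flag also
  rescales time by the time of the maximum). Parameters are regressed on
  initial glucose by OLS with Pearson r and a two-sided t-test; with only
  four fermentations results carry a `small_n` flag and no multiple-testing
  correction is applied (three pre-named responses). Yield trends use
  Spearman rank correlation, which is exact (±1) for the bundled sets and
  invariant to monotone transforms; tied glucose values are rejected rather
  than averaged.

## Problem sizes

Tests and the acceptance script run the study at its native size: 11 time
points per series, four fermentations, 20 replicate noise studies for
recovery medians (80 staged fits, a few seconds in total).

## File formats

Kinetics tables are comma-separated, dot-decimal, UTF-8 with the fixed
header `time_h,biomass_g_per_l,phb_g_per_l,dpa_g_per_l,cry_g_per_l`; a JSON
sidecar `<file>.limits.json` records detection limits so censoring survives
a round-trip. Parameter sets are flat `key = value` configs with keys
mirroring the standard nomenclature (`x_max`, `mu_max`, `t_c`, …,
`y_cry_phb`, optional `glucose_g_per_l`, `soybean_g_per_l`, `label`); floats
are written with `repr` so round-trips are bitwise lossless, and unknown or
missing keys are rejected by name.
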