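# Methods

This note documents the models implemented in `photophys`, the assumptions
behind them, the synthetic-data generators used to validate every
estimator, and the numerical choices that were genuinely open.

## Fluorescence

The four PAM levels (F0, Fm dark-adapted; F′, Fm′ under actinic light)
enter the standard definitions Fv/Fm = (Fm − F0)/Fm,
ΦPSII = (Fm′ − F′)/Fm′ and NPQ = Fm/Fm′ − 1. Physically inconsistent
inputs (F0 > Fm, F′ > Fm′) are flagged invalid rather than clamped, so
downstream code must confront instrument artefacts explicitly.

Relative electron transport is rETR = ΦPSII·E with no absorptance or
PSII-fraction factor: any constant multiplier cancels both in
Ek = rETRmax/α and in all between-line comparisons, which is what the
"relative" prefix buys.

Rapid light curves are fitted with the Webb saturating exponential
rETR(E) = rETRmax·(1 − e^(−αE/rETRmax)), chosen over forms with a
photoinhibition term because the measurement protocol extends the
irradiance ladder only until the saturation plateau and because Ek is then
exactly rETRmax/α (the result object stores Ek as the quotient, making the
identity exact by construction). Fitting is unweighted least squares on
rETR (not ΦPSII), initialised with α from the three lowest-irradiance
points and rETRmax from the raw maximum (also logged, since raw-max and
fitted-asymptote conventions coexist in the literature; this package
reports the fitted asymptote). A fit whose estimated Ek exceeds the
largest measured irradiance is flagged `unsaturated`.

## Electrochromic shift

The linear ECS component is separated from the cytochrome redox signal by
the fixed linear combination Cyt c = [554] − 0.4·[520] − 0.4·[563],
ECS_lin = [520] − 0.25·Cyt c, applied pointwise. Downstream quantities:

* **Flash amplitude** — a single exponential fitted over a 1–20 ms
  post-flash window and back-extrapolated to the flash time, minus the
  50 ms pre-flash baseline mean. Back-extrapolation removes the downward
  bias a raw peak reading inherits from the decay rate; if the decay fit
  fails the mean over the first quartile of the window is used and the
  result flagged `windowed`. Window lengths are engineering choices (no
  protocol standard exists); they are parameters of `flash_amplitude`.
* **PSII:PSI stoichiometry** — with PSII charge separation poisoned
  (DCMU + hydroxylamine) the flash amplitude counts one charge per chain
  from PSI alone; the control-minus-inhibited difference is the PSII
  contribution, and the ratio of the two is the functional reaction-centre
  ratio. A control amplitude below the inhibited one is an error, never
  silently clamped.
* **Electron flow** — ordinary-least-squares slopes of ECS_lin over 200 ms
  windows ending at / starting after a light-to-dark transition; the slope
  difference divided by the single-charge amplitude gives e⁻ s⁻¹ chain⁻¹.
  Slopes are taken on the deconvolved component so cytochrome kinetics
  cannot contaminate them.

## Phenotypes

DES = Dtx/(Dtx + Ddx) is computed per replicate and then averaged, the
construction used for figure-level summaries; it is scale-invariant and
bounded in [0, 1], with the all-zero pool returned as missing.

Division rates are the slope of log2(counts) versus time — directly
"divisions per day" — maximised over all contiguous windows of at least
three samples whose fit reaches R² ≥ 0.99; the line-level rate is the mean
over replicates. The R² floor operationalises "during the exponential
phase", which count series do not label; if no window qualifies, the
best-R² window is reported flagged. Successive-interval rates
log2(N_{i+1}/N_i)/Δt are also returned, since interval means are the other
convention in use.

## Photoinhibition

The high-light ± lincomycin experiment is modelled with a two-state
(intact/damaged) first-order balance dD/dt = k_damage·(1 − D) − k_repair·D
during the HL hour, with k_repair = 0 when chloroplast translation is
blocked, plus a sustained-quenching term q(t) that builds during HL and
relaxes toward a residual q_res in dim light; measured relative Fv/Fm is
(1 − D)(1 − q). The +LINC arm is generated with q ≡ 0, folding any
quenching into the damage constant: that arm's printed endpoint is the
*definition* of the damage rate (k = −ln(rel)/t), so the pure exponential
keeps the generator and the estimator exactly consistent. The
decomposition makes no claim to separate sustained quenching from
unrepaired damage in the recovery deficit — both arrive through the same
measured endpoint.

`photodamage_rate` fits ln(rel) through the origin over the HL phase
(exact for the model; reduces to −ln(rel(t_end))/t_end for one point).
`repair_recovery_metrics` reports endpoint percentages: the two arms at
the end of HL (their gap is the decline repair prevented) and the
no-inhibitor arm after recovery.

The packaged scenario's constants are back-computed so the noise-free
model passes exactly through the study's endpoint fractions: a shared
k_damage = −ln(0.30)/60 ≈ 0.0201 min⁻¹ (both arms of every line reach 30 %
under lincomycin), repair constants 0.10 min⁻¹ (WT) and 0.02 min⁻¹
(mutants) chosen as plausible repair half-times of ~7 and ~35 min, and
q_hl/q_res solved from the 52/96 % (WT) and 40/70 % (mutant) endpoints —
leaving mutants with roughly twice the WT's residual quenching, consistent
with a more persistent photoprotective state.

## Proteomics

Preprocessing first drops proteins missing in ≥ 2 replicates of either
comparison group (the strict per-group reading; a per-row-total mode is
available), then rescales each sample column so its total over the
commonly observed proteins equals the grand mean of those totals —
filtering before normalisation makes the operation idempotent. Log2 ratios
are ratios of arithmetic group means of normalised abundances (the
convention of proteome-platform ratio tables); means of per-sample logs
are available behind a flag. Zeros are treated as missing; no imputation.

The ROTS statistic d = |x̄₁ − x̄₂|/(a₁ + a₂·s) uses the pooled-variance
standard error as s, so (0, 1) is the ordinary t statistic and (1, 0) the
plain mean difference. For each candidate (a₁, a₂) and top-list size k,
B bootstrap pairs (replicates resampled within groups) give the expected
top-k overlap, the same construction on group-label-permuted data gives
the null overlap, and the reproducibility Z-score is their difference over
the bootstrap spread; the maximising triple is selected. P-values and FDR
come from label permutations of the selected statistic pooled over
proteins, the FDR being the permutation-expected count of null statistics
above each observed one divided by its rank, monotonised over the ranking.
Defaults: B = 1000 bootstraps, 1000 permutations, a₁ grid 0–5 with a₂ = 1
plus (1, 0), k grid geometric from 25 to half the protein count. A
degenerate zero pooled SD drops the a₁ = 0 grid entries. Seed semantics
are defined on sorted protein/sample ids, making results invariant to row
and column order.

The selection filter keeps proteins significant (FDR < 0.05) in both
mutant lines with the same ratio sign, |log2| ≥ 0.5 in at least one line
(boundary included) and ≥ 2 detected peptides. Fold/percent conversions
are exact exponentiations, with floored-percent and rounded-fold
presentation forms for prose-style reporting.

## Inference

The two-way fixed-effects ANOVA (line × time, crossed) is delegated to
statsmodels OLS with sequential sums of squares — identical to the
orthogonal decomposition when balanced, with a warning otherwise; a
constant response reports F = 0, p = 1 rather than NaN. Dunnett
many-to-one comparisons run within each time point using the pooled
residual mean square: t_i = (mean_i − mean_ctrl)/√(MSE(1/n_i + 1/n_ctrl)),
and the adjusted p is P(max_j |T_j| ≥ |t_i|) under the exact joint null
(independent group means, shared χ² scale — the equicorrelated
multivariate t with ρ = 0.5 when balanced), estimated by seeded Monte
Carlo. At the default 10⁵ draws the standard error on an adjusted p is
below 0.002; the estimate is monotone in |t| by construction and clipped
from below by the raw p. Monte Carlo was chosen over multivariate-t
quadrature for transparency and testability; replicates are treated as
independent (no repeated-measures structure), matching the test actually
applied to such designs.

## Synthetic data

Each generator emulates one assay's statistical structure and emits a
truth record sufficient to score any downstream estimator:

* **NPQ traces** — 3 min dark, 6 min induction, 6 min relaxation, pulses
  every 30 s; NPQ(t) = NPQ_max(1 − e^(−k_ind·t)) then biexponential-with-
  plateau relaxation (fast qE fraction f_fast plus a sustained component,
  reflecting mutants that stay photoprotected); Fm′ = Fm/(1 + NPQ);
  multiplicative Gaussian noise on F and Fm′.
* **Rapid light curves** — the 13-step irradiance ladder from 4 to
  1088 µmol photons m⁻² s⁻¹; ΦPSII = rETR_webb(E)/E capped at Fv/Fm;
  multiplicative noise on the yield.
* **ECS sessions** — true (ECS_lin, Cyt c) components mixed as
  A563 = 0.1·E, A520 = E + 0.25·C, A554 = C + 0.4·A520 + 0.4·A563 (plus
  per-wavelength Gaussian noise), so the published deconvolution is the
  exact inverse; any mixing weights with that property would do — these
  are fixed for reproducibility. Flash traces jump by a₁(1 + PSII:PSI)
  (control) or a₁ (inhibited) and decay exponentially; light-off traces
  are piecewise linear with slope drift and drift − J·a₁.
* **Pigments** — three replicates per line × {0, 0.5, 6, 24, 168 h} with
  unit-mean lognormal noise (standard for concentration-type assays).
* **Counts** — N0·2^(μ(t − lag)) with a hard ceiling at the carrying
  capacity (a logistic blend would bend the exponential window and spoil
  exact noise-free recovery); lognormal noise.
* **HL ± LINC time courses** — the photoinhibition model above, 10-min
  sampling over 0–90 min, two arms per line.
* **Abundance matrices** — per-protein log2 baselines N(μ0, σ_protein);
  a fraction π_diff carry uniform-magnitude effects with configurable sign
  balance and cross-line concordance; replicate noise N(0, σ_rep) on the
  log2 scale; missingness = MCAR plus a logistic intensity-dependent MNAR
  component; peptide counts 1 + Poisson(λ).

Determinism: all generators draw from NumPy's PCG64 via
`default_rng(seed)`, so a (scenario, seed) pair is byte-identical across
platforms. Instrument noise magnitudes are not published for any of these
assays; the packaged defaults (3–5 % CV, 2·10⁻⁵ ΔA) are stated in the
scenario file as this package's choices of realistic magnitudes, not as
literature values.

What passing these tests shows — and does not. The generators reproduce
the assays' noise structure, design sizes and effect magnitudes, so
recovery tests validate the estimators' correctness and calibration under
realistic conditions. They do not emulate instrument drift, chromatogram
or spectral interferences, batch effects, peptide-level quantification
artefacts, or biological covariance between assays; agreement on synthetic
data is therefore necessary, not sufficient, evidence for real-data
performance.

## Problem sizes

Default analyses run at the study's design sizes (3–5 replicates,
1500 proteins, 13-step light curves). Simulation-heavy validation uses
20–200 seeded repetitions per property and B = 200 resamples for
ROTS calibration sweeps, sizes chosen to bound Monte Carlo error on each
asserted quantity well below its test tolerance.
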