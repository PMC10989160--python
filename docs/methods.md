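# Methods

## Pipeline overview

The package analyses nutrient-limitation plate assays in five stages, each
an importable module:

1. **plate I/O** (`plate`, `config`, `cli`) — long-format delimited tables,
   one row per (well, time point); YAML run configuration; subcommands
   chaining the stages.
2. **growth rates** (`growth`) — per-interval log-ratio rates, the
   top-five maximum-rate statistic, and the zero-growth gate.
3. **Monod kinetics** (`kinetics`) — nonlinear fits, derived traits
   (initial slope, R\*), pairwise contrasts with FDR control.
4. **stoichiometry** (`stoichiometry`) — blank-corrected cellular C/N/P
   quotas, molar ratios, N-vs-P trade-off regressions.
5. **synthetic plates** (`simulate`, `studies`) — a generative model with
   known ground truth, plus Monte-Carlo recovery/calibration studies.

## Growth-rate estimation

For a well with fluorescence F at times t (days), the interval rate is
r_i = ln(F_{i+1}/F_i)/(t_{i+1}−t_i). The well's maximum realized growth
rate is the mean of its five largest interval rates, with SE = SD/√k
(k = 5, or all rates when fewer exist; ties at the k-th rate break by
interval order for determinism). Rates and the top-five statistic are
per-well (per replicate); a config switch (`aggregate: per_treatment`)
pools replicate wells' rates first instead.

No blank subtraction is applied to fluorescence before rate computation by
default; `subtract_control_baseline: true` subtracts the time-matched mean
control signal (floored at 10⁻³ RFU) for sensitivity analyses.

**Zero-growth gate.** Treatment wells (pooled across replicates) and media
controls are ln-transformed and fit to straight lines in time; the slope
difference is tested with the pooled-error t statistic — algebraically the
interaction coefficient of ln F ~ time × side — with df = n₁+n₂−4 and a
two-sided p. A treatment is "growing" only when p < α (default 0.05) *and*
the treatment slope exceeds the control slope; a significantly *declining*
signal is not growth. `min_growth_concentration` reports the lowest
gradient level whose treatment passes the gate.

## Monod fitting

μ(S) = μ_max·S/(S+K_s) is fit to the per-replicate top-five estimates
against total substrate concentration by unweighted least squares
(`scipy.optimize.least_squares`, trf). Both parameters are kept positive
by optimizing in log space (effective lower bound 10⁻⁹); starting values
are deterministic: μ_max⁰ = max observed rate, K_s⁰ = smallest S at which
the rate reaches μ_max⁰/2 (median S as fallback). Convergence: ftol 10⁻¹⁰,
at most 500 function evaluations. Per-point SEs are carried but unused
unless `weighting: inverse_variance` is configured. Zero-growth treatments
contribute their measured near-zero rates to the fit rather than being
censored — Monod predicts small positive μ at small S, and censoring would
bias K_s.

The parameter covariance is the Gauss–Newton covariance at the optimum,
s²(JᵀJ)⁻¹ with s² = RSS/(n−2) and J the model Jacobian in natural
parameters. A constant-rate response is reported with a `flat_response`
flag and a warning (K_s unidentifiable).

**Derived traits.** Initial slope = μ_max/(K_s/M) with M the element's
molar mass (N 14.007, P 30.974 g/mol — element basis, matching
concentrations expressed as μg/l of N or P), giving day⁻¹ μM⁻¹. R\* =
K_s·D/(μ_max−D) at dilution rate D = 0.2 day⁻¹ (configurable); undefined
(reported NaN in tables, an error in the scalar API) when μ_max ≤ D.
R\* is a substrate concentration and is reported in μg/l; published tables
sometimes print it under a day⁻¹ heading, which is dimensionally
inconsistent — the numbers themselves are μg/l.

**Contrasts.** For each parameter and pair of strain × state groups within
a nutrient: t = Δ/√(SE₁²+SE₂²), df = n₁+n₂−4 (two parameters estimated per
group; the df convention is a choice — published analyses do not state
one), two-sided p, Benjamini–Hochberg adjustment within one family per
parameter × nutrient. With both SEs zero and a nonzero difference, t is
infinite and p is reported as 0 with a warning.

## Quotas and stoichiometry

Q [fmol/cell] = (conc/M) [μmol/l] ÷ (density×1000) [cells/l] × 10⁹, after
subtracting the per-element mean filter blank (negative corrected values
clamp to 0 with a warning). Technical replicates (2 filters for P, 3 for
C/N) are summarized by mean and SD only — no inferential tests, as they
are not biological replicates. Quotas for microbiome-bearing (xenic)
cultures carry `overestimate_flag = true`: the associated bacteria
contribute particulate mass but only host cells are counted. Trade-off
checks regress each N-limitation trait on its P counterpart (OLS, Pearson
r, two-sided slope p).

## The synthetic generator

A well's latent trajectory is logistic with Monod-dependent rate:
μ = μ_max·S_tot/(S_tot+K_s) with S_tot = S + background_S, carrying
capacity K′ = min(B + q_f·S_tot, K_max), initial value B + F₀ at the end
of the lag (flat before it). Observations are latent × exp(ε),
ε ~ N(0, σ²) per time point. Each well has its own random stream keyed by
(master seed, SHA-256 of the well identity), so adding wells never
perturbs existing wells' draws and identical configurations are
bit-identical.

Defaults are the assay's conditions: the printed N gradient (8.0–30500
μg/l N) or P gradient (1.1–3030 μg/l P) as totals (the lowest level is the
medium background, so `background_S` = 0), triplicate wells, 3 media
controls, daily readings for 25 days (the real cadence was daily; the
duration is a package choice bounded by the published growth-curve axes),
σ = 0.03 (multiplicative noise, since fluorescence error scales with
signal), lag 0.

The fluorescence scale is anchored on quota arithmetic rather than chosen
freely: taking ≈4×10⁻⁴ RFU per cell/ml, the 5000 cells/ml inoculum is
F₀ = 2 RFU over a baseline B = 10 RFU (phycocyanin background is low —
that is why the pigment is used), and one μg/l of element supports
≈2.5×10⁴ cells/ml of P-limited or ≈1.5×10³ cells/ml of N-limited biomass
(quotas ≈1.3 fmol P, ≈48 fmol N per cell), giving yield coefficients
q_f = 100 RFU/(μg/l P) and 0.6 RFU/(μg/l N), with a shared ceiling
K_max = 25000 RFU (≈6×10⁷ cells/ml). With these values yields saturate
within the upper part of each gradient, as in the real assay.

**What the generator does not emulate:** nutrient-starvation physiology
(chlorosis; real cells may fail to grow at background N, while the latent
model grows slowly wherever μ(S) > 0), substrate depletion dynamics (the
logistic is a closed-form stand-in whose early phase matches the
exponential regime the estimator reads), evaporation, position effects,
and microbiome population dynamics (microbiome effects enter only as
shifted kinetic parameters, exactly as the assay measures them). Passing
recovery tests therefore validate the estimation machinery under the
stated noise model, not robustness to these real-world effects.

Quota samples are generated as Q × cells/l × M / 10⁹ with relative error
N(0, cv²) (default cv 0.05), half-normal blanks at 1% of the signal, and
the assay's replicate counts.

## Known limitations and numerical notes

- **Top-five selection bias.** The top-five statistic is an order
  statistic of noisy interval rates: at σ = 0.03 (interval-rate SD
  ≈ 0.042 day⁻¹) it overestimates μ by ≈ +0.02 day⁻¹ (+3–4% at
  μ_max ≈ 0.55) even though the noiseless pipeline recovers parameters
  essentially exactly. Because the fitted SE of μ_max (~0.004) is much
  smaller than this bias, nominal 1.96·SE intervals for μ_max undercover
  badly (≈0% instead of 95%) in end-to-end simulations; the
  200-plate recovery study in `studies.py` quantifies this, and the
  corresponding acceptance test is expected to fail on its coverage
  clause. Medians remain within ±5% (μ_max) and ±25% (K_s) of truth.
  Consumers should treat the reported SEs as describing fit scatter, not
  total error.
- **K_s and carrying capacity.** At low S the logistic ceiling shortens
  the exponential window and depresses measured rates, inflating K_s
  slightly (≈ +7% median for P at the default scale, more for N where
  yields are lower). This mirrors a genuine limitation of batch-plate
  Monod estimation.
- Gate calibration: the direction rule halves the nominal two-sided error,
  so the empirical false-positive rate is ≈ α/2 (~0.025 at α = 0.05);
  power for a 0.3 day⁻¹ slope difference at σ = 0.03 is ≈ 1.
- Degenerate inputs: < 3 points or < 2 distinct S values refuse to fit;
  all-identical times raise a singular-fit error; zero cell density and
  nonpositive quotas/molar masses are domain errors.
- Problem sizes used by the tests and the acceptance script — 200 plates
  for recovery, 1000/500 draws for gate calibration, 500–1000 cases for
  the oracle comparisons — were chosen so the full verification runs in
  well under a minute while keeping Monte-Carlo error small relative to
  the tested bands.
- Out of scope by design: Droop (internal-stores) growth models,
  mixed-effects/gnls variance structures, profile-likelihood intervals,
  vendor binary plate formats, and any 16S/community analysis.
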