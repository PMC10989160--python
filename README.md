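# monodplate

Resource-competition trait analysis for cyanobacterial plate-reader growth
assays: from raw phycocyanin fluorescence time series to Monod kinetics,
R\* competition traits, cellular C/N/P stoichiometry, and FDR-controlled
group contrasts.

## Who this is for

Microbial ecophysiologists running nutrient-limitation assays in
multi-well plates: cultures (here, *Microcystis aeruginosa* strains with
and without an associated heterotrophic microbiome) grown across a gradient
of a limiting element (N or P), tracked daily by pigment fluorescence as a
biomass proxy. The package turns those curves into the trait parameters
used by resource-competition theory and bloom models, and ships a synthetic
plate generator so the whole pipeline is testable against known ground
truth without any external data.

## The model

Specific growth rate as a function of the external limiting-nutrient
concentration *S* follows the Monod equation

μ(S) = μ_max · S / (S + K_s)

with μ_max the maximum specific growth rate (day⁻¹) and K_s the
half-saturation constant (μg/l of the limiting element). From a fitted
curve, two competition traits follow:

- **initial slope** = μ_max / K_s with K_s in μM (day⁻¹ μM⁻¹): affinity at
  low substrate;
- **R\*** = K_s·D / (μ_max − D): the substrate concentration at which growth
  balances a loss rate D (0.2 day⁻¹ by default); the strain with the lowest
  R\* wins equilibrium competition for that resource.

Per-well growth rates are estimated as the mean of the five largest
log-ratio interval rates r_i = ln(F_{i+1}/F_i)/(t_{i+1}−t_i); a treatment
counts as growing only when its pooled ln(F) slope significantly exceeds
the media-control slope (interaction t-test). Cell quotas are
Q = particulate element mass / (molar mass × cell number), reported in
fmol/cell, with molar N:P, C:N, C:P ratios.

## Worked example

```sh
monodplate --seed 1 --out-dir demo simulate --nutrient P
monodplate --out-dir demo report --plate demo/plate.csv
```

`simulate` writes a synthetic 219-well plate (8 cultures × 9 P levels ×
triplicate + 3 media controls, daily readings for 25 days, 3% lognormal
noise) using published strain parameters as ground truth, and `report`
runs rates → gate → Monod fits → derived traits. For the axenic
PCC 7806 ΔmcyB culture (truth μ_max = 0.55, K_s = 3.58) the summary row in
`demo/monod_fits.csv` reads:

```
strain            state   mu_max  mu_max_se  k_s    k_s_se  initial_slope  r_star
PCC 7806 dmcyB    axenic  0.574   0.004      4.078  0.217   4.357          2.183
```

i.e. the pipeline recovers μ_max within ~4% (the top-five statistic has a
small positive selection bias at this noise level — see `docs/methods.md`),
K_s within ~15%, and R\* ≈ 2.2 μg/l P, close to the 2.05 μg/l implied by
the generating parameters. The same library functions are driven
step-by-step by the numbered scripts in `analysis/` (simulate → rates →
fits → quotas → trade-offs → calibration), which write their tables to
`results/`.

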