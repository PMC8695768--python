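# xylokin

Intra-annual wood-formation kinetics from repeated micro-core cell counts.

Monitoring campaigns in plantation forestry sample small wood cores from the
same trees every 7–10 days across a growing season and count, on each date,
the cells in each developmental phase: cambial, radially enlarging,
wall-thickening, and mature. `xylokin` turns those long-format count tables
into the quantities such studies report:

* a **Gompertz growth model with a tree-level random asymptote**, fitted per
  stand by exact marginal (restricted) maximum likelihood:

  $$Y_{ij} = (A + a_i)\,e^{-e^{\beta - k t_{ij}}} + \varepsilon_{ij},
  \qquad a_i \sim N(0, \sigma_A^2),\ \varepsilon_{ij} \sim N(0, \sigma_e^2)$$

  where $Y_{ij}$ is the total cell count of tree $i$ on day-of-year
  $t_{ij}$, $A$ the final cell number, $\beta$ the time placement and $k$
  (per day) the rate parameter;
* the derived **kinetics**: inflection date $t_p = \beta/k$, maximal daily
  rate $r_\mathrm{max} = kA/e$, the 5% and 95% development dates, and the
  average rate between them, $r_m \approx \tfrac{9}{40}e\,r_\mathrm{max}$;
* **cambial phenology**: onset, end, and duration of wood cell development
  per tree (first/last sampling day with enlarging cells), with stand-level
  means and SDs;
* **bimodal extrema**: subtropical and Mediterranean conifers often show two
  within-season activity peaks; LOWESS-smoothed phase trajectories are
  scanned for the first/second maxima and minima (DOY and cell count);
* the **rate vs. duration decomposition** of final cell number: an OLS model
  $Y = \alpha_0 + \alpha_1 x_1 + \alpha_2 x_2$ (rate $x_1$, duration $x_2$)
  plus the LMG relative-importance allocation of its $R^2$, and age-trend
  ANOVA for every seasonal characteristic;
* a **synthetic trajectory generator** (two-pulse Gompertz production,
  residence-time phase differencing, Poisson or rounded-Gaussian noise,
  tree-level asymptote heterogeneity) that emulates a 5-stand × 5-tree
  campaign, so every stage is testable without field data.

It is aimed at dendroecologists and biostatisticians working with
xylogenesis monitoring data, and at anyone needing a tested reference
implementation of these standard analyses.

## Worked example

```python
from xylokin import (bimodal_demo_scenario, generate_study, fit_stand,
                     kinetic_summary, detect_onset_end, stand_phenology)

sc = bimodal_demo_scenario()            # one bimodal stand, 5 trees
df = generate_study([sc], seed=7)       # long-format count table
fit = fit_stand(df)                     # REML Gompertz mixed model
kin = kinetic_summary(fit.fixed)
print(f"A = {fit.fixed.A:.1f} cells (sigma_A = {fit.sigma_A:.1f}), "
      f"beta = {fit.fixed.beta:.2f}, k = {fit.fixed.k:.4f} /day, R2 = {fit.r_squared:.2f}")
print(f"inflection t_p = {kin.t_p:.1f}, r_max = {kin.r_max:.2f} cells/day, "
      f"r_m = {kin.r_m:.2f} cells/day")

recs = [detect_onset_end(g[["doy", "n_enlarging"]], tree_id=t)
        for t, g in df.groupby("tree_id")]
s = stand_phenology(recs)
print(f"onset {s.onset_mean:.1f} ({s.onset_sd:.1f}), end {s.end_mean:.1f} "
      f"({s.end_sd:.1f}), duration {s.duration_mean:.1f} ({s.duration_sd:.1f}) days")
```

prints

```
A = 116.8 cells (sigma_A = 11.1), beta = 1.73, k = 0.0143 /day, R2 = 0.87
inflection t_p = 120.7, r_max = 0.62 cells/day, r_m = 0.38 cells/day
onset 73.0 (6.4), end 298.0 (0.0), duration 225.0 (6.4) days
```

i.e. this simulated stand levels off near 117 cells with moderate
between-tree spread, produces at most 0.62 cells/day around day 121, and
its trees enlarge cells from early March (day 73) to late October (day
298).  (The single-Gompertz fit summarizes a bimodal season, so $t_p$ here
lands between the two production pulses.)

The same pipeline runs from the shell:

```bash
xylokin simulate --preset paper --seed 1 --out observations.csv
xylokin report --input observations.csv --out reports/
# or directly: xylokin report --preset paper --seed 1 --out reports/
```

`report` writes `table2.tsv` (per-stand fits), `table3.tsv` (seasonal
extrema), `table4.tsv` (kinetics + phenology), `table5.tsv` (age ANOVA),
`table6.tsv` (rate+duration regression), `importance.tsv` (LMG shares) and
a `manifest.json` that makes the run byte-reproducible.

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator, the
numerical choices and the known limitations.
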