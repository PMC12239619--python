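# rcsim — stochastic simulation of rapid-cycle genomic selection in maize

`rcsim` is a self-contained simulator for recurrent **rapid-cycle breeding**
schemes: genomic selection on F2 plants with minimal generation interval,
starting from a panel of fully homozygous doubled-haploid (DH) maize
landrace lines. It is aimed at breeders and quantitative geneticists who
want to quantify, by replicated stochastic simulation, how long-term
genetic gain and genetic diversity respond to breeding-program design
choices — updated training sets, introgression of outside material,
optimum-contribution selection, and selection intensity.

## The scheme and the model

Each cycle, 1,035 F2 lines are ranked on gBLUP breeding values and a
three-trait selection index

&nbsp;&nbsp;&nbsp;&nbsp;I = g₁/σ₁ + g₂/σ₂ − g₃/σ₃,

raising plant height at growth stages V4 and V6 while lowering final
height; the top 30 form 15 random pairs whose selfed F1s rebuild the pool.
Six correlated trait dimensions (3 stages × {DH line *per se*, cross
performance}) are controlled by a shared pleiotropic architecture of 500
additive, 500 dominance and 200 epistatic QTLs per trait, with effect
vectors drawn from a multivariate normal with the genetic correlation
matrix. Breeding values are estimated with the standard mixed model

&nbsp;&nbsp;&nbsp;&nbsp;y = 1μ + g + e, g ~ N(0, σ²_g **G**), **G** = ZZ′ / 2Σpₘ(1−pₘ),

with REML variance components and univariate gBLUP per trait. Meiosis is
Haldane (Poisson crossovers, no interference). All gains are reported in
**gSD** units — standard deviations of the true index in the founder
reference cohorts. See `docs/methods.md` for the full model description.

## Worked example

Five baseline cycles at reduced scale (2,000 markers, 3 replicates):

```python
from rcsim import ScenarioConfig, run_scenario, summarize_replicates

cfg = ScenarioConfig(markers_per_chromosome=200, n_cycles=5)
df = run_scenario(cfg, n_replicates=3, base_seed=1, scenario_name="baseline")
s = summarize_replicates(df)
view = s[(s.cohort == "F2") & (s.metric.isin(["gain_index_cross", "het_share", "accuracy_mean"]))]
print(view.pivot(index="cycle", columns="metric", values="mean").round(3))
```

prints

```
metric  accuracy_mean  gain_index_cross  het_share
cycle
1               0.658             1.858      0.108
2               0.550             2.568      0.099
3               0.427             3.252      0.075
4               0.501             3.727      0.066
5               0.469             4.221      0.060
```

Reading the columns: the F2 pool starts ~10.8% heterozygous (the calibrated
landrace starting point), heterozygosity erodes cycle by cycle as selection
and drift fix markers; the mean index of the pool climbs in founder-
referenced gSD units, fastest in the first cycles; and the accuracy of the
founder-trained predictor (correlation between EBV and true genomic value
of the candidates) decays as the population drifts away from the training
set — the core tension of rapid cycling. Scenario variants are plain
config fields: `phenotyping="crosses"` (2-cycle delay) or `"dh"` (200 DH
derivatives, 4-cycle delay) update the training set, `introgression=True`
injects external donors into 20% of matings, `ocs=True,
target_degrees=40.0` switches parent selection to angle-parameterized
optimum-contribution selection, and `n_selected_f2` sweeps selection
intensity.

The same runs from a shell:

```bash
rcsim run --config scenario.yaml --reps 10 --seed 1 --out results/
rcsim sweep --param target_degrees --values 10,20,30,40,50,60,70 \
            --reps 10 --seed 1 --out results/ocs_sweep/
```

writing `metrics.csv` (replicate × cycle × cohort), `summary.csv`
(mean/SD/SE) and a run log.

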