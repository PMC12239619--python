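# Methods

`rcsim` simulates a recurrent rapid-cycle genomic-selection scheme for maize
pre-breeding, from a panel of fully homozygous doubled-haploid (DH) landrace
lines through 30 short breeding cycles of genomic selection on F2 plants.
This note documents the model, its assumptions, the parameters that matter,
and the choices made where the design was genuinely open.

## The breeding scheme

A replicate starts from 409 founder DH lines. The founders are phenotyped
once, gBLUP breeding values are computed on the founders themselves, and the
top 10 lines by selection index enter a half-diallel (45 crosses). Each
cross is selfed to 23 offspring, giving the first pool of 1,035 F2 lines.
Every subsequent cycle:

1. assemble the training set permitted by the phenotype availability delays;
2. fit univariate gBLUP per selection trait (REML variance components via a
   spectral decomposition of the training block of the genomic relationship
   matrix; VanRaden method 1, allele frequencies on the pooled
   training+candidate set);
3. rank the 1,035 F2 candidates on a three-trait index (raise plant height
   at stages V4 and V6, lower final height; equal weights in gSD units);
4. select 30 parents — truncation (with a per-founder cap in cycle 1), or
   angle-parameterized optimum-contribution selection;
5. pair parents at random (15 pairs), optionally replacing one parent in a
   share of pairs with external donor lines;
6. self each pair's single F1 into 69 offspring, restoring a 1,035-line F2
   pool; and
7. extract 10 DH lines from each of the top 3 F2s as the cycle's finished
   product (evaluation only — they do not re-enter the scheme).

One F1 plant per mating is made and selfed (not one F1 per offspring); a
`f1_per_offspring` switch provides the alternative semantics.

## Genome and founders

Ten chromosomes of 1.6 Morgan with evenly spaced biallelic markers (50,000
at full scale; counts are configurable). Meiosis is Haldane: per chromosome
the crossover count is Poisson(length), positions uniform, no interference,
no mutation. DH induction is one meiosis followed by chromosome doubling.

Synthetic founders draw per-marker allele frequencies from a symmetric
Beta(a, a); `a` is solved in closed form so the panel mean expected
heterozygosity E[2p(1−p)] hits a target. The scenario default is 0.218: an
F2 of two random homozygous lines is heterozygous at half the markers at
which its grandparents differ, so the first F2 pool opens at ~10.9%
heterozygous genotype calls — the calibration anchor for the whole study.
The default panel has no linkage disequilibrium and no founder relatedness;
an optional haplotype-block parameter exists for sensitivity analysis. This
is the main respect in which the synthetic panel is simpler than a real
landrace-derived panel, and it matters quantitatively: with independent
markers, gBLUP accuracy at a given marker count is lower at the start and
decays differently than with a structured panel (see Limitations).

## Trait architecture

Three plant-height stages, each expressed as a DH line and as a cross, give
six trait dimensions. Per trait the architecture holds 500 additive, 500
dominance, 100 qualitative-epistatic and 100 quantitative-epistatic QTLs,
sampled without replacement within each (trait, class) from the marker set.
Every QTL is pleiotropic: its 6-dimensional effect vector is multivariate
normal with the genetic correlation matrix, so trait correlations emerge
from shared loci. The default correlation table has heritabilities
0.95/0.95/0.96 (DH) and 0.76/0.77/0.87 (cross); cross-block correlations
between different traits in different variants are completed as
sqrt(ρ_ij^DH · ρ_ij^cross) · ρ_j^(DH,cross) — the square-root form is the
one that reproduces every directly estimated cell of the table within
±0.005 (the plain product does not; a test asserts both facts).

Epistasis semantics are this package's concrete rendering: a qualitative
QTL pays its effect when an ordered locus pair shows one specific genotype
combination (target drawn uniformly from the 3×3 table); a quantitative QTL
is an additive locus whose slope is scaled by 1 + k·(g_B − 1) at a modifier
locus, k ~ N(0, 0.3²) per trait. Class effects are rescaled by one scalar
per class so the classes contribute 65/25/5/5% of genetic variance in the
reference random-cross cohort — "predominantly additive and dominant, a
small amount of epistasis" made concrete; scalar-per-class preserves the
cross-trait correlations.

Values are affinely standardized once per replicate: founder DH variance 1
per DH trait, reference-cross variance 1 per cross trait. All gains are
reported in these gSD units as (cohort mean − reference mean)/reference
index SD; DH traits are referenced to the founder panel, cross traits to
1,000 random founder crosses generated once per replicate. Phenotypes add a
multivariate-normal environmental deviate with variance (1 − h²)/h² per
trait (so h² is defined against the fixed reference variance and stays
constant over cycles) and the environmental correlation below-diagonal of
the default table; deviates are drawn fresh at each phenotyping event.

## Phenotyping strategies and training windows

- **baseline** — only the 409 founder phenotypes, every cycle.
- **crosses** — each F2 pool is phenotyped on the cross-trait variants;
  records become available two cycles later (seed propagation). Training is
  the most recent available 1,035-line cohort. A switch restricts
  phenotyping to the selected lines only.
- **dh** — 200 of the 1,035 F2s yield one phenotyped DH line each,
  available four cycles later; training is the last four available cohorts
  (800 lines). Under introgression the window is 2 internal + 2 external
  cohorts (still 800).

Early cycles without available records fall back to the founder phenotypes
with a logged warning. A replay test asserts that deleting records that are
not yet available never changes a cycle's decisions.

## External introgression

The external pool restarts from the founder panel and persists across
cycles. Each breeding cycle it is advanced by recurrent selection — 200 of
409 lines selected on a weighted own-phenotype index, random pairs, 409 DH
offspring — until its mean true index exceeds the current F2 mean; weights
are re-derived each generation from the per-trait shortfall to the F2 trait
means, which keeps per-trait progress comparable. The generation *before*
the threshold crossing donates: in 20% of matings (configurable) one parent
is replaced by a random donor line. Keeping the pool persistent rather than
regrowing it from the founders every cycle is a design choice; it matches
the pool's bookkeeping (generation counter, threshold generation) and keeps
later cycles affordable.

## Optimum-contribution selection

With equal contributions and each candidate used at most once, the
(gain, group-coancestry) plane is min–max normalized between the truncation
solution (max gain) and a min-coancestry solution found at equal search
budget; the selector maximizes progress from the worst corner along the
direction at `target_degrees` from the gain axis. The metaheuristic is
simulated annealing over subsets with single-swap moves and O(n)
incremental updates (default budget 4,000 moves, geometric cooling
0.25 → 1e-4); 0° returns the truncation set exactly and 90° the
min-coancestry search result. Only the objective geometry is fixed; the
solver is deliberately replaceable, and instances can be exported as plain
text for cross-checking against external optimizers. Mating among the
selected parents is random.

## Numerical choices

- REML profiles the ratio γ = σ²_g/σ²_e on log scale (bounded ±10) against
  the eigendecomposition of the training GRM block, shared across traits.
  Non-PSD training blocks are repaired by minimal diagonal inflation
  (logged). Fewer than 10 training records is an error.
- Genotype storage is uint8 haplotypes (n, 2, M); GRM products inside the
  scheme run in float32 (configurable) — differences against float64 are
  orders of magnitude below replicate noise.
- When training and candidates are completely fixed (no segregating marker
  in the pool), EBVs are defined as zero: prediction carries no signal and
  selection degenerates to stable id order. This occurs in late cycles of
  high-intensity scenarios.
- Offspring-per-pair counts distribute the 1,035-line pool target over the
  pairs: base = floor(1035/pairs), remainder to the first pairs.
- The cycle-1 per-founder cap (10 when 30 F2s are selected) scales as
  ceil(n_selected/3) in selection-intensity sweeps so the cap stays
  feasible; an explicit integer overrides.
- Ties in ranking break by stable line-id order, making runs reproducible.

## Problem sizes used for verification

The shipped acceptance script (`scripts/acceptance.py`) runs every scenario
at 10,000 markers with 12 (baseline) or 6 (alternative scenarios)
replicates; the test suite's scaled block uses 10,000 markers with 6/4
replicates. Marker density was fixed at 10,000 because the decay of
prediction accuracy — the central mechanism of the study — depends on the
ratio of training-set size to effective marker dimension: with too few
markers the few loci left segregating in late cycles are re-estimated
almost perfectly from 409+ training lines and accuracy artificially
rebounds, inflating long-term gains. 10,000 markers is the smallest density
we found that keeps the full-scale trajectory shape; all cohort sizes, QTL
counts, delays and cycle counts are the study's own.

## What passing tests do and do not show

The synthetic-founder study conditions reproduce the full-scale headline
gains for the training-update and introgression scenarios closely, and the
baseline within about 20–25%. Three quantities are systematically off at
desk scale, and the corresponding checks are expected to stay red rather
than being loosened:

- diversity retention: the no-LD founder panel with a strongly U-shaped
  frequency spectrum fixes markers faster than a structured landrace panel;
  the baseline F2 pool reaches essentially complete fixation by cycle
  ~25 instead of retaining ~26% of its genetic SD;
- consequently the measured diversity-loss and fixed-share figures overshoot
  the published 74% / 94.3%;
- diversity-preserving interventions (angle-40 OCS, relaxed selection
  intensity) are worth more in this harsher world than the published +9%/+7%
  — they rescue a baseline that would otherwise fix completely.

Conclusions about real panels therefore rest on the relative ordering of
scenarios (which the simulation reproduces: cross phenotyping ≈ doubling
gain, introgression + phenotyping largest, OCS a strict improvement over
truncation), not on absolute diversity percentages.

## Known limitations

No founder LD or relatedness by default; no mutation; no crossover
interference; no genotype-by-environment interaction or multi-environment
trials; no inbreeding depression or DH-induction failure; one gene pool
(cross performance is modelled as correlated trait variants of the same
genotype, not via a tester genome); trait architecture constant over time.
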