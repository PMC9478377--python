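# mpcommunity

Community-ecology statistics for soil microplastic (MP) surveys.

Regional MP surveys record, per soil sample, a list of particles each
characterised by size class (<0.5, 0.5–1, 1–2, 2–5 mm), shape (fiber,
pellet, fragment, foam, film), colour (white, black, transparent, blue,
other) and polymer type (rayon, PE, PP, PP+PE, PET, polyester, acrylic,
PS, PA).  Treating those attribute counts like a species community lets
the standard microbial-ecology toolkit answer the questions such surveys
ask — do MP communities differ between regions?  which MP types
characterise each region?  what environmental factors co-vary with MP
abundance? — and this package implements that toolkit end to end for
people analysing paddy-soil (or any soil) MP data:

- **Community matrices** from per-particle tables, in an
  *attribute-union* encoding (one feature per shape/colour/polymer
  level; each particle contributes one count per attribute family) or an
  *attribute-triple* encoding (one feature per observed combination).
- **Diversity.**  Gini–Simpson index `1 − Σ pᵢ²` per attribute family
  and the composite MP diversity index
  `MDII = (Simpson_shape · Simpson_color · Simpson_polymer)^{1/3}`,
  plus the Chao1 richness estimator
  `S_obs + f₁²/(2f₂)` (bias-corrected `S_obs + f₁(f₁−1)/(2(f₂+1))` when
  `f₂ = 0`) for companion 16S OTU tables.
- **Community inference.**  Bray–Curtis dissimilarity
  `d(i,j) = 1 − 2Σₖ min(xᵢₖ,xⱼₖ)/(Σₖxᵢₖ+Σₖxⱼₖ)`; Clarke's ANOSIM
  `R = (r̄_B − r̄_W)/(M/2)` with permutation (or exhaustive) p-values;
  two-matrix and pairwise-region Mantel tests; LDA ordination with
  per-axis explained variance.
- **Marker discovery.**  LEfSe-style two-stage screen: per-feature
  Kruskal–Wallis (mid-rank tie correction, exact enumeration for small
  n) followed by a bootstrapped linear-discriminant effect size on a
  log₁₀ counts-per-million scale.
- **Association screens.**  Spearman rho/p/BH-q matrices
  (pairwise-complete), simple OLS regression, one-way ANOVA with
  Duncan's multiple range letters (studentized-range quantiles computed
  from the distribution, protection level `αₚ = 1 − (1−α)^{p−1}`), and
  Welch/pooled t-tests.
- **Synthetic surveys.**  A generator emulating a five-region ×
  two-depth × three-replicate design with planted, recoverable effects
  (regional community shift, abundance–population slope,
  Chao1–abundance association, soil-ratio correlation), used by the
  tests to verify every statistic against known ground truth.

## Worked example

```python
import mpcommunity as mpc

config = mpc.PipelineConfig(outdir="pipeline_out", seed=42, n_permutations=999)
bundle = mpc.run_pipeline(config)
print(mpc.render_report(bundle))
```

prints (abridged):

```
MP abundance: mean 6,433 +/- 1,696 items/kg (range 4,300-11,900, n=30)

Abundance by region with Duncan letters:
    0-20 cm  HN:    10,000 items/kg  a
    0-20 cm  DB:     7,233 items/kg  b
    ...
ANOSIM (region groups): R=0.493, p=0.001 (monte-carlo, 999 permutations, seed=42)
LDA ordination explained variance: LD1 64.60%, LD2 28.17%
LEfSe discriminant features (6):
              polymer:PE -> DB (LDA 4.86, KW p=0.00389)
             color:black -> HE (LDA 4.78, KW p=0.0104)
    ...
Abundance ~ population: R=0.651, p=9.86e-05, slope=4.87 items/kg per 1e4 persons (n=30)
```

Read: MP abundance averages ~6,400 items per kg of dry soil and differs
among regions (groups not sharing a Duncan letter are separated at
α=0.05); regional MP communities are significantly distinct (ANOSIM
R=0.49 on Bray–Curtis distances, permutation p=0.001), mostly along two
discriminant axes; LEfSe recovers the community markers the generator
planted (PE in DB, black in HE, rayon/blue/other in HN); and abundance
rises with population quantity.

The `examples/` directory holds one short script per capability
(simulation, diversity, ANOSIM/LDA/Mantel, LEfSe, association screens,
full pipeline).  A thin CLI mirrors the pipeline:
`mpcommunity run-all --out run1 --seed 42`, with subcommands
`simulate community diversity anosim lda lefse mantel correlate anova
report` for individual stages.

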