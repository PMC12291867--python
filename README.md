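# betadrivers

Beta-diversity patterns of river macroinvertebrate communities and
their drivers: who replaces whom along a river network, and how much of
that turnover is carved by land use and water quality versus left to
chance.

The package implements, as one tested pipeline, the analysis chain used
in regional monitoring studies of benthic macroinvertebrates:

1. **Beta-diversity partitioning** — pairwise and multi-site Sørensen
   (`β_sor = β_sim + β_nes`) and Bray–Curtis
   (`d_BC = d_BC-bal + d_BC-gra`) dissimilarities, each split additively
   into a turnover/balanced-variation and a nestedness/abundance-gradient
   component.
2. **Landscape drivers in circular buffers** — land-use proportions,
   LPI, CONTAG, SHDI (FRAGSTATS conventions) and the human activity
   intensity index HAILS, extracted from a categorical raster around
   each site at radii from 100 m to 4000 m.
3. **Weighted water-quality index** — 13 physicochemical indicators
   scored through piecewise-linear curves and aggregated as
   `WQI = Σ C_i P_i / Σ P_i`, with tier classification.
4. **Optimal-parameter geographical detector (OPGD)** — the q-statistic
   `q = 1 − SSW/SST` with discretization optimised over five methods ×
   3–7 classes; the operative buffer scale is the radius where the 90th
   percentile of the 11 drivers' q-values peaks.
5. **Generalized dissimilarity modelling (GDM)** — matrix regression
   `μ = 1 − exp(−η)` with non-negative order-2 I-spline transforms of
   geographic distance, altitude distance and group-wise environmental
   dissimilarities `Ed = Euc/Euc_max + 0.001`; reports percent deviance
   explained and per-predictor contributions.
6. **Null-model stochasticity ratios** — the "PF" null model (richness
   fixed, inclusion proportional to occupancy frequency) against
   observed Bray–Curtis, yielding ST / NST / MST; pairs with MST > 0.5
   read as stochasticity-dominated assembly, MST < 0.5 as
   determinism-dominated.

Because raw monitoring data of this kind are typically available only
on request, the package ships a first-class synthetic generator
(`betadrivers.synthetic`) that emulates the study design — 50 sites in
three regions, three months, 69 taxa, land-use-driven water quality
with a known true buffer radius, and communities assembled under a
tunable niche/dispersal mix — so every stage has a parameter-recovery
test with known ground truth. See `docs/methods.md` for models,
assumptions and limitations.

## Worked example

```python
import betadrivers as bd
from betadrivers.synthetic import driver_tables

bundle = bd.simulate_dataset(seed=42)          # 50 sites, 3 months, 69 taxa

# beta diversity, April
ms = bd.multisite_sorensen(bundle.communities["April"])
print(f"beta_SOR = {ms.total:.3f}, turnover share = {ms.turnover/ms.total:.1%}")

# buffer-scale selection against mean WQI
sel = bd.buffer_scale_selection(
    driver_tables(bundle), bd.wqi_mean(bundle.env, bundle.config), bundle.config
)
print(sel["optimal_radius"], {r: round(q, 3) for r, q in sel["percentile_90"].items()})
```

prints

```
beta_SOR = 0.898, turnover share = 97.4%
3000.0 {100.0: 0.275, 500.0: 0.23, 1000.0: 0.334, 2000.0: 0.531, 3000.0: 0.62, 4000.0: 0.513}
```

— overall beta diversity is high and almost entirely turnover (species
replacement, not subset loss), and the q-percentile curve rises and
falls with its peak at the generator's true 3000 m radius, where the
forest and bare-land proportions are the strongest individual drivers
(q = 0.82 and 0.62 in this run).

## Analysis scripts

The `analysis/` directory walks the full chain as numbered, standalone
scripts, each regenerating the seed-42 study and writing its tables to
`results/`:

| script | what it does |
|---|---|
| `01_simulate.py` | generate the synthetic study, summarise the design |
| `02_beta_diversity.py` | pairwise + multi-site partitions per month/region |
| `03_water_quality.py` | WQI per site/month, classification, region means |
| `04_buffer_scale.py` | OPGD q-tables per radius, percentile curve, chosen scale |
| `05_gdm.py` | GDM fits of β_sor and d_BC on six predictors, contributions |
| `06_stochasticity.py` | PF null model, MST summaries per month/region |

Run them in order with `python analysis/01_simulate.py`, etc.

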