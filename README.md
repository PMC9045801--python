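# fwdfungi

Quantitative analysis of fungal community succession on fine woody debris
(FWD — deadwood below 10 cm diameter), for community ecologists working
with ITS amplicon data from decomposition experiments. The package covers
the full desk side of such a study: a synthetic-data generator that
emulates a blocked tree-species × canopy-openness × time factorial design
with known ground truth, OTU-table preparation (species-level aggregation,
rarefaction, Hellinger transformation, abundance filters, guild profiles),
alpha diversity, bespoke per-taxon succession statistics, from-scratch
permutation multivariate tests, and per-hectare deadwood stock estimation.

## The statistics at its core

For a taxon with relative abundance $p_{ts}$ in sample $s$:

* **Specificity** for a factor with reference level $R$ (beech for the
  tree factor, closed canopy for the microclimate factor):

  $S = \dfrac{\sum_{s \in R} p_{ts}}{\sum_{s} p_{ts}} \in [0, 1]$

  $S = 1$: found exclusively on the reference substrate; $S = 0.5$:
  equally abundant on both; $S = 0$: exclusive to the alternative. Taxa
  with $S \in [0.95, 1.0]$ are classed reference-specific and
  $S \in [0, 0.05]$ alternative-specific (bounds inclusive).
* **Succession time** $T = \sum_y y\,w_y / \sum_y w_y$, the
  abundance-weighted mean year, with $w_y$ the taxon's mean relative
  abundance over the samples of year $y$.
* **Occurrence duration** $D$: the length of the shortest contiguous run
  of years holding at least 90% of $\sum_y w_y$ (a central-percentile
  variant is available by flag).

Community-level inference uses permutation machinery implemented in the
package: PERMANOVA via the distance-based linear model (Gower-centered
distance matrix with projection operators of the dummy-coded design;
Type II term tests for two-way designs), Mantel tests, two-dimensional
NMDS by stress majorisation with isotonic regression (Kruskal stress-1),
least-squares vector fitting of environmental variables onto ordinations,
and variation partitioning by partial redundancy analysis with adjusted
R². All permutation p-values follow the $(b+1)/(m+1)$ convention.

The FWD census module scales plot dry mass (wet mass × dry-mass fraction)
to tonnes per hectare by size class and converts a standing FWD stock to
its coarse-woody-debris (CWD) equivalent in yearly-production terms via a
turnover ratio (default 5, FWD decomposing about five times faster).

## Worked example

Deadwood stock arithmetic (`examples/05_deadwood_stock.py`):

```
d0.5-1.5 cm: 1.0 t/ha (19% of the stock)
d1.6-5.0 cm: 1.9 t/ha (36% of the stock)
d5.1-10.0 cm: 2.4 t/ha (45% of the stock)
total FWD stock: 5.3 t/ha
CWD equivalent at 5x turnover: 26.5 t/ha
```

The three census classes sum to a standing stock of 5.3 t/ha, the finest
twigs holding 19% of it; at a 5× turnover ratio that stock matches, in
yearly-production terms, a forest holding 26.5 t/ha of coarse deadwood.

Succession statistics on a simulated community
(`examples/03_succession_statistics.py`, 384 samples, 200 taxa, 2,000
reads per sample):

```
tree specificity: 61 beech-specific, 44 fir-specific, 95 unspecific
mean |estimated - true| tree specificity (top-quartile taxa): 0.023
Spearman rho(succession time, tree specificity) = 0.070 (p = 0.327)
```

The estimator recovers each taxon's generative tree affinity within ~0.02
on average for the abundant quartile, and — as expected under a generator
with no timing–specificity coupling — the rank correlation between
succession time and specificity is near zero.

The other example scripts cover simulation (`01`), preparation and
diversity (`02`) and ordination with permutation tests (`04`). A thin CLI
(`fwdfungi simulate|prep|diversity|succession|multivar|census|run`) wraps
the same functions for shell pipelines; `fwdfungi run --config cfg.yaml`
executes the whole pipeline from a flat YAML config with full seed
provenance.

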