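# refugia

Phylogeography and climate-change risk analysis for cold-adapted mountain
species, combining mitochondrial haplotype diversity with ensemble species
distribution modeling (SDM) over glacial–interglacial time scales.

The package is written for population geneticists and biogeographers who
want to answer, in one reproducible pipeline, the questions posed for
range-restricted mountain taxa such as the Mountain Ringlet butterfly
(*Erebia epiphron*): Where is genetic diversity concentrated today?  Where
did populations survive the Last Glacial Maximum?  And how many
region-unique haplotypes stand to be lost under future warming?

## What it computes

**Genetics** (`refugia.popgen`). Aligned COI sequences tagged by mountain
region are collapsed into haplotypes, giving per-region and overall
haplotype counts $H_n$, region-unique counts $H_u$, haplotype diversity

$$H_d = \frac{n}{n-1}\Bigl(1 - \sum_i p_i^2\Bigr),$$

nucleotide diversity $\pi$ (mean pairwise per-site difference), a
two-level AMOVA with

$$\Phi_{ST} = \frac{\sigma^2_a}{\sigma^2_a + \sigma^2_w}$$

tested against a label-permutation null, and a minimum-spanning haplotype
network whose edges count nucleotide substitutions.

**Ensemble SDM** (`refugia.sdm`). Occupancy is modeled on a coarse 50-km
lattice from eight extreme-cell climate features — the minimum and maximum
over each cell's fine (~5-km) subcells of the temperature and precipitation
of the coldest and warmest quarters.  Pseudo-absences are drawn within a
250-km buffer of presences; four model families (regularized logistic,
additive spline, boosted trees, rectilinear envelope) are trained on a
stratified 70/30 split, and only members with holdout ROC AUC > 0.85 enter
the ensemble, whose prediction is their mean probability.

**Hindcasting and refugia** (`refugia.paleo`). Coarse paleo-anomalies for
each of 21 millennial time slices since the LGM are delta-downscaled
(bilinear anomaly + modern baseline), projected through the ensemble,
clipped to zero under the ice sheets, and summed together with the present
map; the top 30% of cells by summed suitability are flagged as long-term
climate stability areas — candidate glacial refugia.

**Haplotype risk** (`refugia.risk`). Ensemble probabilities are binarized
at the low-elevation range-edge threshold (the study value is 0.49);
occupied cells persist or go extinct under each future scenario, percent
range change is tallied per region over currently occupied cells, and the
haplotype-risk statistic

$$H_r = \sum_{r\,\in\,\text{lost regions}} H_u(r)$$

counts the region-unique haplotypes in regions projected to lose every
occupied cell.

**Synthetic worlds** (`refugia.synthio`). A deterministic generator builds
a complete planar study system — 13 mountain regions, seasonal climate with
lapse rate and orographic precipitation, occupancy from a known logistic
truth, a warming trajectory with ice masks, future scenarios, and a
215-sequence alignment with 31 planted haplotypes (27 region-unique) — so
every stage can be validated against known ground truth.

**Orchestration** (`refugia.workbench`, `refugia.cli`). One YAML config
runs the whole chain and writes a self-contained report bundle; the
`refugia` command exposes `run`, `synth make`, `popgen` and `sdm`
subcommands.

## Worked example

`examples/` holds one short script per capability.  Running
`python examples/04_future_risk.py` fits the ensemble on the default
synthetic world and projects the two 2070 scenarios:

```
range-edge threshold = 0.847

--- scenario high ---
        region  n_occupied  n_persisting  ...  range_change_pct  region_lost
      scotland           9             1  ...             -88.9        False
       england           6             0  ...            -100.0         True
        ...
Hr = 6 unique haplotypes at risk (lost regions: ['england'])
elevation trend of suitability change: slope = 3.90e-04 per m, R^2 = 0.61, p = 2.8e-23
```

The threshold is the ensemble probability of the lowest-elevation occupied
cell.  Under the high (~+2.5 °C) scenario the low-lying England-analog
region loses all six of its occupied cells, so its six planted
region-unique haplotypes are counted at risk ($H_r = 6$) — exactly the
generator's ground truth.  The positive elevation slope means suitability
loss is concentrated at low elevations.

`python examples/01_haplotype_diversity.py` prints the regional diversity
table for the planted panel ($H_n = 31$, $H_u = 27$, overall $H_d = 0.884$,
AMOVA $\Phi = 0.636$, $p = 0.001$), and
`python examples/05_full_pipeline.py` runs everything from one config.

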