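# Methods

This note documents the models, estimators and numerical conventions the
package implements, the defaults it ships with, and what its synthetic
test system does and does not demonstrate.

## Sequence handling and diversity estimators

Input alignments are assumed pre-aligned and uppercase over
`A/C/G/T/N/-`.  Before haplotyping, every column containing any character
outside `{A,C,G,T}` in any record is deleted alignment-wide ("complete
deletion").  This makes haplotype identity well defined — two records are
the same haplotype iff byte-identical on retained sites — at the cost of
discarding some informative sites when ambiguity is scattered.  A
`keep-all` policy is available for callers who handle ambiguity upstream;
pairwise-deletion distances are deliberately not offered because they can
make haplotype identity intransitive.

Haplotype diversity uses the sample-size-corrected estimator
`Hd = n(1 − Σ p_i²)/(n − 1)`, which equals the fraction of discordant
unordered pairs — the form standard popgen software reports.  Nucleotide
diversity is the mean pairwise per-site Hamming difference on retained
sites, computed from haplotype copy counts in O(k²L) for k haplotypes
rather than O(n²L) over individuals.  Scopes with a single sequence
report Hd = π = 0 with a warning rather than an error, so regional tables
stay rectangular.  A haplotype is "unique" to a region when its copy
count is nonzero in exactly one region; the overall `Hu` is the number of
single-region haplotypes, which equals the column sum of regional `Hu`.

## AMOVA

The phi-statistic comes from the standard two-level sum-of-squared-
distances decomposition: with squared Hamming distances d², the total sum
of squares is Σ_{i<j} d²/N and the within-group term is the analogous sum
per group divided by group size.  Variance components use the unbiased
size coefficient n₀ = (N − Σ n_g²/N)/(G − 1) so unequal group sizes are
handled.  When the among-group component is non-positive, phi is reported
as 0 (not negative), which only occurs in effectively unstructured data.
The null distribution permutes individuals across groups with sizes held
fixed; p-values carry the +1 correction, p = (#{phi* ≥ phi} + 1)/(B + 1),
with B = 999 by default.  Calibration is verified in the test suite:
under an exchangeable null (two groups of 10 drawn from a shared
haplotype pool) the rejection rate at α = 0.05 stays within [0.03, 0.07]
over 500 replicates.

## Haplotype network

The network is a minimum spanning network: an MST on pairwise Hamming
distances plus every non-tree edge whose length ties the bottleneck (the
longest edge) of the tree path between its endpoints, so equally
parsimonious alternative connections are retained.  The statistical-
parsimony connection limit is a plain user parameter (default: no limit,
yielding a connected network over all haplotypes) rather than being
derived from a cladogram-probability calculation; with a limit set,
edges longer than the limit are dropped after augmentation.

## Feature construction and the ensemble

A cold-adapted species occupying 50-km atlas squares is limited by the
most favorable microclimate inside the square, not the average.  The
model therefore uses eight features per coarse cell: min and max over the
cell's fine subcells of four seasonal variables (temperature and
precipitation of the coldest and warmest quarters).  Units are °C and mm.

The committee holds four families chosen to span the main inductive
biases of SDM ensembles — regularized linear logistic, additive spline
logistic, gradient-boosted trees, and a rectilinear climate envelope that
scores 1 inside the central 95% presence range of every feature.  The
roster is intentionally small; the scientific content is the gate-and-
average mechanism, and families are config-extensible.  Standardization
parameters are fit on training rows only.  Each fit uses a single
stratified 70/30 split (seeded); repeated-split averaging is a config
knob rather than the default to keep fits cheap and reproducible.
Members enter the ensemble iff holdout ROC AUC exceeds the gate (default
0.85, strict inequality); the ensemble probability is the unweighted mean
of included members, with an AUC-weighted mean behind a flag because the
appropriate weighting is not settled.  AUC itself is computed by midrank
statistics, identical to pair counting with ties worth ½.

Pseudo-absences default to 3× the presence count, drawn uniformly without
replacement from valid non-presence cells within 250 km of any presence
(planar distance in synthetic worlds; the buffer keeps absences out of
unsurveyed but climatically suitable mountain systems).  One draw per
fit; replicated draws are left to the caller's seed policy.

Moran's I uses row-standardized weights (rook contiguity inferred from
nearest-neighbor distance, or inverse distance) and the normal
approximation under the randomization assumption for its p-value.

## Hindcasting, ice and stability

Paleoclimate enters as coarse anomaly grids (paleo − modern).  The
change-factor method interpolates the anomaly bilinearly to fine cell
centers and adds it to the modern baseline; temperature is purely
additive, precipitation additive with a floor at zero.  Fine cells
outside the span of coarse centers receive nearest-edge extrapolation
with a warning — exact for uniform anomalies, and a conscious
simplification versus spline/topographic downscaling, which is out of
scope.  For uniform anomalies the block means of the downscaled field
match baseline means plus offset to ≤ 1e-6.

Each of the 21 millennial slices is projected through the fitted
ensemble and cells under the slice's ice mask are set to probability 0
(clipped, not removed), so iced cells contribute zero to the stability
sum while remaining in the ranking universe.  The stability surface sums
the 21 paleo maps plus the present-day map (22 layers); exactly
`ceil(0.30 × N_unmasked)` cells are flagged as refugial, with ties at the
cut broken by ascending cell index (deterministic); an include-all-ties
mode exists behind a flag.  Cells masked (no valid climate) in any layer
are excluded from the ranking.

## Threshold, fates and haplotype risk

Suitability is binarized at a threshold; "suitable" means probability ≥
threshold, so the range-edge cell that defines the threshold counts as
suitable at present.  The range-edge mode takes the modeled probability
of the occupied cell with the lowest mean elevation; the fixed mode
defaults to the study value 0.49.  Fates follow the two-by-two of current
occupancy × future suitability: persistence, extinction, colonization,
absent.  Percent range change counts only currently occupied cells,
100·(n_persist − n_occupied)/n_occupied; colonization is reported but
never netted, because projected gains at unoccupied cells are speculative
colonizations, not retained range (a `--net-colonization`-style analysis
can be built from the reported counts).  Sub-ranges can be pooled for
range change via a region-alias map (e.g., three Alps blocks into one)
while staying separate for genetics.  A region is lost only when every
occupied cell goes extinct; Hr sums the region-unique haplotype counts of
lost regions, so Hr is monotone nondecreasing in the threshold.  The
elevation trend is an OLS of per-cell suitability change on mean cell
elevation, reported as slope, R², F on (1, n−2) df and two-sided p.

## The synthetic world

The generator emulates the shape of the empirical system: a 20×20 lattice
of 50-km cells, each owning a 10×10 block of 5-km climate cells; 13
Gaussian massifs carrying region labels within 125 km of their centers;
temperature fields built from sea-level bases, a meridional gradient, a
−6.5 °C/km lapse rate and smooth seeded noise (sd 0.3 °C); orographic
precipitation (0.08–0.10 mm/m).  Occurrence truth is a logistic in the
minimum warm-quarter temperature (coefficient −1.2 per °C, intercept
16.2, occupancy at p ≥ 0.5) — cool summer microclimate at altitude is
what the emulated species tracks.  The warming trajectory ramps linearly
from −4.5 °C at 21 ka to −0.2 °C at 1 ka with a proportional
precipitation anomaly (8 mm/°C); cells whose coldest subcell drops below
−20 °C are iced.  Future scenarios are +1.0 °C/−5 mm (low) and
+2.5 °C/−15 mm (high), matching roughly +1 and +2–3 °C warming by 2070.

The sequence panel plants 215 records of 649 bp across the 13 regions: 4
shared haplotypes (one of them the root itself, present in four regions)
and 27 region-unique haplotypes, each unique haplotype carrying 5
region-stem substitutions shared within its region plus 1–7 private ones.
One alignment site per haplotype is reserved so planted haplotypes are
guaranteed distinct; stems occupy disjoint per-region blocks.  The stems
create regional clades, which is what produces realistic among-region
AMOVA structure (phi ≈ 0.64 on the default panel) rather than the near-
zero phi a pure star phylogeny would give.  All draws descend from one
seed through spawned child generators, so worlds are bit-reproducible.

What passing tests on this world show — and do not show.  They show the
estimators, the gate, the projection plumbing and the risk rules are
implemented correctly, because every quantity is checked against the
generator's closed-form truth or a brute-force oracle.  They do not show
that the ensemble transfers well to real paleoclimates: the synthetic
climate has no interannual variance structure, no coastlines or sea-level
change, uniform anomalies instead of GCM spatial patterns, and planted
rather than coalescent sequence variation.  Results on real data depend
on those properties.

## Problem sizes and determinism

Defaults are sized so the full pipeline (215 sequences, 400 coarse cells,
22 time slices, two scenarios, 999 AMOVA permutations) completes in
seconds on one core, and the whole test suite in well under a minute;
the AMOVA calibration study (500 replicates × 199 permutations) is the
largest computation at a few seconds.  Every stochastic step — noise
fields, pseudo-absence draws, the 70/30 split, permutation nulls — takes
an explicit seed, and the pipeline manifest records the config hash and
seed needed to reproduce a bundle exactly.

## Known limitations

* Distances are Hamming counts; no substitution-model correction, which
  is standard at COI intraspecific divergences but matters beyond them.
* The committee omits maximum-entropy and neural members; AUCs near the
  gate can flip inclusion across seeds when holdout sets are small.
* Geographic (great-circle) distance is implemented for the buffer only
  through planar coordinates here; real-world longitude/latitude inputs
  should be projected before gridding.
* Ice masks zero cells rather than removing them; if the intended
  semantics is exclusion from the stability ranking universe, mask the
  cells in the climate layers instead.
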