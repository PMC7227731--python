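# Methods

## The strength fraction and its permutation test

The analysis substrate is a sample table (id, 3D MNI-millimetre
coordinates, anatomical tissue label, rsfMRI-network label 0–13) and a
genes × samples expression matrix aligned to it. The tissue–tissue
correlation graph has one node per sample; the weight of edge (i, j) is the
Pearson correlation of the two samples' expression profiles across genes.

The strength fraction of a set of disjoint networks is

    SF = Σ w⁺ over eligible within-network pairs / Σ w⁺ over all eligible pairs

with `w⁺ = max(w, 0)`. Three choices here are conventions rather than
published formulas, and each sits behind a switch:

- **Edge weights** (`edge_weights="positive"|"absolute"|"raw"`): strength-
  based graph measures conventionally sum positive strengths; negative
  correlations contribute zero to both sums by default.
- **Within-tissue correction** (`within_tissue="exclude"|"none"`): edges
  between samples sharing a tissue label are removed from numerator *and*
  denominator, so trivially high same-structure correlations cannot carry
  the statistic.
- **Denominator** (`denominator="all"|"incident"`): by default all eligible
  pairs count, including pairs of two unlabeled samples.

The permutation test shuffles the network-membership label vector uniformly
over the full analysis pool (network and non-network samples alike),
preserving each network's size, and recomputes SF on the same graph. The
p-value uses the add-one convention `p = (1 + #{null ≥ SF}) / (1 + n)`, so
it is never zero; the *significance* flag uses the stricter historical
criterion — the real SF must exceed every null (ties count against
significance). Because nulls are drawn sequentially from one generator,
extending a run with more shuffles can only remove significance, never
create it.

## Simulated noise networks

A simulated network set is built from 34 spherical clusters grouped into
13 networks (nine networks of three clusters, three of two, one singleton),
mirroring the cluster composition used for real rsfMRI networks. Cluster
centers are samples drawn sequentially, uniformly over the candidates not
blocked by previously accepted centers; a candidate is blocked when its
distance to an accepted center is ≤ 2r (strict non-overlap of cluster
spheres; tangency is allowed). Dead-end configurations are discarded and
redrawn inside a global proposal budget (default 10,000), after which a
packing error reports how many centers fit. The induced distribution over
center sets is that of this sequential process — close to, but not exactly,
uniform over all valid sets; exact uniformity is unreachable at scale
(rejection of whole 34-center draws has acceptance probability ~10⁻⁸).
Cluster membership is the closed ball: every pool sample within r
(inclusive) of the center.

Sampling variants: `All` draws centers and members from every sample;
`Z-cn` forbids rsfMRI samples as centers but keeps them as members;
`omit-RS` restricts the *entire* analysis pool — centers, members, the
correlation graph and the shuffle pool — to non-rsfMRI samples.

The false-positive-rate sweep draws `n_networks` sets per radius and
variant, runs the full permutation test on each, and reports the fraction
significant with a Wilson 95% interval (appropriate at small counts). Every
simulation seeds its own generator from (master seed, variant index, radius
index, simulation index), so results are bit-for-bit reproducible and
independent of execution order; per-simulation records can be streamed to
JSONL and resumed. A packing failure marks the whole row infeasible rather
than dropping hard-to-pack draws, which would bias the estimate.

The control experiment holds the radius at 6 mm and scales the number of
clusters by factors f ∈ [1, 5]: the cluster count is round(34·f), allocated
over 13 networks by flooring the scaled (3,…,3,2,2,2,1) template and
distributing the remainder round-robin from the largest network. It
separates total network size W from cluster size as the driver of FPR.

## Moran's I

Global spatial autocorrelation of per-gene expression is

    I = (n / S0) · Σ_ij w_ij z_i z_j / Σ_i z_i²,   z = x − x̄,  S0 = Σ w_ij.

Weights are distance-banded: zero beyond a threshold (default 16 mm), and
within the band either inverse distance 1/d^α (α = 1 by default, the
continuous convention) or binary. Rows are standardized to sum to one by
default (the usual choice for inference); the raw transformation is kept
for closed-form checks. Samples with no neighbour in the band (islands) are
dropped from the statistic and reported, not silently zero-weighted;
coincident samples are an error under inverse-distance weighting.

Inference defaults to the normal approximation under the randomization
null, with E[I] = −1/(n−1) and the standard randomization variance
(involving S0, S1, S2 and the sample kurtosis); a permutation option with
the add-one p-value is available per gene. A full permutation sweep over
~17k genes is possible but off by default for runtime. Gene-set comparison
reports group means/SDs of I and a two-sided Mann–Whitney U test.

## The synthetic cortex

The generator emulates the study conditions of a cortical atlas sampling:

- **Geometry.** n points on a spherical shell of radius 70 mm with uniform
  jitter ±3 mm (so the cloud diameter is bounded by 2·(70+3) mm), with a
  band of half-width 5° removed around the midline plane to mimic the
  interhemispheric fissure — the cloud splits into two hemispheric caps.
  The 70 mm scale matches an adult brain in MNI coordinates, which matters
  because all cluster radii and weight thresholds are in physical mm.
- **Tissue parcels.** k-means on coordinates, 100 parcels by default
  regardless of n, so parcels keep the physical size of anatomical labels
  (~13 mm radius) and the within-tissue correction operates at the same
  spatial scale as in real data.
- **Network labels.** 13 contiguous sets carved with the same
  cluster-packing machinery used for noise networks (34 spheres grouped
  9×3 + 3×2 + 1×1). The target coverage defaults to n·501/1777, the real
  rsfMRI proportion; the carve radius is derived from the surface density
  so expected membership matches the target (realized counts vary by a few
  tens of percent).
- **Expression.** Each gene block (count, λ) is drawn as a zero-mean,
  unit-variance Gaussian process over the sample coordinates with
  covariance exp(−d/λ) — the simplest kernel reproducing the convex,
  non-linear distance decay of tissue–tissue correlation — plus independent
  Gaussian noise (sd 0.3 by default, i.e. ~8% noise variance); λ = 0 blocks
  are pure i.i.d. noise. Sampling is by Cholesky with 10⁻⁸ diagonal jitter.
  Geometry and expression use independent seed streams derived from one
  config seed, so the whole dataset is reproducible end to end.

The distance–correlation profile bins eligible sample pairs into half-open
[k·8, (k+1)·8) mm bins (the edge convention is a choice; nothing hinges on
it) and reports per-bin medians, excluding same-tissue pairs when the
within-tissue correction is on.

## Problem sizes and what the tests show

The test suite and the acceptance script run desk-scale analogues of the
full design (which at full scale is 10 radii × 1,000 networks × 1,000
shuffles × 3 variants): synthetic cortices of 300–900 samples and 500–1,000
genes, 100–400 networks per condition and 100–200 shuffles per network,
with the control experiment at the original 200 × 200. These sizes were
chosen so each stage's sampling error (binomial bands on FPRs) is small
relative to the effects under test.

What passing shows: the permutation machinery is calibrated — the single
most important correctness property, since the reported inflation must come
from spatial structure, not from a broken test. Under pure exchangeability
(fresh i.i.d. expression per dataset) the strict-significance rate matches
the nominal 1/(n+1) exactly. On a frozen λ = 0 cortex run through the full
pipeline the rate stays at or *below* nominal: the within-tissue correction
interacts with contiguity — spatially contiguous networks lose ~20% more
of their within-network pairs to same-tissue exclusion than scattered null
labelings do, which depresses the real SF relative to its null and makes
the full pipeline conservative at λ = 0 (measured mean normalized rank of
the real SF among its nulls: ~0.01 at 14 mm radius). Real atlas pipelines
carry the same asymmetry; any FPR inflation measured on top of it is
therefore, if anything, understated. with λ = 20 mm expression the SSF-FPR
inflates with contiguous cluster radius and correlates positively with it;
the inflation survives all three sampling variants; and cluster count at
fixed radius does not raise the FPR. The core statistics match independent
brute-force oracles (exhaustive pair enumeration for SF, a double-sum loop
for Moran's I, full labeling enumeration for the permutation null) and
closed forms (ring-dispersion I = −1, E[I] = −1/(n−1), SF = 1 for one
all-inclusive network).

What passing does **not** show: the generator is an idealization — a
homogeneous isotropic GP on a shell has no hemispheric asymmetry, no
donor/batch structure, no geodesic (sulcal) geometry, no heavy-tailed
expression, and its tissue parcels are size-balanced. Absolute FPR values
therefore differ from any real atlas; only the qualitative mechanisms
(calibration, radius-driven inflation, size-vs-count dissociation) carry
over.

## Known limitations

- At desk scale the `omit-RS` variant systematically *lowers* the FPR by
  roughly 0.1: removing ~26% of the samples thins contiguous clusters, and
  with sparse clouds the FPR is steeply member-count dependent. This is a
  density artifact of small synthetic clouds, not an rsfMRI-label effect —
  on dense data the variant differences are small and can go either way.
  Single frozen datasets also show real dataset-by-variant interactions, so
  variant comparisons are meaningful only against the inflation magnitude,
  not at binomial-noise resolution.
- Sequential center placement is not exactly uniform over valid packings
  (documented above); the toy-scale distribution test checks the sequential
  process against its own exact recursion.
- Hierarchical grouping of real networks into clusters uses single linkage
  on Euclidean distance by default (`linkage_method` switch), matching the
  common default of legacy clustering tools.
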