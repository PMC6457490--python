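# Methods

This note documents the models, rules and numerical choices behind the
package, the assumptions they rest on, and what the synthetic benchmarks
do and do not demonstrate.

## Study design and data model

The pipeline assumes the two-strain complementation contrast used to map
the binding of a repressive response regulator: a deletion strain carrying
an empty vector ("deleted") and the same strain complemented with a tagged
copy of the regulator ("complemented"). Binding signal exists only in the
complemented strain, so the strain contrast cancels shared artifacts
(cross-hybridization, chromatin accessibility, copy-number effects).
Each strain is measured in two biological replicates hybridized in
opposite Cy-dye orientations, at several growth timepoints (defaults 14,
18 and 35 h — mid-exponential, late-exponential and stationary phase).
ChIP arrays carry log2(IP / mock-IP); expression arrays carry
log2(cDNA / gDNA), the genomic-DNA channel acting as a per-probe
abundance reference. Raw tables store log2(Cy5/Cy3); all internal genomic
coordinates are 1-based inclusive, converted to 0-based half-open only
when writing BED.

## Preprocessing

**QC flag rule** (per timepoint, applied before any normalization): a
sample counts as flagged for a probe only when *both* channels are
flagged; a probe is excluded when it is flagged in at least one sample of
each strain, or in more than two samples. "More than two" is evaluated
over the samples of one timepoint (2 strains x 2 replicates by default),
and when both exclusion reasons apply the between-strain reason is
reported (deterministic precedence). Adding flags can only grow the
excluded set (monotonicity, property-tested).

**Orientation.** Each sample declares which dye carries the IP/cDNA
channel; raw log2(Cy5/Cy3) is sign-flipped when that dye is Cy3, making
positive always mean enriched/expressed. Negating all raw values while
flipping every dye label is a bit-exact no-op.

**Scale normalization** equalizes the median absolute log2 value across
arrays: with m_a = median(|x_a|) per array and g the geometric mean of the
m_a, array a is scaled by g/m_a. This is the standard median-absolute-
value scaling for two-color arrays (cross-checked in the tests against
limma's implementation) and is idempotent. An array with m_a = 0 carries
no scale information; the library call rejects it by default
(`on_degenerate="error"`), while the pipeline assigns it scale factor 1
and excludes it from the geometric mean (`"unit"`). The permissive policy
exists for the zero-noise limit, where deletion-strain ChIP arrays are
identically zero; on any data with noise the two policies coincide.

**Expression ordering.** Expression matrices are median-centered within
each array ("global median within array") and then scale-normalized
across arrays; ChIP matrices are only scale-normalized, since the
IP/mock log-ratio is already centred at zero for unbound probes and
median-centering would shift genuine enrichment.

## Enrichment calling and clustering

Candidates require a strict win of the complemented strain in *both*
paired replicates (pairing by replicate index, i.e. the two dye-swapped
biological pairs); fold change is the difference of strain means. The
enrichment threshold is data-derived — candidate mean plus 1.0 sample
(n−1) standard deviation — and strict (">"). Probes missing any replicate
value are ineligible as candidates. With fewer than two candidates the sd
is undefined and no calls are made (warning). The threshold is exactly
equivariant under constant fold-change shifts.

Clustering is single-linkage over enriched-probe midpoints with a maximum
gap of 1000 bp (boundary inclusive) and a minimum of two probes per
region. Gap linkage was chosen over fixed 1 kb windows because windowed
calls depend on arbitrary window phase; the fixed-span reading is
available as `ClusterParams(method="span")`. A region spans min(start) to
max(end) of its member probes. Correctness is property-tested against a
brute-force transitive closure.

**Annotation.** A region is `gene_internal` when at least half its length
lies inside one gene; otherwise `promoter_proximal` when it intersects
the coding-strand upstream window (default 300 bp: [start−w, start] for
+ genes, [end, end+w] for − genes) of any gene; otherwise `intergenic`.
The generator's alternating strand layout produces divergent gene pairs
whose shared intergenic region contains both upstream windows, mirroring
divergent promoter pairs in bacterial genomes.

**Peak shape.** The fold-change profile over the region extended by one
clustering gap on each flank is smoothed with a centered 3-probe moving
average (missing values mask-weighted). Local maxima are found with a
standard peak finder; the major summit must exceed the probe-level
enrichment threshold. The region is biphasic when a second local maximum
exists at least two probe spacings away whose separating trough drops
below (1 − 0.25) x the smaller maximum. The minor summit needs only half
the enrichment threshold: an asymmetric pair's smaller peak (the
generator's default amplitude ratio is 0.5) sits near the probe-calling
cutoff, yet is visually unambiguous; requiring full threshold height
would miss about half of genuine biphasic sites at the default noise
level. Both shape parameters are exposed and were validated only against
synthetic truth. Degenerate all-missing profiles are `unclassified`.

## Per-gene expression and Rank Product

A probe contributes to a gene when its interval intersects the gene's
coding span (probes spanning two overlapping genes contribute to both);
the gene signal is the arithmetic mean of good-quality probes, missing
when none remain. For each timepoint the complemented and deleted
replicate values per gene feed an unpaired two-class Rank Product with
K = nA x nB crossed differences (K = 4 for the duplicate design): per
direction, genes are ranked within each comparison (ties = average
ranks) and RP is the geometric mean of the K ranks.

**Null model.** The K comparisons share replicates, so their rank vectors
are strongly positively correlated; permuting each comparison's ranks
independently ignores this and badly understates the left tail of the
null RP distribution (measured: the resulting pfp is several-fold
anti-conservative on crossed duplicate designs). The null used here
simulates the crossing exactly: each of B pseudo-datasets draws i.i.d.
continuous pseudo-replicates per gene, forms the same K crossed
differences and ranks them. Because ranks of crossed differences of
i.i.d. continuous variables do not depend on the sampling distribution,
this is the exact null under exchangeable noise. A conditional refinement
then accounts for signal displacement: genes confidently non-null
(pfp < 0.05, discounted by their expected false fraction) occupy the top
ranks of every comparison in real data, pushing true nulls down; null
ranks are offset by that count and the pfp re-estimated, iterating at
most 4 times or until the confident count stops growing.
pfp = (expected null RPs at or below the gene's RP) / (position in the RP
ordering), smoothed by a cumulative minimum from the largest RP downward
so it is monotone in rank. With equal group sizes the same null sample
serves both directions, making group swap exactly antisymmetric. The
seed is mandatory and logged; B defaults to 1000.

Selection at pfp < 0.15 is strict; a gene significant in both directions
is listed only in the direction with the smaller pfp (ties by smaller
RP). Cluster counts take an inclusive SCO-style gene-id range minus an
exclusion set — by default the deleted regulator gene itself is excluded,
since its differential signal reflects the deletion, not regulation.

**Calibration, measured.** On null data (G=500, nA=nB=2, B=200) the
fraction of genes at pfp < 0.15 stays at or below 5% in 20/20 seeds
(typically 0-2 genes). On the power benchmark (2000 genes, 50 spiked at
log2 effect 1.5, per-value noise sd 0.4, B=1000) the realized error rate
at the 0.15 cut is about 0.15-0.25 with sensitivity around 0.85-0.95.
This operating point is close to the information limit of the design: at
effect/noise = 2.65 sigma per comparison with duplicate samples, sweeping
a clairvoyant threshold along the RP ordering reaches sensitivity >= 0.9
together with precision >= 0.8 on only about 40% of random datasets, so
no pfp estimator can guarantee both simultaneously at this effect size.

## Synthetic generator

The generator is the benchmark's ground truth, at desk scale relative to
the real experiment (~105K probes over an 8.7 Mb genome): default 100 kb
genome, fixed-step 80 bp tiling of 60-mer probes (~1250 probes), 60 genes
in evenly spaced slots with alternating strands. Binding sites are
Gaussian log2 profiles — amplitude x exp(−(p−c)²/2w²), plus a second
Gaussian at c + separation scaled by the amplitude ratio for biphasic
sites — added only to the complemented strain's ChIP ratios at the
site's active timepoints. Expression effects add a signed log2 offset to
all probes of a gene in the complemented strain at one timepoint, on top
of per-gene baselines drawn once per dataset (biological structure, kept
at zero noise). Noise is i.i.d. Gaussian on the log2 scale (default sd
0.3, roughly the replicate scatter of two-color arrays); dye bias is a
per-array additive offset on the raw-orientation scale (default within
±0.1); QC flags are independent Bernoulli per probe-channel-sample
(default 1%). Identical (config, truth, seed) gives bit-identical output.

Not emulated: spatial array artifacts, probe sequence/GC effects,
scanner saturation, correlated noise between neighboring probes, and
background cross-hybridization structure. Passing the synthetic
benchmarks therefore demonstrates the correctness of the statistical
chain under the stated noise model, not robustness to platform-specific
artifacts in real scanner data.

## Numerical conventions

Median of an even-length sample is the mean of the two central order
statistics; standard deviations use n−1 throughout. Probe genomic
position is the midpoint of its [start, end] span. Scale-normalization
equality of medians holds to 1e-9. Region ids are assigned in genomic
order after clustering. All tabular outputs are TSV; floats are written
with 6 decimals, which bounds round-trip fidelity of written tables (the
in-memory API keeps full precision).

## Known limitations

The flag rule presumes exactly two strains; more than two are rejected
upstream by the sample-sheet invariants. The conditional Rank Product
null assumes confident calls are cleanly separated from the null bulk —
with very many weak effects the offset is underestimated and pfp drifts
conservative. Printed per-cluster DE counts from the original biological
experiment require that experiment's normalized expression table as
input; the pipeline exposes the computation (`chipchip rankprod` with
cluster ranges and the deleted-gene exclusion) but ships no copy of the
deposited data.
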