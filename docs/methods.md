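# Methods

This note records the models, rules and numerical choices behind each stage of the
toolkit, the behaviour of the synthetic-data generators, and what the test suite does
and does not demonstrate about real data.

## Gene categorization

Single-copy status is decided from an all-vs-all similarity search of the gene set
against itself (12-column tabular hits; the search itself is out of scope).  A gene is
single copy when its only hit is the self-match or when the **best non-self** bit score
is below 200.  The alternative reading — inspecting only the rank-2 hit — would admit
genes whose rank-2 hit is an artifact while a later hit is strong; scanning all
non-self hits is the stricter, superset-safe choice and is what `classify_single_copy`
implements.  Hit tables are sorted deterministically (bit score descending, subject id
ascending) so rank-2 ties cannot change the outcome.

Cross-species classification needs a "significant homology" cutoff that the original
protocol leaves to pre-optimized search parameters; we expose it as an explicit bit
score, default 100, mirroring the agronomic-gene cutoff.  Single-copy genes with no
significant cross-legume hit are SCP; a significant *Glycine max* hit makes a gene
CSCSP; genes hitting only *Cicer* or *Medicago* match neither definition and are left
UNCLASSIFIED rather than forced into either class.  DRDRP and MCP memberships are
curated id lists.  When memberships overlap, precedence is AGCP > DRDRP > MCP >
single-copy classes, so category assignment is always a partition.

Reference sequences are extracted gene-oriented with 500 bp upstream and 100 bp
downstream flanks (regulatory context for the assay).  On the minus strand the
genomic window is `[start − 100, end + 500]`, reverse complemented, and exon intervals
are re-expressed in extracted coordinates.  Flanks running off a contig end are
truncated and flagged, never padded.

## Site filtering and feature annotation

The variant caller is not re-implemented; its four published thresholds are applied to
per-site pileup summaries (depth ≥ 10, alternate reads ≥ 2, mean base quality ≥ 25,
variant frequency ≥ 0.05 — all inclusive lower bounds).  Multiallelic sites are
rejected with an explicit reason, and every failing site is logged with all of its
failure reasons, which makes the filter auditable and monotone: tightening any
threshold can only shrink the survivor set.

Feature annotation is purely geometric over the extracted sequence: positions before
the first exon are `five_prime`, inside an exon `exon`, between exons `intron`, after
the last exon `three_prime`.  The catalog does not distinguish annotated UTRs from the
added flanks — both end up in the 5′/3′ classes — which matches how the chip's feature
distribution was reported.  If true UTR annotations exist they can be expressed as
exon boundaries.

Report arithmetic (`summary_from_counts`) derives every design-report statistic from
raw counts: density = 1000·SNPs/length, SNPs per gene, inclusion percentages, chip
shares.  Printed values use round-half-up at the printed precision.  Average gene size
is deliberately not asserted at printed precision anywhere: published tables of this
kind mix rounding and truncation for that column (e.g. 3174.6 printed as 3175 in one
row but 2024.6 as 2024 in the total), so only values stable under both conventions are
used as checks.

## Probe design

The 72-bp plex carries the SNP at base 36 (35 bp left, 36 bp right flank) with alleles
bracketed `[A/G]`.  The interference rule removes a target SNP when any other SNP of
the same gene lies at positional distance ≤ 10 bp; the relation is symmetric, so
interfering pairs remove each other.  "Within 10 bp" is read as distance ≤ 10
(distance 11 survives).  SNPs whose flanks do not fit in the extracted sequence are
recorded as `not_possible` rather than silently dropped, keeping the attrition funnel
auditable (identified → interference-filtered → plex-extracted → recommended, counts
non-increasing).

Vendor conversion-probability models (random-forest scores over probe sequence,
binding energy and cross-hybridization) are proprietary.  The surrogate designability
score keeps the pipeline's shape and the strict > 0.50 gate without pretending to
reproduce vendor numbers: the score starts at 1.0 and multiplies in a 0.5 penalty for
each documented defect —

* GC fraction of the plex outside [0.30, 0.70];
* a homopolymer run of ≥ 6 bases;
* a flank 16-mer occurring in another catalog gene (cross-hybridization proxy, via an
  exact k-mer index over the catalog);
* non-ACGT characters in the flanks.

A single defect (score 0.50) already fails the strict > 0.50 gate.  Penalty weight,
bounds and k are configurable on `ProbeConfig`.  One forward/reverse probe pair is
emitted per SNP; multi-probe tiling redundancy (real arrays assign some SNPs extra
probes) is not modelled.

## Genotype QC and the RIL filter

Call rate, heterozygosity, concordance and MAF are standard and permutation-invariant;
the call-rate gate (> 95.5%) is exposed on both the sample and the marker axis, since
both uses occur in chip validation.  Sample QC by signal-space quality metrics
requires raw intensities and is out of scope; call rate is the sample criterion here.

The RIL marker filter expects the two parents in the matrix: markers must be called,
homozygous and polymorphic between them.  Residual heterozygous calls in F8 lines
(expected at rate (1/2)⁷ ≈ 0.78% per locus) are treated as missing, and the remaining
homozygous counts are tested against 1:1 with the df = 1 chi-square
χ² = (n_AA − n_BB)²/(n_AA + n_BB), no continuity correction (standard linkage
practice); markers with P < 0.05 are discarded.  Under fair segregation this discards
≈ 5% of markers by construction (type-I error = α), which the calibration test checks
at 0.05 ± 0.02 with 1000 markers × 94 lines.

## Diversity and structure

IBS distance: per jointly called SNP the shared-allele proportion is 1 − |g − h|/2 on
dosage coding (heterozygote vs homozygote shares 0.5); distance is one minus the mean.
Neighbor joining is classic Saitou–Nei with Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch
lengths l_i = d/2 + (r_i − r_j)/(2(n−2)), reduction d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2,
and deterministic tie-breaking by the lowest index pair.  The Q matrix is computed with
the commutative sum r_i + r_j formed first so it is bit-symmetric and the argmin cannot
fall on only one side of the diagonal.  The final join attaches the last node to the
remaining internal node, yielding the standard trifurcating unrooted topology.
Negative branch lengths (possible on non-additive inputs) are kept as computed.  On
additive matrices with internal branches bounded away from zero, NJ provably returns
the unique generating tree; the suite verifies this by exact tip-to-tip distance
recovery on random additive trees (n ≤ 8), and cross-checks topology against an
independent NJ implementation.  The variant of NJ used by common GUI tools is not
published, so agreement claims are topological.

The unlinked-subset rule ("three per chromosome near the telomeres and centromere,
MAF ≥ 0.3") is operationalized without physical landmark coordinates: the anchor
points are the start, midpoint and end of each chromosome's covered interval, and the
qualifying candidate nearest each anchor is chosen (ties to the smaller position; a
SNP is selected at most once, so sparse chromosomes contribute fewer with a warning).
With 11 chromosomes and dense candidates this yields exactly 33 SNPs.  STRUCTURE input
(two rows per individual, alleles 1/2, −9 missing) and PLINK ped/map are emitted as
plain text; Bayesian structure inference itself is out of scope.  The ped format does
not record which allele is the reference, so the importer defaults to the
alphabetically smaller observed allele — lossless for the exporter's default A/B
labels, overridable per SNP.

## Haplotypes

Haplotypes are defined over **all** of a gene's chip SNPs (that is how per-gene SNP
counts are reported); windowed haplotype definitions are not supported.  The default
assignment policy uses only samples homozygous and fully called at the gene — phase
inside a heterozygote is unknown without family data, and the genes chosen for
published haplotype analyses had 100% call rates.  The alternative policy renders
het/missing as `N` and keeps all samples.

Hd uses Nei's unbiased estimator n/(n−1)(1 − Σ pᵢ²); it is undefined (an error) for
n < 2.

The median-joining network (ε = 0) is built as: (1) the minimum spanning network —
union of all minimum spanning trees under Hamming distance, via Kruskal by distance
class; (2) for every path triple (u, v, w) with u, w adjacent to v, the positionwise
majority consensus median is proposed and accepted when it is strictly cheaper as a
Steiner point (star cost < the triple's own two-edge spanning cost); (3) rebuild over
the enlarged node set and repeat to a fixed point (bounded at 20 rounds).  Three-way
ties in the consensus take the character of the lexicographically smallest member, so
construction is deterministic under fixed input ordering.  By the MST-edge
characterization, the final network contains every minimum spanning tree of its node
set, and medians only ever add nodes, giving the two structural guarantees the tests
assert.  ε > 0 (denser networks) is not implemented.

The saturation experiment draws seeded random SNP subsets of given sizes and counts
the haplotypes each resolves; any subset partition is a coarsening of the full-set
partition, so subset counts never exceed the full count and the full-size draw equals
it exactly.

## Synthetic generators

All generators take a single integer seed (NumPy `default_rng`) and are byte-for-byte
reproducible through the writers.  Sizes below were chosen so the whole suite and the
acceptance script each run in seconds.

* **Catalog**: one contig per gene with 600 bp margins, gene length normal around the
  category mean (published means per category; floored at 400 bp), 2–4 exons, random
  strand.  23 genes across the five categories by default.
* **Sites**: Poisson placement at the published per-category densities (SCP 35.2,
  CSCSP 6.9, AGCP 22.7, DRDRP 16.6, MCP 111.8 per kbp); pileup fields drawn in the
  clearly-passing range, then each field independently pushed below its threshold with
  a configurable failure fraction (default 5% each), so filter behaviour is exercised
  on both sides of every boundary.
* **Population**: 95 varieties in two subpopulations (56/39, matching the published
  panel's inferred split), allele frequencies per subpopulation from the
  Balding–Nichols model (Beta with differentiation parameter Fst, default 0.25, around
  a uniform(0.2, 0.8) ancestral frequency), 36% of samples admixed as frequency
  mixtures with 55–80% majority ancestry.  Genotypes are homozygous dosages — the
  varieties such chips are validated on are predominantly inbred — with explicit
  residual heterozygosity (default 9.8%, the published panel mean) and no-call noise
  (0.73%, matching the 99.27% mean call rate).  This construction makes mean
  heterozygosity a direct moment check rather than an emergent property.  500 SNPs
  over 11 chromosomes by default; at Fst = 0.25 the NJ tree separates the pure samples
  of the two subpopulations essentially perfectly (the acceptance check requires
  ≥ 95%).  Below Fst ≈ 0.05 with 500 SNPs the bipartition signal degrades — the
  generator emulates divergence, not a coalescent, and carries no linkage
  disequilibrium.
* **RIL**: 94 F8 lines × 1000 markers, independent markers (linkage-map construction
  is out of scope, so no recombination map is simulated), AA/BB at the marker's
  segregation probability (0.5, or 0.75 for the planted distorted fraction emulating
  a 3:1 ratio), heterozygous with probability (1/2)⁷.

Because the generators plant exactly the structure the analyses estimate, passing
tests demonstrate internal consistency and correct implementation of the stated rules
— not performance on real chip data, where linkage, genotyping-error structure,
null alleles and population history are all richer than modelled here.

## Known limitations

* Similarity searching, read alignment and variant calling are consumed, not
  performed.
* The surrogate designability score shares only the gate and codomain with vendor
  conversion scores; absolute values are not comparable.
* Median-joining uses ε = 0 and single-character medians over the observed alphabet;
  for highly reticulate data a dedicated network tool will produce denser graphs.
* The probe manifest emits one probe pair per SNP; array-level redundancy schemes are
  not reproduced.
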