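# Methods

`metapan` implements a metapangenomic analysis of a bacterial genus: it builds
a gene-cluster pangenome from isolate genomes, places the genomes in a
phylogenomic context, maps how each genome recruits metagenomic reads across
body sites, and tests which metabolic capabilities distinguish site-specialist
genome groups.  This note describes the models and procedures, the parameters
that matter, the synthetic-data generator used for validation, and the
numerical choices made where the design was genuinely open.

## Genome catalog and dereplication

Input genomes carry manifest metadata (host, oral/nonoral, species label,
CheckM-style completeness and contamination, duplicate-strain flag).
Selection keeps human-host, non-duplicate genomes with completeness >= 90%
and contamination strictly < 5%.  Contigs shorter than 300 nt are removed and
non-canonical letters are masked to N.

Average nucleotide identity (ANI) follows the fragment convention used by
blast-based ANI tools: the query genome is cut into non-overlapping 1,020-nt
windows; each window is aligned to the subject genome; a fragment is accepted
when its aligned query coverage is >= 0.7 and identity >= 0.3; ANI is the mean
identity over accepted fragments, and the aligned fraction is the share of
fragments accepted.  The two directed estimates are averaged, making the
statistic symmetric by construction.  The per-fragment alignment is a
two-stage seeded search: a fast banded infix edit-distance scan (edlib)
locates the best candidate window on each strand, then an affine-gap local
alignment (match +1, mismatch -1, gap existence 5, extension 2; Biopython's
PairwiseAligner) of the fragment against the padded window yields identity
over aligned columns and query coverage.  Exhaustively aligning every
fragment against the whole subject would cost O(fragment x genome) per
fragment for no accuracy benefit; seeded search is the same strategy blastn
itself uses.  Random sequence pairs self-reject through the coverage floor
(the best local alignment of unrelated 1-kb sequences covers only a few
percent of the query).

Dereplication at 98% ANI is greedy: candidates are ranked by completeness
(descending), total length (descending), then genome id; the best unclaimed
genome becomes a representative and claims every genome sharing > 98% ANI
with it.  The rule is deterministic, idempotent, and favours the best
assemblies.  Raising the threshold can only split claim sets, so the number
of representatives is non-decreasing in the threshold — a property the test
suite checks on synthetic and random ANI matrices.  Species-level grouping is
single linkage over the > 95% ANI graph, the conventional species boundary.

## Pangenome construction

All-vs-all protein similarity is Smith-Waterman with BLOSUM62 and affine gaps
in the blast convention (gap of length k costs 11 + k).  Raw scores are
converted to bitscores with the gapped Karlin-Altschul constants
(lambda = 0.267, K = 0.041); because the downstream filter uses only score
ratios, a raw-score mode exists and produces identical filtering.  The X
residue is scored zero against everything.  For each gene pair the minbit is
the cross score divided by the smaller self score; edges with minbit < 0.5
are discarded (boundary inclusive), and asymmetric directions are collapsed
by keeping the larger score per unordered pair.

The surviving weighted graph is clustered with the Markov cluster algorithm
(MCL) at inflation 10: a column-stochastic matrix over minbit weights with a
self-loop per node equal to its maximum incident weight (1 for isolated
nodes); iterations alternate expansion (matrix squaring) and inflation
(entrywise power, column renormalisation), pruning entries below 1e-8 after
renormalisation, until the largest entry change falls below 1e-6 or 200
rounds.  Clusters are read from attractor rows; overlapping attractor
supports are merged and ties break on the smallest gene id.  Pruning must
happen after renormalisation: at inflation 10 the inflated entries are
astronomically small before rescaling, and pruning first empties the matrix.

Clusters present in every genome are core, in exactly one genome singleton,
otherwise accessory; the three categories partition the cluster set.  Genomes
are hierarchically clustered on their gene-cluster frequency vectors with
Euclidean distance and Ward linkage (scipy), and the merge tree is exported
as an ultrametric Newick string.

## Phylogenomics from single-copy core genes

Single-copy core gene clusters (exactly one member in every genome) are
aligned per cluster with center-star progressive alignment: the center is the
member with maximal summed pairwise score; every member is aligned globally
(Needleman-Wunsch, BLOSUM62, same gap convention) to the center, and the
pairwise alignments are merged column-wise ("once a gap, always a gap").
With two members this is exactly the optimal pairwise alignment.  Alignments
are concatenated, columns gapped in more than 50% of taxa are removed (a
column at exactly 50% is kept), and the partition map is re-expressed in
post-trim coordinates.

The tree is neighbor joining on Poisson-corrected distances
d = -ln(1 - p), where p is the proportion of differing residues over
ungapped column pairs (capped just below saturation); negative NJ branch
lengths are clamped to zero.  A site-resampling bootstrap over the NJ tree is
available and off by default.  The center-star aligner and the distance tree
are deliberate substitutions for a full progressive MSA program and a
maximum-likelihood search: the quantity this stage is accountable for is
topology recovery, which the tests check on sequences simulated down known
trees (8-taxon recovery at Robinson-Foulds distance 0) and on the synthetic
catalog (species clades monophyletic, consistent with the pangenome
dendrogram at species level).  Tree comparison uses the unrooted
Robinson-Foulds distance (dendropy), so a degree-2 root cannot contribute a
phantom bipartition.

## Metagenomic read-recruitment profiling

Per-nucleotide depth is accumulated from SAM alignments (pysam): CIGAR
M/=/X blocks add depth, deletions consume reference without depth, insertions
and clips are ignored on the reference; coordinates are 0-based half-open
internally.  Reads are assumed to be single-assigned already (competitive
mapping is the aligner's job).  A plain (contig, pos, depth) table is
accepted as an alternative input dialect.

Detection is inclusive at the stated thresholds: a genome is detected in a
sample when at least 50% of its positions have >= 1x coverage; a gene when at
least 90% do.  Abundance is the Q2Q3 (interquartile) mean: depths are sorted
and positions with rank in [floor(L/4), ceil(3L/4)) are averaged — exactly
the middle half when L is divisible by 4, at least half otherwise.  Relative
abundance divides each genome's Q2Q3 mean by the summed Q2Q3 mean over all
reference genomes in the sample (default), with a `denominator="detected"`
switch restricting the denominator to detected genomes; the two conventions
both appear in the literature and the default follows the more inclusive one.
Undetected genomes are reported and still contribute to the default
denominator.  Species abundance is the sum over member genomes, emitted only
for samples where at least one genome was detected.

A caveat the tests quantify: the interquartile mean of an integer-valued
depth distribution is biased low at small mean depth (for Poisson-distributed
depths at 3.3x the bias is ~4%, at 13x ~1%, at 50x ~0.3%), because discrete
quantiles cannot straddle the mean symmetrically.  Ratio-recovery checks are
therefore run at coverage where the estimator operates in its intended
regime (tens of x for the weakest genome); at very low depth the statistic
is a detection-robust rank, not an unbiased density.

## Module completeness and enrichment

A metabolic module is an ordered list of steps, each satisfied by any of its
alternative orthologs (nested boolean definitions are out of scope; inputs
are pre-flattened).  Completeness is the fraction of satisfied steps; a
genome carries a complete module at >= 0.75.  Enrichment between genome
groups tests each item's indicator (module completeness, or raw function
presence) with the Rao score test of the logistic GLM `presence ~ group`
against the intercept-only model.  For a one-way categorical design the score
statistic equals the Pearson chi-square of the group x presence table,
referred to chi-square with (groups - 1) degrees of freedom; items identical
across genomes score 0 with p = 1.  P-values are Benjamini-Hochberg adjusted
within each pairwise group comparison (comparisons are not pooled), and items
with q <= 0.01 are flagged.  Fisher's exact test serves as a cross-check
oracle in the tests (rank concordance), not as the implementation.  At 10
genomes per group the chi-square reference is slightly liberal in the extreme
tail, so occasional borderline false flags among ~50 independent null items
are expected and are reported as such.

## Synthetic-data generator

The generator emulates the structure the pipeline is designed to detect:

* **Catalog** — an ancestral repertoire of gene families (random stop-free
  codon sequences, 300 nt by default, 60-nt intergenic spacers) is split into
  core (present everywhere), species-specific accessory, and per-genome
  singleton families in a 50/30/20 ratio; three species of four genomes each
  by default.  Species ancestors and genomes are derived by substitution
  along a two-level tree whose branch rates are solved analytically from the
  within-species (0.98) and between-species (0.85) ANI targets, using the
  exact composition rule for uniform substitution processes
  (p_eff = p1 + p2 - (4/3) p1 p2).  The substitution count per branch is
  conditioned on its expectation (round(rate x L) positions drawn without
  replacement): the process mean is unchanged while the realised pairwise
  identity concentrates tightly around the target (measured deviation
  <= 0.6%), which is what makes exact parameter-recovery assertions possible
  at desk-scale genome lengths.  Stop codons created by substitution are
  masked to X at translation, keeping the nucleotide process unbiased.
  No indels are introduced by default.
* **Metagenomes** — each species is tropic to one or more of the configured
  oral sites (round-robin by default, so every site recruits something);
  expected depth per genome and site is weight x depth_per_site (default
  50x), realised as error-free 100-nt reads at uniform random positions with
  the read count fixed at its expectation, written as plain SAM against the
  source genome (idealised competitive mapping).  Total read counts per
  sample back out from a configurable genus fraction (default 6.5%) so that
  mapped/total mirrors a realistic genus abundance.  A uniform read-error
  option exists for stressing the breadth thresholds.
* **Annotations** — 50 modules of 4 steps with 2 alternative orthologs per
  step; a configurable number (default 2) are planted complete only in a
  designated species group and far below the completeness threshold
  elsewhere; the rest are complete per genome independently with probability
  1/2.

What the generator does not emulate — and hence what passing tests do not
show about real data: within-species strain mixtures, indels and
rearrangements, horizontal transfer blurring species boundaries, sequencing
error profiles, host-read contamination, and the enormous size asymmetry of
real reference sets.  The generator's role is ground-truthed unit and
recovery testing, not benchmarking.

## Problem sizes and determinism

Default validation conditions: 12 genomes of ~12 kb (33 genes each), four
oral sites with three samples per site at 50x, 50 modules with 2 planted and
10 genomes per group for the power condition, 1,000 items for the type-I
check.  These sizes make the full pipeline run in about a minute while
leaving every recovery property comfortably identifiable.  All randomness
flows from a single integer seed (numpy Generator); a fixed seed reproduces
byte-identical FASTA/SAM/TSV outputs, which the test suite asserts.  Thread
count never affects results (the implementation is single-threaded numpy).

## Known limitations

* The seeded two-stage fragment search can in principle miss a best local
  alignment whose location edlib does not rank first; at the divergence
  levels where ANI is meaningful (>= 70% identity) this was never observed.
* Center-star alignment is not optimal for >2 divergent sequences; its star
  topology can misplace gaps relative to a true progressive aligner.  It is
  only used to build the trimmed supermatrix, where column-level noise is
  absorbed by the distance correction.
* The NJ tree has no branch support unless the bootstrap option is enabled,
  and no model selection; it is a distance method by design.
* MCL determinism holds for a fixed input ordering; gene ids are sorted
  wherever order could leak into output.
* The chi-square reference for the score test is asymptotic; at very small
  group sizes Fisher's exact test is the safer choice and is exposed in the
  test utilities.
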