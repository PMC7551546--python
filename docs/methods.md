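# Methods

## Scope and model

`mirrorphage` analyses a collection of partial phage genomes (contigs) with
predicted protein ORFs, relative to one complete reference genome. Three
measurements are made per reference gene: how widespread its homologs are,
how conserved they are, and how strongly their evolutionary history mirrors
that of every other gene. The package does not call genes, align with
external tools, or infer ML trees; those steps are accepted as inputs
(FASTA ORFs, aligned FASTA, 12-column tabular hits, phylip-style `.mldist`
matrices) and are replaced by self-contained equivalents where a run must
stand alone.

## Homology search and clustering

The built-in search is a single-pass Smith–Waterman alignment (BLOSUM62,
gap open −11 / extend −1, via Biopython's `PairwiseAligner`) of each
reference ORF against each database ORF. Significance uses the
Karlin–Altschul form `E = K·m·n·exp(−λS)` with fixed constants `K = 0.041`,
`λ = 0.267` — standard approximations for gapped BLOSUM62 scoring, adequate
for thresholding at `E ≤ 0.001`. Query coverage is (aligned query
residues)/(query length); the working threshold is 0.80, with 0.50 and 0.95
supported for sensitivity analysis. Hit sets are nested by construction
across these thresholds. An ORF that hits several references stays in every
cluster it hits; no best-hit resolution is attempted, because only the
ancient-paralog (`build_paralog_clusters`: only-A / only-B / union) and
split-reference (`merge_split_reference`) cases have principled
resolutions. Identical contigs (same ordered protein content) are
de-duplicated before clustering, and contigs represented in fewer than two
clusters are removed everywhere.

Duplication events are (cluster, contig) pairs with ≥ 2 member ORFs.
Split genes are detected from a *lenient* search (coverage ≥ 0.25): two
ORFs of one contig hitting the same reference on near-disjoint query
intervals (overlap ≤ 10% of the query), jointly covering ≥ 55% of it, and
sitting exactly two gene-order positions apart, with the inserted marker ORF
between them. The joint-coverage floor is deliberately far below 100%
because a local alignment trims the diverged ends of each gene piece and so
systematically understates its true extent; 55% still requires both pieces
to carry substantial, non-overlapping homology.

## Conservation

Column information is `log2(20) − H` bits with `H` the Shannon entropy of
residue frequencies computed over non-gap symbols; gaps are excluded from
the frequencies (keeping the 4.32-bit ceiling exact) and all-gap columns are
excluded from the alignment mean. No small-sample entropy correction is
applied. Conservation is related to ubiquity by the Pearson correlation
between `log10`(cluster size) and mean information, per functional category
and pooled, with a two-sided t-based p-value; categories with fewer than
five clusters are skipped with a warning because the fit is meaningless at
that size. Zero variance in either variable yields a NaN sentinel rather
than an exception.

## Mirrortree coevolution

Internal distances are Poisson-corrected 20-state distances
`d = −(19/20) ln(1 − (20/19) p)` over columns where neither row is gapped;
saturated pairs (`p ≥ 19/20`) are capped at `d = 10` with a warning, and a
pair with no shared ungapped columns is an error naming the pair. For each
family pair, both matrices are restricted to shared contigs; when a contig
contributes several sequences to a family, the representative is the copy
with the smallest mean distance to the other shared contigs (ties broken by
gene-order position). The strict upper triangles (diagonal excluded — the
zero diagonal would bias the statistic, and the lower triangle duplicates
points) are vectorised in a common contig order and compared with Pearson
correlation. Pairs sharing fewer than five *contigs* are discarded. Summary
outputs: symmetric all-pairs matrix (missing where discarded/undefined),
per-family mean over non-missing partners, histogram with fixed 0.05 bins
over [−1, 1], counts in caller-supplied coefficient ranges, and per-category
means. The category test is a one-tailed Mann–Whitney U (focal group
stochastically greater), exact by enumeration when the smaller group has
≤ 8 values and no ties, tie-corrected normal approximation otherwise; the
fully tied degenerate case returns p = 0.5. Neighbor joining (via
scikit-bio, labels sorted for deterministic tie-breaks, negative branch
lengths clamped to zero) is provided for clade-level reporting on distance
matrices.

## Synthetic-genome generator

The generator defines the study conditions under which the pipeline is
validated. Topologies are built by random sequential joins (uniform over
labelled topologies) with i.i.d. exponential branch lengths; sequences
evolve indel-free under a 20-state equal-rates (Poisson) model — along a
branch of length `t` each site is redrawn uniformly with probability
`1 − exp(−(20/19)t)`, so two sequences at path length `t` differ at an
expected fraction `(19/20)(1 − exp(−(20/19)t))` of sites. Core families all
evolve on one shared species tree; each accessory family gets its own
independent random tree with the same branch-length distribution — a
deliberately simple stand-in for horizontal acquisition that produces the
low-correlation mirrortree peak without modelling transfer events.

Defaults (40 genomes; 12 core + 6 accessory families; 200-residue proteins;
mean branch length 0.1 substitutions/site; truncation to a uniformly placed
window covering 40–90% of the gene order; three duplications at divergence
0.05; one gene split at residue 90 around a 60-residue marker in two
genomes) describe a moderately diverged clade in which typical
reference-to-leaf distances approach one substitution per site — deep enough
that conservation varies strongly across families, shallow enough that the
Poisson correction is far from saturation. Genome 0 (`ref`) is the complete
reference genome and is never truncated. Implant order is: assemble full
genomes → inject duplications (adjacent diverged copy) → inject the split
gene (N-piece, marker, C-piece; concatenating the pieces reproduces the
original gene exactly) → truncate. Truth records carry a `retained` flag
updated by truncation so that detection is judged against what the data
actually contain. The event-detection benchmark uses a shallower clade
(mean branch length 0.05): duplications and intron insertions of interest
are recent events among closely related genomes, and at large distances a
short diverged gene fragment legitimately drops below the 0.001 significance
threshold of any homology search.

What the generator does *not* emulate: insertions/deletions (so alignments
are trivially exact and alignment quality is never a confounder), rate
variation across sites, codon-level effects, gene-length variation within a
family, recombination within genes, and compositional bias. Passing tests
therefore demonstrate the correctness of the clustering/conservation/
mirrortree computations and their statistical behaviour under a clean
evolutionary signal — not robustness to alignment error or to non-Poisson
sequence evolution.

## Validation design

Statistics are checked two ways: against closed forms (the 4.32-bit ceiling,
`p = 0.5 → d = 0.70985`, the equal-rates p-distance expectation within 3
standard errors at length 10⁴) and against independent brute-force oracles
implemented in the tests (direct entropy sums, textbook Pearson with t-based
p, full enumeration of Mann–Whitney arrangements, dendropy patristic
distances on a hand-built additive tree). Benchmark problem sizes — 5
replicates of the 40-genome two-peak benchmark, 20 replicates of the
180-leaf subsampling experiment, one 20-genome event-detection round trip —
were chosen so the whole suite runs in well under a minute on one CPU while
keeping Monte-Carlo error small relative to the asserted margins.

## Known limitations

The significance surrogate is calibrated for BLOSUM62 with these gap costs
only; imported hits should be pre-filtered with their own e-values. The
split-gene detector assumes the marker is a single ORF directly between the
two pieces. The mirrortree statistic is not corrected for the background
speciation signal shared by all families, so absolute coefficients are
comparable within a dataset, not across datasets.
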