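# Methods

## The landscape procedure

Every analysis in this package reduces to the same three steps: compute a
per-gene scalar metric, order the genes on a reference genome, and smooth
the ordered series with a centered sliding window.

**Per-gene metrics.** GC content of a transcript is 100·(G+C)/(A+C+G+T)
with ambiguous IUPAC bases excluded from numerator and denominator, so
assembly gaps (N runs) neither inflate nor dilute the value; a sequence
with no unambiguous bases yields a missing value rather than an error.
Amino-acid usage is the mole fraction of each residue over the classified
residues of the protein (trailing stop stripped; B/Z/X/U/* excluded), and
the three group percentages are sums of member fractions. The groups are
GARP = {G,A,R,P} (GC-rich codons), FYMINK = {F,Y,M,I,N,K} (AU-rich codons)
and MIXED = the remaining ten residues. Tryptophan sits in MIXED: its
single codon UGG is neither GC- nor AU-rich, and placing it there is the
only assignment that partitions the 20 standard residues into 4 + 6 + 10
disjoint classes with percentages summing to 100.

**Reference order.** Genes are ranked 1..n by chromosome (natural sort:
chr2 before chr10) and midpoint coordinate within chromosome, for one
chosen reference species. Other species' genes are placed at the rank of
their reference ortholog; species-specific genes without a reference
counterpart are dropped, since everything downstream lives on the
reference axis.

**Sliding window.** The landscape value at rank k is the mean of the
metric over ranks max(1, k−w)..min(n, k+w) with half-width w = 50 by
default — a gene and its 100 nearest neighbors, sliding one gene at a
time. Two design choices were genuinely open:

* *Edges.* Windows are truncated at the ends of the ordered set (the mean
  runs over the available neighbors) instead of dropping the first and
  last w genes; an interior window always contains exactly 2w+1 values.
  Truncation keeps the landscape full-length at the cost of noisier end
  values; callers that want chromosome-local windows can smooth per
  chromosome by splitting the series first.
* *Missing genes.* Genes without a value (absent ortholog, missing
  sequence, discarded alignment) are removed before windowing, so every
  window is the mean of the 100 nearest *available* neighbors. This keeps
  window support constant across species with different gene complements.

The interior window mean is Lipschitz in any single gene: a perturbation
bounded by Δ moves it by at most Δ/(2w+1), i.e. a 100-point outlier moves
a 101-gene mean by 100/101 ≈ 0.99 < 1 point. The acceptance suite checks
this bound exhaustively on random series, and checks every window mean
against a brute-force range mean.

## Ortholog catalog

Catalogs are TSVs with one row per gene (symbol, chromosome, 1-based
inclusive coordinates, strand, RefSeq transcript accession, optional
transcript length and protein accession, species, clade). Finalizing a
catalog keeps protein-coding entries only — accession prefixes NM_ and XM_
(curated and predicted mRNA); NR_/XR_ (non-coding) and accession-less rows
are dropped — and retains the longest transcript per symbol, breaking ties
by lexicographically smallest accession for reproducibility. Symbol
matching across species is case-insensitive, with an explicit two-column
alias map for species-specific identifiers (LOC numbers); unmatched
symbols are reported, and duplicate symbols after aliasing are an error.
The common vertebrate gene set keeps a gene when at least `min_count` = 2
species among the basal clades {fish, amphibia, non-avian reptile} possess
it — a rule that anchors the set in deep-branching lineages rather than
the mammal-heavy part of a species sample.

## Protein divergence

Ortholog pairs are aligned globally with affine gap scoring (BLOSUM62;
gap run of length L costs open + (L−1)·extend, defaults open 12,
extend 2 — gap penalties are configurable since the conventional values
are a choice, not a law). The unknown residue X scores 0 against
everything and never counts as a match. Identity is

    matches / (alignment length − gap columns)

where a gap column is any column with a gap in either row: gapped columns
are removed from the denominator so truncated gene models (incomplete
sequence information) do not masquerade as divergence. Pairs below 30%
identity are discarded as unreliable orthology; divergence = 1 − identity
for the rest. The aligner is cross-checked in the test suite against an
independent enumerator that scores *every* global alignment: exhaustively
for all sequence pairs of lengths ≤ 3 over a 4-letter alphabet (7 056
pairs) and on a seeded sample of length-4..6 pairs, where full
enumeration of all ~30 M pairs would be pointless as well as slow.

## Landscape phylogenetics

The species × gene matrix holds smoothed values over the genes present in
every included species (smoothing happens after the intersection so all
vectors share window support). Pearson correlations are reported for all
unordered species pairs; clustering uses the Euclidean distance between
smoothed vectors by default, with 1 − r available as an alternative
reading, and average linkage (UPGMA) by default with single/complete/ward
selectable. The dendrogram is exported as Newick with node heights at half
the merge distance (ultrametric convention), and trees are compared by
unrooted Robinson–Foulds distance plus the Pearson correlation of
patristic distance matrices (cophenetic correlation). The clustering is
verified against a hand-rolled UPGMA-by-minimum-search oracle on random
distance matrices.

## The simulator

The generator plants exactly the structure the pipeline is meant to
detect, and nothing more:

* **GC target curve** — baseline (default 50%) plus Gaussian bumps
  (center rank, width = Gaussian σ in ranks, amplitude in points),
  clipped to [25, 75]%, the observed range of vertebrate mRNA GC.
* **GC-coupled codon usage** — each codon draws a residue group with
  P(GARP) = 0.25 + κ·(gc − 50)/100, P(FYMINK) mirrored, MIXED absorbing
  the rest (κ ∈ [0,1]); residues are uniform within group; the synonymous
  codon ends in G/C with probability gc/100 when the amino acid offers a
  choice. At κ = 1 and a ±15-point GC swing this produces windowed
  GC↔GARP correlations ≈ +0.99 — the strong-coupling regime in which the
  mirrored-landscape prediction should hold.
* **Branch evolution** — each site substitutes with probability
  1 − exp(−b·(1+β)) on a branch of length b, the replacement drawn from
  the other three bases. Inside a gBGC interval of bias β the rate is
  scaled by (1+β) *and* G/C replacements get weight (1+β): hotspots both
  accumulate GC and diverge faster, which is the co-location the
  divergence-landscape claim needs. Substitutions that would create a
  stop codon are rejected (the codon reverts), so proteins stay
  translatable without indel handling. With β = 0 and base composition at
  the uniform stationary point (50% GC) composition is stationary in
  expectation; away from 50% the neutral process relaxes slowly toward
  it, which over the short branches used here (b ≤ 0.3) perturbs planted
  structure by well under the smoothing noise.
* **Rearrangements** — Poisson(rate) contiguous gene blocks per branch
  move to uniformly random positions (block length ≤ 25 by default).
  Only gene order changes; coordinates are re-derived from the new order.

The substitution model is deliberately a per-site i.i.d. process with an
acceptance bias, not a mutation–selection model: the claims under test
concern composition and divergence *tracks along the genome*, not
realistic site-level evolution. The simulator also omits indels,
paralogy, annotation error and the mammal-biased gene sampling of real
catalogs — so green tests demonstrate that the pipeline recovers planted
regional structure from clean catalogs, not that real genomes contain
such structure.

A closed-form oracle backs the divergence tests: under the model the
descendant codon distribution is the site-independent product with the
stop mass returned to the ancestral codon, so the expected amino-acid
difference between two leaves is computable exactly and the simulated
mean divergence is checked against it at binomial tolerance.

## Problem sizes and defaults

Simulation-recovery analyses use 600–2 000 genes of 90–300 codons on 2–6
taxon trees with branch lengths 0.01–0.08 substitutions/site and gBGC
bias β = 3–4 — large enough that window means average ~100 genes as in
the full-scale method and that clade signal dominates sampling noise,
small enough to run in seconds. The window half-width default is 50
(window = gene + 100 neighbors), the identity discard threshold 0.30, and
all percentages are on the 0–100 scale.

## Known limitations

* Windows may cross chromosome boundaries (an option to smooth per
  chromosome is available by splitting the input); which behavior the
  genome-scale method should use is a judgment call.
* UPGMA assumes clock-like divergence of landscapes; strongly uneven gBGC
  exposure between sister lineages would distort branch lengths, though
  usually not topology.
* The identity denominator counts gap *columns*; counting gap characters
  instead is exposed to users only through the alignment result fields,
  not as a switch.
* Physical-axis landscapes concatenate chromosomes end-to-end by midpoint
  offset; inter-chromosomal gaps are not to scale.
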