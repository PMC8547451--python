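# Methods

## Scope and model

`envprimer` turns a curated functional-gene family plus reference
metagenome evidence into a minimal qPCR primer panel.  The underlying
assumptions are: (i) amino-acid identity clustering groups gene variants
that can share primers; (ii) read-alignment counts against cluster
representatives are a usable proxy for how much each variant matters in
the target environment; (iii) a primer amplifies a template only on a
perfect (100 %) match of both primers, which makes in silico coverage a
conservative, deterministic predicate; (iv) panel selection is a set-cover
problem over that predicate.

## Clustering and threshold choice

Pairwise protein identity is counted on the optimal global alignment under
BLOSUM62 with affine gaps (open 11, extend 1; Biopython's
`PairwiseAligner` computes the alignment) and divided by the length of the
shorter sequence.  The shorter-sequence denominator is the CD-HIT
convention: a perfect fragment is 100 % identical to its parent, which is
the right behavior when representatives are later used as alignment
subjects for short reads.  Identity counting depends on the scoring
scheme, so the scheme is pinned rather than configurable.

Clustering is greedy incremental, longest-first (ties broken by ascending
id): each sequence joins the first cluster whose representative it matches
at `identity >= threshold`, else founds a new cluster.  Representatives
are therefore always cluster founders and the longest members.  The
threshold sweep (default 80–100 % in 1 % steps) yields the curve N(t) of
cluster counts; the recommended operating point is the interior threshold
maximizing the symmetric difference (N(t+step) − N(t−step))/(2·step), ties
resolved toward the lower threshold — the onset of the steepest rise,
where the family's redundancy stops collapsing.  Thresholds compare
inclusively (`>=`), so a tie in the symmetric difference on a plateau edge
resolves to the threshold that still merges the subfamilies.

No k-mer prefilter is applied: inputs at desk scale (10²–10³ proteins)
cluster in seconds, and a prefilter would complicate the equivalence with
the step-by-step reference used in tests.

## Hit filtering and the R-score

Hits are 12-column BLAST/DIAMOND tabular rows, one file per metagenome.
Filtering keeps hits with identity ≥ `min_identity` (default 97 %), then
reduces each read to its single best hit per metagenome (highest bitscore,
ties to the lexicographically smallest subject) so one read never counts
toward two representatives.  The stated identity-over-gene-length rule is
ambiguous for reads shorter than the gene; the filter therefore applies an
optional read-coverage fraction (`min_aln_fraction_of_read`, default 0.8)
only when the caller supplies the read length, since hit tables do not
carry it.

Abundance is the raw count of retained hits per representative across all
metagenomes; prevalence the number of distinct metagenomes with ≥ 1 hit.
Both are min-max normalized across representatives — making the R-score a
bounded mean in [0, 1] — and averaged.  Two degenerate-case choices: a
statistic constant across all representatives normalizes to 1.0 (a gene
observed equally everywhere should rank maximal, not minimal), and a
single representative scores 1.0.  Abundance is deliberately a raw count,
not per-metagenome-size normalized; metagenome size normalization can be
done upstream by subsampling if needed.

Clusters are sorted by descending R-score (ties by ascending
representative id) and included until the cumulative score reaches
`cum_threshold` (default 0.8) of the total, the crossing cluster included.
All-zero scores are an error: nothing was observed, so ranking is
meaningless.

## Primer design

Within each selected cluster the member nucleotide sequences are aligned
by progressive center-star alignment around the longest member (match 5,
mismatch −4, gap open −10, extend −0.5); pre-aligned input can bypass this.
Center-star is adequate because within-cluster sequences are, by
construction of the clustering step, highly similar; it is deterministic
and dependency-free.

Design enumerates every window of primer length (default 18–25 nt) that is
gap-free in all rows, takes the minimal IUPAC consensus per column, and
keeps the window if its degeneracy (product of column base-set sizes) is
at most `max_degeneracy_per_primer` (default 6) and **every** plain-ACGT
expansion individually passes the GC window (default 35–65 %) and Tm
window (default 55–65 °C).  A degenerate primer is synthesized as an oligo
mixture, so its worst component governs.

Melting temperature uses the unified nearest-neighbor model (SantaLucia
1998): stack ΔH°/ΔS° sums with terminal initiation terms, entropic salt
correction ΔS += 0.368·(N−1)·ln[Na⁺] (default 50 mM), total strand
concentration 200 nM with the CT/4 term for non-self-complementary
duplexes and the −1.4 cal/(K·mol) symmetry term otherwise.  The Wallace
rule 2(A+T)+4(G+C) is available for quick estimates.  The implementation
is cross-checked in tests against an independent thermodynamic reference
to within 0.5 °C.

Windows pair as forward (consensus as-is) and reverse (reverse complement
of a downstream consensus) when: the windows do not overlap; for **every**
member the ungapped distance from forward start to reverse end lies in the
product range (default 70–200 bp, qPCR-appropriate) — alignment-level
spans can differ from per-member product lengths when indels sit between
the primers; and the two Tm intervals are compatible in the worst case,
max(hi_F − lo_R, hi_R − lo_F, 0) ≤ `max_tm_gap_within_pair` (default
3 °C), i.e. no combination of one expansion from each side exceeds the
gap.  Because consensus windows cover every observed base and per-member
product lengths are checked at pairing time, every emitted pair amplifies
every member it was designed on — an invariant the evaluation stage
re-verifies.

Valid windows combine combinatorially, so a cluster can admit thousands of
acceptable pairs; pairs are sorted by (members matched exactly,
descending; coordinates ascending) and only the top
`max_pairs_per_cluster` (default 50) are emitted.  Coordinates are 0-based
half-open on the cluster alignment.  No hairpin/self-dimer/cross-dimer or
3'-stability screening is performed in this version; the output schema
leaves room for such columns.

## In silico PCR and coverage

Degenerate pairs expand to the cartesian product of their per-primer
expansions, deduplicated globally on (forward, reverse) with first
occurrence kept; expanded ids are the parent id plus an ordinal following
lexicographic (forward, reverse) order.  The pre-deduplication count
Σ deg(F)·deg(R) is reported alongside.

`find_amplicons` enumerates all forward/reverse binding-site combinations
under exact string equality on both template orientations (gene
collections do not guarantee a deposition strand); `N` in a template
matches nothing, and only products within the length bounds are reported.
Evaluation of designed pairs uses the same product range as design;
published-primer comparison uses a wide 50–1,500 bp window because
external pairs target arbitrary regions.

The boolean pair-by-gene matrix feeds per-cluster targeting rates
(covered / cluster size, % to 2 decimals) and panel selection: greedy set
cover (pick the pair covering the most uncovered genes; ties prefer the
pair with the smaller total coverage, then ascending id) runs until no
pair adds coverage, so coverage always equals the union over all
candidates; a final sweep removes any pair whose coverage the rest of the
selection subsumes, leaving every retained pair with a uniquely covered
gene.  Greedy set cover is the standard ln(n)-approximation; an exhaustive
minimum-cardinality solver (`exact_min_cover`) is included for small
instances and used in tests to bound greedy's panel size.  On the classic
trap instance where pure greedy grabs a large middle set, the redundancy
sweep recovers the optimum; the approximation gap can still appear on
instances whose greedy picks each retain a private gene.

## Synthetic fixtures

The generator emulates the two external inputs.  Gene families: a random
ancestor gene (random codons, no stops) is mutated at disjoint codon
positions into subfamily ancestors and then into member genes, with
mutation counts chosen so realized pairwise amino-acid divergences land on
the within- and between-subfamily targets (whole-codon rounding is the
only slack, ≲ 2 % at the default 150 codons); ~5 % of codons additionally
swap synonymously so nucleotide variation exceeds amino-acid variation as
in real coding genes.  Defaults — 3 subfamilies × 4 genes, 450 nt, 2 %
within / 30 % between divergence — give a family whose sweep curve has one
clean step, the smallest structure that exercises threshold
recommendation, ranking, and multi-cluster design.

Read sets: per metagenome, a planted weight matrix splits reads
multinomially across genes (defaults: 5 metagenomes × 200 reads of 90 nt,
10 % uniform-random background that cannot pass a 97 % identity filter);
reads are error-free substrings sampled uniformly along the gene, and the
realized counts are returned as ground truth.  Hit tables are emitted
directly from that truth with identity 100·(1−noise) jittered ±0.5 and
capped at 100, so noise 0 stays above, and noise ≥ 0.05 below, the default
filter.  Everything is reproducible bit-for-bit from the seeds.

What the fixtures do **not** model: sequencing error profiles, quality
scores, chimeras, gene-length variation within a family, paralog
cross-talk, or real aligner score distributions.  Passing tests therefore
demonstrate the pipeline's bookkeeping and algorithmic contracts — counts,
scores, coverage, determinism — not robustness to noisy real-world
alignments.

## Determinism and degenerate inputs

Every tie in the pipeline is broken deterministically (lengths, then
lexicographic ids; lowest threshold; smallest subject; ascending pair id),
and all randomness flows through explicit integer seeds, so a rerun on
identical inputs is byte-identical — asserted at the artifact level in
tests.  Degenerate inputs fail loudly rather than silently: empty
sequences, duplicate ids, gap characters inside consensus blocks,
non-IUPAC codes, all-zero R-scores, and hit subjects that are not known
representatives are all hard errors with located messages.

## Problem sizes

Default test and acceptance runs use the 12-gene / 5-metagenome fixture
(~1,000 planted reads), a 21-point threshold sweep, and ≤ 10 × 12
set-cover instances for the exhaustive cross-checks — sizes chosen so the
exact oracles (full alignment-path enumeration, subset enumeration,
all-positions scans) stay tractable while every pipeline stage is
exercised end to end.
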