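# Methods

This note documents the models, statistics and design choices behind
`taprna`, and what the synthetic fixture does and does not establish.

## Coordinate model

All internal coordinates are 0-based half-open on the forward strand. GTF
(1-based closed) and the MAF-style mutation table (1-based positions) are
converted at the I/O boundary; BED/BEDPE pass through unchanged. On the
minus strand the TSS is reported as the half-open end coordinate of the
transcript span, which makes promoter windows mirror exactly:
`[TSS − up, TSS + down)` on `+` becomes `[TSS − down, TSS + up)` on `−`.
The distance from a point to an interval is 0 inside, `start − pos` to the
left and `pos − end + 1` to the right (distance to the last base), so
distances are strand-symmetric.

## Candidate catalogue

A candidate lncRNA must have ≥ 2 exons (`min_exons`), no exon overlapping
any CDS interval on the same chromosome *and strand* (antisense overlap is
explicitly allowed — antisense lncRNAs are a core category), and a longest
ATG-initiated open reading frame below `max_orf_codons` = 100 codons over
the three forward frames of the spliced sequence. The ORF scorer is a
transparent, testable stand-in for heavier coding-potential classifiers and
can be replaced via the `coding_scorer` hook; the threshold lives in
config. Catalogue merging keys on the intron chain (chrom, strand, ordered
intron boundaries); annotated records win over assembled ones, and
surviving assembled transcripts are the "novel" fraction.

## Promoter synteny mapping

Promoters default to TSS −1000/+500 bp (configurable; the window is a
common convention, and all downstream overlap calls read it from config).
Cross-genome placement is seed-and-refine: edlib's semi-global ("HW")
bit-parallel search locates the best candidate locus of the full promoter
on each chromosome and strand, and an affine-gap Smith–Waterman
(Bio.Align.PairwiseAligner; match +1, mismatch −1, gap open −2, extend −1;
`N` mismatches everything including `N`) rescoring of the padded window
produces the reported alignment. A hit qualifies with identity ≥ 0.6
(matched columns / aligned columns) over ≥ `synteny_window` = 500 aligned
columns. Ties among co-optimal alignments break to the lowest start in the
query, then in the target, so results are exactly reproducible. Genome-scale
users can bypass the aligner entirely by supplying precomputed hits.

## pcRNA calling and orientation classes

A record is emitted per human candidate isoform when (a) its promoter has a
qualifying hit, (b) the hit lies within `association_window` = 50 kb of the
ortholog of the associated gene, (c) a spliced lncRNA in the other species
has its TSS within half the promoter window of the hit, and (d) the
orientation agrees between species at the sense/antisense level (strict
seven-way agreement is an optional mode). The associated gene is the
nearest ortholog-bearing coding gene within 50 kb of the promoter midpoint,
ties to the earlier start.

Classification is a fixed decision order that makes the classifier total
and deterministic: span overlap → AS (opposite strand) or OLAP (same);
otherwise divergent head-to-head TSSs within `bidirectional_window` = 1 kb
→ BT; otherwise the position in the gene's 5′→3′ frame crossed with
relative strand gives US-S/US-AS/DS-S/DS-AS. A convergent (tail-to-tail)
close pair is deliberately *not* BT and falls through to DS-AS/US-AS.
Systematic names append the category to the gene symbol, with positional
ordinals only when several distinct promoters share a (symbol, category).
Isoforms sharing an identical promoter interval count once in
promoter-level summaries. Summary percentages are integer-rounded
(`round(100·k/n)`).

## Topology statistics

A pcRNA is a tapRNA iff its promoter intersects a loop anchor by ≥ 1 bp,
strand-agnostic — the conservative anchor-only rule; the OR-set (anchor
overlap or TAD boundary within 10 kb) is reported separately. TAD
boundaries are both end coordinates of every domain, nested domains
contributing all of theirs. Overlap enrichment is the exact hypergeometric
upper tail with the population = test ∪ background. Meta-locus profiles
average per-transcript coverage over `[−flank, body scaled to body_bins,
+flank]`, strand-oriented; bin edges are the exact integer partition
`i·L // n`. Co-occupancy correlation is Pearson on the flattened paired
binary matrices, with a column-pairing permutation null and add-one
smoothing `(s+1)/(n_perm+1)`. Distal-anchor chromatin states assign each
base to one state by a configurable priority list (default: any label
containing "Enhancer" counts as enhancer); state-fraction distributions are
compared with the two-sided two-sample KS test, exact for samples of ≤ 10.

## Conserved domains

Each 100-nt window (step 50, plus a tail window so no 3′ bases are blind)
of the human spliced transcript is locally aligned against the entire other
transcript — patches need not be collinear. Window identity is defined as
matched columns / window length (coverage-weighted): a local alignment
keeps only positive-scoring columns, so normalising by aligned columns
alone would let a 10-nt exact sliver qualify a 100-nt window, and unrelated
sequences would never score zero patches. Windows at ≥ `domain_min_identity`
= 0.6 merge into patches; conservation groups are high ≥ 0.73 of the
transcript (anchored to the published top-group description), medium ≥
0.30, low > 0, none = 0 — the medium/low cut-offs are package defaults.
Binned patch profiles are clustered by average-linkage agglomerative
clustering on Euclidean distance, cut at `n_minor` and `n_major`; labels
are renumbered by first occurrence so the assignment is deterministic.

## Motifs and mutations

8-mer counting is single-strand in transcript space with overlaps allowed;
k-mers containing `N` are skipped but their positions still count toward
totals. Enrichment is the one-sided Fisher exact test on the 2×2 position
table, computed through the equivalent hypergeometric upper tail and
vectorised over unique count pairs; foreground = conserved patches,
background = the non-conserved remainder of the same transcripts, so
composition biases partially cancel. α = 10⁻⁴ raw (a BH option exists, off
by default). Consensus clustering is greedy: the most significant
unassigned k-mer seeds a cluster and absorbs every k-mer whose best
ungapped offset alignment has ≥ `min_overlap` = 6 shared positions and
≤ `max_mismatch` = 1 mismatches; cluster PWMs use +0.5 pseudocounts. PWM
scanning is double-strand log-odds against the motif background with a
threshold of `min_score_fraction` × maximum attainable score; windows
containing `N` are skipped. The mutation-burden unit is the motif *site*
(mutated yes/no), making the 2×2 one-sided Fisher test independent of
per-sample mutation multiplicity; duplicate (sample, position, alt) records
collapse first. A tapRNA locus is promoter ∪ transcript span, and the
background mirrors that definition on non-tapRNA lncRNAs.

## Expression statistics

Spearman ρ is Pearson on average ranks; zero-variance members are excluded
and logged, never imputed as ρ = 0. The mean-correlation permutation test
pre-ranks all rows once and evaluates each derangement-style re-pairing
with vectorised dot products; p uses add-one smoothing, so the smallest
attainable p is `1/(n_perm+1)`. Matched backgrounds (expression level or
intergenic span) sample the pool without replacement to reproduce the test
set's quantile-bin counts exactly, erroring on underfilled bins. Tissue
specificity is τ (scale-invariant; 0 uniform, 1 one-hot); the choice of τ
is a documented default, with the function exposed so alternatives can be
plugged.

## Synthetic data: what it emulates

The generator lays out disjoint ~17-kb loci along 2 × 500-kb chromosomes
(uniform base composition by default; a GC-bias knob is deliberately absent
from defaults because k-mer enrichment is composition-sensitive). Each
planted pcRNA locus holds one orthologous coding gene (3 exons, CDS in
exons 2–3, random strand) and one spliced lncRNA placed by category
geometry in the gene's frame, mirrored with gene strand. Promoters are
copied across genomes and point-mutated at `promoter_mutation_rate`
(default 0.1); the middle exon is copied as a known conserved domain
carrying three instances of the planted 8-mer; the rest of the partner
transcript stays random (identity ≈ 0.25, far below threshold). Stop
codons are planted into any spliced ORF reaching 100 codons (avoiding
planted k-mers, preferring positions outside copied regions) because
~1.3-kb uniform-random transcripts would otherwise fail the ORF filter
about 10% of the time and contaminate recovery measurements. CTCF-like and
ZNF263-like consensus instances are planted in lncRNA introns before the
cross-species copy. Half the planted pcRNAs receive loops whose proximal
anchor overlaps their promoter, with enhancer states covering a configured
fraction of the distal anchor; background loops and peaks avoid all
promoters. Expression couples each pair through a Gaussian copula with
latent correlation `2·sin(π·ρ_s/6)`, so the planted target is exact on the
Spearman scale; species share per-pair tissue effects (weight 0.7), giving
positive cross-species correlation. The copula relation targets the
population coefficient; the finite-sample Spearman estimator at 12 tissues
is biased slightly toward zero, so cohort means sit a few hundredths below
the planted value (≈ 0.22 for a planted 0.25 over 50 pairs). Optional sparsification zeroes the
smallest tissues until a τ target is met — this ties ranks and attenuates
ρ, so correlation-calibration experiments run with sparsification off (the
default). Mutations hit motif sites in tapRNA loci at rate 0.3 and
background sites at 0.1, one mutation per selected site, uniform within the
site.

Every stage draws from `default_rng([seed, stage])`, so identical configs
produce byte-identical files regardless of call order.

**What passing tests do not show:** the fixture has uniform base
composition, exact planted copies, disjoint loci, no repeats,
no assembly/annotation error, clean one-to-one orthology and idealised
loop/TAD geometry. Recovery rates and p-values measured on it characterise
the correctness and calibration of the computations, not expected
performance on real genomes, where promoter alignment specificity, ortholog
ambiguity and composition biases dominate.

## Problem sizes and numerical choices

Default analyses run at fixture scale: 2 × 500 kb genomes, ~40 planted
pcRNAs + 10 decoys, 12 tissues, 100-seed power replicates for the k-mer and
mutation designs, 200-run calibration sweeps, and exhaustive oracle sweeps
to N ≤ 30 urns — sizes chosen so the full suite and the acceptance script
each complete in minutes on one CPU while keeping every check exact or
well-powered. Permutation tests default to 10⁴ permutations (999 in the
acceptance script). Exact KS enumeration switches to the asymptotic
distribution above sample size 10. Known limitation: the site-level Fisher
design with 60 test vs 300 background sites at rates 0.3/0.1 has exact
power 0.888 at α = 0.01 (by binomial enumeration), so experiments at that
scale should expect roughly one in nine replicates to miss.
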