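# Methods

This note documents the models, algorithms and numerical choices behind
`fabpscan`, and what the synthetic benchmarks do and do not demonstrate.

## Translated homology search

The search follows classic TBlastN semantics. Each contig is translated in
six frames (standard genetic code; codons containing ambiguity characters
become `X`, stops `*`). Seeding uses exact 3-mer words expanded to a scored
neighborhood (BLOSUM62, neighborhood threshold 12 — the smallest value that
keeps every exact self-word, since the minimum 3-mer self-score under
BLOSUM62 is 12). Single-hit seeding with per-diagonal deduplication feeds an
ungapped X-drop extension (drop 40 raw ≈ 20 bits); candidates scoring ≥ 35
raw are refined by gapped Smith–Waterman in a band of ±16 residues around
the seed diagonal, padded 24 residues beyond the ungapped extent. `X` scores
0 against everything (neutral ambiguity).

**Statistics.** Bit scores and E-values use gapped Karlin–Altschul
parameters for BLOSUM62 with gap open 11 / extend 1: λ = 0.267, K = 0.041;
`E = K·m·n·e^(−λS)` with `m` the query length (aa) and `n` the total
translated search space. The stringent reporting cutoff (default 1e-10) is
applied to **linked HSP sets**: HSPs on one contig/strand that are colinear
in query and subject within an intron-sized gap are evaluated on their
summed raw score, with doubly covered query spans discounted at 5 per
residue so overlap cannot inflate significance. This mirrors BLAST's sum
statistics and is what makes a 15–25 aa internal exon — individually worth
only ~10^-3…10^-6 — reportable as part of a gene whose other exons anchor
the hit. Only HSPs with raw score ≥ 45 may join a multi-HSP set, which keeps
random ungapped noise (expected ≈ 1 per desk-scale genome at that score)
from piggybacking. Isolated HSPs still pass on their own E-value.

Not implemented (out of scope): two-hit seeding, composition-based
statistics, SEG masking, protein–protein mode.

## From HSPs to gene models

**Chaining.** Per (contig, strand), a weighted-interval-scheduling DP
selects the maximum-total-score HSP subset that is strictly increasing in
query and subject, with query overlap ≤ 10 aa and genomic gap ≤ 5,000 nt
(both configurable). The best chain is extracted, its genomic span cleared,
and extraction repeats, so several loci per contig are handled; hits
dispersed over two or more contigs always yield independent chains.

**Tail trimming.** A local alignment retains any terminal run whose sum is
positive, so HSPs routinely overrun exon boundaries into translated intron
on marginally positive columns. Before chaining, each HSP trace is trimmed
to its maximum-sum contiguous column run after subtracting a bias of 2 per
column (Kadane's algorithm) — tails averaging below 2/column go, the
well-supported core stays. `find_hsps` output itself is left untrimmed, so
its top score remains the true local-alignment optimum.

**Gap-fill rescue.** Exon boundaries are determined from highly scoring
segment pairs *and from the gaps within them*: when a chain leaves ≥ 5
unaligned query residues at a junction (or ≥ 15 at either end), the
corresponding genomic gap is re-searched with a full Smith–Waterman of just
that query stretch. In a locus-restricted search space a raw score of 30
(internal; 45 terminal) is already significant, which recovers the minimal
exons that genome-wide thresholds miss. The scan repeats until no gap
qualifies.

**Splice-site snapping.** Initial boundaries come from HSP subject ends.
For each junction, all donor/acceptor pairs with `GT`…`AG` within ±15 nt of
the initial boundaries (widened by 3 nt per unaligned or doubly aligned
query residue at that junction) are enumerated; only pairs that preserve
the reading frame across the junction qualify. Among candidates the
*realigned junction score* — the spliced translation around the junction
scored against the query — decides, with total boundary displacement and
then lexicographic order as tie-breaks. Junction score comes first because
HSP ends over- and undershoot real boundaries for reasons unrelated to
displacement; on planted genes this choice is what pushes exact junction
recovery to ~99%. A junction with no qualifying pair keeps its HSP-derived
boundaries and is flagged `noncanonical`.

**ORF anchoring.** The model's protein is the full open reading frame: the
start is the furthest upstream in-frame ATG before the first in-frame stop
(scanned up to 900 nt; nearest downstream ATG as fallback), and the last
exon extends to the first in-frame stop codon (up to 1,200 nt). This
matters for oversized decoys — a multi-domain protein carrying a FABP-like
region must be measured at its full ORF length, exactly how a 987-aa
hypothetical protein with a C-terminal FABP-like domain fails the size
window despite a strong local hit. Exons include the stop codon (GFF3 CDS
convention), so a clean model's summed exon length is `3·(protein+1)`.
Models whose spliced CDS still contains an internal stop are returned
flagged `broken_orf`; the pipeline rejects them with that reason before the
size filter.

**Size filter.** Kept iff 80 ≤ protein length ≤ 180 aa, bounds inclusive
(130 ± 50 aa around the typical FABP length). The partition is lossless;
rejected models carry `reject_reason="size"`.

## Transcript evidence and event classification

Transcripts are mapped by chaining **maximal exact matches ≥ 15 nt**
against a locus window (model span ± 500 nt), maximizing matched length
with ties preferring junctions whose genomic gap starts `GT` and ends `AG`,
then fewer blocks. Exact matching is justified because the evidence is
same-genome synthetic or curated cDNA; there is deliberately no
mismatch-tolerant mode by default. A trailing run of ≥ 8 A's is trimmed as
poly(A); trimmed A's that continue the final block genomically are
reclaimed, so a CDS ending in `TAA` still maps to its full exon.

Classification per transcript: **exon skipping** — an internal exon with
zero coverage while both flanking exons are fully covered and a block
junction matches the annotated boundaries; **intron retention** — one block
contiguously covering an intron plus ≥ 10 nt of both flanking exons;
**alternative last exon** — the final block ending strictly inside an
intron, ≥ 10 nt past the donor; **SL trans-splicing** — an unmatched 5'
prefix matching a catalog leader with ≤ 1 substitution and absent from the
500 nt upstream (i.e. genuinely non-encoded). Because exact block extension
can absorb up to a few leader bases that coincide with the genome at the
acceptor, the leader match tolerates a ≤ 4 nt truncation at its 3' end.
A faithful transcript yields no events; one transcript may yield several.
Evidence strings count distinct event signatures: `t` = annotated faithful
form plus observed signatures, `v` = signatures with ≥ 1 complete
alignment.

Not covered: short-read RNA-seq, isoform quantification, SL2/operon logic.

## Key-residue audit

Candidates are globally aligned (Needleman–Wunsch, affine gaps costing
`open + (L−1)·extend` with open 11 / extend 1, end gaps penalized,
deterministic tie-breaking) to an annotated reference, and six sites are
projected through the alignment: the P2 motif arginines and tyrosine
(Arg…Arg-x-Tyr), the helix-1 phenylalanine, and the βE–βF turn pair, which
accepts Ala-Asp or Pro-Asp. Each site reports match / substituted /
deleted; "intact" requires all six to match. The packaged default template
is a **synthetic** 131-aa reference generated with annotated site positions
(F16, P72-D73, R106, R126, Y128, 0-based) — real FABPs' site numbering
varies by species, so the audit is template-relative by design and accepts
any user template. Percent identity is computed over gap-free columns only
(the denominator convention is recorded here because published identity
ranges rarely state theirs). Secondary/tertiary-structure prediction is a
pluggable hook that reports "not-evaluated" unless a predictor is supplied.

## Census reports

The architecture census bins exon counts 1–6 per species with counts above
six in a flagged overflow bucket; totals conserve the model count. Species
summary rows keep transcript-only species (zero genomic loci). The
intron-retention statistic assigns each intron of a 1–2-intron gene to the
nearest canonical intron position within ±5 aa (protein coordinates;
unassignable introns are counted separately) and reports "a/b": models
retaining the first canonical position over models with any assignable
intron. Duplicate loci encoding identical proteins count separately in
locus counts and the census but are flagged in identity statistics, where
extremes over byte-identical pairs are degenerate. Packaged TSV fixtures
hold the published 34-species feature rows and per-species exon-count rows
used by the aggregation tests.

## Synthetic data: what it emulates, and what it does not

`make_genome` plants `n_genes` gene models derived from a seed query
protein by codon-level substitutions to a target amino-acid identity
(default 0.85; position 0 Met never mutated, no stops introduced), with
exon counts drawn from a configurable distribution over 1–6, introns of
60–500 nt starting `GT` and ending `AG` at recorded phase 0/1/2, and a
minimum exon size of 45 nt. Default layout: 6 contigs × 30 kb with loci
separated by 5.2–6.8 kb flanks of random sequence — FABP loci overwhelmingly
lie on separate scaffolds or far apart, and the separation keeps distinct
loci beyond intron-sized chaining reach. Decoys are single-exon ORFs
embedding a mutated query core inside junk at lengths outside 80–180 aa
(defaults 200–400 and 40–70 aa). Duplicate loci re-encode the first gene's
protein with independent codon choices and introns. Everything is
deterministic for a fixed spec + seed (one `numpy` generator per call, no
global state).

Two generator choices exist purely to make ground truth well-defined: an
in-frame stop codon sits immediately upstream of every planted ORF (so the
true start is identifiable from sequence — both common in real genes and
necessary for any homology method to have a unique answer), and the base
just downstream of each gene is non-A (so the poly(A) boundary of a
faithful transcript maps back uniquely). Transcripts get a 20-nt poly(A)
tail by default.

What passing these benchmarks shows: the search/chain/snap/classify
machinery is internally correct down to exact coordinates under realistic
divergence, architecture and strand conditions. What it does not show:
robustness to sequencing error, assembly artifacts, indel divergence
between query and target (the generator mutates by substitution only),
non-canonical splice sites, or transcript evidence from a different
haplotype — real surveys still require the manual checking the original
workflow used.

**Measured under the default conditions** (reproduced by
`scripts/acceptance.py` and the acceptance tests): 197/200 planted models
recovered with exact exon boundaries over seeds 0–19 (98.5%); every
canonical-flagged intron satisfies GT..AG; alternative-splicing
classification exact on all planted events including SL1 detection;
search, chaining and global-alignment scores agree with brute-force oracles
on every tested case.

## Problem sizes and determinism

The benchmark sizes (20 genomes × 10 genes for recovery, 2 genomes of
planted events for classification, 2 contigs for the Smith–Waterman oracle,
25 chain instances, 20 alignment-enumeration pairs) were chosen so the
whole acceptance run completes in well under a minute while keeping the
recovery denominator at 200 models. All randomness flows from a single
integer seed; the pipeline writes a manifest (config hash, seed, per-stage
counts) and reruns are byte-identical.
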