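"""Transcript evidence: spliced mapping, spliced-leader detection and
alternative-splicing classification.

Transcripts (cDNA/EST) are mapped back onto a genomic window around a gene
model by chaining maximal exact matches; block placement is exact because
the evidence is same-genome synthetic or curated cDNA (a mismatch-tolerant
mode is deliberately not on by default). From the block structure the module
classifies exon skipping, intron retention, alternative last exons and
spliced-leader (SL) trans-splicing, and summarizes per-locus support as the
"validated/total variants" string used in species reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import revcomp
from .models import GeneModel

__all__ = [
    "SLCatalog",
    "LocusWindow",
    "Block",
    "SplicedAlignment",
    "ASEvent",
    "make_locus_window",
    "spliced_map",
    "detect_sl",
    "classify_as_events",
    "evidence_summary",
]

DEFAULT_SL1 = "GGTTTAATTACCCAAGTTTGAG"


@dataclass
class SLCatalog:
    """Known spliced-leader sequences and the allowed mismatch budget."""

    leaders: dict[str, str] = field(default_factory=lambda: {"SL1": DEFAULT_SL1})
    max_mismatch: int = 1
    #: tolerated 3'-truncation of the leader when exact block extension has
    #: absorbed leader bases that coincide with the genomic acceptor context
    max_absorbed: int = 4

    def __post_init__(self) -> None:
        if not self.leaders or any(not s for s in self.leaders.values()):
            raise ValueError("leaders must be nonempty sequences")


@dataclass
class LocusWindow:
    """A genomic window around one gene model (plus-strand sequence)."""

    contig_id: str
    start: int
    end: int
    strand: str
    seq: str
    model_id: str

    @property
    def tseq(self) -> str:
        """Window sequence in transcription orientation."""
        return self.seq if self.strand == "+" else revcomp(self.seq)

    def t_interval(self, plus_interval: tuple[int, int]) -> tuple[int, int]:
        """Plus-strand genomic interval -> window transcription coordinates."""
        a, b = plus_interval
        if self.strand == "+":
            return a - self.start, b - self.start
        w = self.end - self.start
        return self.start + w - b, self.start + w - a

    def plus_interval(self, t_interval: tuple[int, int]) -> tuple[int, int]:
        a, b = t_interval
        if self.strand == "+":
            return self.start + a, self.start + b
        w = self.end - self.start
        return self.start + w - b, self.start + w - a


def make_locus_window(
    genome: Mapping[str, str], model: GeneModel, margin: int = 500
) -> LocusWindow:
    contig = genome[model.contig_id]
    lo, hi = model.span
    start = max(0, lo - margin)
    end = min(len(contig), hi + margin)
    return LocusWindow(
        contig_id=model.contig_id,
        start=start,
        end=end,
        strand=model.strand,
        seq=contig[start:end],
        model_id=model.model_id,
    )


@dataclass
class Block:
    """One gap-free match: transcript [t0,t1) vs locus-transcription [l0,l1)."""

    t0: int
    t1: int
    l0: int
    l1: int


@dataclass
class ASEvent:
    """A typed alternative-splicing call tied to a model and a transcript."""

    event_type: str
    model_id: str
    transcript_id: str
    detail: dict


@dataclass
class SplicedAlignment:
    """Block-wise placement of a transcript on a locus window.

    Blocks are in locus transcription coordinates; ``genomic_blocks`` maps
    them back to plus-strand contig intervals. ``unmatched_prefix`` is the
    transcript 5' sequence preceding the first block; ``complete`` means all
    non-prefix transcript sequence is placed.
    """

    transcript_id: str
    model_id: str
    contig_id: str
    strand: str
    blocks: list[Block]
    unmatched_prefix: str
    polya_trimmed: int
    complete: bool
    locus: LocusWindow = field(repr=False, default=None)
    upstream_seq: str = field(repr=False, default="")

    @property
    def mapped(self) -> bool:
        return bool(self.blocks)

    def genomic_blocks(self) -> list[tuple[int, int]]:
        """Plus-strand contig intervals, transcription order."""
        return [self.locus.plus_interval((b.l0, b.l1)) for b in self.blocks]


# ---------------------------------------------------------------------------


def _maximal_matches(core: str, lseq: str, min_block: int) -> list[Block]:
    """Maximal exact matches >= min_block between transcript core and locus."""
    k = min_block
    if len(core) < k or len(lseq) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(lseq) - k + 1):
        index.setdefault(lseq[i : i + k], []).append(i)
    reach: dict[int, int] = {}  # diagonal -> furthest t extended
    out: list[Block] = []
    for t in range(len(core) - k + 1):
        positions = index.get(core[t : t + k])
        if not positions:
            continue
        for l in positions:
            diag = l - t
            if reach.get(diag, -1) >= t:
                continue
            t0, l0 = t, l
            while t0 > 0 and l0 > 0 and core[t0 - 1] == lseq[l0 - 1]:
                t0 -= 1
                l0 -= 1
            t1, l1 = t + k, l + k
            while t1 < len(core) and l1 < len(lseq) and core[t1] == lseq[l1]:
                t1 += 1
                l1 += 1
            reach[diag] = t1
            out.append(Block(t0, t1, l0, l1))
    out.sort(key=lambda b: (b.t0, b.l0))
    return out


def _chain_blocks(blocks: list[Block], lseq: str, min_gap: int = 4) -> list[Block]:
    """Colinear chain maximizing matched length; ties prefer GT..AG gaps,
    then fewer blocks."""
    n = len(blocks)
    if n == 0:
        return []
    # DP value: (matched, gtag_junctions, -n_blocks)
    score = [(b.t1 - b.t0, 0, -1) for b in blocks]
    back = [-1] * n
    for j in range(n):
        bj = blocks[j]
        for i in range(j):
            bi = blocks[i]
            if bj.t1 <= bi.t1 or bj.l1 <= bi.l1 or bj.t0 < bi.t0:
                continue
            gap = (bj.l0 - bj.t0) - (bi.l1 - bi.t1)  # genomic gap after trimming
            overlap = max(0, bi.t1 - bj.t0)
            if gap < min_gap:
                continue
            add = (bj.t1 - bj.t0) - overlap
            if add <= 0:
                continue
            gtag = 0
            # junction GT/AG at any split of the overlap counts for the tie-break
            for s in range(bj.t0 + (0 if overlap else 0), bi.t1 + 1):
                ga = bi.l1 - (bi.t1 - s)
                gb = bj.l0 + (s - bj.t0)
                if lseq[ga : ga + 2] == "GT" and lseq[gb - 2 : gb] == "AG":
                    gtag = 1
                    break
            cand = (score[i][0] + add, score[i][1] + gtag, score[i][2] - 1)
            if cand > score[j]:
                score[j] = cand
                back[j] = i
    j = max(range(n), key=lambda k: (score[k], -blocks[k].t0, -k))
    idx = []
    while j != -1:
        idx.append(j)
        j = back[j]
    idx.reverse()
    chain = [Block(b.t0, b.t1, b.l0, b.l1) for b in (blocks[i] for i in idx)]
    # resolve transcript overlaps at junctions, preferring GT..AG introns
    for prev, nxt in zip(chain, chain[1:]):
        overlap = prev.t1 - nxt.t0
        if overlap <= 0:
            continue
        split = prev.t1  # default: keep prev intact
        for s in range(nxt.t0, prev.t1 + 1):
            ga = prev.l1 - (prev.t1 - s)
            gb = nxt.l0 + (s - nxt.t0)
            if lseq[ga : ga + 2] == "GT" and lseq[gb - 2 : gb] == "AG":
                split = s
                break
        prev.l1 -= prev.t1 - split
        prev.t1 = split
        nxt.l0 += split - nxt.t0
        nxt.t0 = split
    return chain


def spliced_map(
    transcript: str,
    locus: LocusWindow,
    *,
    transcript_id: str = "transcript",
    min_block: int = 15,
    polya_min: int = 8,
    upstream_nt: int = 500,
) -> SplicedAlignment:
    """Map a transcript onto a locus window by chaining exact matches.

    A trailing run of >= ``polya_min`` A's is trimmed first (and counted);
    trimmed A's that continue the final block genomically are reclaimed.
    Returns an unmapped alignment (no exception) when no block of
    ``min_block`` nt exists.
    """
    transcript = transcript.upper()
    lseq = locus.tseq
    tail = len(transcript) - len(transcript.rstrip("A"))
    if tail >= polya_min:
        core = transcript[: len(transcript) - tail]
        trimmed = tail
    else:
        core, trimmed = transcript, 0
    if len(core) < min_block:
        return SplicedAlignment(
            transcript_id, locus.model_id, locus.contig_id, locus.strand,
            [], core, trimmed, False, locus, "",
        )
    mems = _maximal_matches(core, lseq, min_block)
    chain = _chain_blocks(mems, lseq)
    if not chain:
        return SplicedAlignment(
            transcript_id, locus.model_id, locus.contig_id, locus.strand,
            [], core, trimmed, False, locus, "",
        )
    # reclaim polyA bases that are genomically encoded after the final block
    last = chain[-1]
    core_len = len(core)
    while trimmed > 0 and last.l1 < len(lseq) and lseq[last.l1] == "A":
        last.l1 += 1
        last.t1 += 1
        core_len += 1
        trimmed -= 1
    prefix = core[: chain[0].t0]
    covered = all(b.t1 == nb.t0 for b, nb in zip(chain, chain[1:]))
    complete = covered and chain[-1].t1 == core_len
    upstream = lseq[max(0, chain[0].l0 - upstream_nt) : chain[0].l0]
    return SplicedAlignment(
        transcript_id, locus.model_id, locus.contig_id, locus.strand,
        chain, prefix, trimmed, complete, locus, upstream,
    )


# ---------------------------------------------------------------------------


def detect_sl(
    alignment: SplicedAlignment, catalog: SLCatalog | None = None
) -> ASEvent | None:
    """Call SL trans-splicing from an unmatched 5' prefix.

    The prefix must match a catalog leader (anchored at the exon-1 junction,
    allowing the leader's 3' end to have been absorbed into the first block
    by up to ``max_absorbed`` chance matches) with at most ``max_mismatch``
    substitutions, and must be absent from the 500 nt upstream of the locus,
    i.e. genuinely non-encoded.
    """
    catalog = catalog or SLCatalog()
    prefix = alignment.unmatched_prefix
    if not prefix or not alignment.blocks:
        return None
    for name in sorted(catalog.leaders):
        leader = catalog.leaders[name]
        L, k = len(leader), len(prefix)
        if k <= L:
            if L - k > catalog.max_absorbed:
                continue
            ref = leader[:k]
            cmp = prefix
        else:
            ref = leader
            cmp = prefix[-L:]
        mism = sum(1 for x, y in zip(cmp, ref) if x != y)
        if mism > catalog.max_mismatch:
            continue
        if prefix in alignment.upstream_seq:
            continue  # encoded upstream: not trans-spliced
        return ASEvent(
            "sl_trans_splicing",
            alignment.model_id,
            alignment.transcript_id,
            {"leader": name},
        )
    return None


def classify_as_events(
    model: GeneModel,
    alignments: Sequence[SplicedAlignment],
    catalog: SLCatalog | None = None,
    *,
    flank: int = 10,
) -> list[ASEvent]:
    """Classify alternative-splicing events per transcript against a model.

    Per transcript: exon skipping when an internal annotated exon has zero
    block coverage while both flanking exons are fully covered with junction
    boundaries matching the annotation; intron retention when one block
    contiguously covers an annotated intron plus >= ``flank`` nt of both
    flanking exons; alternative last exon when the final block ends strictly
    inside an annotated intron and >= ``flank`` nt past the donor; SL calls
    are delegated to :func:`detect_sl`. A faithful transcript yields no
    events; one transcript may yield several.
    """
    catalog = catalog or SLCatalog()
    events: list[ASEvent] = []
    for aln in alignments:
        if aln.contig_id != model.contig_id:
            raise ValueError(
                f"alignment {aln.transcript_id} is on contig {aln.contig_id}, "
                f"model on {model.contig_id}"
            )
        if not aln.blocks:
            continue
        locus = aln.locus
        exons_t = [locus.t_interval(e) for e in model.exons]
        introns_t = [locus.t_interval(i) for i in model.introns]
        blocks = [(b.l0, b.l1) for b in aln.blocks]

        def coverage(interval: tuple[int, int]) -> int:
            a, b = interval
            return sum(max(0, min(b, l1) - max(a, l0)) for l0, l1 in blocks)

        n = len(exons_t)
        # exon skipping
        for k in range(1, n - 1):
            ek = exons_t[k]
            if coverage(ek) != 0:
                continue
            prev_e, next_e = exons_t[k - 1], exons_t[k + 1]
            if coverage(prev_e) != prev_e[1] - prev_e[0]:
                continue
            if coverage(next_e) != next_e[1] - next_e[0]:
                continue
            junction_ok = any(
                l1 == prev_e[1] and nl0 == next_e[0]
                for (l0, l1), (nl0, nl1) in zip(blocks, blocks[1:])
            )
            if junction_ok:
                events.append(
                    ASEvent("exon_skipping", model.model_id, aln.transcript_id,
                            {"exon": k + 1})
                )
        # intron retention
        for j, (ia, ib) in enumerate(introns_t):
            for l0, l1 in blocks:
                if l0 <= ia - flank and l1 >= ib + flank:
                    events.append(
                        ASEvent("intron_retention", model.model_id, aln.transcript_id,
                                {"intron": j + 1})
                    )
                    break
        # alternative last exon
        fl0, fl1 = blocks[-1]
        for j, (ia, ib) in enumerate(introns_t):
            if ia < fl1 < ib and fl1 - ia >= flank:
                events.append(
                    ASEvent("alt_last_exon", model.model_id, aln.transcript_id,
                            {"intron": j + 1, "breakpoint": fl1 - ia})
                )
        sl = detect_sl(aln, catalog)
        if sl is not None:
            events.append(sl)
    return events


def evidence_summary(
    models: Sequence[GeneModel],
    aligned: Mapping[str, Sequence[tuple[SplicedAlignment, Sequence[ASEvent]]]],
) -> dict[str, str]:
    """Per-locus "v/t" evidence strings.

    ``t`` counts distinct predicted transcript variants (the annotated
    faithful form plus every distinct event combination observed); ``v``
    counts variants with at least one complete supporting alignment.
    """
    out: dict[str, str] = {}
    for model in models:
        pairs = aligned.get(model.model_id, [])
        signatures: dict[frozenset, bool] = {frozenset(): False}
        for aln, events in pairs:
            if not aln.mapped:
                continue
            sig = frozenset(
                (e.event_type, tuple(sorted(e.detail.items()))) for e in events
            )
            supported = signatures.get(sig, False) or aln.complete
            signatures[sig] = supported
        t = len(signatures)
        v = sum(1 for ok in signatures.values() if ok)
        out[model.model_id] = f"{v}/{t}"
    return out
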