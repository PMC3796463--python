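"""Gene-model construction from HSPs.

HSPs sharing a query are chained colinearly per (contig, strand) by
weighted-interval-scheduling dynamic programming; each chain becomes one
gene model. Initial exon boundaries come from HSP subject ends; every
inter-HSP gap is treated as a candidate intron whose donor/acceptor pair is
snapped to the nearest in-frame GT..AG pair within a window. Terminal exons
are anchored at the nearest in-frame ATG and extended to the first in-frame
stop codon. Chains never span contigs: hits dispersed over two or more
contigs yield independent chains, one per contig.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from dataclasses import replace

from ._seq import CODON_MAP, STOP_CODONS, revcomp, translate_cds
from .search import HSP, FilterConfig, ScoringScheme, _frame_to_plus, _trace_stats

__all__ = [
    "GeneModel",
    "Chain",
    "Architecture",
    "chain_hsps",
    "snap_splice_sites",
    "build_models",
    "size_filter",
    "classify_architecture",
]

log = logging.getLogger(__name__)

MIN_INTRON = 4  # room for GT..AG


@dataclass
class GeneModel:
    """A strand-aware exon chain on one contig.

    ``exons`` are 0-based half-open plus-strand intervals listed in
    transcription order (descending plus coordinates on the minus strand).
    The CDS includes the stop codon, so the summed exon length of a clean
    model is ``3 * (len(protein) + 1)``. ``splice_flags`` holds one
    'canonical'/'noncanonical' flag per intron; canonical means the intron
    starts GT and ends AG read in transcription orientation.
    """

    model_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    protein: str
    splice_flags: list[str] = field(default_factory=list)
    source: str = "predicted"
    broken_orf: bool = False
    score: float | None = None
    reject_reason: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        plus_sorted = sorted(self.exons)
        if self.strand == "-":
            expected = sorted(self.exons, reverse=True)
        else:
            expected = plus_sorted
        if self.exons != expected:
            raise ValueError("exons must be listed in transcription order")
        for (a0, a1), (b0, b1) in zip(plus_sorted, plus_sorted[1:]):
            if a1 > b0:
                raise ValueError("exons must not overlap")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Plus-strand intervals between consecutive exons, transcription order."""
        out = []
        for (a0, a1), (b0, b1) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a1, b0))
            else:
                out.append((b1, a0))
        return out

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for e in self.exons]
        ends = [e[1] for e in self.exons]
        return min(starts), max(ends)

    def cds(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in transcription orientation."""
        contig = genome[self.contig_id]
        parts = []
        for a, b in self.exons:
            piece = contig[a:b]
            parts.append(piece if self.strand == "+" else revcomp(piece))
        return "".join(parts)

    def intron_seq(self, genome: Mapping[str, str], i: int) -> str:
        """Intron ``i`` (0-based, transcription order) read in transcription
        orientation."""
        a, b = self.introns[i]
        piece = genome[self.contig_id][a:b]
        return piece if self.strand == "+" else revcomp(piece)


@dataclass
class Chain:
    """Colinear HSPs from one query on one contig/strand, transcription order."""

    hsps: list[HSP]
    total_score: float

    def __post_init__(self) -> None:
        contigs = {h.contig_id for h in self.hsps}
        if len(contigs) > 1:
            raise ValueError("a chain must not span contigs")

    @property
    def contig_id(self) -> str:
        return self.hsps[0].contig_id

    @property
    def strand(self) -> str:
        return self.hsps[0].strand

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Plus-strand genomic intervals between consecutive HSPs."""
        out = []
        for a, b in zip(self.hsps, self.hsps[1:]):
            if self.strand == "+":
                out.append((a.s_end, b.s_start))
            else:
                out.append((b.s_end, a.s_start))
        return out


def _compatible(prev: HSP, nxt: HSP, max_intron: int, max_query_overlap: int) -> bool:
    if nxt.q_start < prev.q_end - max_query_overlap or nxt.q_end <= prev.q_end:
        return False
    if prev.strand == "+":
        gap = nxt.s_start - prev.s_end
    else:
        gap = prev.s_start - nxt.s_end
    return -3 * max_query_overlap <= gap <= max_intron


def _best_chain(
    hsps: list[HSP], max_intron: int, max_query_overlap: int
) -> tuple[list[int], float]:
    """Maximum-total-score colinear subset via DP over transcription order."""
    n = len(hsps)
    best = [h.raw_score for h in hsps]
    back = [-1] * n
    for j in range(n):
        for i in range(j):
            if _compatible(hsps[i], hsps[j], max_intron, max_query_overlap):
                cand = best[i] + hsps[j].raw_score
                if cand > best[j]:
                    best[j] = cand
                    back[j] = i
    j = max(range(n), key=lambda k: (best[k], -k))
    idx = []
    while j != -1:
        idx.append(j)
        j = back[j]
    idx.reverse()
    return idx, best[idx[-1]]


def chain_hsps(
    hsps: Sequence[HSP], max_intron: int = 5000, max_query_overlap: int = 10
) -> list[Chain]:
    """Chain HSPs of one query into colinear groups, one gene locus each.

    Per (contig, strand) the highest-scoring colinear subset is extracted,
    its genomic span is cleared (overlapping leftovers are logged and
    dropped), and extraction repeats on the remainder, so several loci per
    contig are supported. HSP sets spanning multiple contigs always yield
    one chain per contig.
    """
    queries = {h.query_id for h in hsps}
    if len(queries) > 1:
        raise ValueError("chain_hsps expects HSPs from a single query")
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.contig_id, h.strand), []).append(h)
    chains: list[Chain] = []
    for (cid, strand), group in sorted(groups.items()):
        # transcription order
        group.sort(key=(lambda h: (h.s_start, h.q_start)) if strand == "+" else (lambda h: (-h.s_end, h.q_start)))
        remaining = list(group)
        while remaining:
            idx, score = _best_chain(remaining, max_intron, max_query_overlap)
            chosen = [remaining[i] for i in idx]
            chains.append(Chain(hsps=chosen, total_score=score))
            lo = min(h.s_start for h in chosen)
            hi = max(h.s_end for h in chosen)
            nxt = []
            for k, h in enumerate(remaining):
                if k in idx:
                    continue
                if min(h.s_end, hi) - max(h.s_start, lo) > 0:
                    log.info(
                        "dropping HSP overlapping chained locus %s:%d-%d", cid, lo, hi
                    )
                    continue
                nxt.append(h)
            remaining = nxt
    chains.sort(key=lambda c: (c.contig_id, c.hsps[0].s_start))
    return chains


# ---------------------------------------------------------------------------
# HSP end trimming

def trim_hsp_ends(
    hsp: HSP,
    query: str,
    genome: Mapping[str, str],
    scoring: ScoringScheme,
    bias: float = 2.0,
    _frame_cache: dict | None = None,
) -> HSP | None:
    """Trim weakly supported HSP tails before chaining.

    A local alignment keeps any tail whose summed score is positive, so HSPs
    routinely overrun exon boundaries into translated intron sequence on
    marginally positive columns. Trimming keeps the maximum-sum contiguous
    column run after subtracting ``bias`` per column (Kadane), which removes
    tails scoring below ``bias`` per column on average while leaving the
    well-supported core untouched. Returns None when nothing survives.
    Requires the alignment trace and frame; HSPs read from tabular files are
    returned unchanged.
    """
    if hsp.aligned_pairs is None or hsp.frame < 0:
        return hsp
    key = (hsp.contig_id, hsp.strand, hsp.frame)
    cache = _frame_cache if _frame_cache is not None else {}
    if key not in cache:
        contig = genome[hsp.contig_id]
        src = contig if hsp.strand == "+" else revcomp(contig)
        cache[key] = translate_cds(src, hsp.frame)
    fr_aa = cache[key]
    cols = hsp.aligned_pairs
    contribs = []
    in_gap = False
    for qi, si in cols:
        if qi is None or si is None:
            contribs.append(-(scoring.gap_open if not in_gap else scoring.gap_extend))
            in_gap = True
        else:
            contribs.append(scoring.score(query[qi], fr_aa[si]))
            in_gap = False
    # max-sum contiguous run of (contrib - bias)
    best_sum, best_lo, best_hi = -1.0, 0, 0
    cur, lo = 0.0, 0
    for i, c in enumerate(contribs):
        cur += c - bias
        if cur > best_sum:
            best_sum, best_lo, best_hi = cur, lo, i + 1
        if cur < 0:
            cur, lo = 0.0, i + 1
    if best_sum <= 0:
        return None
    kept = cols[best_lo:best_hi]
    if best_lo == 0 and best_hi == len(cols):
        return hsp
    q_idx = [c[0] for c in kept if c[0] is not None]
    s_idx = [c[1] for c in kept if c[1] is not None]
    if not q_idx or not s_idx:
        return None
    contig_len = len(genome[hsp.contig_id])
    s0, s1 = _frame_to_plus(hsp.strand, hsp.frame, s_idx[0], s_idx[-1] + 1, contig_len)
    q_enc = scoring.encode(query)
    s_enc = scoring.encode(fr_aa)
    align_len, mism, gapo, pident = _trace_stats(kept, q_enc, s_enc)
    raw = float(sum(contribs[best_lo:best_hi]))
    return replace(
        hsp,
        q_start=q_idx[0],
        q_end=q_idx[-1] + 1,
        s_start=s0,
        s_end=s1,
        raw_score=raw,
        bit_score=scoring.bit_score(raw),
        pct_identity=pident,
        align_len=align_len,
        n_mismatch=mism,
        n_gapopen=gapo,
        aligned_pairs=kept,
    )


# ---------------------------------------------------------------------------
# exon rescue in chain gaps

def _sw_best_end(q_enc, s_enc, mat, go, ge) -> tuple[float, int, int]:
    """Score and end coordinates of the best local affine-gap alignment."""
    n, m = len(q_enc), len(s_enc)
    NEG = float(-(10**9))
    prev_m = [0.0] * (m + 1)
    prev_d = [NEG] * (m + 1)
    prev_i = [NEG] * (m + 1)
    best, bq, bs = 0.0, 0, 0
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_d = [NEG] * (m + 1)
        cur_i = [NEG] * (m + 1)
        qa = q_enc[i - 1]
        for j in range(1, m + 1):
            cur_d[j] = max(prev_m[j] - go, prev_d[j] - ge)
            cur_i[j] = max(cur_m[j - 1] - go, cur_i[j - 1] - ge)
            cand = max(0.0, prev_m[j - 1], prev_d[j - 1], prev_i[j - 1])
            val = cand + float(mat[qa, s_enc[j - 1]])
            cur_m[j] = val
            if val > best:
                best, bq, bs = val, i, j
        prev_m, prev_d, prev_i = cur_m, cur_d, cur_i
    return best, bq, bs


def _local_sw_small(q_enc, s_enc, mat, go, ge) -> tuple[float, int, int, int, int]:
    """Full local affine-gap DP for small rescue regions.

    Returns (score, q0, q1, s0, s1); the start is located by rerunning the
    DP on the reversed prefixes (the classic two-pass trick).
    """
    best, q1, s1 = _sw_best_end(q_enc, s_enc, mat, go, ge)
    if best <= 0:
        return 0.0, 0, 0, 0, 0
    rbest, rq, rs = _sw_best_end(q_enc[:q1][::-1], s_enc[:s1][::-1], mat, go, ge)
    return best, q1 - rq, q1, s1 - rs, s1


def _rescue_exons(
    chain: "Chain",
    query: str,
    genome: Mapping[str, str],
    scoring: ScoringScheme,
    *,
    max_intron: int,
    min_gap_aa: int = 5,
    # short terminal truncations are healed by the ATG/stop anchoring during
    # snapping; only a plausibly whole missing exon justifies a rescue scan
    min_terminal_aa: int = 15,
    internal_min_raw: float = 30.0,
    terminal_min_raw: float = 45.0,
    terminal_search_nt: int = 2000,
) -> "Chain":
    """Recover small exons hiding in the gaps within a chained hit.

    Minimal exons (15-20 aa) frequently score below the genome-wide
    reporting thresholds; once a gene locus is established by its stronger
    exons, the unaligned query stretch at each junction (or chain end) is
    re-searched against just the local genomic gap, where the tiny search
    space makes modest scores significant. Hits above the rescue thresholds
    are inserted as additional chain members; the scan repeats until no gap
    qualifies.
    """
    contig = genome[chain.contig_id]
    L = len(contig)
    strand = chain.strand
    tseq = contig if strand == "+" else revcomp(contig)
    q_enc = scoring.encode(query)
    m = len(query)
    frame_aa = {f: translate_cds(tseq, f) for f in range(3)}
    frame_enc = {f: scoring.encode(frame_aa[f]) for f in range(3)}

    def to_t(h: HSP) -> tuple[int, int]:
        return _to_t((h.s_start, h.s_end), L, strand)

    def scan(q_lo: int, q_hi: int, r0: int, r1: int, min_raw: float) -> HSP | None:
        if q_hi - q_lo < 3 or r1 - r0 < 3 * (q_hi - q_lo) // 2:
            return None
        qs = q_enc[q_lo:q_hi]
        best = None
        for f in range(3):
            a0 = max(0, (r0 - f + 2) // 3)
            a1 = max(a0, min(len(frame_aa[f]), (r1 - f) // 3))
            if a1 - a0 < 4:
                continue
            score, bq0, bq1, bs0, bs1 = _local_sw_small(
                qs, frame_enc[f][a0:a1], scoring.matrix, scoring.gap_open, scoring.gap_extend
            )
            if best is None or score > best[0]:
                best = (score, f, a0 + bs0, a0 + bs1, q_lo + bq0, q_lo + bq1)
        if best is None or best[0] < min_raw:
            return None
        score, f, sa0, sa1, bq0, bq1 = best
        if bq1 <= bq0 or sa1 <= sa0:
            return None
        t0, t1 = f + 3 * sa0, f + 3 * sa1
        s0, s1 = (t0, t1) if strand == "+" else (L - t1, L - t0)
        return HSP(
            query_id=chain.hsps[0].query_id,
            contig_id=chain.contig_id,
            strand=strand,
            frame=f,
            q_start=bq0,
            q_end=bq1,
            s_start=s0,
            s_end=s1,
            raw_score=float(score),
            bit_score=scoring.bit_score(score),
            evalue=0.0,
            pct_identity=0.0,
            align_len=bq1 - bq0,
            n_mismatch=0,
            n_gapopen=0,
        )

    hsps = list(chain.hsps)
    changed = True
    while changed:
        changed = False
        spans = [to_t(h) for h in hsps]
        # internal gaps
        for i in range(len(hsps) - 1):
            q_lo, q_hi = hsps[i].q_end, hsps[i + 1].q_start
            if q_hi - q_lo < min_gap_aa:
                continue
            r0 = spans[i][1] + MIN_INTRON
            r1 = spans[i + 1][0] - MIN_INTRON
            found = scan(max(0, q_lo - 2), min(m, q_hi + 2), r0, r1, internal_min_raw)
            if found is not None:
                hsps.insert(i + 1, found)
                changed = True
                break
        if changed:
            continue
        # missing first exon
        q0 = hsps[0].q_start
        if q0 >= min_terminal_aa:
            r1 = spans[0][0] - MIN_INTRON
            r0 = max(0, r1 - min(max_intron, terminal_search_nt) - 3 * q0)
            found = scan(0, min(m, q0 + 2), r0, r1, terminal_min_raw)
            if found is not None:
                hsps.insert(0, found)
                changed = True
                continue
        # missing last exon
        q1 = hsps[-1].q_end
        if m - q1 >= min_terminal_aa:
            r0 = spans[-1][1] + MIN_INTRON
            r1 = min(len(tseq), r0 + min(max_intron, terminal_search_nt) + 3 * (m - q1))
            found = scan(max(0, q1 - 2), m, r0, r1, terminal_min_raw)
            if found is not None:
                hsps.append(found)
                changed = True
    if len(hsps) != len(chain.hsps):
        return Chain(hsps=hsps, total_score=sum(h.raw_score for h in hsps))
    return chain


# ---------------------------------------------------------------------------
# splice-site snapping


def _to_t(interval: tuple[int, int], L: int, strand: str) -> tuple[int, int]:
    a, b = interval
    if strand == "+":
        return a, b
    return L - b, L - a


def _junction_score(
    tseq: str,
    query: str | None,
    scoring: ScoringScheme,
    exon_start: int,
    cum_before: int,
    d: int,
    a: int,
    next_end: int,
) -> int:
    """Score of the re-translated junction context against the query.

    Used only to break ties between equally displaced GT/AG pairs; returns 0
    when no query sequence is available.
    """
    if query is None:
        return 0
    cum_d = cum_before + (d - exon_start)
    x = cum_d % 3 + 3 * min(6, (cum_d // 3), (d - exon_start) // 3)
    y = 3 * min(7, (next_end - a) // 3)
    nt = tseq[d - x : d] + tseq[a : a + y]
    pep = translate_cds(nt)
    qa0 = (cum_d - x) // 3
    score = 0
    for t, ch in enumerate(pep):
        qi = qa0 + t
        if 0 <= qi < len(query):
            score += scoring.score(query[qi], ch)
    return score


def snap_splice_sites(
    chain: Chain,
    genome: Mapping[str, str],
    window: int = 15,
    query: str | None = None,
    scoring: ScoringScheme | None = None,
    *,
    start_window: int = 900,
    end_window: int = 1200,
    merge_gap: int = 20,
    model_id: str | None = None,
) -> GeneModel:
    """Refine a chain into a gene model with GT/AG-snapped intron boundaries.

    For every inter-HSP gap the donor/acceptor pair is moved within
    ``+/-window`` nt (widened by the unaligned query gap) to the GT..AG pair
    that preserves the reading frame across the junction and minimizes total
    boundary displacement; ties are broken by the realigned junction score
    against ``query`` and then lexicographically. Gaps with no in-frame
    GT..AG pair keep their HSP-derived boundaries and are flagged
    noncanonical. The first exon is anchored at the nearest in-frame ATG and
    the last exon extended to the first in-frame stop codon. Models whose
    spliced CDS still contains an internal stop are flagged ``broken_orf``
    but returned.
    """
    if not chain.hsps:
        raise ValueError("empty chain")
    scoring = scoring or ScoringScheme.default()
    contig = genome[chain.contig_id]
    L = len(contig)
    strand = chain.strand
    tseq = contig if strand == "+" else revcomp(contig)

    # exon scaffold in transcription coordinates
    raw = [_to_t((h.s_start, h.s_end), L, strand) for h in chain.hsps]
    qcoords = [(h.q_start, h.q_end) for h in chain.hsps]
    exons: list[list[int]] = []
    qgaps: list[int] = []  # unaligned query aa before each junction
    qovs: list[int] = []   # query overlap at each junction (overshoot signal)
    for (ts, te), (q0, q1) in zip(raw, qcoords):
        if exons and ts - exons[-1][1] < merge_gap:
            exons[-1][1] = max(exons[-1][1], te)
        else:
            if exons:
                qgaps.append(max(0, q0 - prev_q1))
                qovs.append(max(0, prev_q1 - q0))
            exons.append([ts, te])
        prev_q1 = q1

    anchors = [ts % 3 for ts, _ in exons]

    # start-codon anchoring: the maximal open reading frame. Walk upstream
    # in frame from the first HSP boundary and take the furthest ATG before
    # the first in-frame stop (the 5'-most start of the ORF); with no
    # upstream ATG, fall back to the nearest downstream ATG inside the exon.
    ts0 = exons[0][0]
    start = None
    p = ts0 - 3
    while p >= 0 and ts0 - p <= start_window:
        codon = tseq[p : p + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            start = p
        p -= 3
    if start is None:
        if tseq[ts0 : ts0 + 3] == "ATG":
            start = ts0
        else:
            p = ts0 + 3
            while p + 3 <= exons[0][1]:
                codon = tseq[p : p + 3]
                if codon in STOP_CODONS:
                    break
                if codon == "ATG":
                    start = p
                    break
                p += 3
    if start is not None:
        exons[0][0] = start
        anchors[0] = start % 3

    # junction snapping, left to right
    flags: list[str] = []
    cum = 0
    for j in range(len(exons) - 1):
        ex = exons[j]
        nx = exons[j + 1]
        d0, a0 = ex[1], nx[0]
        # widen the window by the unaligned query gap (missing codons may
        # belong to either exon) and by the query overlap (an HSP that
        # overshot into the intron displaces the true boundary inward)
        qgap3 = 3 * qgaps[j]
        qov3 = 3 * qovs[j]
        best: tuple | None = None
        d_lo = max(ex[0] + 3, d0 - window - qov3)
        d_hi = min(a0 - MIN_INTRON, d0 + window + qgap3)
        a_lo = max(d0 + MIN_INTRON, a0 - window - qgap3)
        a_hi = min(nx[1] - 3, a0 + window + qov3)
        for d in range(d_lo, d_hi + 1):
            if tseq[d : d + 2] != "GT":
                continue
            for a in range(a_lo, a_hi + 1):
                if a - d < MIN_INTRON or tseq[a - 2 : a] != "AG":
                    continue
                cum_d = cum + (d - ex[0])
                carry = (3 - cum_d % 3) % 3
                if (a + carry) % 3 != anchors[j + 1] % 3:
                    continue
                disp = abs(d - d0) + abs(a - a0)
                js = _junction_score(tseq, query, scoring, ex[0], cum, d, a, nx[1])
                # realigned junction score first (HSP ends can overshoot or
                # undershoot the real boundary), displacement as tie-break
                cand = (-js, disp, d, a)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            d, a = best[2], best[3]
            ex[1] = d
            nx[0] = a
            flags.append("canonical")
        else:
            flags.append(
                "canonical"
                if tseq[ex[1] : ex[1] + 2] == "GT" and tseq[nx[0] - 2 : nx[0]] == "AG"
                else "noncanonical"
            )
        cum += ex[1] - ex[0]

    # stop-codon extension of the last exon
    last = exons[-1]
    cum_last = sum(e[1] - e[0] for e in exons[:-1])
    carry = (3 - cum_last % 3) % 3
    p = last[0] + carry
    limit = min(len(tseq) - 2, last[1] + end_window)
    while p + 3 <= limit:
        if tseq[p : p + 3] in STOP_CODONS:
            last[1] = p + 3
            break
        p += 3
    else:
        # no stop found: trim to a codon boundary
        last[1] = last[0] + carry + 3 * ((last[1] - last[0] - carry) // 3)

    cds = "".join(tseq[a:b] for a, b in exons)
    pep = translate_cds(cds)
    if pep.endswith("*"):
        protein = pep[:-1]
    else:
        protein = pep
    broken = ("*" in protein) or (len(cds) % 3 != 0) or not protein

    plus_exons = [
        (a, b) if strand == "+" else (L - b, L - a) for a, b in exons
    ]
    span_lo = min(e[0] for e in plus_exons)
    span_hi = max(e[1] for e in plus_exons)
    mid = model_id or f"{chain.contig_id}:{span_lo}-{span_hi}({strand})"
    return GeneModel(
        model_id=mid,
        contig_id=chain.contig_id,
        strand=strand,
        exons=[tuple(e) for e in plus_exons],
        protein=protein,
        splice_flags=flags,
        source="predicted",
        broken_orf=broken,
        score=chain.total_score,
    )


def build_models(
    hsps: Sequence[HSP],
    genome: Mapping[str, str],
    filt: FilterConfig | None = None,
    *,
    max_intron: int = 5000,
    max_query_overlap: int = 10,
    window: int = 15,
    query: str | None = None,
    scoring: ScoringScheme | None = None,
    trim_bias: float = 2.0,
) -> list[GeneModel]:
    """Chain HSPs and snap every chain into a gene model (no size filter)."""
    scoring = scoring or ScoringScheme.default()
    if query is not None:
        cache: dict = {}
        trimmed = []
        for h in hsps:
            t = trim_hsp_ends(h, query, genome, scoring, bias=trim_bias, _frame_cache=cache)
            if t is not None:
                trimmed.append(t)
        hsps = trimmed
    chains = chain_hsps(hsps, max_intron=max_intron, max_query_overlap=max_query_overlap)
    if query is not None:
        chains = [
            _rescue_exons(c, query, genome, scoring, max_intron=max_intron)
            for c in chains
        ]
    models = []
    for i, chain in enumerate(chains):
        models.append(
            snap_splice_sites(
                chain, genome, window=window, query=query, scoring=scoring,
                model_id=f"model{i:03d}_{chain.contig_id}",
            )
        )
    return models


def size_filter(
    models: Iterable[GeneModel], filt: FilterConfig | None = None
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Partition models by translated protein length (bounds inclusive).

    Rejected models carry ``reject_reason='size'``; no model is lost.
    """
    filt = filt or FilterConfig()
    kept, rejected = [], []
    for m in models:
        if filt.min_protein_len <= len(m.protein) <= filt.max_protein_len:
            kept.append(m)
        else:
            m.reject_reason = "size"
            rejected.append(m)
    return kept, rejected


Architecture = namedtuple(
    "Architecture", ["exon_count", "intron_phases", "intron_positions"]
)


def classify_architecture(model: GeneModel) -> Architecture:
    """Exon count plus, per intron, the interrupted amino-acid position and
    the intron phase (0/1/2). A 1-exon model is intronless: empty lists."""
    phases, positions = [], []
    cum = 0
    lengths = [b - a for a, b in model.exons]
    for ln in lengths[:-1]:
        cum += ln
        positions.append(cum // 3)
        phases.append(cum % 3)
    return Architecture(len(model.exons), phases, positions)
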