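"""TBlastN-style translated homology search.

A protein query is compared against all six reading frames of every contig
using seed-and-extend: exact 3-mer word seeds expanded to a scored
neighborhood, ungapped X-drop extension, then gapped banded Smith-Waterman
refinement around surviving seeds. Each high-scoring segment pair (HSP)
receives a Karlin-Altschul E-value ``K*m*n*exp(-lambda*S)`` with ``m`` the
query length and ``n`` the total translated search-space length; HSPs above
the configured E-value cutoff are discarded.

Single-hit seeding only; no two-hit heuristics, composition-based statistics
or low-complexity masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import substitution_matrices

from ._seq import STD_AA, six_frame_translate

__all__ = [
    "ScoringScheme",
    "FilterConfig",
    "HSP",
    "six_frame_translate",
    "find_hsps",
    "write_hsp_table",
    "read_hsp_table",
]

_LN2 = math.log(2.0)


def _blosum62() -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    arr = np.array(mat, dtype=np.int64)
    # neutral treatment of ambiguity: X scores 0 against everything
    xi = alphabet.index("X")
    arr[xi, :] = 0
    arr[:, xi] = 0
    return alphabet, arr


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap costs and E-value statistics.

    ``gap_open`` is the cost of the first gapped position; a gap of length L
    costs ``gap_open + (L-1)*gap_extend``. ``lam``/``K`` are the gapped
    Karlin-Altschul parameters used for E-values and bit scores.
    """

    alphabet: str
    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.matrix.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        self._index = {c: i for i, c in enumerate(self.alphabet)}
        self._x = self._index["X"]

    @classmethod
    def default(cls) -> "ScoringScheme":
        alphabet, arr = _blosum62()
        return cls(alphabet=alphabet, matrix=arr)

    def encode(self, seq: str) -> np.ndarray:
        """Indices into the matrix; unknown symbols map to X."""
        return np.array([self._index.get(c, self._x) for c in seq.upper()], dtype=np.int64)

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index.get(a, self._x), self._index.get(b, self._x)])

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / _LN2

    def raw_from_bits(self, bits: float) -> float:
        return (bits * _LN2 + math.log(self.K)) / self.lam

    def evalue(self, raw: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


@dataclass
class FilterConfig:
    """Candidate filters: the E-value cutoff and the protein size window."""

    evalue_max: float = 1e-10
    min_protein_len: int = 80
    max_protein_len: int = 180

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.min_protein_len >= self.max_protein_len:
            raise ValueError("min_protein_len must be < max_protein_len")


@dataclass
class HSP:
    """One high-scoring segment pair (query protein vs translated genome).

    Query coordinates are 0-based half-open amino-acid positions; subject
    coordinates are 0-based half-open nucleotide positions on the plus strand
    of the contig regardless of ``strand``. ``frame`` is the offset of the
    reading frame (0/1/2) into the plus strand or reverse complement, or -1
    when unknown (e.g. HSPs read back from a tabular file).
    ``aligned_pairs`` is the alignment trace as (query_aa_index,
    subject_frame_aa_index) columns with None marking gaps.
    """

    query_id: str
    contig_id: str
    strand: str
    frame: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: float
    bit_score: float
    evalue: float
    pct_identity: float
    align_len: int
    n_mismatch: int
    n_gapopen: int
    aligned_pairs: list[tuple[int | None, int | None]] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValueError("HSP intervals must be non-empty half-open")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity out of range")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


# ---------------------------------------------------------------------------
# seeding


def _std_encode(seq: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(STD_AA)}
    return np.array([idx.get(c, -1) for c in seq.upper()], dtype=np.int64)


def _neighborhood(q_std: np.ndarray, mat20: np.ndarray, threshold: int) -> dict[int, list[int]]:
    """word code -> query positions whose 3-mer scores >= threshold vs the word."""
    nbr: dict[int, list[int]] = {}
    n = len(q_std)
    for i in range(n - 2):
        a, b, c = q_std[i], q_std[i + 1], q_std[i + 2]
        if a < 0 or b < 0 or c < 0:
            continue
        s = (
            mat20[:, a][:, None, None]
            + mat20[:, b][None, :, None]
            + mat20[:, c][None, None, :]
        )
        for wa, wb, wc in np.argwhere(s >= threshold):
            code = (int(wa) * 20 + int(wb)) * 20 + int(wc)
            nbr.setdefault(code, []).append(i)
    return nbr


def _extend_ungapped(
    q_enc: np.ndarray,
    s_enc: np.ndarray,
    q0: int,
    s0: int,
    word: int,
    mat: np.ndarray,
    xdrop: int,
) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension of a word hit.

    Returns (score, q_beg, q_end, s_beg, s_end) of the maximal-scoring
    ungapped segment containing the word.
    """
    score = int(sum(mat[q_enc[q0 + k], s_enc[s0 + k]] for k in range(word)))
    # right
    best_r, gain, steps = 0, 0, 0
    i, j = q0 + word, s0 + word
    r_steps = 0
    while i < len(q_enc) and j < len(s_enc):
        gain += int(mat[q_enc[i], s_enc[j]])
        steps += 1
        if gain > best_r:
            best_r, r_steps = gain, steps
        elif best_r - gain > xdrop:
            break
        i += 1
        j += 1
    # left
    best_l, gain, steps = 0, 0, 0
    i, j = q0 - 1, s0 - 1
    l_steps = 0
    while i >= 0 and j >= 0:
        gain += int(mat[q_enc[i], s_enc[j]])
        steps += 1
        if gain > best_l:
            best_l, l_steps = gain, steps
        elif best_l - gain > xdrop:
            break
        i -= 1
        j -= 1
    return (
        score + best_r + best_l,
        q0 - l_steps,
        q0 + word + r_steps,
        s0 - l_steps,
        s0 + word + r_steps,
    )


# ---------------------------------------------------------------------------
# gapped banded Smith-Waterman refinement

_NEG = -(10**9)


def _banded_sw(
    q_enc: np.ndarray,
    s_enc: np.ndarray,
    qw0: int,
    qw1: int,
    sw0: int,
    sw1: int,
    d0: int,
    band: int,
    mat: np.ndarray,
    go: int,
    ge: int,
) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Local affine-gap alignment restricted to |(s-q) - d0| <= band.

    Returns (score, trace columns) with indices into the full q/s arrays.
    """
    width = 2 * band + 1
    nrow = qw1 - qw0
    M = [[_NEG] * width for _ in range(nrow + 1)]
    D = [[_NEG] * width for _ in range(nrow + 1)]  # gap in subject (consumes q)
    I = [[_NEG] * width for _ in range(nrow + 1)]  # gap in query (consumes s)
    ptr_m = [[0] * width for _ in range(nrow + 1)]  # 0 fresh,1 M,2 D,3 I
    ptr_d = [[0] * width for _ in range(nrow + 1)]  # 1 from M, 2 from D
    ptr_i = [[0] * width for _ in range(nrow + 1)]  # 1 from M, 3 from I
    best, bi, bo = 0, -1, -1
    for i in range(1, nrow + 1):
        qi = qw0 + i - 1
        qa = q_enc[qi]
        row_m, row_d, row_i = M[i], D[i], I[i]
        pm, pd, pi_ = ptr_m[i], ptr_d[i], ptr_i[i]
        prev_m, prev_d, prev_i = M[i - 1], D[i - 1], I[i - 1]
        for o in range(width):
            s = qi + d0 + (o - band)
            if s < sw0 or s >= sw1:
                continue
            # M: diagonal predecessor keeps the same offset
            cand, src = 0, 0
            pmv = prev_m[o]
            if pmv > cand:
                cand, src = pmv, 1
            pdv = prev_d[o]
            if pdv > cand:
                cand, src = pdv, 2
            piv = prev_i[o]
            if piv > cand:
                cand, src = piv, 3
            mv = cand + int(mat[qa, s_enc[s]])
            row_m[o] = mv
            pm[o] = src
            # D: consumes q only -> predecessor (i-1, o+1)
            if o + 1 < width:
                dm = prev_m[o + 1] - go
                dd = prev_d[o + 1] - ge
                if dm >= dd:
                    row_d[o] = dm
                    pd[o] = 1
                else:
                    row_d[o] = dd
                    pd[o] = 2
            # I: consumes s only -> predecessor (i, o-1)
            if o - 1 >= 0:
                im = row_m[o - 1] - go
                ii = row_i[o - 1] - ge
                if im >= ii:
                    row_i[o] = im
                    pi_[o] = 1
                else:
                    row_i[o] = ii
                    pi_[o] = 3
            if mv > best:
                best, bi, bo = mv, i, o
    if bi < 0 or best <= 0:
        return 0, []
    # traceback from the best M cell
    cols: list[tuple[int | None, int | None]] = []
    state, i, o = 1, bi, bo
    while True:
        qi = qw0 + i - 1
        s = qi + d0 + (o - band)
        if state == 1:
            cols.append((qi, s))
            src = ptr_m[i][o]
            i -= 1
            if src == 0:
                break
            state = src
        elif state == 2:
            cols.append((qi, None))
            src = ptr_d[i][o]
            i -= 1
            o += 1
            state = src
        else:
            cols.append((None, s))
            src = ptr_i[i][o]
            o -= 1
            state = src
    cols.reverse()
    return best, cols


# ---------------------------------------------------------------------------


def _trace_stats(
    cols: list[tuple[int | None, int | None]], q_enc: np.ndarray, s_enc: np.ndarray
) -> tuple[int, int, int, float]:
    matches = 0
    mismatches = 0
    gapopens = 0
    in_gap = False
    for qi, si in cols:
        if qi is None or si is None:
            if not in_gap:
                gapopens += 1
            in_gap = True
        else:
            in_gap = False
            if q_enc[qi] == s_enc[si]:
                matches += 1
            else:
                mismatches += 1
    align_len = len(cols)
    pident = 100.0 * matches / align_len if align_len else 0.0
    return align_len, mismatches, gapopens, pident


def _frame_to_plus(
    strand: str, frame: int, aa0: int, aa1: int, contig_len: int
) -> tuple[int, int]:
    nt0 = frame + 3 * aa0
    nt1 = frame + 3 * aa1
    if strand == "+":
        return nt0, nt1
    return contig_len - nt1, contig_len - nt0


def _link_sets(
    hsps: list[HSP],
    scoring: ScoringScheme,
    m: int,
    n_total: int,
    evalue_max: float,
    min_link_raw: float,
    link_max_intron: int,
    link_max_overlap: int,
) -> list[HSP]:
    """Apply the E-value cutoff to colinear linked HSP sets (sum statistics).

    Exons of one gene rarely reach a stringent cutoff individually, so — as
    BLAST does with its sum statistics — HSPs on one contig/strand that are
    colinear in query and subject within an intron-sized gap are evaluated
    as a set: the set E-value uses the summed raw score. HSPs in a passing
    set are kept and report the set E-value (never worse than their own);
    everything else is discarded. Only HSPs with raw score >=
    ``min_link_raw`` may join a multi-HSP set, which keeps random noise
    from piggybacking on a genuine gene hit.
    """
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.contig_id, h.strand), []).append(h)
    kept: list[HSP] = []
    for (cid, strand), group in sorted(groups.items()):
        group.sort(key=(lambda h: (h.s_start, h.q_start)) if strand == "+" else (lambda h: (-h.s_end, h.q_start)))
        remaining = [h for h in group if h.raw_score >= min_link_raw]
        while remaining:
            n = len(remaining)
            best = [h.raw_score for h in remaining]
            back = [-1] * n
            for j in range(n):
                hj = remaining[j]
                for i in range(j):
                    hi = remaining[i]
                    overlap = hi.q_end - hj.q_start
                    if overlap > link_max_overlap or hj.q_end <= hi.q_end:
                        continue
                    gap = (hj.s_start - hi.s_end) if strand == "+" else (hi.s_start - hj.s_end)
                    if not -3 * link_max_overlap <= gap <= link_max_intron:
                        continue
                    # count doubly covered query spans once (conservatively:
                    # 5 is a high per-column score for BLOSUM62 matches)
                    contrib = hj.raw_score - 5.0 * max(0, overlap)
                    if contrib <= 0:
                        continue
                    if best[i] + contrib > best[j]:
                        best[j] = best[i] + contrib
                        back[j] = i
            j = max(range(n), key=lambda k: (best[k], -k))
            total = best[j]
            set_ev = scoring.evalue(total, m, n_total)
            if set_ev > evalue_max:
                break
            idx = []
            while j != -1:
                idx.append(j)
                j = back[j]
            for k in idx:
                h = remaining[k]
                h.evalue = min(h.evalue, set_ev)
                kept.append(h)
            remaining = [h for k, h in enumerate(remaining) if k not in idx]
        # isolated HSPs below the linkage score can still pass on their own
        for h in group:
            if h.raw_score < min_link_raw and h.evalue <= evalue_max:
                kept.append(h)
    return kept


def find_hsps(
    query: str,
    genome: Mapping[str, str],
    scoring: ScoringScheme | None = None,
    filt: FilterConfig | None = None,
    *,
    query_id: str = "query",
    word_size: int = 3,
    seed_threshold: int = 12,
    xdrop: int = 40,
    gapped_trigger: int = 35,
    band: int = 16,
    pad: int = 24,
    min_link_raw: float = 45.0,
    link_max_intron: int = 5000,
    link_max_overlap: int = 45,
) -> list[HSP]:
    """Search ``query`` against all six frames of every contig in ``genome``.

    Output is sorted by (contig, s_start, q_start). The E-value cutoff is
    applied to colinear linked HSP sets (see :func:`_link_sets`), so the
    exons of a multi-exon gene stand or fall together as one gene-level hit.
    """
    scoring = scoring or ScoringScheme.default()
    filt = filt or FilterConfig()
    query = query.upper()
    allowed = set(STD_AA + "X")
    bad = sorted(set(query) - allowed)
    if bad:
        raise ValueError(f"query contains non-amino-acid symbols: {bad}")
    if len(query) < word_size:
        raise ValueError("query shorter than the seed word size")

    std_idx = [scoring.alphabet.index(c) for c in STD_AA]
    mat20 = scoring.matrix[np.ix_(std_idx, std_idx)]
    q_std = _std_encode(query)
    q_enc = scoring.encode(query)
    nbr = _neighborhood(q_std, mat20, seed_threshold)

    frames_by_contig = {cid: six_frame_translate(seq) for cid, seq in genome.items()}
    m = len(query)
    n_total = sum(len(fr.aa) for frames in frames_by_contig.values() for fr in frames)

    raw_hsps: list[HSP] = []
    for cid in genome:
        contig_len = len(genome[cid])
        for fr in frames_by_contig[cid]:
            if len(fr.aa) < word_size:
                continue
            s_enc = scoring.encode(fr.aa)
            s_std = _std_encode(fr.aa)
            codes = (s_std[:-2] * 20 + s_std[1:-1]) * 20 + s_std[2:]
            valid = (s_std[:-2] >= 0) & (s_std[1:-1] >= 0) & (s_std[2:] >= 0)
            reach: dict[int, int] = {}
            candidates: list[tuple[int, int, int, int, int]] = []
            for pos in np.nonzero(valid)[0]:
                code = int(codes[pos])
                qlist = nbr.get(code)
                if qlist is None:
                    continue
                for qpos in qlist:
                    diag = pos - qpos
                    if reach.get(diag, -1) >= pos:
                        continue
                    score, qb, qe, sb, se = _extend_ungapped(
                        q_enc, s_enc, qpos, int(pos), word_size, scoring.matrix, xdrop
                    )
                    reach[diag] = se
                    if score >= gapped_trigger:
                        candidates.append((score, qb, qe, sb, se))
            # refine strongest candidates first; drop seeds inside refined HSPs
            candidates.sort(key=lambda t: (-t[0], t[3], t[1]))
            refined: list[tuple[int, list[tuple[int | None, int | None]]]] = []
            covered: list[tuple[int, int, int, int]] = []
            for score, qb, qe, sb, se in candidates:
                contained = False
                for cq0, cq1, cs0, cs1 in covered:
                    q_ov = min(qe, cq1) - max(qb, cq0)
                    s_ov = min(se, cs1) - max(sb, cs0)
                    if q_ov > 0.5 * (qe - qb) and s_ov > 0.5 * (se - sb):
                        contained = True
                        break
                if contained:
                    continue
                qw0 = max(0, qb - pad)
                qw1 = min(m, qe + pad)
                sw0 = max(0, sb - pad)
                sw1 = min(len(fr.aa), se + pad)
                d0 = sb - qb
                g_score, cols = _banded_sw(
                    q_enc, s_enc, qw0, qw1, sw0, sw1, d0, band,
                    scoring.matrix, scoring.gap_open, scoring.gap_extend,
                )
                if not cols:
                    continue
                q_idx = [c[0] for c in cols if c[0] is not None]
                s_idx = [c[1] for c in cols if c[1] is not None]
                covered.append((q_idx[0], q_idx[-1] + 1, s_idx[0], s_idx[-1] + 1))
                refined.append((g_score, cols))
            for g_score, cols in refined:
                q_idx = [c[0] for c in cols if c[0] is not None]
                s_idx = [c[1] for c in cols if c[1] is not None]
                align_len, mism, gapo, pident = _trace_stats(cols, q_enc, s_enc)
                ev = scoring.evalue(g_score, m, n_total)
                s0_nt, s1_nt = _frame_to_plus(
                    fr.strand, fr.frame, s_idx[0], s_idx[-1] + 1, contig_len
                )
                raw_hsps.append(
                    HSP(
                        query_id=query_id,
                        contig_id=cid,
                        strand=fr.strand,
                        frame=fr.frame,
                        q_start=q_idx[0],
                        q_end=q_idx[-1] + 1,
                        s_start=s0_nt,
                        s_end=s1_nt,
                        raw_score=float(g_score),
                        bit_score=scoring.bit_score(g_score),
                        evalue=ev,
                        pct_identity=pident,
                        align_len=align_len,
                        n_mismatch=mism,
                        n_gapopen=gapo,
                        aligned_pairs=cols,
                    )
                )

    # global dedupe: drop HSPs largely overlapping a higher-scoring one
    raw_hsps.sort(key=lambda h: (-h.raw_score, h.contig_id, h.s_start, h.q_start))
    deduped: list[HSP] = []
    for h in raw_hsps:
        dup = False
        for k in deduped:
            if k.contig_id != h.contig_id or k.strand != h.strand or k.frame != h.frame:
                continue
            q_ov = min(h.q_end, k.q_end) - max(h.q_start, k.q_start)
            s_ov = min(h.s_end, k.s_end) - max(h.s_start, k.s_start)
            if q_ov > 0.5 * (h.q_end - h.q_start) and s_ov > 0.5 * (h.s_end - h.s_start):
                dup = True
                break
        if not dup:
            deduped.append(h)
    kept = _link_sets(
        deduped, scoring, m, n_total, filt.evalue_max,
        min_link_raw, link_max_intron, link_max_overlap,
    )
    kept.sort(key=lambda h: (h.contig_id, h.s_start, h.q_start, -h.raw_score))
    return kept


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) dialect

_COLS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def write_hsp_table(hsps: Iterable[HSP]) -> str:
    """Serialize HSPs as 12-column BLAST tabular text (1-based inclusive
    coordinates; minus-strand HSPs encoded by sstart > send)."""
    lines = []
    for h in hsps:
        if h.strand == "+":
            sstart, send = h.s_start + 1, h.s_end
        else:
            sstart, send = h.s_end, h.s_start + 1
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.contig_id,
                    f"{h.pct_identity:.3f}",
                    str(h.align_len),
                    str(h.n_mismatch),
                    str(h.n_gapopen),
                    str(h.q_start + 1),
                    str(h.q_end),
                    str(sstart),
                    str(send),
                    f"{h.evalue:.3e}",
                    f"{h.bit_score:.1f}",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_hsp_table(text: str, scoring: ScoringScheme | None = None) -> list[HSP]:
    """Parse 12-column BLAST tabular text back into HSPs.

    The tabular dialect carries no frame or alignment trace: read-back HSPs
    have ``frame=-1`` and ``aligned_pairs=None``; raw scores are inverted
    from the bit score.
    """
    scoring = scoring or ScoringScheme.default()
    hsps = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            (qseqid, sseqid, pident, length, mism, gapo,
             qstart, qend, sstart, send, evalue, bits) = fields
            pident_f = float(pident)
            length_i = int(length)
            mism_i = int(mism)
            gapo_i = int(gapo)
            q0, q1 = int(qstart) - 1, int(qend)
            ss, se = int(sstart), int(send)
            ev = float(evalue)
            bits_f = float(bits)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed field ({exc})") from None
        if ss <= se:
            strand, s0, s1 = "+", ss - 1, se
        else:
            strand, s0, s1 = "-", se - 1, ss
        hsps.append(
            HSP(
                query_id=qseqid,
                contig_id=sseqid,
                strand=strand,
                frame=-1,
                q_start=q0,
                q_end=q1,
                s_start=s0,
                s_end=s1,
                raw_score=scoring.raw_from_bits(bits_f),
                bit_score=bits_f,
                evalue=ev,
                pct_identity=pident_f,
                align_len=length_i,
                n_mismatch=mism_i,
                n_gapopen=gapo_i,
            )
        )
    return hsps
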