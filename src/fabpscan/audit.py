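"""Pairwise global alignment and the fatty-acid-binding key-residue audit.

FABPs bind their ligand through a small set of conserved sites: the P2 motif
(Arg ... Arg-x-Tyr) lining the beta-barrel cavity, a Phe on the first helix,
and an Ala/Pro-Asp pair in the turn between strands betaE and betaF. The
audit aligns a candidate protein to an annotated reference, projects each
template site through the alignment and reports per-site status
(match / substituted / deleted) plus an overall intact/altered verdict.

The aligner is Needleman-Wunsch with affine gaps (end gaps penalized) and
deterministic tie-breaking: diagonal preferred, then the gap-in-second-
sequence state. Secondary-structure prediction is exposed only as a
pluggable hook; without a predictor it reports "not-evaluated".
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

from ._seq import STD_AA
from .search import ScoringScheme

__all__ = [
    "AlignmentTrace",
    "KeyResidueTemplate",
    "SiteRecord",
    "ResidueAudit",
    "global_align",
    "percent_identity",
    "identity_matrix",
    "audit_key_residues",
    "default_template",
    "predict_secondary_structure",
    "write_identity_matrix",
    "write_pairwise_fasta",
]

_NEG = -(10**9)


@dataclass
class AlignmentTrace:
    """A global alignment of ``a`` vs ``b`` as (i, j) columns; None marks a gap."""

    a: str
    b: str
    columns: list[tuple[int | None, int | None]]
    score: float

    def aligned_strings(self) -> tuple[str, str]:
        ra = "".join("-" if i is None else self.a[i] for i, _ in self.columns)
        rb = "".join("-" if j is None else self.b[j] for _, j in self.columns)
        return ra, rb


def _validate_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = sorted(set(seq) - set(STD_AA + "X"))
    if bad:
        raise ValueError(f"{name}: invalid residue symbols {bad}")
    return seq


def global_align(a: str, b: str, scoring: ScoringScheme | None = None) -> AlignmentTrace:
    """Needleman-Wunsch with affine gaps; optimal score guaranteed.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; end gaps are
    penalized. Ties prefer the diagonal, then a gap in ``b`` (consuming
    ``a``), then a gap in ``a``.
    """
    scoring = scoring or ScoringScheme.default()
    a = _validate_protein(a, "a")
    b = _validate_protein(b, "b")
    go, ge = scoring.gap_open, scoring.gap_extend
    ea = scoring.encode(a)
    eb = scoring.encode(b)
    la, lb = len(a), len(b)
    M = [[_NEG] * (lb + 1) for _ in range(la + 1)]
    D = [[_NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consumes a)
    I = [[_NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consumes b)
    pm = [[0] * (lb + 1) for _ in range(la + 1)]
    pd = [[0] * (lb + 1) for _ in range(la + 1)]
    pi = [[0] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0
    for i in range(1, la + 1):
        D[i][0] = -go - (i - 1) * ge
        pd[i][0] = 1 if i == 1 else 2
    for j in range(1, lb + 1):
        I[0][j] = -go - (j - 1) * ge
        pi[0][j] = 1 if j == 1 else 3
    mat = scoring.matrix
    for i in range(1, la + 1):
        rm, rd, ri = M[i], D[i], I[i]
        qm, qd, qi_ = M[i - 1], D[i - 1], I[i - 1]
        for j in range(1, lb + 1):
            # M from the best of M/D/I at (i-1, j-1); tie order M, D, I
            best, src = qm[j - 1], 1
            if qd[j - 1] > best:
                best, src = qd[j - 1], 2
            if qi_[j - 1] > best:
                best, src = qi_[j - 1], 3
            rm[j] = best + int(mat[ea[i - 1], eb[j - 1]])
            pm[i][j] = src
            # D from (i-1, j); opening from M or I, extending from D
            best, src = qm[j] - go, 1
            if qd[j] - ge > best:
                best, src = qd[j] - ge, 2
            if qi_[j] - go > best:
                best, src = qi_[j] - go, 3
            rd[j] = best
            pd[i][j] = src
            # I from (i, j-1)
            best, src = rm[j - 1] - go, 1
            if ri[j - 1] - ge > best:
                best, src = ri[j - 1] - ge, 3
            if rd[j - 1] - go > best:
                best, src = rd[j - 1] - go, 2
            ri[j] = best
            pi[i][j] = src
    finals = [(M[la][lb], 1), (D[la][lb], 2), (I[la][lb], 3)]
    score, state = max(finals, key=lambda t: (t[0], -t[1]))
    cols: list[tuple[int | None, int | None]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if state == 1:
            cols.append((i - 1, j - 1))
            state = pm[i][j]
            i -= 1
            j -= 1
        elif state == 2:
            cols.append((i - 1, None))
            state = pd[i][j]
            i -= 1
        else:
            cols.append((None, j - 1))
            state = pi[i][j]
            j -= 1
    cols.reverse()
    return AlignmentTrace(a=a, b=b, columns=cols, score=float(score))


def percent_identity(trace: AlignmentTrace) -> float:
    """100 * identical columns / columns where neither row is a gap."""
    both = [(i, j) for i, j in trace.columns if i is not None and j is not None]
    if not both:
        raise ValueError("alignment has no gap-free columns; identity undefined")
    same = sum(1 for i, j in both if trace.a[i] == trace.b[j])
    return 100.0 * same / len(both)


def identity_matrix(
    proteins: dict[str, str] | Sequence[tuple[str, str]],
    scoring: ScoringScheme | None = None,
) -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Full pairwise percent-identity matrix (symmetric, diagonal 100)."""
    import pandas as pd

    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    names = [n for n, _ in items]
    seqs = [s for _, s in items]
    n = len(items)
    out = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(global_align(seqs[i], seqs[j], scoring))
            out[i][j] = out[j][i] = pid
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# key-residue audit


def _default_reference() -> str:
    """A synthetic 131-aa FABP-like reference with annotated binding sites.

    This is a generated stand-in sequence (not any species' real FABP); only
    the annotated site positions and identities matter for the audit.
    """
    rng = random.Random(20131)
    aas = STD_AA
    seq = ["M"] + [aas[rng.randrange(len(aas))] for _ in range(130)]
    for pos, res in ((16, "F"), (72, "P"), (73, "D"), (106, "R"), (126, "R"), (128, "Y")):
        seq[pos] = res
    return "".join(seq)


@dataclass
class KeyResidueTemplate:
    """Reference protein plus 0-based indices of the ligand-binding sites.

    P2 motif: Arg at ``p2_arg1_pos``, Arg at ``p2_arg2_pos`` and Tyr two
    residues later (Arg-x-Tyr). ``helix1_phe_pos`` marks the helix-1 Phe;
    ``turn_pos`` is the (Ala|Pro, Asp) pair in the betaE-betaF turn.
    """

    reference_protein: str
    p2_arg1_pos: int
    p2_arg2_pos: int
    p2_tyr_pos: int
    helix1_phe_pos: int
    turn_pos: tuple[int, int]

    def __post_init__(self) -> None:
        ref = self.reference_protein
        expected = {
            self.p2_arg1_pos: "R",
            self.p2_arg2_pos: "R",
            self.p2_tyr_pos: "Y",
            self.helix1_phe_pos: "F",
            self.turn_pos[1]: "D",
        }
        for pos, res in expected.items():
            if not 0 <= pos < len(ref):
                raise ValueError(f"site index {pos} outside reference")
            if ref[pos] != res:
                raise ValueError(f"reference residue at {pos} is {ref[pos]}, expected {res}")
        if ref[self.turn_pos[0]] not in "AP":
            raise ValueError("turn site must be Ala or Pro on the reference")

    def sites(self) -> list[tuple[str, int, str | tuple[str, ...]]]:
        """(name, reference index, accepted residue(s)) per audited site."""
        return [
            ("helix1_Phe", self.helix1_phe_pos, "F"),
            ("turn_AlaPro", self.turn_pos[0], ("A", "P")),
            ("turn_Asp", self.turn_pos[1], "D"),
            ("P2_Arg1", self.p2_arg1_pos, "R"),
            ("P2_Arg2", self.p2_arg2_pos, "R"),
            ("P2_Tyr", self.p2_tyr_pos, "Y"),
        ]


def default_template() -> KeyResidueTemplate:
    return KeyResidueTemplate(
        reference_protein=_default_reference(),
        p2_arg1_pos=106,
        p2_arg2_pos=126,
        p2_tyr_pos=128,
        helix1_phe_pos=16,
        turn_pos=(72, 73),
    )


@dataclass
class SiteRecord:
    site: str
    ref_residue: str
    cand_residue: str | None  # None when deleted (gap)
    status: str  # match | substituted | deleted


@dataclass
class ResidueAudit:
    records: list[SiteRecord]
    intact: bool
    pct_identity: float
    trace: AlignmentTrace = field(repr=False, default=None)

    @property
    def overall(self) -> str:
        return "intact" if self.intact else "altered"


def audit_key_residues(
    candidate: str,
    template: KeyResidueTemplate | None = None,
    scoring: ScoringScheme | None = None,
) -> ResidueAudit:
    """Audit the fatty-acid-binding key residues of ``candidate``.

    The candidate is globally aligned to the template reference; each site
    is projected through the alignment and scored match / substituted /
    deleted. Overall 'intact' requires every site to match (the turn accepts
    Ala-Asp or Pro-Asp).
    """
    template = template or default_template()
    trace = global_align(candidate, template.reference_protein, scoring)
    # reference index -> candidate index (None for gap)
    proj: dict[int, int | None] = {}
    for i, j in trace.columns:
        if j is not None:
            proj[j] = i
    cand = trace.a
    records = []
    intact = True
    for name, ref_idx, accepted in template.sites():
        ref_res = template.reference_protein[ref_idx]
        ci = proj.get(ref_idx)
        if ci is None:
            records.append(SiteRecord(name, ref_res, None, "deleted"))
            intact = False
            continue
        res = cand[ci]
        ok = res in accepted if isinstance(accepted, tuple) else res == accepted
        records.append(SiteRecord(name, ref_res, res, "match" if ok else "substituted"))
        intact = intact and ok
    return ResidueAudit(
        records=records,
        intact=intact,
        pct_identity=percent_identity(trace),
        trace=trace,
    )


def write_identity_matrix(
    proteins: dict[str, str], path, scoring: ScoringScheme | None = None
) -> None:
    """Write the full pairwise percent-identity matrix as TSV."""
    identity_matrix(proteins, scoring).to_csv(path, sep="\t")


def write_pairwise_fasta(trace: AlignmentTrace, path, id_a: str = "a", id_b: str = "b") -> None:
    """Export one pairwise alignment as gapped FASTA (e.g. for tree tools)."""
    ra, rb = trace.aligned_strings()
    with open(path, "w") as fh:
        fh.write(f">{id_a}\n{ra}\n>{id_b}\n{rb}\n")


def predict_secondary_structure(
    seq: str, predictor: Callable[[str], str] | None = None
) -> str:
    """Pluggable secondary-structure hook; no predictor ships with the package."""
    if predictor is None:
        return "not-evaluated"
    return predictor(seq)
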