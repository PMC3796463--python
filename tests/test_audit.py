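"""Global alignment, percent identity and the key-residue audit."""

import itertools
import random

import pytest
from Bio import Align as BioAlign

from fabpscan import audit_key_residues, default_template, global_align, percent_identity
from fabpscan.audit import AlignmentTrace, predict_secondary_structure


def test_self_alignment_scores_sum_of_diagonal(scoring, query):
    trace = global_align(query, query, scoring)
    assert trace.score == sum(scoring.score(a, a) for a in query)
    assert all(i == j for i, j in trace.columns)
    assert percent_identity(trace) == 100.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        global_align("A", "")


def test_invalid_residue_rejected():
    with pytest.raises(ValueError, match="invalid residue"):
        global_align("MK1", "MK")


def alignment_score_oracle(a, b, scoring):
    """Exhaustive enumeration of all global alignments (tiny sequences).

    An alignment is scored as substitution sums minus, per maximal gap run,
    gap_open + (len-1)*gap_extend.
    """

    def gap_cost(length):
        return scoring.gap_open + (length - 1) * scoring.gap_extend

    best = -(10**9)
    stack = [(0, 0, [])]
    while stack:
        i, j, cols = stack.pop()
        if i == len(a) and j == len(b):
            score = 0
            run_a = run_b = 0
            for ci, cj in cols:
                if ci is None:
                    if run_b:
                        score -= gap_cost(run_b)
                        run_b = 0
                    run_a += 1
                elif cj is None:
                    if run_a:
                        score -= gap_cost(run_a)
                        run_a = 0
                    run_b += 1
                else:
                    if run_a:
                        score -= gap_cost(run_a)
                    if run_b:
                        score -= gap_cost(run_b)
                    run_a = run_b = 0
                    score += scoring.score(a[ci], b[cj])
            if run_a:
                score -= gap_cost(run_a)
            if run_b:
                score -= gap_cost(run_b)
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, cols + [(i, j)]))
        if i < len(a):
            stack.append((i + 1, j, cols + [(i, None)]))
        if j < len(b):
            stack.append((i, j + 1, cols + [(None, j)]))
    return best


def test_nw_score_matches_exhaustive_enumeration(scoring):
    rng = random.Random(13)
    aas = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(25):
        a = "".join(rng.choice(aas) for _ in range(rng.randint(1, 6)))
        b = "".join(rng.choice(aas) for _ in range(rng.randint(1, 6)))
        got = global_align(a, b, scoring).score
        assert got == alignment_score_oracle(a, b, scoring), (a, b)


def test_nw_score_matches_biopython_on_longer_pairs(scoring):
    """Independent cross-check against Biopython's PairwiseAligner with the
    same matrix and affine gap convention (end gaps penalized)."""
    aligner = BioAlign.PairwiseAligner()
    aligner.substitution_matrix = BioAlign.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = "global"
    rng = random.Random(29)
    aas = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(10):
        a = "".join(rng.choice(aas) for _ in range(rng.randint(10, 40)))
        b = "".join(rng.choice(aas) for _ in range(rng.randint(10, 40)))
        assert global_align(a, b, scoring).score == aligner.score(a, b)


def test_percent_identity_examples_and_symmetry(scoring):
    t = global_align("AAAA", "AAAT", scoring)
    assert percent_identity(t) == 75.0
    rng = random.Random(3)
    aas = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(5):
        a = "".join(rng.choice(aas) for _ in range(30))
        b = "".join(rng.choice(aas) for _ in range(25))
        pid_ab = percent_identity(global_align(a, b, scoring))
        pid_ba = percent_identity(global_align(b, a, scoring))
        assert pid_ab == pytest.approx(pid_ba)


def test_percent_identity_counts_match_column_oracle(scoring):
    rng = random.Random(4)
    aas = "ARNDCQEGHILKMFPSTWYV"
    a = "".join(rng.choice(aas) for _ in range(40))
    b = "".join(rng.choice(aas) for _ in range(38))
    trace = global_align(a, b, scoring)
    both = [(i, j) for i, j in trace.columns if i is not None and j is not None]
    same = sum(1 for i, j in both if a[i] == b[j])
    assert percent_identity(trace) == pytest.approx(100.0 * same / len(both))


def test_percent_identity_undefined_without_gapfree_columns():
    t = AlignmentTrace(a="A", b="T", columns=[(0, None), (None, 0)], score=0.0)
    with pytest.raises(ValueError, match="identity undefined"):
        percent_identity(t)


def test_score_never_below_all_gap_baseline(scoring):
    rng = random.Random(17)
    aas = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(10):
        a = "".join(rng.choice(aas) for _ in range(rng.randint(2, 12)))
        b = "".join(rng.choice(aas) for _ in range(rng.randint(2, 12)))
        baseline = -(scoring.gap_open + (len(a) - 1) * scoring.gap_extend) - (
            scoring.gap_open + (len(b) - 1) * scoring.gap_extend
        )
        assert global_align(a, b, scoring).score >= baseline


# ---------------------------------------------------------------------------
# key-residue audit


def test_reference_audits_intact():
    template = default_template()
    audit = audit_key_residues(template.reference_protein, template)
    assert audit.intact
    assert audit.overall == "intact"
    assert all(r.status == "match" for r in audit.records)


def test_turn_accepts_ala_or_pro_but_not_val():
    template = default_template()
    ref = template.reference_protein
    t0 = template.turn_pos[0]
    ala = ref[:t0] + "A" + ref[t0 + 1 :]
    assert audit_key_residues(ala, template).intact
    # the mosquito-style Val-Asp turn is a substitution -> altered
    val = ref[:t0] + "V" + ref[t0 + 1 :]
    audit = audit_key_residues(val, template)
    assert not audit.intact
    rec = {r.site: r.status for r in audit.records}
    assert rec["turn_AlaPro"] == "substituted"


def test_deleted_p2_tyrosine_reported_as_deleted():
    template = default_template()
    truncated = template.reference_protein[:120]  # removes Arg2 and Tyr sites
    audit = audit_key_residues(truncated, template)
    assert not audit.intact
    rec = {r.site: r.status for r in audit.records}
    assert rec["P2_Tyr"] == "deleted"
    assert rec["P2_Arg2"] == "deleted"


def test_matrix_and_alignment_exports(tmp_path, scoring, query):
    from fabpscan.audit import write_identity_matrix, write_pairwise_fasta
    import pandas as pd

    other = query[:60] + query[70:]
    write_identity_matrix({"a": query, "b": other}, tmp_path / "idm.tsv", scoring)
    mat = pd.read_csv(tmp_path / "idm.tsv", sep="\t", index_col=0)
    assert mat.loc["a", "a"] == 100.0 and mat.loc["a", "b"] == mat.loc["b", "a"]
    trace = global_align(query, other, scoring)
    write_pairwise_fasta(trace, tmp_path / "aln.faa", "a", "b")
    lines = (tmp_path / "aln.faa").read_text().splitlines()
    assert lines[0] == ">a" and len(lines[1]) == len(lines[3])
    assert lines[1].replace("-", "") == query


def test_structure_hook_defaults_to_not_evaluated(query):
    assert predict_secondary_structure(query) == "not-evaluated"
    assert predict_secondary_structure(query, lambda s: "H" * len(s)) == "H" * len(query)
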