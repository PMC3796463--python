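"""Gene-model construction: chaining, splice snapping, size filter,
architecture classification."""

import itertools
import random

import pytest

from conftest import make_model_with_lengths
from fabpscan import (
    Chain,
    FilterConfig,
    GeneModel,
    HSP,
    build_models,
    chain_hsps,
    classify_architecture,
    find_hsps,
    size_filter,
    snap_splice_sites,
)
from fabpscan._seq import revcomp


def mk_hsp(q0, q1, s0, s1, score, contig="c", strand="+", query="q"):
    return HSP(
        query_id=query, contig_id=contig, strand=strand, frame=0,
        q_start=q0, q_end=q1, s_start=s0, s_end=s1,
        raw_score=float(score), bit_score=float(score) / 2, evalue=1e-30,
        pct_identity=90.0, align_len=q1 - q0, n_mismatch=0, n_gapopen=0,
    )


# ---------------------------------------------------------------------------
# chaining


def test_two_colinear_hsps_form_single_chain():
    h1 = mk_hsp(0, 60, 100, 280, 300)
    h2 = mk_hsp(60, 130, 780, 990, 350)
    chains = chain_hsps([h1, h2])
    assert len(chains) == 1
    assert chains[0].total_score == 650
    assert chains[0].gaps == [(280, 780)]


def test_hsps_on_two_contigs_never_merge():
    h1 = mk_hsp(0, 60, 100, 280, 300, contig="c1")
    h2 = mk_hsp(60, 130, 780, 990, 350, contig="c2")
    chains = chain_hsps([h1, h2])
    assert len(chains) == 2
    assert {c.contig_id for c in chains} == {"c1", "c2"}


def test_chain_rejects_mixed_queries():
    with pytest.raises(ValueError, match="single query"):
        chain_hsps([mk_hsp(0, 10, 0, 30, 50, query="a"), mk_hsp(0, 10, 90, 120, 50, query="b")])


def oracle_best_chain(hsps, max_intron, max_overlap):
    """Exhaustive maximum over all colinear subsets (independent re-statement
    of the chaining constraints)."""
    best = 0.0
    for r in range(1, len(hsps) + 1):
        for combo in itertools.combinations(hsps, r):
            ordered = sorted(combo, key=lambda h: h.s_start)
            ok = True
            for a, b in zip(ordered, ordered[1:]):
                gap = b.s_start - a.s_end
                if b.q_start < a.q_end - max_overlap or b.q_end <= a.q_end:
                    ok = False
                    break
                if gap > max_intron or gap < -3 * max_overlap:
                    ok = False
                    break
            if ok:
                best = max(best, sum(h.raw_score for h in combo))
    return best


def test_chain_score_matches_exhaustive_subset_oracle():
    rng = random.Random(42)
    for _ in range(40):
        hsps = []
        for _ in range(rng.randint(1, 6)):
            q0 = rng.randrange(0, 100)
            q1 = q0 + rng.randrange(5, 40)
            s0 = rng.randrange(0, 4000)
            s1 = s0 + 3 * (q1 - q0)
            hsps.append(mk_hsp(q0, q1, s0, s1, rng.randrange(40, 400)))
        chains = chain_hsps(hsps, max_intron=1000, max_query_overlap=10)
        got = max(c.total_score for c in chains)
        assert got == oracle_best_chain(hsps, 1000, 10)


# ---------------------------------------------------------------------------
# splice-site snapping


def hsps_from_truth(model, truth, shrink_codons=0):
    """Codon-aligned pseudo-HSPs over the planted exons.

    Translated HSPs always start/end on full codons, so phase-1/2 introns
    leave the initial boundaries up to 2 nt short of the truth even for
    perfect hits; ``shrink_codons`` removes further whole codons at every
    internal junction to emulate trimmed alignments.
    """
    contig_len = len(truth.genome[model.contig_id])
    out = []
    cum = 0
    n = len(model.exons)
    for i, (a, b) in enumerate(model.exons):
        ln = b - a
        if model.strand == "+":
            ts, te = a, b
        else:
            ts, te = contig_len - b, contig_len - a
        lead = (3 - cum % 3) % 3  # partial codon carried over the junction
        tail = (cum + ln) % 3
        ts_h, te_h = ts + lead, te - tail
        q0, q1 = (cum + 2) // 3, (cum + ln) // 3
        if i > 0:
            ts_h += 3 * shrink_codons
            q0 += shrink_codons
        if i < n - 1:
            te_h -= 3 * shrink_codons
            q1 -= shrink_codons
        s0, s1 = (ts_h, te_h) if model.strand == "+" else (contig_len - te_h, contig_len - ts_h)
        out.append(
            HSP(
                query_id="q", contig_id=model.contig_id, strand=model.strand,
                frame=-1, q_start=q0, q_end=q1,
                s_start=s0, s_end=s1, raw_score=5.0 * (q1 - q0),
                bit_score=1.0, evalue=0.0, pct_identity=100.0,
                align_len=q1 - q0, n_mismatch=0, n_gapopen=0,
            )
        )
        cum += ln
    return out


def pick_multi_exon(truth):
    return next(m for m in truth.models if len(m.exons) >= 3)


def test_snap_recovers_truth_from_phase_offset_boundaries(truth, query):
    """Codon-aligned HSP boundaries sit up to 2 nt off phase-1/2 introns;
    snapping must restore the exact planted exons (and leave phase-0
    boundaries, which already lie on GT/AG, untouched)."""
    for model in truth.models:
        if len(model.exons) < 2:
            continue
        hsps = hsps_from_truth(model, truth)
        chain = Chain(hsps=hsps, total_score=sum(h.raw_score for h in hsps))
        snapped = snap_splice_sites(chain, truth.genome, query=truth.query)
        assert snapped.exons == list(model.exons), model.model_id
        assert all(f == "canonical" for f in snapped.splice_flags)
        assert snapped.protein == model.protein


def test_snap_recovers_truth_from_one_codon_trimmed_boundaries(truth):
    model = pick_multi_exon(truth)
    hsps = hsps_from_truth(model, truth, shrink_codons=1)
    chain = Chain(hsps=hsps, total_score=sum(h.raw_score for h in hsps))
    snapped = snap_splice_sites(chain, truth.genome, query=truth.query, window=15)
    assert snapped.exons == list(model.exons)
    assert snapped.protein == model.protein


def test_gap_without_gt_ag_flagged_noncanonical(query):
    """A junction whose window holds no in-frame GT..AG keeps its
    HSP-derived boundaries and is flagged noncanonical."""
    rng = random.Random(5)
    from fabpscan._seq import AA_TO_CODONS

    cds = "".join(AA_TO_CODONS[a][0] for a in query) + "TAA"
    w = 6
    cut = None
    for c in range(30, len(cds) - 30, 3):
        if "GT" not in cds[c - w - 2 : c] and "AG" not in cds[c : c + w + 2]:
            cut = c
            break
    assert cut is not None
    intron = "C" * 120  # no GT donor or AG acceptor anywhere inside
    gene = cds[:cut] + intron + cds[cut:]
    flank1 = "".join(rng.choice("ACGT") for _ in range(300))
    flank2 = "".join(rng.choice("ACGT") for _ in range(300))
    contig = flank1 + gene + flank2
    g0 = len(flank1)
    h1 = mk_hsp(0, cut // 3, g0, g0 + cut, 400)
    h2 = mk_hsp(cut // 3, len(query), g0 + cut + 120, g0 + len(gene), 400)
    chain = Chain(hsps=[h1, h2], total_score=800)
    snapped = snap_splice_sites(chain, {"c": contig}, query=query, window=w)
    assert "noncanonical" in snapped.splice_flags


def test_broken_orf_flagged_but_model_returned(query):
    """A chain spliced across junk translates with internal stops."""
    rng = random.Random(9)
    contig = "".join(rng.choice("ACGT") for _ in range(2000))
    h1 = mk_hsp(0, 40, 300, 420, 200)
    h2 = mk_hsp(40, 80, 900, 1020, 200)
    chain = Chain(hsps=[h1, h2], total_score=400)
    model = snap_splice_sites(chain, {"c": contig})
    assert model.broken_orf


# ---------------------------------------------------------------------------
# size filter


def model_of_length(aa_len, mid="m"):
    return make_model_with_lengths([3 * (aa_len + 1)], model_id=mid,
                                   protein="M" + "L" * (aa_len - 1))


@pytest.mark.parametrize(
    "length,kept",
    [(987, False), (80, True), (130, True), (180, True), (79, False), (181, False)],
)
def test_size_filter_window_inclusive(length, kept):
    model = model_of_length(length)
    k, r = size_filter([model])
    assert (len(k) == 1) is kept
    if not kept:
        assert r[0].reject_reason == "size"


def test_size_filter_partitions_input():
    models = [model_of_length(n, mid=f"m{n}") for n in (60, 85, 130, 179, 200, 987)]
    kept, rejected = size_filter(models)
    assert len(kept) + len(rejected) == len(models)
    assert {m.model_id for m in kept} | {m.model_id for m in rejected} == {m.model_id for m in models}


# ---------------------------------------------------------------------------
# architecture


def test_architecture_counts_and_intronless():
    m4 = make_model_with_lengths([90, 120, 90, 99])
    arch = classify_architecture(m4)
    assert arch.exon_count == 4
    assert len(arch.intron_positions) == 3
    m1 = make_model_with_lengths([396])
    arch1 = classify_architecture(m1)
    assert arch1.exon_count == 1
    assert arch1.intron_phases == [] and arch1.intron_positions == []


def test_architecture_matches_generator_records(truth):
    for model in truth.models:
        arch = classify_architecture(model)
        positions, phases = truth.intron_truth[model.model_id]
        assert arch.exon_count == len(model.exons)
        assert arch.intron_positions == positions
        assert arch.intron_phases == phases


# ---------------------------------------------------------------------------
# end-to-end properties on the shared genome


def test_predicted_models_in_frame_and_canonical(truth, truth_hsps, query):
    models = build_models(truth_hsps, truth.genome, query=query)
    kept, _ = size_filter(models)
    assert kept, "no models recovered on the shared genome"
    for m in kept:
        if m.broken_orf:
            continue
        total = sum(b - a for a, b in m.exons)
        assert total % 3 == 0
        for i, flag in enumerate(m.splice_flags):
            if flag == "canonical":
                s = m.intron_seq(truth.genome, i)
                assert s.startswith("GT") and s.endswith("AG")
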