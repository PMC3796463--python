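"""Transcript mapping, spliced-leader detection and AS classification."""

import pytest

from fabpscan import (
    SLCatalog,
    classify_as_events,
    detect_sl,
    evidence_summary,
    make_locus_window,
    spliced_map,
)
from fabpscan.synthetic import DEFAULT_SL_LEADER, PlanError, make_transcripts


@pytest.fixture(scope="module")
def faithful(truth):
    return {t.model_id: t for t in make_transcripts(truth) if not t.planted_events}


def test_faithful_transcript_roundtrips_exon_blocks(truth, faithful):
    """spliced_map o make_transcripts is the identity on exon blocks."""
    for model in truth.models:
        t = faithful[model.model_id]
        locus = make_locus_window(truth.genome, model)
        aln = spliced_map(t.seq, locus, transcript_id=t.transcript_id)
        assert aln.complete
        assert aln.unmatched_prefix == ""
        assert aln.polya_trimmed > 0
        assert sorted(aln.genomic_blocks()) == sorted(model.exons), model.model_id


@pytest.fixture(scope="module")
def intronless_truth(query):
    from fabpscan import GenomeSpec, make_genome

    spec = GenomeSpec(
        n_contigs=2, contig_length=16000, n_genes=2, n_decoys=0,
        exon_count_distribution={1: 1.0}, query_identity=1.0, seed=3,
    )
    return make_genome(spec, query)


def test_faithful_single_exon_transcript_is_cds_plus_polya(intronless_truth):
    truth = intronless_truth
    model = truth.models[0]
    assert len(model.exons) == 1
    t = [x for x in make_transcripts(truth) if x.model_id == model.model_id][0]
    assert t.seq == model.cds(truth.genome) + "A" * 20


def test_identity_one_intronless_spec_plants_query_verbatim(intronless_truth, query):
    """query_identity 1.0 with a single-exon distribution: every planted
    protein equals the query and every model is intronless."""
    for m in intronless_truth.models:
        assert m.protein == query
        assert len(m.exons) == 1


def test_exon_skipping_transcript_is_plain_concatenation(truth):
    """String-concatenation oracle for the generator's skipping transcripts."""
    model = next(m for m in truth.models if len(m.exons) >= 4)
    txs = make_transcripts(truth, [(model.model_id, "exon_skipping", {"exon": 2})])
    t = [x for x in txs if x.planted_events][0]
    contig = truth.genome[model.contig_id]
    from fabpscan import revcomp

    exon_seqs = [
        contig[a:b] if model.strand == "+" else revcomp(contig[a:b])
        for a, b in model.exons
    ]
    assert t.seq == exon_seqs[0] + "".join(exon_seqs[2:]) + "A" * 20


def test_sl_transcript_starts_with_leader(truth):
    model = truth.models[0]
    txs = make_transcripts(truth, [(model.model_id, "sl_trans_splicing", {"leader": "SL1"})])
    t = [x for x in txs if x.planted_events][0]
    assert t.seq.startswith("GGTTTAATTACCCAAGTTTGAG")
    assert t.seq[22:].startswith(
        model.cds(truth.genome)[:20]
    )


def test_event_plan_validation(truth, intronless_truth):
    single = intronless_truth.models[0]
    with pytest.raises(PlanError):
        make_transcripts(intronless_truth, [(single.model_id, "intron_retention", {"intron": 1})])
    with pytest.raises(PlanError):
        make_transcripts(intronless_truth, [(single.model_id, "exon_skipping", {"exon": 2})])
    with pytest.raises(PlanError):
        make_transcripts(truth, [(truth.models[0].model_id, "frob", {})])


# ---------------------------------------------------------------------------
# classification


def build_plan(truth):
    plan = []
    for m in truth.models:
        n = len(m.exons)
        if n >= 3:
            plan.append((m.model_id, "exon_skipping", {"exon": 2}))
        if n >= 2:
            plan.append((m.model_id, "intron_retention", {"intron": 1}))
            plan.append((m.model_id, "alt_last_exon", {"intron": min(2, n - 1)}))
        plan.append((m.model_id, "sl_trans_splicing", {"leader": "SL1"}))
    return plan


def test_planted_events_classified_exactly(truth):
    """Label-and-detail classification is exact on planted transcripts; a
    faithful transcript yields no events (100% specificity, incl. SL)."""
    catalog = SLCatalog()
    txs = make_transcripts(truth, build_plan(truth))
    n_events = 0
    for t in txs:
        model = truth.model(t.model_id)
        locus = make_locus_window(truth.genome, model)
        aln = spliced_map(t.seq, locus, transcript_id=t.transcript_id)
        events = classify_as_events(model, [aln], catalog)
        expected = {
            (e["type"], e.get("exon") or e.get("intron") or e.get("leader"))
            for e in t.planted_events
        }
        got = {
            (e.event_type, e.detail.get("exon") or e.detail.get("intron") or e.detail.get("leader"))
            for e in events
        }
        assert got == expected, t.transcript_id
        n_events += len(t.planted_events)
    assert n_events >= 20


def test_retained_intron_is_single_contiguous_block(truth):
    model = next(m for m in truth.models if len(m.exons) == 2)
    txs = make_transcripts(truth, [(model.model_id, "intron_retention", {"intron": 1})])
    t = [x for x in txs if x.planted_events][0]
    locus = make_locus_window(truth.genome, model)
    aln = spliced_map(t.seq, locus, transcript_id=t.transcript_id)
    assert len(aln.blocks) == 1
    lo, hi = model.span
    assert aln.genomic_blocks()[0] == (lo, hi)


def test_alt_last_exon_breakpoint_depth(truth):
    model = next(m for m in truth.models if len(m.exons) >= 2)
    txs = make_transcripts(truth, [(model.model_id, "alt_last_exon", {"intron": 1, "keep_nt": 45})])
    t = [x for x in txs if x.planted_events][0]
    locus = make_locus_window(truth.genome, model)
    aln = spliced_map(t.seq, locus, transcript_id=t.transcript_id)
    events = classify_as_events(model, [aln])
    alt = [e for e in events if e.event_type == "alt_last_exon"][0]
    assert alt.detail["intron"] == 1
    assert alt.detail["breakpoint"] == 45


def test_unmappable_transcript_returns_unmapped_not_exception(truth):
    model = truth.models[0]
    locus = make_locus_window(truth.genome, model)
    aln = spliced_map("ACGT" * 10, locus, transcript_id="junk")
    assert not aln.mapped
    assert not aln.complete


def test_alignment_on_wrong_contig_raises(truth):
    m0 = truth.models[0]
    other = next(m for m in truth.models if m.contig_id != m0.contig_id)
    locus = make_locus_window(truth.genome, other)
    t = make_transcripts(truth)[0]
    aln = spliced_map(t.seq, locus)
    with pytest.raises(ValueError, match="contig"):
        classify_as_events(m0, [aln])


# ---------------------------------------------------------------------------
# detect_sl specifics


def test_detect_sl_mismatch_threshold(truth):
    model = truth.models[0]
    leader = DEFAULT_SL_LEADER
    # two substitutions under max_mismatch=1 -> no event
    mutated = "TT" + leader[2:]
    txs_seq = mutated + model.cds(truth.genome) + "A" * 20
    locus = make_locus_window(truth.genome, model)
    aln = spliced_map(txs_seq, locus, transcript_id="x")
    assert detect_sl(aln, SLCatalog(max_mismatch=1)) is None
    # one substitution passes
    mutated1 = "T" + leader[1:]
    aln1 = spliced_map(mutated1 + model.cds(truth.genome) + "A" * 20, locus, transcript_id="y")
    ev = detect_sl(aln1, SLCatalog(max_mismatch=1))
    assert ev is not None and ev.detail["leader"] == "SL1"


def test_detect_sl_ignores_genomically_encoded_prefix(truth):
    """A 5' extension copied from the upstream genome is not trans-spliced."""
    model = truth.models[0]
    locus = make_locus_window(truth.genome, model)
    lseq = locus.tseq
    first_exon_t = locus.t_interval(model.exons[0])
    upstream22 = lseq[first_exon_t[0] - 22 : first_exon_t[0]]
    catalog = SLCatalog(leaders={"FAKE": upstream22})
    seq = upstream22 + model.cds(truth.genome) + "A" * 20
    aln = spliced_map(seq, locus, transcript_id="enc")
    # the prefix (if any remains unmatched) is encoded upstream -> no event
    assert detect_sl(aln, catalog) is None


def test_detect_sl_empty_prefix_no_event(truth, faithful):
    model = truth.models[0]
    locus = make_locus_window(truth.genome, model)
    aln = spliced_map(faithful[model.model_id].seq, locus)
    assert detect_sl(aln, SLCatalog()) is None


# ---------------------------------------------------------------------------
# evidence summary


def test_evidence_summary_strings(truth):
    model = next(m for m in truth.models if len(m.exons) >= 3)
    locus = make_locus_window(truth.genome, model)
    txs = make_transcripts(truth, [(model.model_id, "exon_skipping", {"exon": 2})])
    faithful_t = [t for t in txs if t.model_id == model.model_id and not t.planted_events][0]
    skip_t = [t for t in txs if t.planted_events][0]
    catalog = SLCatalog()

    def pair(t):
        aln = spliced_map(t.seq, locus, transcript_id=t.transcript_id)
        return aln, classify_as_events(model, [aln], catalog)

    # faithful supported -> 1/1
    assert evidence_summary([model], {model.model_id: [pair(faithful_t)]}) == {
        model.model_id: "1/1"
    }
    # only the skipping variant supported -> 1/2
    assert evidence_summary([model], {model.model_id: [pair(skip_t)]}) == {
        model.model_id: "1/2"
    }
    # both -> 2/2
    assert evidence_summary(
        [model], {model.model_id: [pair(faithful_t), pair(skip_t)]}
    ) == {model.model_id: "2/2"}
    # zero alignments -> 0/1
    assert evidence_summary([model], {}) == {model.model_id: "0/1"}
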