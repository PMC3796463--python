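import pytest

from fabpscan import GenomeSpec, ScoringScheme, default_template, find_hsps, make_genome


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme.default()


@pytest.fixture(scope="session")
def query():
    return default_template().reference_protein


@pytest.fixture(scope="session")
def truth(query):
    """One default synthetic genome shared by read-only tests."""
    return make_genome(GenomeSpec(seed=11), query)


@pytest.fixture(scope="session")
def truth_hsps(truth, query):
    return find_hsps(query, truth.genome)


def make_model_with_lengths(exon_lengths, *, model_id="m", contig_id="c", strand="+",
                            intron_len=100, protein=None):
    """Build a GeneModel from exon lengths (nt, transcription order)."""
    from fabpscan import GeneModel

    exons = []
    pos = 0
    for ln in exon_lengths:
        exons.append((pos, pos + ln))
        pos += ln + intron_len
    if strand == "-":
        # mirror: the list stays in transcription order (descending plus coords)
        hi = exons[-1][1]
        exons = [(hi - b, hi - a) for a, b in exons]
    total = sum(exon_lengths)
    if protein is None:
        protein = "M" + "A" * (total // 3 - 2)
    return GeneModel(
        model_id=model_id,
        contig_id=contig_id,
        strand=strand,
        exons=exons,
        protein=protein,
        splice_flags=["canonical"] * (len(exons) - 1),
        source="truth",
    )
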