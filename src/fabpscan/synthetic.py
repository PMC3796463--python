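"""Synthetic genomes with planted FABP-like genes and transcript evidence.

The generator plants multi-exon genes derived from a seed query protein at a
controlled amino-acid identity (codon-level synonymous/nonsynonymous edits),
with GT..AG introns inserted at codon boundaries or mid-codon (phase 0/1/2
recorded), intergenic flanks of random sequence, decoy ORFs whose proteins
fall outside the FABP size window, and optional duplicate loci encoding
identical proteins. Transcripts are emitted per model: one faithful copy
plus one per planned alternative-splicing event (exon skipping, intron
retention, alternative last exon, spliced-leader addition), each carrying a
poly(A) tail. All output is deterministic for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import AA_TO_CODONS, STD_AA, revcomp
from .models import GeneModel

__all__ = [
    "GenomeSpec",
    "TruthSet",
    "TranscriptEvidence",
    "SizingError",
    "PlanError",
    "make_genome",
    "make_transcripts",
    "DEFAULT_SL_LEADER",
]

DEFAULT_SL_LEADER = "GGTTTAATTACCCAAGTTTGAG"

NT = "ACGT"


class SizingError(ValueError):
    """Spec infeasible: contigs too short to host the requested loci."""


class PlanError(ValueError):
    """An event plan entry is incompatible with its model's architecture."""


@dataclass
class GenomeSpec:
    """Study conditions for one synthetic genome."""

    n_contigs: int = 6
    contig_length: int = 30000
    n_genes: int = 10
    exon_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.15, 3: 0.20, 4: 0.30, 5: 0.10, 6: 0.10}
    )
    protein_length_range: tuple[int, int] = (80, 180)
    intron_length_range: tuple[int, int] = (60, 500)
    query_identity: float = 0.85
    n_decoys: int = 2
    decoy_length_ranges: tuple[tuple[int, int], ...] = ((200, 400), (40, 70))
    duplicate_locus_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        probs = self.exon_count_distribution
        if not probs or any(k < 1 or k > 6 for k in probs):
            raise ValueError("exon_count_distribution support must be 1..6")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("exon count probabilities must sum to 1")
        if self.intron_length_range[0] < 4:
            raise ValueError("intron min must be >= 4 (room for GT..AG)")
        lo, hi = self.protein_length_range
        if lo < 80 or hi > 180 or lo > hi:
            raise ValueError("protein_length_range must lie within [80, 180]")
        for dlo, dhi in self.decoy_length_ranges:
            if dlo > dhi or (dlo <= 180 and dhi >= 80):
                raise ValueError("decoy length ranges must be disjoint from [80, 180]")


@dataclass
class TranscriptEvidence:
    """One synthetic mRNA/EST with its planted event labels."""

    transcript_id: str
    model_id: str
    seq: str
    planted_events: list[dict] = field(default_factory=list)
    polya_len: int = 20
    description: str = ""


@dataclass
class TruthSet:
    """Ground truth for one synthetic genome."""

    genome: dict[str, str]
    models: list[GeneModel]
    transcripts: list[TranscriptEvidence] = field(default_factory=list)
    decoy_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    query: str = ""
    #: model_id -> (intron aa positions, intron phases) recorded at planting
    intron_truth: dict[str, tuple[list[int], list[int]]] = field(default_factory=dict)

    def model(self, model_id: str) -> GeneModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


# ---------------------------------------------------------------------------


def _rand_nt(
    rng: np.random.Generator, n: int,
    first_not: str | None = None, last_not: str | None = None,
) -> str:
    """Random sequence, optionally constraining the first/last base.

    The constraint pins down the poly(A) boundary of transcripts: the base
    just downstream of a planted gene (transcription sense) is kept non-A so
    a trailing A run maps back to a unique genomic endpoint.
    """
    seq = [NT[i] for i in rng.integers(0, 4, size=n)]
    if n and first_not and seq[0] == first_not:
        options = [c for c in NT if c != first_not]
        seq[0] = options[int(rng.integers(0, 3))]
    if n and last_not and seq[-1] == last_not:
        options = [c for c in NT if c != last_not]
        seq[-1] = options[int(rng.integers(0, 3))]
    return "".join(seq)


def _mutate_protein(protein: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues (never position 0) to hit the target identity."""
    n_sub = int(round((1.0 - identity) * len(protein)))
    n_sub = min(n_sub, len(protein) - 1)
    seq = list(protein)
    if n_sub:
        positions = rng.choice(np.arange(1, len(protein)), size=n_sub, replace=False)
        for p in sorted(int(x) for x in positions):
            choices = [a for a in STD_AA if a != seq[p]]
            seq[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        codons = AA_TO_CODONS[aa]
        out.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(out)


def _stop_codon(rng: np.random.Generator) -> str:
    return ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]


def _intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    ln = int(rng.integers(lo, hi + 1))
    return "GT" + _rand_nt(rng, ln - 4) + "AG"


def _pick_cut_points(
    cds_len: int, n_introns: int, rng: np.random.Generator, min_exon: int = 45
) -> list[int]:
    """Intron insertion offsets into the CDS, pairwise >= min_exon apart."""
    if n_introns == 0:
        return []
    spacing = min_exon
    while cds_len - 2 * spacing < (n_introns - 1) * spacing and spacing > 9:
        spacing -= 3
    lo, hi = spacing, cds_len - spacing
    for _ in range(1000):
        cuts = sorted(int(x) for x in rng.integers(lo, hi + 1, size=n_introns))
        if all(b - a >= spacing for a, b in zip(cuts, cuts[1:])):
            return cuts
    raise SizingError("cannot place introns with the requested exon spacing")


def make_genome(spec: GenomeSpec, query_protein: str) -> TruthSet:
    """Generate a genome with planted gene models and known ground truth."""
    spec.validate()
    query_protein = query_protein.upper()
    lo, hi = spec.protein_length_range
    if not lo <= len(query_protein) <= hi:
        raise ValueError("query protein length outside protein_length_range")
    if set(query_protein) - set(STD_AA):
        raise ValueError("query protein contains invalid residues")
    if not query_protein.startswith("M"):
        raise ValueError("query protein must start with Met")
    rng = np.random.default_rng(spec.seed)

    exon_counts = sorted(spec.exon_count_distribution)
    exon_probs = [spec.exon_count_distribution[k] for k in exon_counts]

    # item: (kind, name, strand, gene_seq, exon_offsets, protein, positions, phases)
    items: list[tuple] = []

    def _build_gene(name: str, protein: str) -> tuple:
        ec = int(rng.choice(exon_counts, p=exon_probs))
        cds = _backtranslate(protein, rng) + _stop_codon(rng)
        cuts = _pick_cut_points(len(cds), ec - 1, rng)
        # an in-frame stop just upstream pins down the ORF's 5' extent, so
        # the true start codon is identifiable from sequence alone
        parts = [_stop_codon(rng)]
        offsets = []  # (offset within gene_seq, length) per exon
        pos = 3
        prev = 0
        for cut in cuts + [len(cds)]:
            exon = cds[prev:cut]
            offsets.append((pos, len(exon)))
            parts.append(exon)
            pos += len(exon)
            if cut != len(cds):
                intr = _intron(rng, *spec.intron_length_range)
                parts.append(intr)
                pos += len(intr)
            prev = cut
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        positions = [c // 3 for c in cuts]
        phases = [c % 3 for c in cuts]
        return ("gene", name, strand, "".join(parts), offsets, protein, positions, phases)

    gene_proteins: list[str] = []
    for i in range(spec.n_genes):
        protein = _mutate_protein(query_protein, spec.query_identity, rng)
        gene_proteins.append(protein)
        items.append(_build_gene(f"gene{i:03d}", protein))
    for j in range(spec.duplicate_locus_count):
        if not gene_proteins:
            raise ValueError("duplicate loci require at least one gene")
        items.append(_build_gene(f"dup{j:03d}", gene_proteins[0]))

    for k in range(spec.n_decoys):
        dlo, dhi = spec.decoy_length_ranges[k % len(spec.decoy_length_ranges)]
        dlen = int(rng.integers(dlo, dhi + 1))
        core = _mutate_protein(query_protein, spec.query_identity, rng)[1:]
        if dlen - 1 <= len(core):
            protein = "M" + core[: dlen - 1]
        else:
            spare = dlen - 1 - len(core)
            left = int(rng.integers(0, spare + 1))
            protein = (
                "M"
                + "".join(STD_AA[i] for i in rng.integers(0, 20, size=left))
                + core
                + "".join(STD_AA[i] for i in rng.integers(0, 20, size=spare - left))
            )
        cds = _stop_codon(rng) + _backtranslate(protein, rng) + _stop_codon(rng)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        items.append(
            ("decoy", f"decoy{k:03d}", strand, cds, [(3, len(cds) - 3)], protein, [], [])
        )

    # round-robin placement with random intergenic flanks
    per_contig: list[list[tuple]] = [[] for _ in range(spec.n_contigs)]
    for i, item in enumerate(items):
        per_contig[i % spec.n_contigs].append(item)

    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    decoys: list[tuple[str, int, int, str]] = []
    intron_truth: dict[str, tuple[list[int], list[int]]] = {}
    for ci in range(spec.n_contigs):
        cid = f"ctg{ci:03d}"
        pieces: list[str] = []
        cursor = 0
        prev_plus_gene = False
        for kind, name, strand, gseq, offsets, protein, positions, phases in per_contig[ci]:
            # FABP loci overwhelmingly sit on separate scaffolds or far apart
            # on one chromosome; keep neighbouring loci beyond intron reach
            flank = _rand_nt(
                rng, int(rng.integers(5200, 6801)),
                first_not="A" if prev_plus_gene else None,
                last_not="T" if (kind == "gene" and strand == "-") else None,
            )
            pieces.append(flank)
            cursor += len(flank)
            prev_plus_gene = kind == "gene" and strand == "+"
            g0 = cursor
            glen = len(gseq)
            inserted = gseq if strand == "+" else revcomp(gseq)
            pieces.append(inserted)
            cursor += glen
            if strand == "+":
                exons = [(g0 + off, g0 + off + ln) for off, ln in offsets]
            else:
                exons = [(g0 + glen - off - ln, g0 + glen - off) for off, ln in offsets]
            if kind == "gene":
                model = GeneModel(
                    model_id=name,
                    contig_id=cid,
                    strand=strand,
                    exons=exons,
                    protein=protein,
                    splice_flags=["canonical"] * (len(exons) - 1),
                    source="truth",
                )
                models.append(model)
                intron_truth[name] = (list(positions), list(phases))
            else:
                decoys.append((cid, g0, g0 + glen, strand))
        tail = spec.contig_length - cursor
        if tail < 0:
            raise SizingError(
                f"contig {cid} needs {cursor} nt but contig_length is {spec.contig_length}"
            )
        pieces.append(_rand_nt(rng, tail, first_not="A" if prev_plus_gene else None))
        genome[cid] = "".join(pieces)
    return TruthSet(
        genome=genome,
        models=models,
        decoy_loci=decoys,
        query=query_protein,
        intron_truth=intron_truth,
    )


# ---------------------------------------------------------------------------
# transcripts


def _spliced(truth: TruthSet, model: GeneModel) -> list[str]:
    """Exon sequences in transcription orientation."""
    contig = truth.genome[model.contig_id]
    out = []
    for a, b in model.exons:
        piece = contig[a:b]
        out.append(piece if model.strand == "+" else revcomp(piece))
    return out


def make_transcripts(
    truth: TruthSet,
    event_plan: Sequence[tuple[str, str, Mapping]] = (),
    sl_catalog: Mapping[str, str] | None = None,
    seed: int = 0,
    polya_len: int = 20,
) -> list[TranscriptEvidence]:
    """One faithful transcript per model plus one per planned event.

    Plan entries are (model_id, event_type, params): exon_skipping drops one
    internal exon (params ``exon``, 1-based ordinal); intron_retention keeps
    intron ``intron``; alt_last_exon truncates inside intron ``intron`` and
    extends with ``keep_nt`` of intronic sequence; sl_trans_splicing
    prepends leader ``leader`` from the catalog. Every transcript carries a
    poly(A) tail of ``polya_len``.
    """
    sl_catalog = dict(sl_catalog or {"SL1": DEFAULT_SL_LEADER})
    del seed  # generation is fully determined by truth + plan
    polya = "A" * polya_len
    out: list[TranscriptEvidence] = []
    for model in truth.models:
        exons = _spliced(truth, model)
        out.append(
            TranscriptEvidence(
                transcript_id=f"{model.model_id}.t0",
                model_id=model.model_id,
                seq="".join(exons) + polya,
                planted_events=[],
                polya_len=polya_len,
                description="faithful",
            )
        )
    for idx, (mid, etype, params) in enumerate(event_plan):
        model = truth.model(mid)
        exons = _spliced(truth, model)
        n = len(exons)
        if etype == "exon_skipping":
            k = int(params.get("exon", 2))
            if n < 3 or not 2 <= k <= n - 1:
                raise PlanError(f"{mid}: cannot skip exon {k} of a {n}-exon model")
            seq = "".join(exons[: k - 1] + exons[k:])
            detail = {"exon": k}
        elif etype == "intron_retention":
            j = int(params.get("intron", 1))
            if n < 2 or not 1 <= j <= n - 1:
                raise PlanError(f"{mid}: no intron {j} to retain")
            intron = model.intron_seq(truth.genome, j - 1)
            seq = "".join(exons[:j]) + intron + "".join(exons[j:])
            detail = {"intron": j}
        elif etype == "alt_last_exon":
            j = int(params.get("intron", 1))
            keep = int(params.get("keep_nt", 45))
            if n < 2 or not 1 <= j <= n - 1:
                raise PlanError(f"{mid}: no intron {j} for an alternative last exon")
            intron = model.intron_seq(truth.genome, j - 1)
            keep = min(keep, len(intron) - 1)
            if keep < 10:
                raise PlanError(f"{mid}: intron {j} too short for an alternative last exon")
            seq = "".join(exons[:j]) + intron[:keep]
            detail = {"intron": j, "keep_nt": keep}
        elif etype == "sl_trans_splicing":
            name = params.get("leader", "SL1")
            if name not in sl_catalog:
                raise PlanError(f"unknown spliced leader {name!r}")
            seq = sl_catalog[name] + "".join(exons)
            detail = {"leader": name}
        else:
            raise PlanError(f"unknown event type {etype!r}")
        out.append(
            TranscriptEvidence(
                transcript_id=f"{mid}.e{idx}_{etype}",
                model_id=mid,
                seq=seq + polya,
                planted_events=[{"type": etype, **detail}],
                polya_len=polya_len,
                description=f"event={etype};" + ";".join(f"{k}={v}" for k, v in detail.items()),
            )
        )
    return out
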