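"""Format plumbing: FASTA, GFF3 gene models, BED12 spliced alignments, TSV.

Conventions: internal coordinates are 0-based half-open on the plus strand;
GFF3 is written 1-based inclusive and BED12 0-based half-open, with the
conversions round-trip tested. The GFF3 writer/reader covers exactly the
gene/mRNA/exon/CDS feature set this package produces (translation and
splice flags are carried as mRNA attributes so a models file is
self-contained).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evidence import SplicedAlignment
from .models import GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3",
    "write_bed12",
]


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Records as (id, description, sequence)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, str(rec.seq)))
    return out


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, description, sequence) records."""
    seqs = [
        SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _gff_escape(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")
    )


def _gff_unescape(value: str) -> str:
    return (
        value.replace("%2C", ",").replace("%3D", "=").replace("%3B", ";").replace("%25", "%")
    )


def write_gff3(models: Sequence[GeneModel], path: str | Path, source: str = "fabpscan") -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive, phase populated."""
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.span
        gid = _gff_escape(m.model_id)
        score = f"{m.score:.1f}" if m.score is not None else "."
        attrs = [f"ID={gid}"]
        if m.species:
            attrs.append(f"species={_gff_escape(m.species)}")
        lines.append(
            "\t".join(
                [m.contig_id, source, "gene", str(lo + 1), str(hi), score, m.strand, ".",
                 ";".join(attrs)]
            )
        )
        mattrs = [f"ID={gid}.t", f"Parent={gid}", f"src={m.source}"]
        if m.protein:
            mattrs.append(f"translation={m.protein}")
        if m.splice_flags:
            mattrs.append("splice_flags=" + "|".join(m.splice_flags))
        if m.broken_orf:
            mattrs.append("broken_orf=1")
        if m.reject_reason:
            mattrs.append(f"reject_reason={m.reject_reason}")
        lines.append(
            "\t".join(
                [m.contig_id, source, "mRNA", str(lo + 1), str(hi), ".", m.strand, ".",
                 ";".join(mattrs)]
            )
        )
        # phase of each CDS piece, transcription order
        phases = []
        cum = 0
        for a, b in m.exons:
            phases.append((3 - cum % 3) % 3)
            cum += b - a
        plus_order = sorted(range(len(m.exons)), key=lambda i: m.exons[i][0])
        for i in plus_order:
            a, b = m.exons[i]
            lines.append(
                "\t".join(
                    [m.contig_id, source, "exon", str(a + 1), str(b), ".", m.strand, ".",
                     f"Parent={gid}.t"]
                )
            )
            lines.append(
                "\t".join(
                    [m.contig_id, source, "CDS", str(a + 1), str(b), ".", m.strand,
                     str(phases[i]), f"Parent={gid}.t"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
        contig, _src, ftype, start, end, score, strand, _phase, attr_str = fields
        try:
            a, b = int(start) - 1, int(end)
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric coordinates") from None
        attrs = {}
        for part in attr_str.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                attrs[k] = _gff_unescape(v)
        if ftype == "gene":
            gid = attrs["ID"]
            genes[gid] = {
                "contig": contig,
                "strand": strand,
                "score": None if score == "." else float(score),
                "species": attrs.get("species"),
                "exons": [],
            }
            order.append(gid)
        elif ftype == "mRNA":
            gid = attrs["Parent"]
            genes[gid].update(
                protein=attrs.get("translation", ""),
                source=attrs.get("src", "predicted"),
                splice_flags=attrs.get("splice_flags", ""),
                broken=attrs.get("broken_orf") == "1",
                reject=attrs.get("reject_reason"),
            )
        elif ftype == "exon":
            gid = attrs["Parent"].removesuffix(".t")
            genes[gid]["exons"].append((a, b))
    out = []
    for gid in order:
        g = genes[gid]
        exons = sorted(g["exons"], reverse=(g["strand"] == "-"))
        flags = g.get("splice_flags", "")
        out.append(
            GeneModel(
                model_id=gid,
                contig_id=g["contig"],
                strand=g["strand"],
                exons=exons,
                protein=g.get("protein", ""),
                splice_flags=flags.split("|") if flags else [],
                source=g.get("source", "predicted"),
                broken_orf=g.get("broken", False),
                score=g["score"],
                reject_reason=g.get("reject"),
                species=g.get("species"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED12


def write_bed12(alignments: Sequence[SplicedAlignment], path: str | Path) -> None:
    """One BED12 line per mapped spliced alignment (0-based half-open)."""
    lines = []
    for aln in alignments:
        if not aln.mapped:
            continue
        blocks = sorted(aln.genomic_blocks())
        chrom_start = blocks[0][0]
        chrom_end = blocks[-1][1]
        sizes = ",".join(str(b - a) for a, b in blocks)
        starts = ",".join(str(a - chrom_start) for a, b in blocks)
        lines.append(
            "\t".join(
                [
                    aln.contig_id,
                    str(chrom_start),
                    str(chrom_end),
                    aln.transcript_id,
                    "0",
                    aln.strand,
                    str(chrom_start),
                    str(chrom_end),
                    "0,0,0",
                    str(len(blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
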