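"""Nucleotide primitives: complement, codon translation, six-frame translation.

The codon table is the standard genetic code (NCBI table 1). Codons containing
ambiguity characters translate to ``X``; stop codons render ``*``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, stops included as '*'
CODON_MAP: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_MAP[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)

#: amino acid -> sorted list of codons (stops excluded)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STD_AA = "ARNDCQEGHILKMFPSTWYV"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str, offset: int = 0) -> str:
    """Translate ``seq`` from ``offset``; trailing partial codon dropped."""
    n = (len(seq) - offset) // 3
    out = []
    for i in range(n):
        codon = seq[offset + 3 * i : offset + 3 * i + 3].upper()
        out.append(CODON_MAP.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class TranslatedFrame:
    """One of the six reading frames of a contig.

    ``strand`` is '+' or '-'; ``frame`` is the 0-based offset into the plus
    strand ('+') or into the reverse complement ('-').
    """

    strand: str
    frame: int
    aa: str


def six_frame_translate(contig: str) -> list[TranslatedFrame]:
    """All six translated reading frames of ``contig``.

    Frames +0,+1,+2 read the plus strand at offsets 0/1/2; frames -0,-1,-2
    read the reverse complement the same way. Empty input yields six empty
    frames.
    """
    rc = revcomp(contig)
    frames = [TranslatedFrame("+", f, translate_cds(contig, f)) for f in range(3)]
    frames += [TranslatedFrame("-", f, translate_cds(rc, f)) for f in range(3)]
    return frames
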