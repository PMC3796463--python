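"""Census reports: architecture histograms, species summaries, intron-
retention statistics and identity-range statistics.

The module aggregates gene models into the two summary tables used for
FABP family surveys: a per-species feature table (locus count, protein
length range, transcript-evidence string, alternative-splicing flag) and a
per-species exon-count census with a totals row. It also computes the
intron-position retention statistic for intron-poor genes relative to a
canonical multi-exon architecture, and pairwise identity extremes.

Packaged reference fixtures (``data/*.tsv``) hold published per-species
rows so that the aggregation path can be exercised without any genome
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .audit import identity_matrix
from .models import GeneModel, classify_architecture
from .search import ScoringScheme

__all__ = [
    "ArchitectureCensus",
    "SpeciesSummaryRow",
    "RetentionStats",
    "architecture_census",
    "census_from_counts",
    "species_summary",
    "intron_retention_stats",
    "identity_matrix_stats",
    "load_architecture_table",
    "load_species_table",
    "species_table_stats",
]

EXON_BINS = [1, 2, 3, 4, 5, 6]
OVERFLOW = "7+"


@dataclass
class ArchitectureCensus:
    """Per-species exon-count histogram plus a totals row."""

    per_species: pd.DataFrame  # index species, columns 1..6 and '7+'
    warnings: list[str] = field(default_factory=list)

    @property
    def totals(self) -> pd.Series:
        return self.per_species.sum(axis=0)

    @property
    def n_models(self) -> int:
        return int(self.per_species.to_numpy().sum())


def architecture_census(
    models_by_species: Mapping[str, Sequence[GeneModel]]
) -> ArchitectureCensus:
    """Histogram of exon counts 1-6 per species; counts above 6 go to an
    overflow bucket with a warning. Totals conserve the model count."""
    cols = [str(k) for k in EXON_BINS] + [OVERFLOW]
    rows = {}
    warnings = []
    for species in sorted(models_by_species):
        counts = dict.fromkeys(cols, 0)
        for model in models_by_species[species]:
            ec = classify_architecture(model).exon_count
            if ec in EXON_BINS:
                counts[str(ec)] += 1
            else:
                counts[OVERFLOW] += 1
                warnings.append(
                    f"{species}/{model.model_id}: {ec} exons exceeds the 1-6 bins"
                )
        rows[species] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols).fillna(0).astype(int)
    return ArchitectureCensus(per_species=df, warnings=warnings)


def census_from_counts(table: pd.DataFrame) -> ArchitectureCensus:
    """Build a census from a per-species exon-count table (columns 1..6)."""
    df = table.copy()
    df.columns = [str(c) for c in df.columns]
    for c in [str(k) for k in EXON_BINS]:
        if c not in df.columns:
            df[c] = 0
    if OVERFLOW not in df.columns:
        df[OVERFLOW] = 0
    df = df[[str(k) for k in EXON_BINS] + [OVERFLOW]].fillna(0).astype(int)
    return ArchitectureCensus(per_species=df)


@dataclass
class SpeciesSummaryRow:
    species: str
    n_loci: int
    length_range: tuple[int, int] | None
    evidence: str
    alternative_splicing: str  # Yes | No


def species_summary(
    models_by_species: Mapping[str, Sequence[GeneModel]],
    evidence_by_species: Mapping[str, str] | None = None,
    events_by_species: Mapping[str, Sequence] | None = None,
) -> list[SpeciesSummaryRow]:
    """One row per species: locus count, protein length range, evidence
    string and an alternative-splicing flag (Yes iff any event).

    Species present only in the evidence or event maps (e.g. transcript-only
    species with zero genomic loci) keep their row.
    """
    evidence_by_species = dict(evidence_by_species or {})
    events_by_species = dict(events_by_species or {})
    species = sorted(
        set(models_by_species) | set(evidence_by_species) | set(events_by_species)
    )
    rows = []
    for sp in species:
        models = list(models_by_species.get(sp, []))
        lengths = [len(m.protein) for m in models]
        rows.append(
            SpeciesSummaryRow(
                species=sp,
                n_loci=len(models),
                length_range=(min(lengths), max(lengths)) if lengths else None,
                evidence=evidence_by_species.get(sp, f"0/{max(1, len(models))}"),
                alternative_splicing="Yes" if events_by_species.get(sp) else "No",
            )
        )
    return rows


@dataclass
class RetentionStats:
    """Which canonical intron positions intron-poor genes retain."""

    per_position: dict[int, int]  # canonical position ordinal (1-based) -> introns
    unassigned: int
    a: int  # reduced models retaining the first canonical position
    b: int  # reduced models with >= 1 assignable intron

    @property
    def fraction(self) -> str:
        return f"{self.a}/{self.b}"


def intron_retention_stats(
    reduced_models: Sequence[GeneModel],
    canonical_positions: Sequence[int],
    tolerance: int = 5,
) -> RetentionStats:
    """Assign the introns of 1-2 intron genes to canonical intron positions.

    ``canonical_positions`` are the protein positions (aa offsets) of the
    introns of a reference multi-exon architecture, strictly increasing.
    Each intron of each reduced model is matched to the nearest canonical
    position within ``tolerance`` aa (else unassigned). ``b`` counts reduced
    models with at least one assignable intron and ``a`` those retaining the
    first canonical position; the headline statistic is "a/b".
    """
    canon = list(canonical_positions)
    if canon != sorted(canon) or len(set(canon)) != len(canon):
        raise ValueError("canonical positions must be strictly increasing")
    per_position = {i + 1: 0 for i in range(len(canon))}
    unassigned = 0
    a = b = 0
    for model in reduced_models:
        arch = classify_architecture(model)
        if not 1 <= len(arch.intron_positions) <= 2:
            continue
        assigned_ordinals = set()
        for pos in arch.intron_positions:
            dists = [(abs(pos - c), i) for i, c in enumerate(canon)]
            dist, i = min(dists)
            if dist <= tolerance:
                per_position[i + 1] += 1
                assigned_ordinals.add(i + 1)
            else:
                unassigned += 1
        if assigned_ordinals:
            b += 1
            if 1 in assigned_ordinals:
                a += 1
    return RetentionStats(per_position=per_position, unassigned=unassigned, a=a, b=b)


def identity_matrix_stats(
    proteins: Mapping[str, str], scoring: ScoringScheme | None = None
) -> tuple[pd.DataFrame, float, float, list[tuple[str, str]]]:
    """Pairwise identity matrix plus min/max off-diagonal percent identity.

    Returns (matrix, min_off, max_off, identical_pairs); pairs of byte-
    identical sequences are flagged rather than excluded from the extremes.
    """
    if len(proteins) < 2:
        raise ValueError("identity statistics require at least 2 proteins")
    mat = identity_matrix(dict(proteins), scoring)
    names = list(mat.index)
    off = []
    identical = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            off.append(float(mat.iloc[i, j]))
            if proteins[names[i]] == proteins[names[j]]:
                identical.append((names[i], names[j]))
    return mat, min(off), max(off), identical


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("fabpscan").joinpath("data", name)


def load_architecture_table() -> pd.DataFrame:
    """Published per-species exon-count rows (no totals row)."""
    with resources.as_file(_data_path("architecture_by_species.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="species")
    return df.drop(columns=["phylum"])


def load_species_table() -> pd.DataFrame:
    """Published per-species feature rows (34 species, 8 phyla)."""
    with resources.as_file(_data_path("species_features.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def species_table_stats(df: pd.DataFrame) -> dict[str, int]:
    """Headline counts from a species feature table.

    A species "has FABP sequences" when its evidence string reports at least
    one transcript variant (genomic or transcript-only loci both count).
    """

    def _t(ev) -> int:
        if not isinstance(ev, str) or "/" not in ev:
            return 0
        try:
            return int(ev.split("/")[1])
        except ValueError:
            return 0

    n_total = len(df)
    n_with = int(sum(1 for ev in df["evidence"] if _t(ev) > 0))
    max_loci = int(pd.to_numeric(df["n_loci"], errors="coerce").max())
    return {
        "n_species": n_total,
        "n_species_with_fabp": n_with,
        "max_loci_per_species": max_loci,
    }
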