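"""End-to-end orchestration: search -> annotate -> filter -> evidence ->
audit -> census, with a machine-readable run manifest.

Stages communicate only through the declared file formats (FASTA, BLAST
tabular, GFF3, TSV), so a third-party BLAST tabular file can replace the
in-package search. Reruns with the same configuration and seed reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .audit import audit_key_residues, default_template
from .census import architecture_census, species_summary
from .evidence import (
    SLCatalog,
    classify_as_events,
    evidence_summary,
    make_locus_window,
    spliced_map,
)
from .models import build_models, size_filter
from .search import FilterConfig, ScoringScheme, find_hsps, read_hsp_table, write_hsp_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("fabpscan.pipeline")


@dataclass
class PipelineConfig:
    genome: str
    queries: str
    out_dir: str
    transcripts: str | None = None
    hsp_table: str | None = None  # precomputed BLAST tabular; skips the search
    species: str = "synthetic"
    evalue_max: float = 1e-10
    min_protein_len: int = 80
    max_protein_len: int = 180
    gap_open: int = 11
    gap_extend: int = 1
    max_intron: int = 5000
    max_query_overlap: int = 10
    snap_window: int = 15
    sl_leaders: dict = field(default_factory=lambda: {"SL1": "GGTTTAATTACCCAAGTTTGAG"})
    sl_max_mismatch: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str):
    log.info("[%s] starting", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    try:
        genome = {rid: seq for rid, _d, seq in fio.read_fasta(config.genome)}
        queries = fio.read_fasta(config.queries)
        scoring = ScoringScheme.default()
        scoring.gap_open = config.gap_open
        scoring.gap_extend = config.gap_extend
        filt = FilterConfig(
            evalue_max=config.evalue_max,
            min_protein_len=config.min_protein_len,
            max_protein_len=config.max_protein_len,
        )

        _stage("search")
        if config.hsp_table:
            hsps = read_hsp_table(Path(config.hsp_table).read_text(), scoring)
        else:
            hsps = []
            for qid, _desc, qseq in queries:
                hsps.extend(find_hsps(qseq, genome, scoring, filt, query_id=qid))
        (out / "hits.tsv").write_text(write_hsp_table(hsps))
        manifest["stages"]["search"] = {"n_hsps": len(hsps)}

        _stage("annotate")
        by_query: dict[str, list] = {}
        for h in hsps:
            by_query.setdefault(h.query_id, []).append(h)
        qseq_by_id = {qid: seq for qid, _d, seq in queries}
        models = []
        for qid in sorted(by_query):
            models.extend(
                build_models(
                    by_query[qid], genome, filt,
                    max_intron=config.max_intron,
                    max_query_overlap=config.max_query_overlap,
                    window=config.snap_window,
                    query=qseq_by_id.get(qid),
                    scoring=scoring,
                )
            )
        # one locus, one model: drop lower-scoring duplicates on the same span
        models.sort(key=lambda m: (-(m.score or 0), m.contig_id, m.span))
        unique = []
        for m in models:
            if any(
                u.contig_id == m.contig_id
                and min(u.span[1], m.span[1]) - max(u.span[0], m.span[0]) > 0
                for u in unique
            ):
                log.info("[annotate] dropping overlapping model %s", m.model_id)
                continue
            unique.append(m)
        models = sorted(unique, key=lambda m: (m.contig_id, m.span))
        for m in models:
            m.species = config.species
        manifest["stages"]["annotate"] = {"n_models": len(models)}

        _stage("size_filter")
        clean = []
        rejected = []
        for m in models:
            if m.broken_orf:
                m.reject_reason = "broken_orf"
                rejected.append(m)
            else:
                clean.append(m)
        kept, size_rejected = size_filter(clean, filt)
        rejected.extend(size_rejected)
        fio.write_gff3(kept, out / "models.gff3")
        fio.write_fasta(
            [(m.model_id, f"len={len(m.protein)}", m.protein) for m in kept],
            out / "proteins.faa",
        )
        pd.DataFrame(
            [
                {"model_id": m.model_id, "protein_len": len(m.protein),
                 "reason": m.reject_reason}
                for m in rejected
            ]
        ).to_csv(out / "rejected.tsv", sep="\t", index=False)
        manifest["stages"]["size_filter"] = {"kept": len(kept), "rejected": len(rejected)}

        _stage("evidence")
        catalog = SLCatalog(leaders=dict(config.sl_leaders), max_mismatch=config.sl_max_mismatch)
        transcripts = fio.read_fasta(config.transcripts) if config.transcripts else []
        events_rows = []
        aligned: dict[str, list] = {m.model_id: [] for m in kept}
        alignments_all = []
        for m in kept:
            locus = make_locus_window(genome, m)
            for tid, _desc, tseq in transcripts:
                aln = spliced_map(tseq, locus, transcript_id=tid)
                if not aln.mapped or not aln.complete:
                    continue
                evs = classify_as_events(m, [aln], catalog)
                aligned[m.model_id].append((aln, evs))
                alignments_all.append(aln)
                for e in evs:
                    events_rows.append(
                        {"model_id": m.model_id, "transcript_id": tid,
                         "event_type": e.event_type,
                         "detail": ";".join(f"{k}={v}" for k, v in sorted(e.detail.items()))}
                    )
        evidence = evidence_summary(kept, aligned)
        pd.DataFrame(events_rows).to_csv(out / "events.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"model_id": mid, "evidence": ev} for mid, ev in sorted(evidence.items())]
        ).to_csv(out / "evidence.tsv", sep="\t", index=False)
        fio.write_bed12(alignments_all, out / "alignments.bed")
        manifest["stages"]["evidence"] = {
            "n_transcripts": len(transcripts),
            "n_events": len(events_rows),
        }

        _stage("audit")
        template = default_template()
        audit_rows = []
        for m in kept:
            audit = audit_key_residues(m.protein, template)
            audit_rows.append(
                {
                    "model_id": m.model_id,
                    "overall": audit.overall,
                    "pct_identity_to_reference": round(audit.pct_identity, 1),
                    **{r.site: r.status for r in audit.records},
                }
            )
        pd.DataFrame(audit_rows).to_csv(out / "audit.tsv", sep="\t", index=False)
        manifest["stages"]["audit"] = {
            "intact": sum(1 for r in audit_rows if r["overall"] == "intact"),
            "audited": len(audit_rows),
        }

        _stage("census")
        by_species = {config.species: kept}
        census = architecture_census(by_species)
        census.per_species.to_csv(out / "architecture_census.tsv", sep="\t")
        events_by_species = {config.species: events_rows}
        rows = species_summary(
            by_species,
            {config.species: "; ".join(f"{mid}:{ev}" for mid, ev in sorted(evidence.items()))},
            events_by_species,
        )
        pd.DataFrame(
            [
                {
                    "species": r.species,
                    "n_loci": r.n_loci,
                    "length_min": r.length_range[0] if r.length_range else "",
                    "length_max": r.length_range[1] if r.length_range else "",
                    "evidence": r.evidence,
                    "alternative_splicing": r.alternative_splicing,
                }
                for r in rows
            ]
        ).to_csv(out / "species_summary.tsv", sep="\t", index=False)
        manifest["stages"]["census"] = {"n_species": len(rows)}
    except Exception as exc:  # record the failing stage, then re-raise
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
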