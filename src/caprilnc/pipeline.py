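"""End-to-end orchestration: identify -> classify -> compare -> TE -> targets.

One :class:`PipelineConfig` drives the whole analysis; every stage's outputs
are written as TSV/JSON under one directory together with a
``run_manifest.json`` that echoes the configuration and the per-stage
attrition counts, so results are self-describing.  The pipeline itself is
deterministic: rerunning with the same config on the same inputs reproduces
every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classify import ClassifiedLncRNASet, SUBTYPES, classify_all
from .compare import build_feature_table, compare_all
from .genome_io import (
    ConfigurationError,
    read_expression_table,
    read_fasta,
    read_gtf,
    read_repeatmasker_out,
)
from .identify import FilterReport, read_call_table, run_identification
from .targets import (
    cis_targets,
    cis_trans_intersection,
    differential_expression,
    ease_enrichment,
    pairs_within,
    read_term_map,
    trans_targets,
)
from .telandscape import (
    te_composition_fisher,
    te_density,
    te_density_table,
    tss_profile,
    tss_profile_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    candidates_gtf: str
    reference_gtf: str
    expression_tsv: str
    groups_tsv: str
    fasta: str
    outdir: str
    repeats: str | None = None
    repeats_bed: bool = False
    call_tables: tuple[str, ...] = ()
    conservation_tsv: str | None = None
    term_map_tsv: str | None = None
    min_length: int = 200
    min_exons: int = 2
    orf_threshold: int = 300
    windows: tuple[int, ...] = (10_000, 100_000)
    r_threshold: float = 0.95
    alpha: float = 0.05
    tss_window: int = 2_000

    def __post_init__(self) -> None:
        positive = {
            "min_length": self.min_length,
            "min_exons": self.min_exons,
            "orf_threshold": self.orf_threshold,
            "alpha": self.alpha,
            "tss_window": self.tss_window,
            "r_threshold": self.r_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if any(w <= 0 for w in self.windows):
            raise ConfigurationError("windows must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from JSON or a flat key=value file."""
        text = Path(path).read_text()
        if text.lstrip().startswith("{"):
            data = json.loads(text)
        else:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
            for key in ("min_length", "min_exons", "orf_threshold", "tss_window"):
                if key in data:
                    data[key] = int(data[key])
            for key in ("r_threshold", "alpha"):
                if key in data:
                    data[key] = float(data[key])
            if "windows" in data and isinstance(data["windows"], str):
                data["windows"] = tuple(
                    int(w) for w in data["windows"].split(",") if w
                )
            if "call_tables" in data and isinstance(data["call_tables"], str):
                data["call_tables"] = tuple(
                    p for p in data["call_tables"].split(",") if p
                )
        if "windows" in data:
            data["windows"] = tuple(data["windows"])
        if "call_tables" in data:
            data["call_tables"] = tuple(data["call_tables"])
        return cls(**data)


def read_group_map(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ConfigurationError(f"group map row needs 2 columns: {line!r}")
            groups[cols[0]] = cols[1]
    return groups


def read_conservation(path: str | Path) -> dict[str, float]:
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            scores[cols[0]] = float(cols[1])
    return scores


@dataclass
class PipelineResult:
    lncRNAs: ClassifiedLncRNASet
    report: FilterReport
    feature_table: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs[name] = path

    # ---- inputs ----
    candidates = read_gtf(config.candidates_gtf)
    reference = read_gtf(config.reference_gtf)
    groups = read_group_map(config.groups_tsv)
    expression = read_expression_table(config.expression_tsv, groups)
    sequences = read_fasta(config.fasta)
    tes = (
        read_repeatmasker_out(config.repeats, bed=config.repeats_bed)
        if config.repeats
        else []
    )
    call_tables = [read_call_table(p) for p in config.call_tables]
    conservation = (
        read_conservation(config.conservation_tsv) if config.conservation_tsv else None
    )

    # ---- identify ----
    survivors, report = run_identification(
        candidates,
        reference,
        sequences=sequences,
        call_tables=call_tables,
        min_length=config.min_length,
        min_exons=config.min_exons,
        builtin_threshold=config.orf_threshold,
    )
    emit("identify_report.tsv", pd.DataFrame(report.to_rows()))
    emit(
        "removal_reasons.tsv",
        pd.DataFrame(
            sorted(report.removed.items()), columns=["transcript_id", "reason"]
        ),
    )

    # ---- classify ----
    coding = reference.biotype_subset(["protein_coding"])
    classified = classify_all(survivors, coding)
    if not classified.calls:
        logger.warning("no lncRNAs survive identification; downstream tables empty")
    from .genome_io import write_gtf

    write_gtf(
        classified.annotation,
        outdir / "lncRNAs.gtf",
        extra_attributes={
            tid: {"subtype": call.subtype} for tid, call in classified.calls.items()
        },
    )
    outputs["lncRNAs.gtf"] = outdir / "lncRNAs.gtf"
    emit("subtype_counts.tsv", classified.counts)

    # ---- compare ----
    classes = {s: classified.transcripts_of(s) for s in SUBTYPES}
    classes["mRNA"] = list(coding)
    classes = {k: v for k, v in classes.items() if v}
    feature_table = (
        build_feature_table(classes, expression, sequences, conservation)
        if classes
        else pd.DataFrame()
    )
    emit("feature_table.tsv", feature_table)
    if not feature_table.empty and feature_table["class"].nunique() >= 2:
        emit(
            "comparisons.tsv",
            compare_all(
                feature_table,
                features=("length", "exon_count", "orf_length", "log_expression"),
            ),
        )

    # ---- TE landscape ----
    if tes and classes:
        lnc_classes = {s: classes[s] for s in SUBTYPES if s in classes}
        emit("te_density.tsv", te_density_table(classes, tes))
        fisher_rows = []
        labels = sorted(lnc_classes)
        density_rows = {
            label: {
                r.te_family: r
                for r in te_density(label, lnc_classes[label], tes)
            }
            for label in labels
        }
        families = sorted({te.te_family for te in tes})
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                for family in families:
                    res = te_composition_fisher(
                        density_rows[a][family], density_rows[b][family]
                    )
                    fisher_rows.append(
                        {
                            "class_a": a,
                            "class_b": b,
                            "family": family,
                            "odds_ratio": res.odds_ratio,
                            "p": res.pvalue,
                        }
                    )
        emit("te_fisher.tsv", pd.DataFrame(fisher_rows))
        profile_frames = [
            tss_profile_table(
                tss_profile(label, lnc_classes[label], tes, family, config.tss_window)
            )
            for label in labels
            for family in families
        ]
        if profile_frames:
            emit("tss_profiles.tsv", pd.concat(profile_frames, ignore_index=True))

    # ---- targets ----
    lnc_transcripts = list(classified.annotation)
    cis = cis_targets(lnc_transcripts, coding, config.windows) if lnc_transcripts else []
    emit(
        "cis_pairs.tsv",
        pd.DataFrame(
            [dataclasses.asdict(p) for p in cis],
            columns=["lnc_id", "gene_id", "distance", "tier"],
        ),
    )
    gene_ids = [g for g in sorted(coding.gene_ids) if g in expression]
    lnc_ids = [t.transcript_id for t in lnc_transcripts if t.transcript_id in expression]
    trans = (
        trans_targets(expression, lnc_ids, gene_ids, config.r_threshold)
        if lnc_ids and gene_ids
        else []
    )
    emit(
        "trans_pairs.tsv",
        pd.DataFrame(
            [{"lnc_id": p.lnc_id, "gene_id": p.gene_id, "r": p.r, "sign": p.sign} for p in trans],
            columns=["lnc_id", "gene_id", "r", "sign"],
        ),
    )
    both = cis_trans_intersection(cis, trans)
    emit(
        "cis_trans_pairs.tsv",
        pd.DataFrame(
            [dataclasses.asdict(p) for p in both],
            columns=["lnc_id", "gene_id", "distance", "tier", "r"],
        ),
    )
    de = differential_expression(expression, config.alpha)
    emit("de.tsv", de)
    if config.term_map_tsv:
        term_map = read_term_map(config.term_map_tsv)
        target_genes = sorted({p.gene_id for p in both}) or sorted(
            {p.gene_id for p in pairs_within(cis, min(config.windows))}
        )
        background = gene_ids
        if target_genes and background:
            emit(
                "enrichment.tsv",
                ease_enrichment(target_genes, term_map, background),
            )

    # ---- run manifest ----
    manifest = {
        "tool": "caprilnc",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": report.to_rows(),
        "n_candidates": len(candidates),
        "n_lncRNAs": len(classified.annotation),
        "subtype_counts": {
            s: len(classified.ids_of(s)) for s in SUBTYPES
        },
        "n_ambiguous": len(classified.ambiguous),
        "n_cis_pairs": len(cis),
        "n_trans_pairs": len(trans),
        "n_cis_trans_pairs": len(both),
        "n_de_significant": int(de["significant"].sum()),
    }
    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    outputs["run_manifest.json"] = manifest_path

    return PipelineResult(classified, report, feature_table, outputs)
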