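"""Screening cascade that reduces assembled transcripts to candidate lncRNAs.

The cascade applies, in order: a structural filter (spliced length >= 200 nt
and >= 2 exons — single-exon models are treated as assembly background), a
known-class filter (exonic overlap with annotated mRNA / small-RNA /
pseudogene transcripts), and a coding-potential consensus filter.  External
coding-potential callers (CNCI, CPC, Pfam-scan, PhyloCSF and the like) are
not run here; their per-transcript verdict tables are inputs.  A transcript
survives the consensus only if *every* supplied table calls it noncoding.
When no tables are supplied, a built-in longest-ORF heuristic (noncoding iff
longest ORF < 300 nt, the conventional 100-codon rule) acts as the single
caller.

Every filter returns a :class:`FilterReport` so per-step attrition is
auditable and reconcilable (n_in = n_removed + n_out at every step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import (
    AnnotationSet,
    ConfigurationError,
    ParseError,
    TranscriptModel,
    ValidationError,
)

#: Reference biotypes screened out by the known-class filter.
DEFAULT_EXCLUDED_BIOTYPES = (
    "protein_coding",
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "pre_miRNA",
    "pseudogene",
)

#: Built-in ORF-length threshold (nt) below which a transcript is called
#: noncoding: 300 nt = 100 codons, the standard lncRNA convention.
DEFAULT_ORF_THRESHOLD = 300

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_in: int
    n_removed: int
    n_out: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_removed + self.n_out:
            raise ValidationError(
                f"step {self.name!r} does not reconcile: "
                f"{self.n_in} != {self.n_removed} + {self.n_out}"
            )


@dataclass
class FilterReport:
    """Ordered per-step attrition log plus per-transcript removal reasons."""

    steps: list[FilterStep] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)

    def append(self, step: FilterStep, removed: Mapping[str, str]) -> None:
        if self.steps and self.steps[-1].n_out != step.n_in:
            raise ValidationError(
                f"step {step.name!r} n_in={step.n_in} does not chain from "
                f"previous n_out={self.steps[-1].n_out}"
            )
        self.steps.append(step)
        for tid, reason in removed.items():
            if tid in self.removed:
                raise ValidationError(f"{tid} removed twice")
            self.removed[tid] = reason

    @property
    def n_initial(self) -> int:
        return self.steps[0].n_in if self.steps else 0

    @property
    def n_final(self) -> int:
        return self.steps[-1].n_out if self.steps else 0

    def reconciles(self) -> bool:
        """Initial count = total removed + final count, and steps chain."""
        if not self.steps:
            return True
        chained = all(
            a.n_out == b.n_in for a, b in zip(self.steps, self.steps[1:])
        )
        total_removed = sum(s.n_removed for s in self.steps)
        return chained and self.n_initial == total_removed + self.n_final

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": s.name,
                "n_in": s.n_in,
                "n_removed": s.n_removed,
                "n_out": s.n_out,
            }
            for s in self.steps
        ]


@dataclass(frozen=True)
class CodingCallTable:
    """Per-transcript coding/noncoding verdicts from one external tool."""

    tool: str
    verdicts: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.verdicts.values()} - {"coding", "noncoding"}
        if bad:
            raise ValidationError(f"{self.tool}: unknown verdicts {sorted(bad)}")

    @classmethod
    def from_scores(
        cls,
        tool: str,
        scores: Mapping[str, float],
        threshold: float,
        coding_if: str = "greater",
    ) -> "CodingCallTable":
        """Derive verdicts from a score table: coding iff score is beyond
        ``threshold`` in the ``coding_if`` direction ("greater" or "less")."""
        if coding_if not in ("greater", "less"):
            raise ConfigurationError("coding_if must be 'greater' or 'less'")
        if coding_if == "greater":
            verdicts = {
                tid: "coding" if s > threshold else "noncoding"
                for tid, s in scores.items()
            }
        else:
            verdicts = {
                tid: "coding" if s < threshold else "noncoding"
                for tid, s in scores.items()
            }
        return cls(tool, verdicts)


def read_call_table(
    path: str | Path,
    tool: str | None = None,
    threshold: float | None = None,
    coding_if: str = "greater",
) -> CodingCallTable:
    """Read a two-column TSV (transcript_id, verdict-or-score).

    Text verdicts must be ``coding``/``noncoding``; numeric second columns
    require ``threshold`` to derive verdicts.
    """
    path = Path(path)
    name = tool or path.stem
    entries: dict[str, str] = {}
    scores: dict[str, float] = {}
    numeric: bool | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path.name}:{lineno}: need 2 columns")
            tid, value = cols[0], cols[1]
            if lineno == 1 and value.lower() in ("verdict", "score"):
                continue  # header
            try:
                scores[tid] = float(value)
                is_num = True
            except ValueError:
                entries[tid] = value.lower()
                is_num = False
            if numeric is None:
                numeric = is_num
            elif numeric != is_num:
                raise ParseError(f"{path.name}:{lineno}: mixed verdicts and scores")
    if numeric:
        if threshold is None:
            raise ConfigurationError(
                f"{path.name}: numeric call table requires a threshold"
            )
        return CodingCallTable.from_scores(name, scores, threshold, coding_if)
    return CodingCallTable(name, entries)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_structural(
    candidates: AnnotationSet, min_length: int = 200, min_exons: int = 2
) -> tuple[AnnotationSet, FilterReport]:
    """Keep transcripts with >= ``min_exons`` exons and spliced length >=
    ``min_length`` nt (both boundaries inclusive).  The two predicates are
    reported as separate sub-steps (exon count first)."""
    report = FilterReport()

    survivors = []
    removed_exons: dict[str, str] = {}
    for t in candidates:
        if t.n_exons >= min_exons:
            survivors.append(t)
        else:
            removed_exons[t.transcript_id] = "exon_count"
    report.append(
        FilterStep(
            "exon_count",
            len(candidates),
            len(removed_exons),
            len(survivors),
            {"min_exons": min_exons},
        ),
        removed_exons,
    )

    survivors2 = []
    removed_len: dict[str, str] = {}
    for t in survivors:
        if t.length >= min_length:
            survivors2.append(t)
        else:
            removed_len[t.transcript_id] = "length"
    report.append(
        FilterStep(
            "length",
            len(survivors),
            len(removed_len),
            len(survivors2),
            {"min_length": min_length},
        ),
        removed_len,
    )
    return AnnotationSet(survivors2), report


def _exonic_overlap(t: TranscriptModel, other: TranscriptModel) -> bool:
    for e in t.exons:
        for f in other.exons:
            if e.overlaps(f):
                return True
    return False


def filter_known_classes(
    candidates: AnnotationSet,
    reference: AnnotationSet,
    excluded_biotypes: Sequence[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> tuple[AnnotationSet, FilterReport]:
    """Remove candidates with exonic overlap of annotated known-class transcripts.

    Overlap is exon-against-exon (>= 1 bp), never span-level, so intronic
    candidates inside coding genes survive.  For ``protein_coding`` the
    overlap must be on the *same* strand — antisense exonic overlap survives
    to be classified later.  For the small-RNA and pseudogene classes either
    strand removes.
    """
    excluded = set(excluded_biotypes)
    survivors = []
    removed: dict[str, str] = {}
    for t in candidates:
        if t.strand == ".":
            raise ValidationError(
                f"{t.transcript_id}: unstranded candidate cannot be screened"
            )
        reason = None
        for exon in t.exons:
            for ref in reference.overlapping(exon):
                if ref.biotype not in excluded:
                    continue
                if ref.biotype == "protein_coding" and ref.strand != t.strand:
                    continue
                if _exonic_overlap(t, ref):
                    reason = f"known_class:{ref.biotype}"
                    break
            if reason:
                break
        if reason:
            removed[t.transcript_id] = reason
        else:
            survivors.append(t)
    report = FilterReport()
    report.append(
        FilterStep(
            "known_class",
            len(candidates),
            len(removed),
            len(survivors),
            {"excluded_biotypes": sorted(excluded)},
        ),
        removed,
    )
    return AnnotationSet(survivors), report


def longest_orf(sequence: str) -> int:
    """Length in nt (including the stop codon) of the longest complete
    ATG -> stop open reading frame across the three forward frames; 0 if none.

    Codons containing ``N`` are neither starts nor stops.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValidationError(f"invalid characters in sequence: {sorted(invalid)}")
    best = 0
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    best = max(best, i + 3 - open_start)
                    open_start = None
            elif codon == START_CODON and open_start is None:
                open_start = i
    return best


def consensus_noncoding(
    candidates: AnnotationSet,
    call_tables: Sequence[CodingCallTable] = (),
    sequences: Mapping[str, str] | None = None,
    builtin_threshold: int = DEFAULT_ORF_THRESHOLD,
    missing_policy: str = "remove",
) -> tuple[AnnotationSet, FilterReport]:
    """Keep only transcripts called noncoding by *every* supplied call table.

    A transcript flagged coding by any tool is removed; a transcript absent
    from a table is removed as ``unscored`` (conservative default) or raises,
    per ``missing_policy`` ("remove" | "error").  With zero tables the
    built-in heuristic (longest ORF < ``builtin_threshold``) acts as the
    single table and requires ``sequences``.
    """
    if missing_policy not in ("remove", "error"):
        raise ConfigurationError("missing_policy must be 'remove' or 'error'")
    tables = list(call_tables)
    if not tables:
        if sequences is None:
            raise ConfigurationError(
                "no call tables supplied: built-in ORF heuristic needs sequences"
            )
        missing = [t.transcript_id for t in candidates if t.transcript_id not in sequences]
        if missing:
            raise ConfigurationError(f"sequences missing for: {missing[:5]}")
        verdicts = {
            t.transcript_id: (
                "noncoding"
                if longest_orf(sequences[t.transcript_id]) < builtin_threshold
                else "coding"
            )
            for t in candidates
        }
        tables = [CodingCallTable("builtin_orf", verdicts)]

    survivors = []
    removed: dict[str, str] = {}
    per_tool_removed = {tbl.tool: 0 for tbl in tables}
    for t in candidates:
        reason = None
        for tbl in tables:
            verdict = tbl.verdicts.get(t.transcript_id)
            if verdict is None:
                if missing_policy == "error":
                    raise ConfigurationError(
                        f"{t.transcript_id} absent from call table {tbl.tool!r}"
                    )
                reason = reason or f"coding_potential:unscored[{tbl.tool}]"
            elif verdict == "coding":
                per_tool_removed[tbl.tool] += 1
                reason = reason or f"coding_potential:{tbl.tool}"
        if reason:
            removed[t.transcript_id] = reason
        else:
            survivors.append(t)
    report = FilterReport()
    report.append(
        FilterStep(
            "coding_potential",
            len(candidates),
            len(removed),
            len(survivors),
            {
                "tools": [tbl.tool for tbl in tables],
                "per_tool_removed": per_tool_removed,
                "intersection_size": len(survivors),
            },
        ),
        removed,
    )
    return AnnotationSet(survivors), report


def run_identification(
    candidates: AnnotationSet,
    reference: AnnotationSet,
    sequences: Mapping[str, str] | None = None,
    call_tables: Sequence[CodingCallTable] = (),
    min_length: int = 200,
    min_exons: int = 2,
    excluded_biotypes: Sequence[str] = DEFAULT_EXCLUDED_BIOTYPES,
    builtin_threshold: int = DEFAULT_ORF_THRESHOLD,
    min_fpkm: float | None = None,
    expression=None,
) -> tuple[AnnotationSet, FilterReport]:
    """Full cascade: structural -> known-class -> coding-potential consensus.

    ``min_fpkm`` is an optional expression floor (mean FPKM across samples);
    it is off by default — no expression filter is part of the standard
    cascade.
    """
    report = FilterReport()
    survivors, rep = filter_structural(candidates, min_length, min_exons)
    for step in rep.steps:
        report.append(step, {k: v for k, v in rep.removed.items() if v == step.name})
    survivors, rep = filter_known_classes(survivors, reference, excluded_biotypes)
    report.append(rep.steps[0], rep.removed)
    survivors, rep = consensus_noncoding(
        survivors, call_tables, sequences, builtin_threshold
    )
    report.append(rep.steps[0], rep.removed)
    if min_fpkm is not None:
        if expression is None:
            raise ConfigurationError("min_fpkm filter requires an expression matrix")
        keep, removed = [], {}
        means = expression.mean_fpkm()
        for t in survivors:
            if t.transcript_id in expression and means[t.transcript_id] >= min_fpkm:
                keep.append(t)
            else:
                removed[t.transcript_id] = "min_fpkm"
        report.append(
            FilterStep("min_fpkm", len(survivors), len(removed), len(keep)),
            removed,
        )
        survivors = AnnotationSet(keep)
    return survivors, report
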