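"""Positional classification of lncRNAs relative to protein-coding annotation.

Each surviving lncRNA is assigned exactly one of three subtypes:

* **antisense** — >= 1 bp exon-against-exon overlap with a coding transcript
  on the opposite strand;
* **intronic** — the transcript's span lies entirely within a single intron
  of some coding transcript (either strand), with zero exonic overlap;
* **lincRNA** — the span overlaps no coding-transcript span at all.

Precedence is antisense > intronic > lincRNA: exonic overlap is the stronger
positional signal, and the classes must be mutually exclusive.  A transcript
whose span overlaps a coding span without satisfying any of the three
geometries (e.g. straddling a gene end) is reported as ``ambiguous`` and
excluded from the classified set with a warning.  Same-strand exonic overlap
with a coding transcript is an error here — such transcripts should have
been removed by the identification cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .genome_io import (
    AnnotationSet,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

SUBTYPES = ("lincRNA", "antisense", "intronic")


class ClassificationError(ValueError):
    """Geometry inconsistent with an upstream-filtered candidate set."""


@dataclass(frozen=True)
class SubtypeCall:
    transcript_id: str
    subtype: str  # lincRNA | antisense | intronic | ambiguous
    evidence_gene: str = ""  # coding gene triggering the call; empty for lincRNA
    detail: str = ""

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES + ("ambiguous",):
            raise ValidationError(f"unknown subtype {self.subtype!r}")


@dataclass
class ClassifiedLncRNASet:
    """Classified lncRNAs: the annotation subset plus one call per transcript."""

    annotation: AnnotationSet
    calls: dict[str, SubtypeCall]
    ambiguous: dict[str, SubtypeCall] = field(default_factory=dict)

    def ids_of(self, subtype: str) -> list[str]:
        return [tid for tid, c in self.calls.items() if c.subtype == subtype]

    def transcripts_of(self, subtype: str) -> list[TranscriptModel]:
        return [self.annotation[tid] for tid in self.ids_of(subtype)]

    @property
    def counts(self) -> pd.DataFrame:
        rows = [
            {"subtype": s, "count": len(self.ids_of(s))} for s in SUBTYPES
        ]
        rows.append({"subtype": "ambiguous", "count": len(self.ambiguous)})
        return pd.DataFrame(rows)


def _exon_exon_overlap(
    t: TranscriptModel, other: TranscriptModel
) -> bool:
    for e in t.exons:
        for f in other.exons:
            if e.overlaps(f):
                return True
    return False


def classify_subtype(t: TranscriptModel, coding: AnnotationSet) -> SubtypeCall:
    """Classify one transcript against a protein-coding annotation set."""
    if t.strand == ".":
        raise ValidationError(f"{t.transcript_id}: unstranded transcript")
    for ref in coding:
        if ref.biotype != "protein_coding":
            raise ValidationError(
                f"coding set contains non-coding biotype {ref.biotype!r} "
                f"({ref.transcript_id})"
            )

    span = t.span
    hits = coding.overlapping(span)

    # antisense: exon-exon overlap, opposite strand (checked before intronic)
    for ref in hits:
        if ref.strand != t.strand and _exon_exon_overlap(t, ref):
            return SubtypeCall(
                t.transcript_id, "antisense", ref.gene_id,
                f"exonic overlap with {ref.transcript_id} on opposite strand",
            )

    # same-strand exonic overlap should never reach classification
    for ref in hits:
        if ref.strand == t.strand and _exon_exon_overlap(t, ref):
            raise ClassificationError(
                f"{t.transcript_id}: same-strand exonic overlap with coding "
                f"{ref.transcript_id}; should have been removed upstream"
            )

    # intronic: span inside a single intron of some coding transcript
    for ref in hits:
        for intron in ref.introns:
            if intron.contains(span):
                return SubtypeCall(
                    t.transcript_id, "intronic", ref.gene_id,
                    f"contained in intron [{intron.start},{intron.end}) "
                    f"of {ref.transcript_id}",
                )

    # lincRNA: span-disjoint from every coding span
    if not hits:
        return SubtypeCall(t.transcript_id, "lincRNA", "", "no coding span overlap")

    # span overlap without any of the above geometries
    return SubtypeCall(
        t.transcript_id, "ambiguous", hits[0].gene_id,
        f"span overlaps {hits[0].transcript_id} without exonic overlap or "
        "intron containment",
    )


def classify_all(
    lncRNAs: AnnotationSet | Iterable[TranscriptModel], coding: AnnotationSet
) -> ClassifiedLncRNASet:
    """Classify every transcript; returns the set plus a subtype count table.

    Raises on duplicated transcript ids.  Ambiguous transcripts are excluded
    from the classified annotation and collected separately with a warning.
    """
    if not isinstance(lncRNAs, AnnotationSet):
        lncRNAs = AnnotationSet(lncRNAs)  # raises on duplicate ids
    calls: dict[str, SubtypeCall] = {}
    ambiguous: dict[str, SubtypeCall] = {}
    kept = []
    for t in lncRNAs:
        call = classify_subtype(t, coding)
        if call.subtype == "ambiguous":
            logger.warning(
                "%s excluded as ambiguous: %s", t.transcript_id, call.detail
            )
            ambiguous[t.transcript_id] = call
        else:
            calls[t.transcript_id] = call
            kept.append(t)
    return ClassifiedLncRNASet(AnnotationSet(kept), calls, ambiguous)
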