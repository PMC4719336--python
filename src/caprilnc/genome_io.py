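"""Coordinate model and readers/writers for the formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals.
GTF/GFF3 and RepeatMasker ``.out`` files use 1-based fully-closed coordinates;
the conversion happens in exactly one place (read/write), so every downstream
overlap computation is plain half-open arithmetic with no ``±1`` corrections.

The unit that flows through every analysis stage is the
:class:`TranscriptModel`: an exon-resolved, stranded transcript.  Collections
of transcripts are held in an :class:`AnnotationSet`, which maintains a
per-chromosome interval index for overlap queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: Biotypes a transcript may carry.  Assembled transcripts of unknown class
#: enter the pipeline as "candidate"; the reference annotation supplies the
#: known classes that the identification cascade screens against.
KNOWN_BIOTYPES = (
    "protein_coding",
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "pre_miRNA",
    "pseudogene",
    "candidate",
)


class ValidationError(ValueError):
    """An object violates a structural invariant (coordinates, strands, shapes)."""


class ParseError(ValueError):
    """A file does not conform to its declared format; the message names the line."""


class ConfigurationError(ValueError):
    """User-supplied configuration is inconsistent with the data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/scaffold) name; non-empty.
    start, end : int
        0-based half-open span; ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap between the two intervals; 0 when they overlap.

        Raises if the intervals are on different chromosomes, where distance
        is undefined.
        """
        if self.chrom != other.chrom:
            raise ValidationError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-resolved transcript on a single chromosome and strand.

    ``exons`` are normalized to coordinate-sorted order at construction and
    must be non-overlapping (abutting exons are permitted).  ``length`` is the
    spliced length (sum of exon lengths); ``span`` the unspliced genomic locus.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.transcript_id or not self.gene_id:
            raise ValidationError("transcript_id and gene_id must be non-empty")
        if len(self.exons) == 0:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValidationError(
                f"{self.transcript_id}: exons must share one chromosome and strand"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:  # abutting exons leave no intron
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def tss(self) -> int:
        """Genomic position of the 5' end: span start on "+", span end - 1 on "-"."""
        if self.strand == ".":
            raise ValidationError(f"{self.transcript_id}: TSS undefined without strand")
        return self.span.start if self.strand == "+" else self.span.end - 1


class AnnotationSet:
    """Indexed collection of transcript models.

    Transcripts are keyed by ``transcript_id`` and grouped by ``gene_id``.
    A per-chromosome interval tree over transcript spans backs
    :meth:`overlapping`; results are returned in deterministic
    (start, transcript_id) order.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        self._genes: dict[str, list[str]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self._genes.setdefault(t.gene_id, []).append(t.transcript_id)
        span = t.span
        self._trees.setdefault(t.chrom, IntervalTree()).addi(
            span.start, span.end, t.transcript_id
        )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._transcripts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [self._transcripts[tid] for tid in self._genes.get(gene_id, [])]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Union span of all transcripts of a gene (single chrom/strand assumed)."""
        ts = self.transcripts_of_gene(gene_id)
        if not ts:
            raise KeyError(gene_id)
        chroms = {t.chrom for t in ts}
        if len(chroms) != 1:
            raise ValidationError(f"gene {gene_id!r} spans multiple chromosomes")
        return GenomicInterval(
            ts[0].chrom,
            min(t.span.start for t in ts),
            max(t.span.end for t in ts),
            ts[0].strand,
        )

    # -- queries ------------------------------------------------------------

    def overlapping(
        self, interval: GenomicInterval, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps ``interval`` by >= 1 bp.

        ``strand``: ``None`` (ignore), ``"same"`` or ``"opposite"`` relative to
        the query interval's strand.
        """
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [self._transcripts[iv.data] for iv in tree.overlap(interval.start, interval.end)]
        if strand == "same":
            hits = [t for t in hits if t.strand == interval.strand]
        elif strand == "opposite":
            want = {"+": "-", "-": "+"}.get(interval.strand)
            hits = [t for t in hits if t.strand == want]
        elif strand is not None:
            raise ConfigurationError(f"strand must be None/'same'/'opposite', got {strand!r}")
        return sorted(hits, key=lambda t: (t.span.start, t.transcript_id))

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self._transcripts[tid] for tid in transcript_ids)

    def biotype_subset(self, biotypes: Iterable[str]) -> "AnnotationSet":
        wanted = set(biotypes)
        return AnnotationSet(t for t in self if t.biotype in wanted)


@dataclass(frozen=True)
class TEElement:
    """A transposable-element annotation: genomic span plus class/family labels."""

    interval: GenomicInterval
    te_class: str
    te_family: str

    def __post_init__(self) -> None:
        if not self.te_class or not self.te_family:
            raise ValidationError("TE class and family must be non-empty")


class ExpressionMatrix:
    """FPKM values, transcripts/genes x samples, with a group label per sample.

    Backed by a pandas DataFrame (rows = feature ids, columns = sample ids).
    Values must be rectangular, complete and non-negative.
    """

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str]) -> None:
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValidationError("expression matrix ids and samples must be unique")
        if values.isna().any().any():
            raise ValidationError("expression matrix contains missing cells")
        arr = values.to_numpy(dtype=float)
        if (arr < 0).any():
            bad = values.index[(arr < 0).any(axis=1)][:5].tolist()
            raise ValidationError(f"negative FPKM values (e.g. rows {bad})")
        missing = [s for s in values.columns if s not in groups]
        if missing:
            raise ConfigurationError(f"samples missing from group map: {missing}")
        self._values = values.astype(float)
        self._groups = {s: groups[s] for s in values.columns}

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def samples(self) -> list[str]:
        return list(self._values.columns)

    @property
    def groups(self) -> dict[str, str]:
        return dict(self._groups)

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self._groups.values()))

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self._groups[s] == group]

    def row(self, feature_id: str) -> np.ndarray:
        return self._values.loc[feature_id].to_numpy(dtype=float)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._values.index

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self._values.loc[list(feature_ids)], self._groups)

    def mean_fpkm(self) -> pd.Series:
        return self._values.mean(axis=1)


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_attributes(text: str, gff3: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if gff3:
        for part in text.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise ValueError(f"malformed GFF3 attribute {part!r}")
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    else:
        for key, value in _GTF_ATTR.findall(text):
            attrs[key] = value
    return attrs


def read_gtf(path: str | Path, *, gff3: bool = False) -> AnnotationSet:
    """Read transcript models from a GTF (default) or GFF3 (``gff3=True``) file.

    Transcripts are assembled solely from ``exon`` feature lines; each exon
    line must carry ``transcript_id``/``gene_id`` attributes (GFF3: ``Parent``
    is accepted for the transcript id).  File coordinates (1-based inclusive)
    are converted to internal 0-based half-open.  Biotype is taken from a
    ``biotype``/``transcript_biotype``/``gene_biotype`` attribute when present,
    else ``"candidate"``.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ValidationError(f"{path.name}:{lineno}: exon end < start")
            if strand not in STRANDS:
                raise ValidationError(
                    f"{path.name}:{lineno}: unknown strand symbol {strand!r}"
                )
            try:
                attrs = _parse_attributes(attr_s, gff3)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            if not tid:
                raise ParseError(f"{path.name}:{lineno}: exon without transcript_id")
            gid = attrs.get("gene_id") or tid
            biotype = (
                attrs.get("biotype")
                or attrs.get("transcript_biotype")
                or attrs.get("gene_biotype")
                or "candidate"
            )
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = (gid, biotype)
            exons[tid].append(GenomicInterval(chrom, start - 1, end, strand))
    return AnnotationSet(
        TranscriptModel(tid, meta[tid][0], tuple(exons[tid]), meta[tid][1])
        for tid in order
    )


def write_gtf(
    annotation: AnnotationSet,
    path: str | Path,
    *,
    source: str = "caprilnc",
    extra_attributes: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write exon lines for every transcript, 1-based inclusive coordinates.

    ``extra_attributes`` maps transcript_id to additional ``key "value";``
    attributes (e.g. a ``subtype`` tag) appended to each of its exon lines.
    """
    extra_attributes = extra_attributes or {}
    transcripts = sorted(
        annotation, key=lambda t: (t.chrom, t.span.start, t.transcript_id)
    )
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'biotype "{t.biotype}";'
            )
            for key, value in extra_attributes.get(t.transcript_id, {}).items():
                attrs += f' {key} "{value}";'
            for exon in t.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out / BED
# ---------------------------------------------------------------------------


def _split_class_family(label: str) -> tuple[str, str]:
    # "LINE/L1" -> ("LINE", "L1"); a label without "/" is its own family.
    if "/" in label:
        te_class, te_family = label.split("/", 1)
    else:
        te_class = te_family = label
    return te_class, te_family


def read_repeatmasker_out(path: str | Path, *, bed: bool = False) -> list[TEElement]:
    """Read repeat elements from RepeatMasker ``.out`` (default) or BED (flagged).

    RepeatMasker layout: three header lines, whitespace-separated columns with
    query sequence/begin/end at columns 5-7 (1-based inclusive), strand at
    column 9 (``C`` = minus), and ``class/family`` at column 11.  The BED
    dialect is BED4+ with ``name`` = ``class/family`` and 0-based coordinates.
    """
    path = Path(path)
    elements: list[TEElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split() if not bed else raw.rstrip("\n").split("\t")
            if bed:
                if len(cols) < 4:
                    raise ParseError(f"{path.name}:{lineno}: BED4 needs >= 4 columns")
                chrom, start_s, end_s, name = cols[:4]
                strand = cols[5] if len(cols) >= 6 else "."
                start, end = int(start_s), int(end_s)
                if end < start:
                    raise ValidationError(f"{path.name}:{lineno}: end < start")
                te_class, te_family = _split_class_family(name)
                elements.append(
                    TEElement(
                        GenomicInterval(chrom, start, end, strand), te_class, te_family
                    )
                )
                continue
            # RepeatMasker: skip header lines (first token not an integer score)
            try:
                int(cols[0])
            except ValueError:
                continue
            if len(cols) < 11:
                raise ParseError(
                    f"{path.name}:{lineno}: RepeatMasker row with "
                    f"{len(cols)} columns lacks the class/family field"
                )
            chrom = cols[4]
            begin, end = int(cols[5]), int(cols[6])
            if begin > end:
                raise ValidationError(f"{path.name}:{lineno}: begin > end")
            strand = "-" if cols[8] == "C" else cols[8]
            if strand not in STRANDS:
                raise ValidationError(f"{path.name}:{lineno}: bad strand {cols[8]!r}")
            te_class, te_family = _split_class_family(cols[10])
            elements.append(
                TEElement(
                    GenomicInterval(chrom, begin - 1, end, strand), te_class, te_family
                )
            )
    return elements


def write_repeatmasker_out(elements: Iterable[TEElement], path: str | Path) -> None:
    """Write elements in a minimal RepeatMasker ``.out`` layout (3 header lines)."""
    header = (
        "   SW  perc perc perc  query    position in query    matching repeat\n"
        "score  div. del. ins.  sequence begin  end  (left)   repeat   class/family  begin end (left) ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, te in enumerate(elements, 1):
            iv = te.interval
            strand = "C" if iv.strand == "-" else "+"
            label = (
                te.te_class
                if te.te_class == te.te_family
                else f"{te.te_class}/{te.te_family}"
            )
            fh.write(
                f"1000 0.0 0.0 0.0 {iv.chrom} {iv.start + 1} {iv.end} "
                f"(0) {strand} {te.te_family} {label} 1 {iv.length} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Expression tables and FASTA
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a TSV of FPKM values (first column = feature ids, header = samples)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path.name}: empty expression table")
    header = lines[0].split("\t")
    samples = header[1:]
    n = len(samples)
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], 2):
        cols = line.split("\t")
        if len(cols) != n + 1:
            raise ParseError(
                f"{path.name}:{lineno}: ragged row ({len(cols)} fields, expected {n + 1})"
            )
        ids.append(cols[0])
        try:
            rows.append([float(v) for v in cols[1:]])
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: non-numeric value") from exc
    frame = pd.DataFrame(rows, index=ids, columns=samples)
    return ExpressionMatrix(frame, group_map)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="id", float_format="%.6f")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences into a dict keyed by record id (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
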