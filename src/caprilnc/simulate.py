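"""Synthetic genome/annotation/expression bundles with planted ground truth.

The generator emulates the structure of a small two-phenotype RNA-seq study
(two groups x 3 biological replicates) on a toy genome: protein-coding genes
spaced along a few chromosomes, lncRNA candidates of the three positional
subtypes (intergenic, antisense, intronic), decoy transcripts engineered to
fail exactly one identification filter each, housekeeping-RNA reference
genes, a transposable-element landscape with an optional family-specific
coverage peak planted upstream of the TSSs of one subtype, and an FPKM
matrix with planted high-correlation lncRNA-mRNA pairs and planted group
differences.  Every planted fact is recorded in a machine-readable
:class:`TruthManifest`, so downstream stages have an exact recovery target.

Everything is driven by one ``numpy`` generator seeded from
``SimulationConfig.seed``; a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import (
    AnnotationSet,
    ConfigurationError,
    GenomicInterval,
    TEElement,
    TranscriptModel,
    write_expression_table,
    write_fasta,
    write_gtf,
    write_repeatmasker_out,
    ExpressionMatrix,
)
from .identify import longest_orf

import pandas as pd


class SimulationError(RuntimeError):
    """The generator could not satisfy a planted constraint."""


_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class TEFamilySpec:
    te_class: str
    te_family: str
    density: float  # target genome-coverage fraction
    min_length: int
    max_length: int


@dataclass(frozen=True)
class TssBiasSpec:
    """A planted family-specific coverage excess in a TSS-relative window.

    ``window`` is (lo, hi) in transcript-oriented offsets, hi exclusive
    (e.g. (-500, 0) = the 500 bp immediately upstream of the TSS).
    ``excess`` is the extra mean coverage fraction planted in that window:
    each target transcript receives one element of length
    ``excess * (hi - lo)`` placed uniformly inside the window.
    """

    te_family: str = "ERV1"
    subtype: str = "lincRNA"
    window: tuple[int, int] = (-500, 0)
    excess: float = 0.4


DEFAULT_TE_FAMILIES = (
    TEFamilySpec("LINE", "L1", 0.04, 300, 1200),
    TEFamilySpec("LINE", "RTE-BovB", 0.02, 300, 1000),
    TEFamilySpec("LTR", "ERV1", 0.01, 200, 600),
    TEFamilySpec("LTR", "ERVL", 0.01, 200, 600),
    TEFamilySpec("SINE", "Core-RTE", 0.02, 80, 300),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator.  ``seed`` is mandatory.

    Defaults describe the standard study bundle: 200 coding genes on two
    2-Mb chromosomes; 60 intergenic, 20 antisense and 12 intronic lncRNAs;
    40 decoys (10 single-exon, 10 sub-200-nt, 10 ORF-bearing, 10 overlapping
    housekeeping RNAs); 2 groups x 3 samples; 8 planted trans pairs of which
    5 are also cis-colocated; 10 planted differentially expressed lncRNAs.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_coding_genes: int = 200
    n_linc: int = 60
    n_antisense: int = 20
    n_intronic: int = 12
    n_decoy_monoexon: int = 10
    n_decoy_short: int = 10
    n_decoy_coding: int = 10
    n_housekeeping_decoys: int = 10
    te_families: tuple[TEFamilySpec, ...] = DEFAULT_TE_FAMILIES
    tss_bias: TssBiasSpec | None = TssBiasSpec()
    n_samples_per_group: int = 3
    n_planted_trans_pairs: int = 8
    n_planted_cis_trans: int = 5
    target_r: float = 0.97
    n_planted_de: int = 10
    de_log2_fc: float = 4.0
    de_noise_sd: float = 0.03  # per-sample log10 scatter of planted DE rows
    noise_sd: float = 0.25
    intergenic_gap: int = 2_000
    coding_orf_nt: int = 330  # planted ORF length for mRNAs and coding decoys

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms,
            self.n_coding_genes,
            self.n_linc,
            self.n_antisense,
            self.n_intronic,
            self.n_decoy_monoexon,
            self.n_decoy_short,
            self.n_decoy_coding,
            self.n_housekeeping_decoys,
            self.n_planted_trans_pairs,
            self.n_planted_de,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_planted_trans_pairs > self.n_linc * max(1, self.n_coding_genes):
            raise ConfigurationError("more planted pairs than (lncRNA, gene) slots")
        if self.n_planted_cis_trans > self.n_planted_trans_pairs:
            raise ConfigurationError("cis-trans planted pairs exceed trans pairs")
        if not 0 < self.target_r < 1:
            raise ConfigurationError("target_r must lie in (0, 1)")


@dataclass
class TruthManifest:
    """Machine-readable record of everything the generator planted."""

    subtypes: dict[str, str]  # true lncRNA id -> subtype
    filter_fate: dict[str, str]  # every candidate id -> pass | removing filter
    trans_pairs: list[dict]  # {lnc, gene, sign, cis, distance}
    de_ids: list[str]
    te_counts: dict[str, dict[str, int]]  # family -> {background, biased}
    te_genome_density: dict[str, float]  # merged coverage fraction per family
    tss_bias: dict | None
    expression_ids: list[str]
    genome: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    candidates: AnnotationSet  # assembled transcripts entering identification
    reference: AnnotationSet  # coding + housekeeping annotation with biotypes
    tes: list[TEElement]
    sequences: dict[str, str]  # candidate + mRNA transcript sequences
    expression: ExpressionMatrix
    manifest: TruthManifest

    @property
    def group_map(self) -> dict[str, str]:
        return self.expression.groups


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _noncoding_sequence(
    rng: np.random.Generator, length: int, max_orf: int = 300
) -> str:
    """Random sequence whose longest ORF is < ``max_orf`` nt (rejection-sampled)."""
    for _ in range(200):
        seq = _random_sequence(rng, length)
        if longest_orf(seq) < max_orf:
            return seq
    raise SimulationError(
        f"could not draw a noncoding sequence of length {length} "
        f"with max ORF < {max_orf}"
    )


def _coding_sequence(rng: np.random.Generator, length: int, orf_nt: int) -> str:
    """Random sequence with a planted complete ORF of >= ``orf_nt`` nt."""
    orf_nt = 3 * (orf_nt // 3)
    if length < orf_nt:
        raise SimulationError(f"sequence length {length} < planted ORF {orf_nt}")
    n_codons = orf_nt // 3 - 2
    codon_idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    orf = "ATG" + "".join(_NON_STOP_CODONS[i] for i in codon_idx) + "TAA"
    backbone = _random_sequence(rng, length)
    pos = int(rng.integers(0, length - orf_nt + 1))
    return backbone[:pos] + orf + backbone[pos + orf_nt :]


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------


class _FreeSpace:
    """Per-chromosome free intergenic intervals with carve-out bookkeeping."""

    def __init__(self) -> None:
        self.intervals: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        if end - start > 0:
            self.intervals.setdefault(chrom, []).append((start, end))

    def place(
        self, rng: np.random.Generator, span_len: int, margin: int
    ) -> tuple[str, int]:
        """Reserve ``span_len`` bases plus ``margin`` clearance on both sides.

        Returns (chrom, start).  Raises when no free interval fits.
        """
        need = span_len + 2 * margin
        candidates = [
            (chrom, i)
            for chrom, ivs in sorted(self.intervals.items())
            for i, (s, e) in enumerate(ivs)
            if e - s >= need
        ]
        if not candidates:
            raise ConfigurationError(
                f"no intergenic space for a {span_len}-bp feature; "
                "increase chrom_length or reduce feature counts"
            )
        chrom, idx = candidates[int(rng.integers(0, len(candidates)))]
        s, e = self.intervals[chrom][idx]
        start = int(rng.integers(s + margin, e - margin - span_len + 1))
        # split the free interval around the carved region
        del self.intervals[chrom][idx]
        self.add(chrom, s, start - margin)
        self.add(chrom, start + span_len + margin, e)
        return chrom, start


def _make_exons(
    chrom: str,
    strand: str,
    start: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lengths):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return tuple(exons)


def _span_length(exon_lengths: Sequence[int], intron_lengths: Sequence[int]) -> int:
    return int(sum(exon_lengths) + sum(intron_lengths))


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[AnnotationSet, AnnotationSet, list[TEElement], dict[str, str], TruthManifest]:
    """Build the genome annotation side of a bundle.

    Returns (candidates, reference, TE elements, transcript sequences,
    manifest).  The expression matrix is added by
    :func:`simulate_expression`; :func:`simulate_bundle` runs both.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    edge = 2_000

    # ---- protein-coding genes, cursor placement per chromosome ----
    reference: list[TranscriptModel] = []
    genes_per_chrom = [
        config.n_coding_genes // config.n_chroms
        + (1 if i < config.n_coding_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    free = _FreeSpace()
    gene_no = 0
    for chrom, n_genes in zip(chroms, genes_per_chrom):
        cursor = edge
        prev_end = edge
        for _ in range(n_genes):
            gap = int(rng.integers(config.intergenic_gap * 2, config.intergenic_gap * 4 + 1))
            n_ex = int(rng.integers(3, 8))
            exon_lens = rng.integers(120, 301, size=n_ex).tolist()
            intron_lens = rng.integers(400, 2501, size=n_ex - 1).tolist()
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            start = cursor + gap
            span = _span_length(exon_lens, intron_lens)
            if start + span > config.chrom_length - edge:
                raise ConfigurationError(
                    f"{chrom}: ran out of space after {gene_no} genes; "
                    "increase chrom_length"
                )
            gene_no += 1
            gid = f"GENE{gene_no:04d}"
            reference.append(
                TranscriptModel(
                    f"{gid}.t1",
                    gid,
                    _make_exons(chrom, strand, start, exon_lens, intron_lens),
                    "protein_coding",
                )
            )
            free.add(chrom, prev_end + 500, start - 500)
            prev_end = start + span
            cursor = prev_end
        free.add(chrom, prev_end + 500, config.chrom_length - edge)

    coding = AnnotationSet(reference)
    candidates: list[TranscriptModel] = []
    subtypes: dict[str, str] = {}
    filter_fate: dict[str, str] = {}
    xloc = 0

    def next_id() -> str:
        nonlocal xloc
        xloc += 1
        return f"XLOC_{xloc:06d}"

    bias = config.tss_bias
    linc_margin = 100 + (abs(bias.window[0]) if bias else 0) + 100

    # ---- lincRNAs: intergenic, span-disjoint from coding ----
    for _ in range(config.n_linc):
        n_ex = int(rng.integers(2, 4))
        exon_lens = rng.integers(150, 351, size=n_ex).tolist()
        intron_lens = rng.integers(300, 701, size=n_ex - 1).tolist()
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        span = _span_length(exon_lens, intron_lens)
        chrom, start = free.place(rng, span, linc_margin)
        tid = next_id()
        candidates.append(
            TranscriptModel(tid, tid, _make_exons(chrom, strand, start, exon_lens, intron_lens))
        )
        subtypes[tid] = "lincRNA"
        filter_fate[tid] = "pass"

    # ---- antisense: one exon over a coding exon, opposite strand ----
    host_pool = [t for t in reference]
    rng.shuffle(host_pool)
    used_hosts: set[str] = set()
    n_made = 0
    for host in host_pool:
        if n_made == config.n_antisense:
            break
        if host.gene_id in used_hosts or host.n_exons < 3:
            continue
        # pick an internal exon followed by a roomy intron
        choices = [
            i
            for i in range(host.n_exons - 1)
            if host.exons[i + 1].start - host.exons[i].end >= 1400
        ]
        if not choices:
            continue
        i = choices[int(rng.integers(0, len(choices)))]
        host_exon = host.exons[i]
        intron_start, intron_end = host.exons[i].end, host.exons[i + 1].start
        strand = "-" if host.strand == "+" else "+"
        e1_len = int(rng.integers(150, 301))
        overlap = int(rng.integers(50, min(150, host_exon.length) + 1))
        e1_start = host_exon.end - overlap
        e1_end = e1_start + e1_len
        if e1_end > intron_end - 700:
            continue
        gap = int(rng.integers(150, 301))
        e2_len = int(rng.integers(150, 301))
        e2_start = e1_end + gap
        if e2_start + e2_len > intron_end - 100:
            continue
        tid = next_id()
        exons = (
            GenomicInterval(host.chrom, e1_start, e1_end, strand),
            GenomicInterval(host.chrom, e2_start, e2_start + e2_len, strand),
        )
        candidates.append(TranscriptModel(tid, tid, exons))
        subtypes[tid] = "antisense"
        filter_fate[tid] = "pass"
        used_hosts.add(host.gene_id)
        n_made += 1
    if n_made < config.n_antisense:
        raise ConfigurationError(
            f"only {n_made}/{config.n_antisense} antisense lncRNAs placeable; "
            "increase n_coding_genes or intron sizes"
        )

    # ---- intronic: strictly inside one intron, touching no exon ----
    n_made = 0
    for host in host_pool:
        if n_made == config.n_intronic:
            break
        if host.gene_id in used_hosts:
            continue
        roomy = [iv for iv in host.introns if iv.length >= 2400]
        if not roomy:
            continue
        intron = roomy[int(rng.integers(0, len(roomy)))]
        exon_lens = rng.integers(400, 601, size=2).tolist()
        intron_len = int(rng.integers(200, 401))
        span = _span_length(exon_lens, [intron_len])
        if span > intron.length - 200:
            exon_lens = [400, 400]
            intron_len = 200
            span = 1000
        start = int(rng.integers(intron.start + 100, intron.end - 100 - span + 1))
        strand = host.strand if rng.integers(0, 2) == 0 else (
            "-" if host.strand == "+" else "+"
        )
        tid = next_id()
        candidates.append(
            TranscriptModel(
                tid, tid, _make_exons(host.chrom, strand, start, exon_lens, [intron_len])
            )
        )
        subtypes[tid] = "intronic"
        filter_fate[tid] = "pass"
        used_hosts.add(host.gene_id)
        n_made += 1
    if n_made < config.n_intronic:
        raise ConfigurationError(
            f"only {n_made}/{config.n_intronic} intronic lncRNAs placeable"
        )

    # ---- decoys ----
    for _ in range(config.n_decoy_monoexon):
        length = int(rng.integers(300, 801))
        chrom, start = free.place(rng, length, 100)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        tid = next_id()
        candidates.append(
            TranscriptModel(
                tid, tid, (GenomicInterval(chrom, start, start + length, strand),)
            )
        )
        filter_fate[tid] = "exon_count"

    for _ in range(config.n_decoy_short):
        exon_lens = rng.integers(80, 96, size=2).tolist()  # total 160-190 < 200
        intron_len = int(rng.integers(150, 301))
        span = _span_length(exon_lens, [intron_len])
        chrom, start = free.place(rng, span, 100)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        tid = next_id()
        candidates.append(
            TranscriptModel(
                tid, tid, _make_exons(chrom, strand, start, exon_lens, [intron_len])
            )
        )
        filter_fate[tid] = "length"

    coding_decoy_ids: list[str] = []
    for _ in range(config.n_decoy_coding):
        exon_lens = rng.integers(250, 451, size=2).tolist()
        intron_len = int(rng.integers(200, 501))
        span = _span_length(exon_lens, [intron_len])
        chrom, start = free.place(rng, span, 100)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        tid = next_id()
        candidates.append(
            TranscriptModel(
                tid, tid, _make_exons(chrom, strand, start, exon_lens, [intron_len])
            )
        )
        filter_fate[tid] = "coding_potential"
        coding_decoy_ids.append(tid)

    # ---- housekeeping genes + their overlapping decoys ----
    hk_biotypes = ("tRNA", "rRNA", "snRNA", "snoRNA", "pre_miRNA", "pseudogene")
    housekeeping: list[TranscriptModel] = []
    for j in range(config.n_housekeeping_decoys):
        hk_len = int(rng.integers(150, 251))
        e1_len = int(rng.integers(150, 301))
        gap = int(rng.integers(150, 301))
        e2_len = int(rng.integers(150, 301))
        region = hk_len // 2 + e1_len + gap + e2_len
        chrom, start = free.place(rng, hk_len + region, 100)
        hk_strand = "+" if rng.integers(0, 2) == 0 else "-"
        hid = f"HK{j + 1:03d}"
        housekeeping.append(
            TranscriptModel(
                f"{hid}.t1",
                hid,
                (GenomicInterval(chrom, start, start + hk_len, hk_strand),),
                hk_biotypes[j % len(hk_biotypes)],
            )
        )
        # decoy exon 1 overlaps the tail half of the housekeeping exon;
        # strand alternates to exercise the strand-agnostic removal rule
        d_strand = hk_strand if j % 2 == 0 else ("-" if hk_strand == "+" else "+")
        e1_start = start + hk_len // 2
        e2_start = e1_start + e1_len + gap
        tid = next_id()
        candidates.append(
            TranscriptModel(
                tid,
                tid,
                (
                    GenomicInterval(chrom, e1_start, e1_start + e1_len, d_strand),
                    GenomicInterval(chrom, e2_start, e2_start + e2_len, d_strand),
                ),
            )
        )
        filter_fate[tid] = "known_class"

    reference_all = AnnotationSet([*reference, *housekeeping])
    candidate_set = AnnotationSet(candidates)

    # ---- transposable elements ----
    genome_len = config.n_chroms * config.chrom_length
    tes: list[TEElement] = []
    te_counts: dict[str, dict[str, int]] = {}
    for spec in config.te_families:
        mean_len = (spec.min_length + spec.max_length) / 2
        n_elements = int(round(spec.density * genome_len / mean_len))
        for _ in range(n_elements):
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            chrom = chroms[int(rng.integers(0, config.n_chroms))]
            start = int(rng.integers(0, config.chrom_length - length))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            tes.append(
                TEElement(
                    GenomicInterval(chrom, start, start + length, strand),
                    spec.te_class,
                    spec.te_family,
                )
            )
        te_counts[spec.te_family] = {"background": n_elements, "biased": 0}

    if bias is not None:
        lo, hi = bias.window
        window_len = hi - lo
        elem_len = int(round(bias.excess * window_len))
        fam_class = next(
            (s.te_class for s in config.te_families if s.te_family == bias.te_family),
            "LTR",
        )
        n_biased = 0
        for tid, sub in subtypes.items():
            if sub != bias.subtype:
                continue
            t = candidate_set[tid]
            tss = t.tss
            if t.strand == "+":
                g_lo, g_hi = tss + lo, tss + hi  # genomic window, half-open
            else:
                g_lo, g_hi = tss - hi + 1, tss - lo + 1
            start = int(rng.integers(g_lo, g_hi - elem_len + 1))
            tes.append(
                TEElement(
                    GenomicInterval(t.chrom, start, start + elem_len, t.strand),
                    fam_class,
                    bias.te_family,
                )
            )
            n_biased += 1
        te_counts.setdefault(bias.te_family, {"background": 0, "biased": 0})
        te_counts[bias.te_family]["biased"] = n_biased

    # genome-wide merged coverage per family (the TSS-bias null baseline)
    from .telandscape import merge_intervals

    te_genome_density: dict[str, float] = {}
    for family in sorted({t.te_family for t in tes}):
        covered = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for t in tes:
            if t.te_family == family:
                by_chrom.setdefault(t.interval.chrom, []).append(
                    (t.interval.start, t.interval.end)
                )
        for ivs in by_chrom.values():
            covered += sum(e - s for s, e in merge_intervals(ivs))
        te_genome_density[family] = covered / genome_len

    # ---- sequences ----
    sequences: dict[str, str] = {}
    for t in candidates:
        if t.transcript_id in coding_decoy_ids:
            sequences[t.transcript_id] = _coding_sequence(
                rng, t.length, config.coding_orf_nt
            )
        else:
            sequences[t.transcript_id] = _noncoding_sequence(rng, t.length)
    for t in reference:
        orf = max(config.coding_orf_nt, 3 * int(0.5 * t.length / 3))
        sequences[t.transcript_id] = _coding_sequence(rng, t.length, min(orf, t.length))

    # ---- planted pairs (annotated with actual cis geometry) ----
    from .targets import cis_targets

    true_lnc = [tid for tid in subtypes]
    linc_ids = [tid for tid, s in subtypes.items() if s == "lincRNA"]
    cis = cis_targets(
        [candidate_set[tid] for tid in linc_ids], coding, windows=(10_000,)
    )
    cis_by_lnc: dict[str, list] = {}
    for p in cis:
        cis_by_lnc.setdefault(p.lnc_id, []).append(p)

    trans_pairs: list[dict] = []
    used_lnc: set[str] = set()
    used_gene: set[str] = set()
    # cis-colocated planted pairs first
    for lnc in sorted(cis_by_lnc):
        if len(trans_pairs) == config.n_planted_cis_trans:
            break
        options = [p for p in cis_by_lnc[lnc] if p.gene_id not in used_gene]
        if not options:
            continue
        p = options[int(rng.integers(0, len(options)))]
        sign = 1 if len(trans_pairs) % 2 == 0 else -1
        trans_pairs.append(
            {
                "lnc": lnc,
                "gene": p.gene_id,
                "sign": sign,
                "cis": True,
                "distance": p.distance,
            }
        )
        used_lnc.add(lnc)
        used_gene.add(p.gene_id)
    if len(trans_pairs) < config.n_planted_cis_trans:
        raise SimulationError(
            f"only {len(trans_pairs)}/{config.n_planted_cis_trans} cis-colocated "
            "pairs available for planting"
        )
    # trans-only pairs: gene on another chromosome or far beyond the 100-kb
    # cis window, so the pair can never be co-localized
    remaining_lnc = [t for t in linc_ids if t not in used_lnc]
    gene_spans = {g: coding.gene_span(g) for g in coding.gene_ids}
    for lnc in remaining_lnc:
        if len(trans_pairs) == config.n_planted_trans_pairs:
            break
        lnc_span = candidate_set[lnc].span
        far = [
            g
            for g, sp in sorted(gene_spans.items())
            if g not in used_gene
            and (
                sp.chrom != lnc_span.chrom
                or lnc_span.distance_to(sp) > 120_000
            )
        ]
        if not far:
            continue
        gene = far[int(rng.integers(0, len(far)))]
        sign = 1 if len(trans_pairs) % 2 == 0 else -1
        trans_pairs.append(
            {"lnc": lnc, "gene": gene, "sign": sign, "cis": False, "distance": None}
        )
        used_lnc.add(lnc)
        used_gene.add(gene)
    if len(trans_pairs) < config.n_planted_trans_pairs:
        raise SimulationError("could not plant the requested number of trans pairs")

    # planted DE rows: lncRNAs not used in any correlation pair
    de_pool = [t for t in true_lnc if t not in used_lnc]
    if len(de_pool) < config.n_planted_de:
        raise SimulationError("not enough free lncRNAs for planted DE rows")
    de_ids = de_pool[: config.n_planted_de]

    expression_ids = [t.transcript_id for t in candidates] + sorted(coding.gene_ids)

    manifest = TruthManifest(
        subtypes=subtypes,
        filter_fate=filter_fate,
        trans_pairs=trans_pairs,
        de_ids=list(de_ids),
        te_counts=te_counts,
        te_genome_density=te_genome_density,
        tss_bias=(
            {
                "te_family": bias.te_family,
                "subtype": bias.subtype,
                "window": list(bias.window),
                "excess": bias.excess,
            }
            if bias
            else None
        ),
        expression_ids=expression_ids,
        genome={"n_chroms": config.n_chroms, "chrom_length": config.chrom_length},
    )
    return candidate_set, reference_all, tes, sequences, manifest


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, manifest: TruthManifest
) -> ExpressionMatrix:
    """FPKM matrix: log-normal baseline, planted correlated pairs, planted DE.

    Planted pairs share a latent factor through a *linear* map, so with
    ``noise_sd = 0`` the empirical correlation is exactly +/-1; otherwise the
    pair is resampled (bounded retries) until |r| >= ``config.target_r``.
    Planted DE rows are shifted by ``de_log2_fc`` in the second group.
    """
    # independent stream from the annotation stage, still seed-determined
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = 2 * config.n_samples_per_group
    samples = [
        f"{grp}_{i + 1}"
        for grp in ("dark", "white")
        for i in range(config.n_samples_per_group)
    ]
    groups = {s: s.split("_")[0] for s in samples}
    group2 = np.array([g == "white" for g in (groups[s] for s in samples)])

    values: dict[str, np.ndarray] = {}

    for pair in manifest.trans_pairs:
        sign = pair["sign"]
        achieved = 0.0
        for _ in range(1000):
            z = rng.uniform(-1.0, 1.0, size=n)
            lnc = 20.0 + 10.0 * z + rng.normal(0.0, config.noise_sd, size=n)
            gene = 20.0 + sign * 10.0 * z + rng.normal(0.0, config.noise_sd, size=n)
            lnc = np.clip(lnc, 0.0, None)
            gene = np.clip(gene, 0.0, None)
            lc = lnc - lnc.mean()
            gc = gene - gene.mean()
            denom = np.sqrt((lc @ lc) * (gc @ gc))
            if denom == 0:
                continue
            achieved = float((lc @ gc) / denom)
            if sign * achieved >= config.target_r:
                break
        else:
            raise SimulationError(
                f"planted pair {pair['lnc']}-{pair['gene']}: could not reach "
                f"|r| >= {config.target_r}; achieved r = {achieved:.4f}"
            )
        values[pair["lnc"]] = lnc
        values[pair["gene"]] = gene

    for tid in manifest.de_ids:
        base = float(rng.uniform(5.0, 20.0))
        row = base * 10.0 ** rng.normal(0.0, config.de_noise_sd, size=n)
        row[group2] *= 2.0 ** config.de_log2_fc
        values[tid] = row

    for rid in manifest.expression_ids:
        if rid in values:
            continue
        mu = float(rng.normal(0.5, 0.6))
        values[rid] = 10.0 ** (mu + rng.normal(0.0, config.noise_sd, size=n))

    frame = pd.DataFrame(
        [values[rid] for rid in manifest.expression_ids],
        index=manifest.expression_ids,
        columns=samples,
    )
    return ExpressionMatrix(frame, groups)


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Generate the complete input bundle plus its truth manifest."""
    candidates, reference, tes, sequences, manifest = simulate_annotation(config)
    expression = simulate_expression(config, manifest)
    return SimulatedBundle(
        config, candidates, reference, tes, sequences, expression, manifest
    )


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the same formats the readers consume.

    Emits candidates.gtf, reference.gtf, repeats.out, transcripts.fa,
    expression.tsv, groups.tsv, truth_manifest.json and config.txt; returns
    the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": outdir / "candidates.gtf",
        "reference": outdir / "reference.gtf",
        "repeats": outdir / "repeats.out",
        "fasta": outdir / "transcripts.fa",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "manifest": outdir / "truth_manifest.json",
        "config": outdir / "config.txt",
    }
    write_gtf(bundle.candidates, paths["candidates"])
    write_gtf(bundle.reference, paths["reference"])
    write_repeatmasker_out(bundle.tes, paths["repeats"])
    write_fasta(bundle.sequences, paths["fasta"])
    write_expression_table(bundle.expression, paths["expression"])
    with open(paths["groups"], "w") as fh:
        for sample, group in bundle.expression.groups.items():
            fh.write(f"{sample}\t{group}\n")
    bundle.manifest.to_json(paths["manifest"])
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(bundle.config):
            fh.write(f"{f.name}={getattr(bundle.config, f.name)!r}\n")
    return paths
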