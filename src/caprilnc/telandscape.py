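"""Transposable-element composition per transcript class and TSS position bias.

Density is computed over transcript *spans* (introns included): for each
family, overlapping same-family elements are merged first, then the covered
fraction of the summed span length is reported per class, together with
with/without-family transcript counts.  Family presence contrasts between
classes use the two-sided Fisher exact test.  Position bias is profiled as a
per-transcript presence fraction at every offset in a window centred on the
TSS, oriented 5'->3' (negative offsets = upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    GenomicInterval,
    TEElement,
    TranscriptModel,
    ValidationError,
)

ALL_FAMILIES = "ALL"  # pseudo-family aggregating every element


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting half-open intervals into a sorted disjoint set."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _family_index(
    tes: Sequence[TEElement], family: str
) -> dict[str, list[tuple[int, int]]]:
    """Merged per-chromosome intervals of one family (or ALL families)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        if family != ALL_FAMILIES and te.te_family != family:
            continue
        by_chrom.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end)
        )
    return {chrom: merge_intervals(ivs) for chrom, ivs in by_chrom.items()}


def _covered_bases(merged: list[tuple[int, int]], start: int, end: int) -> int:
    """Bases of [start, end) covered by a merged, sorted interval list."""
    total = 0
    for s, e in merged:
        if e <= start:
            continue
        if s >= end:
            break
        total += min(e, end) - max(s, start)
    return total


@dataclass(frozen=True)
class TEDensityRow:
    class_label: str
    te_family: str
    covered_bases: int
    total_bases: int
    n_with: int
    n_without: int

    @property
    def density(self) -> float:
        return self.covered_bases / self.total_bases

    def __post_init__(self) -> None:
        if not (0 <= self.covered_bases <= self.total_bases):
            raise ValidationError("covered bases outside [0, total]")


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]
    haldane_corrected: bool = False  # 0.5 added to cells for the OR only
    degenerate: bool = False  # a margin was entirely zero


@dataclass(frozen=True)
class TSSProfile:
    class_label: str
    te_family: str
    window: int  # profile covers offsets [-window, +window]
    fractions: np.ndarray  # length 2*window + 1, TSS at index `window`
    n_transcripts: int

    def __post_init__(self) -> None:
        if self.fractions.shape != (2 * self.window + 1,):
            raise ValidationError("profile length must be 2*window + 1")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValidationError("profile fractions must lie in [0, 1]")

    def mean_fraction(self, lo: int, hi: int) -> float:
        """Mean coverage fraction over offsets [lo, hi) relative to the TSS."""
        return float(np.mean(self.fractions[lo + self.window : hi + self.window]))


def te_density(
    class_label: str,
    transcripts: Sequence[TranscriptModel],
    tes: Sequence[TEElement],
    families: Sequence[str] | None = None,
) -> list[TEDensityRow]:
    """Span-level TE density of one class, per family plus an ALL aggregate.

    Covered bases of a transcript are the bases of its span covered by >= 1
    element of the family after merging same-family elements; the class
    density is sum(covered)/sum(span length).
    """
    if not transcripts:
        raise ValidationError(f"empty class {class_label!r}")
    if families is None:
        families = sorted({te.te_family for te in tes})
    rows = []
    for family in [ALL_FAMILIES, *families]:
        index = _family_index(tes, family)
        covered = 0
        total = 0
        n_with = 0
        for t in transcripts:
            span = t.span
            merged = index.get(span.chrom, [])
            c = _covered_bases(merged, span.start, span.end)
            covered += c
            total += span.length
            if c > 0:
                n_with += 1
        rows.append(
            TEDensityRow(
                class_label, family, covered, total, n_with,
                len(transcripts) - n_with,
            )
        )
    return rows


def te_density_table(
    classes: Mapping[str, Sequence[TranscriptModel]],
    tes: Sequence[TEElement],
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    rows = []
    for label, transcripts in classes.items():
        for r in te_density(label, list(transcripts), tes, families):
            rows.append(
                {
                    "class": r.class_label,
                    "family": r.te_family,
                    "covered_bases": r.covered_bases,
                    "total_bases": r.total_bases,
                    "density": r.density,
                    "n_with": r.n_with,
                    "n_without": r.n_without,
                }
            )
    return pd.DataFrame(rows)


def te_composition_fisher(row_a: TEDensityRow, row_b: TEDensityRow) -> FisherResult:
    """Two-sided Fisher exact test on family presence between two classes.

    2x2 table = (with, without) x (class A, class B).  The odds ratio uses a
    0.5 (Haldane) continuity correction only when a cell is zero, flagged in
    the result.  A table with an all-zero margin is degenerate: p = 1 with a
    warning.
    """
    table = ((row_a.n_with, row_a.n_without), (row_b.n_with, row_b.n_without))
    a, b = table[0]
    c, d = table[1]
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return FisherResult(float("nan"), 1.0, table, degenerate=True)
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        odds = (a * d) / (b * c)
        corrected = False
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherResult(float(odds), float(p), table, haldane_corrected=corrected)


def tss_profile(
    class_label: str,
    transcripts: Sequence[TranscriptModel],
    tes: Sequence[TEElement],
    family: str,
    window: int = 2000,
) -> TSSProfile:
    """Presence-fraction profile of one TE family around the TSSs of a class.

    For each transcript, offset k in [-window, +window] maps to genomic
    position TSS + k on the "+" strand and TSS - k on the "-" strand, so the
    profile is oriented 5'->3' with negative offsets upstream.  The fraction
    at offset k is the share of transcripts whose position k is covered by
    >= 1 family element; each transcript votes 0/1 per position.  Positions
    falling off the chromosome count as uncovered.
    """
    if not transcripts:
        raise ValidationError(f"empty class {class_label!r}")
    index = _family_index(tes, family)
    width = 2 * window + 1
    counts = np.zeros(width, dtype=np.int64)
    for t in transcripts:
        if t.strand == ".":
            raise ValidationError(f"{t.transcript_id}: TSS profile needs a strand")
        tss = t.tss
        lo = tss - window
        hi = tss + window + 1
        covered = np.zeros(width, dtype=bool)
        for s, e in index.get(t.chrom, []):
            if e <= lo:
                continue
            if s >= hi:
                break
            covered[max(s, lo) - lo : min(e, hi) - lo] = True
        if t.strand == "-":
            covered = covered[::-1]
        counts += covered
    fractions = counts / len(transcripts)
    return TSSProfile(class_label, family, window, fractions, len(transcripts))


def tss_profile_table(profile: TSSProfile) -> pd.DataFrame:
    offsets = np.arange(-profile.window, profile.window + 1)
    return pd.DataFrame(
        {
            "offset": offsets,
            "fraction": profile.fractions,
            "class": profile.class_label,
            "family": profile.te_family,
        }
    )


def plot_tss_profiles(profiles: Sequence[TSSProfile], path: str) -> None:
    """Simple coverage plot, one panel per class (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted({p.class_label for p in profiles})
    fig, axes = plt.subplots(1, len(labels), figsize=(4 * len(labels), 3), squeeze=False)
    for ax, label in zip(axes[0], labels):
        for p in profiles:
            if p.class_label != label:
                continue
            offsets = np.arange(-p.window, p.window + 1)
            ax.plot(offsets, p.fractions, label=p.te_family, lw=1)
        ax.set_title(label)
        ax.set_xlabel("offset from TSS (bp)")
        ax.set_ylabel("coverage fraction")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
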