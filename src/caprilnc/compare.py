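"""Architecture/expression feature table and two-sample distribution contrasts.

Per-transcript features: spliced length, exon count, isoforms per locus
(transcripts sharing the gene_id within the same class), longest ORF, mean
FPKM across all samples, log-expression = log10(mean FPKM + 1), and an
optional conservation score.  Class-against-class contrasts use the
two-sample Kolmogorov-Smirnov test with the asymptotic two-sided p-value at
effective sample size n1*n2/(n1+n2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .genome_io import (
    AnnotationSet,
    ConfigurationError,
    ExpressionMatrix,
    TranscriptModel,
    ValidationError,
)
from .identify import longest_orf

FEATURES = (
    "length",
    "exon_count",
    "isoforms_per_locus",
    "orf_length",
    "mean_fpkm",
    "log_expression",
    "conservation",
)


@dataclass(frozen=True)
class KSResult:
    statistic: float  # sup-distance D between the two empirical CDFs
    pvalue: float
    n1: int
    n2: int


@dataclass(frozen=True)
class ClassComparison:
    class_a: str
    class_b: str
    feature: str
    ks: KSResult
    median_a: float
    median_b: float


def build_feature_table(
    classes: Mapping[str, Iterable[TranscriptModel]],
    expression: ExpressionMatrix,
    sequences: Mapping[str, str],
    conservation: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per transcript with its class label and feature values.

    Every transcript must have an expression row and a sequence; conservation
    scores are optional and yield NaN where absent.  Expression rows are
    looked up by transcript id first, then by gene id (gene-level FPKM is the
    common summary for multi-isoform coding loci).
    """
    rows = []
    missing_expr: list[str] = []
    missing_seq: list[str] = []
    for label, transcripts in classes.items():
        transcripts = list(transcripts)
        per_gene: dict[str, int] = {}
        for t in transcripts:
            per_gene[t.gene_id] = per_gene.get(t.gene_id, 0) + 1
        for t in transcripts:
            tid = t.transcript_id
            expr_id = tid if tid in expression else t.gene_id
            if expr_id not in expression:
                missing_expr.append(tid)
                continue
            if tid not in sequences:
                missing_seq.append(tid)
                continue
            mean_fpkm = float(np.mean(expression.row(expr_id)))
            rows.append(
                {
                    "transcript_id": tid,
                    "class": label,
                    "length": t.length,
                    "exon_count": t.n_exons,
                    "isoforms_per_locus": per_gene[t.gene_id],
                    "orf_length": longest_orf(sequences[tid]),
                    "mean_fpkm": mean_fpkm,
                    "log_expression": math.log10(mean_fpkm + 1.0),
                    "conservation": (
                        conservation.get(tid, float("nan"))
                        if conservation
                        else float("nan")
                    ),
                }
            )
    if missing_expr:
        raise ValidationError(f"no expression row for: {sorted(missing_expr)[:10]}")
    if missing_seq:
        raise ValidationError(f"no sequence for: {sorted(missing_seq)[:10]}")
    return pd.DataFrame(rows)


def class_medians(table: pd.DataFrame, feature: str) -> pd.Series:
    if feature not in table.columns:
        raise ConfigurationError(f"unknown feature {feature!r}")
    return table.groupby("class")[feature].median()


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over the pooled sample points of |F1 - F2| between the
    two empirical CDFs; the two-sided p-value comes from the asymptotic
    Kolmogorov distribution evaluated at sqrt(n1*n2/(n1+n2)) * D.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("KS test requires non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    pooled.sort(kind="mergesort")
    # ECDF values at every pooled point (right-continuous)
    f1 = np.searchsorted(np.sort(x), pooled, side="right") / n1
    f2 = np.searchsorted(np.sort(y), pooled, side="right") / n2
    d = float(np.max(np.abs(f1 - f2)))
    en = n1 * n2 / (n1 + n2)
    p = float(special.kolmogorov(math.sqrt(en) * d))
    return KSResult(d, min(1.0, max(0.0, p)), n1, n2)


def compare_classes(
    table: pd.DataFrame, class_a: str, class_b: str, feature: str
) -> ClassComparison:
    """KS contrast of one feature between two classes, with class medians."""
    if feature not in table.columns or feature in ("transcript_id", "class"):
        raise ConfigurationError(f"unknown feature {feature!r}")
    xa = table.loc[table["class"] == class_a, feature].dropna().to_numpy()
    xb = table.loc[table["class"] == class_b, feature].dropna().to_numpy()
    if xa.size == 0 or xb.size == 0:
        raise ValidationError(
            f"empty class in comparison: {class_a}={xa.size}, {class_b}={xb.size}"
        )
    ks = ks_two_sample(xa, xb)
    return ClassComparison(
        class_a, class_b, feature, ks, float(np.median(xa)), float(np.median(xb))
    )


def compare_all(
    table: pd.DataFrame,
    features: Sequence[str] = ("length", "exon_count", "log_expression"),
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All pairwise class contrasts for the named features, as a tidy table."""
    labels = sorted(table["class"].unique())
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]
        ]
    rows = []
    for feature in features:
        for a, b in pairs:
            cmp_ = compare_classes(table, a, b, feature)
            rows.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "feature": feature,
                    "D": cmp_.ks.statistic,
                    "p": cmp_.ks.pvalue,
                    "n_a": cmp_.ks.n1,
                    "n_b": cmp_.ks.n2,
                    "median_a": cmp_.median_a,
                    "median_b": cmp_.median_b,
                }
            )
    return pd.DataFrame(rows)
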