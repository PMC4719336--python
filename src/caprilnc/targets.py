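"""Cis/trans target prediction, differential expression and set enrichment.

*Cis* candidates are protein-coding genes within a genomic window (10 kb and
100 kb tiers by default) of an lncRNA, measured edge-to-edge between spans
(overlap = distance 0), boundary inclusive, strand-agnostic.  *Trans*
candidates are genes whose expression correlates with the lncRNA across
samples beyond a strict Pearson threshold (|r| > 0.95 by default, computed
on raw FPKM).  The intersection of the two yields co-localized,
co-expressed lncRNA-gene pairs.

Differential expression between the two sample groups is a Welch t-test on
log10(FPKM + 1) with Holm-Sidak step-down correction.  Gene-set
over-representation uses the EASE score: a one-tailed Fisher exact test with
the overlap count decremented by one, which is conservative for small
overlaps (k <= 1 gives p = 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import (
    AnnotationSet,
    ConfigurationError,
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (10_000, 100_000)
DEFAULT_R_THRESHOLD = 0.95


@dataclass(frozen=True)
class CisPair:
    lnc_id: str
    gene_id: str
    distance: int  # signed: + downstream of the lncRNA 5'->3', 0 on overlap
    tier: int  # smallest window (bp) containing the pair

    def __post_init__(self) -> None:
        if abs(self.distance) > self.tier:
            raise ValidationError("pair distance exceeds its window tier")


@dataclass(frozen=True)
class TransPair:
    lnc_id: str
    gene_id: str
    r: float

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation out of range: {self.r}")


@dataclass(frozen=True)
class CisTransPair:
    lnc_id: str
    gene_id: str
    distance: int
    tier: int
    r: float


def cis_targets(
    lncRNAs: Iterable[TranscriptModel],
    coding: AnnotationSet,
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> list[CisPair]:
    """All (lncRNA, coding gene) pairs within the largest window.

    A pair is emitted iff the edge-to-edge distance between the lncRNA span
    and the gene span (union of the gene's transcripts) is <= window,
    inclusive, on the same chromosome, any strand.  ``tier`` records the
    smallest window containing the pair; tiers are nested by construction.
    The sign of ``distance`` marks the gene's position along the lncRNA's
    5'->3' orientation (+ downstream, - upstream, 0 on span overlap).
    """
    windows = sorted(windows)
    w_max = windows[-1]
    gene_spans = {gid: coding.gene_span(gid) for gid in coding.gene_ids}
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for gid, span in gene_spans.items():
        by_chrom.setdefault(span.chrom, []).append((gid, span))
    for spans in by_chrom.values():
        spans.sort(key=lambda g: g[1].start)

    pairs: list[CisPair] = []
    for t in lncRNAs:
        span = t.span
        for gid, gspan in by_chrom.get(span.chrom, []):
            if gspan.end + w_max < span.start:
                continue
            if gspan.start > span.end + w_max:
                break
            gap = span.distance_to(gspan)
            if gap > w_max:
                continue
            tier = next(w for w in windows if gap <= w)
            if gap == 0:
                signed = 0
            else:
                downstream = (
                    gspan.start >= span.end
                    if t.strand == "+"
                    else gspan.end <= span.start
                )
                signed = gap if downstream else -gap
            pairs.append(CisPair(t.transcript_id, gid, signed, tier))
    return pairs


def pairs_within(pairs: Sequence[CisPair], window: int) -> list[CisPair]:
    """Cis pairs whose edge distance is within ``window`` (tier nesting)."""
    return [p for p in pairs if abs(p.distance) <= window]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch")
    if x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValidationError("zero variance: correlation undefined")
    return float(xc @ yc) / denom


def trans_targets(
    expression: ExpressionMatrix,
    lnc_ids: Sequence[str],
    gene_ids: Sequence[str],
    threshold: float = DEFAULT_R_THRESHOLD,
) -> list[TransPair]:
    """All (lncRNA, gene) pairs with r > threshold or r < -threshold (strict).

    Correlation is computed on raw FPKM across all samples.  Rows with zero
    variance have no defined correlation; their pairs are skipped and logged.
    """
    missing = [i for i in [*lnc_ids, *gene_ids] if i not in expression]
    if missing:
        raise ValidationError(f"ids absent from expression matrix: {missing[:10]}")
    lnc = expression.values.loc[list(lnc_ids)].to_numpy(dtype=float)
    gen = expression.values.loc[list(gene_ids)].to_numpy(dtype=float)

    def standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centred = a - a.mean(axis=1, keepdims=True)
        norm = np.sqrt((centred**2).sum(axis=1))
        ok = norm > 0
        out = np.zeros_like(centred)
        out[ok] = centred[ok] / norm[ok, None]
        return out, ok

    zl, ok_l = standardize(lnc)
    zg, ok_g = standardize(gen)
    for ids, ok in ((lnc_ids, ok_l), (gene_ids, ok_g)):
        for i, good in zip(ids, ok):
            if not good:
                logger.warning("%s: zero variance, correlations skipped", i)

    corr = zl @ zg.T
    pairs: list[TransPair] = []
    for i, lid in enumerate(lnc_ids):
        if not ok_l[i]:
            continue
        for j, gid in enumerate(gene_ids):
            if not ok_g[j]:
                continue
            r = float(np.clip(corr[i, j], -1.0, 1.0))
            if r > threshold or r < -threshold:
                pairs.append(TransPair(lid, gid, r))
    return pairs


def cis_trans_intersection(
    cis: Sequence[CisPair], trans: Sequence[TransPair]
) -> list[CisTransPair]:
    """Pairs present in both sets, keyed by (lncRNA id, gene id)."""
    trans_by_key = {(p.lnc_id, p.gene_id): p for p in trans}
    out = []
    for c in cis:
        t = trans_by_key.get((c.lnc_id, c.gene_id))
        if t is not None:
            out.append(CisTransPair(c.lnc_id, c.gene_id, c.distance, c.tier, t.r))
    return out


def differential_expression(
    expression: ExpressionMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch t-test on log10(FPKM + 1) between the two sample groups,
    Holm-Sidak corrected.

    Returns a DataFrame (id, mean_<group>, t, p_raw, p_adj, significant)
    ordered as the input matrix.  Rows where both groups have zero variance
    get p = 1 when the means are equal (no evidence) and p = 0 otherwise
    (the infinite-t limit).
    """
    labels = expression.group_labels
    if len(labels) != 2:
        raise ConfigurationError(f"need exactly two groups, got {labels}")
    ga, gb = labels
    sa, sb = expression.samples_in(ga), expression.samples_in(gb)
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("each group needs >= 2 samples for a t-test")
    log_vals = np.log10(expression.values.to_numpy(dtype=float) + 1.0)
    cols = expression.samples
    ia = [cols.index(s) for s in sa]
    ib = [cols.index(s) for s in sb]
    a, b = log_vals[:, ia], log_vals[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal = np.isclose(mean_a, mean_b)
    t_stat = np.where(degenerate & equal, 0.0, t_stat)
    p_raw = np.where(degenerate, np.where(equal, 1.0, 0.0), p_raw)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="holm-sidak")
    return pd.DataFrame(
        {
            "id": expression.ids,
            f"mean_{ga}": mean_a,
            f"mean_{gb}": mean_b,
            "t": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": reject,
        }
    )


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    With raw p sorted ascending, adjusted p_i = max_{j<=i} 1 - (1-p_j)^(m-j+1)
    (1-based ranks), clipped to 1, mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(adj_sorted))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def ease_enrichment(
    target_set: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """EASE-score over-representation of each term in the target set.

    For a term with K background genes, a target list of n genes out of a
    background of N, and an overlap of k, the EASE p is the hypergeometric
    upper tail P(X >= k - 1); k <= 1 yields p = 1 by construction.
    Returns a DataFrame (term, k, n, K, N, p) sorted by p then term.
    """
    background = set(background)
    if not background:
        raise ValidationError("empty background set")
    targets = set(target_set)
    stray = targets - background
    if stray:
        raise ValidationError(
            f"target genes absent from background: {sorted(stray)[:10]}"
        )
    n = len(targets)
    N = len(background)
    rows = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & background
        K = len(term_genes)
        k = len(term_genes & targets)
        if k <= 1:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 2, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(1.0, p)})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return frame


def read_term_map(path: str) -> dict[str, set[str]]:
    """Read a two-column TSV (term, gene) into a term -> genes mapping."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValidationError(f"term map row needs 2 columns: {line!r}")
            out.setdefault(cols[0], set()).add(cols[1])
    return out
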