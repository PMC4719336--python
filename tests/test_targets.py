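"""Cis windows, trans correlation, DE flagging and EASE enrichment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caprilnc import (
    AnnotationSet,
    ExpressionMatrix,
    ValidationError,
    cis_targets,
    cis_trans_intersection,
    differential_expression,
    ease_enrichment,
    holm_sidak,
    pearson_r,
    trans_targets,
)
from caprilnc.targets import TransPair, pairs_within
from conftest import make_transcript


def _expr(ids, values, n_per_group=3):
    samples = [f"d{i}" for i in range(n_per_group)] + [
        f"w{i}" for i in range(n_per_group)
    ]
    groups = {s: ("dark" if s.startswith("d") else "white") for s in samples}
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples), groups)


class TestCisTargets:
    def _gene(self, gid, start, end, chrom="chr1", strand="+"):
        return make_transcript(
            f"{gid}.t", chrom, strand, [(start, end)], biotype="protein_coding", gene_id=gid
        )

    def test_exact_window_boundary_included(self):
        """A gene ending exactly 10,000 bp before the lncRNA start is in the
        10 kb tier (inclusive boundary)."""
        lnc = make_transcript("l", "chr1", "+", [(50_000, 50_500), (51_000, 51_500)])
        coding = AnnotationSet([self._gene("g", 39_000, 40_000)])
        (pair,) = cis_targets([lnc], coding, windows=(10_000, 100_000))
        assert pair.tier == 10_000
        assert pair.distance == -10_000  # upstream of a "+" strand lncRNA

    def test_overlap_gives_distance_zero(self):
        lnc = make_transcript("l", "chr1", "+", [(50_000, 50_500), (51_000, 51_500)])
        coding = AnnotationSet([self._gene("g", 51_400, 52_000)])
        (pair,) = cis_targets([lnc], coding)
        assert pair.distance == 0 and pair.tier == 10_000

    def test_sign_follows_lnc_orientation(self):
        gene = self._gene("g", 60_000, 61_000)
        plus = make_transcript("p", "chr1", "+", [(50_000, 50_500), (51_000, 51_500)])
        minus = make_transcript("m", "chr1", "-", [(50_000, 50_500), (51_000, 51_500)])
        coding = AnnotationSet([gene])
        (pp,) = cis_targets([plus], coding)
        (pm,) = cis_targets([minus], coding)
        assert pp.distance > 0  # downstream for "+"
        assert pm.distance < 0  # upstream for "-"

    def test_matches_quadratic_scan(self):
        """Random fixture: the pair set equals an O(n^2) brute-force scan."""
        rng = np.random.default_rng(29)
        genes = []
        for i in range(120):
            start = int(rng.integers(0, 2_000_000))
            genes.append(
                self._gene(f"g{i}", start, start + int(rng.integers(500, 5_000)),
                           chrom=f"chr{int(rng.integers(1, 3))}")
            )
        lncs = []
        for i in range(60):
            start = int(rng.integers(0, 2_000_000))
            lncs.append(
                make_transcript(
                    f"l{i}", f"chr{int(rng.integers(1, 3))}",
                    "+" if rng.integers(0, 2) == 0 else "-",
                    [(start, start + 400), (start + 800, start + 1_400)],
                )
            )
        coding = AnnotationSet(genes)
        got = {(p.lnc_id, p.gene_id) for p in cis_targets(lncs, coding)}
        want = set()
        for l in lncs:
            for g in genes:
                if g.chrom != l.chrom:
                    continue
                gap = l.span.distance_to(g.span)
                if gap <= 100_000:
                    want.add((l.transcript_id, g.gene_id))
        assert got == want

    def test_tier_nesting(self, default_bundle):
        coding = default_bundle.reference.biotype_subset(["protein_coding"])
        lncs = [
            default_bundle.candidates[t] for t in default_bundle.manifest.subtypes
        ]
        pairs = cis_targets(lncs, coding)
        inner = {(p.lnc_id, p.gene_id) for p in pairs_within(pairs, 10_000)}
        outer = {(p.lnc_id, p.gene_id) for p in pairs_within(pairs, 100_000)}
        assert inner <= outer
        assert all(abs(p.distance) <= p.tier for p in pairs)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_matches_summation_formula(self):
        """100 random pairs agree with the explicit sum formula to 1e-12."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            sx, sy = math.fsum(x), math.fsum(y)
            sxx = math.fsum(v * v for v in x)
            syy = math.fsum(v * v for v in y)
            sxy = math.fsum(a * b for a, b in zip(x, y))
            want = (n * sxy - sx * sy) / math.sqrt(
                (n * sxx - sx * sx) * (n * syy - sy * sy)
            )
            assert pearson_r(x, y) == pytest.approx(want, abs=1e-12)


class TestTransTargets:
    def test_threshold_is_strict(self):
        """A pair whose correlation equals the threshold is NOT emitted:
        r is exactly 1 for an affine relation, and 1 > 1 is false."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 2.0 * x + 1.0
        expr = _expr(["l", "g"], [x, y])
        assert trans_targets(expr, ["l"], ["g"], threshold=1.0) == []
        below = trans_targets(expr, ["l"], ["g"], threshold=0.999999)
        assert len(below) == 1 and below[0].r == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_role_swap(self):
        rng = np.random.default_rng(37)
        x, y = rng.uniform(1, 10, size=6), rng.uniform(1, 10, size=6)
        expr = _expr(["a", "b"], [x, y])
        r_ab = trans_targets(expr, ["a"], ["b"], threshold=0.0)
        r_ba = trans_targets(expr, ["b"], ["a"], threshold=0.0)
        if r_ab and r_ba:
            assert r_ab[0].r == pytest.approx(r_ba[0].r, abs=1e-12)

    def test_zero_variance_rows_skipped(self, caplog):
        expr = _expr(["flat", "g"], [[1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6]])
        assert trans_targets(expr, ["flat"], ["g"], threshold=0.0) == []

    def test_bundle_recovers_planted_pairs(self, default_bundle):
        manifest = default_bundle.manifest
        lnc_ids = sorted(manifest.subtypes)
        gene_ids = sorted(
            i for i in manifest.expression_ids if i.startswith("GENE")
        )
        got = {
            (p.lnc_id, p.gene_id): p.sign
            for p in trans_targets(default_bundle.expression, lnc_ids, gene_ids)
        }
        for pair in manifest.trans_pairs:
            key = (pair["lnc"], pair["gene"])
            assert key in got and got[key] == pair["sign"], pair
        # spurious pairs stay near the small-n null rate (see methods note)
        n_tested = len(lnc_ids) * len(gene_ids)
        extras = len(got) - len(manifest.trans_pairs)
        assert extras <= 3 * 0.0037 * n_tested


class TestIntersection:
    def test_disjoint_inputs_empty(self):
        from caprilnc.targets import CisPair

        cis = [CisPair("l1", "g1", 100, 10_000)]
        trans = [TransPair("l2", "g2", 0.99)]
        assert cis_trans_intersection(cis, trans) == []

    def test_intersection_subset_of_inputs(self, default_bundle):
        manifest = default_bundle.manifest
        coding = default_bundle.reference.biotype_subset(["protein_coding"])
        lncs = [default_bundle.candidates[t] for t in sorted(manifest.subtypes)]
        cis = cis_targets(lncs, coding)
        trans = trans_targets(
            default_bundle.expression,
            sorted(manifest.subtypes),
            sorted(coding.gene_ids),
        )
        both = cis_trans_intersection(cis, trans)
        cis_keys = {(p.lnc_id, p.gene_id) for p in cis}
        trans_keys = {(p.lnc_id, p.gene_id) for p in trans}
        both_keys = {(p.lnc_id, p.gene_id) for p in both}
        assert both_keys <= cis_keys and both_keys <= trans_keys
        planted = {
            (p["lnc"], p["gene"]) for p in manifest.trans_pairs if p["cis"]
        }
        assert planted <= both_keys


class TestHolmSidak:
    def test_single_test_identity(self):
        assert holm_sidak([0.03])[0] == pytest.approx(0.03)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(41)
        p = rng.uniform(size=25)
        _, want, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(holm_sidak(p), want, atol=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, p):
        adj = holm_sidak(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDifferentialExpression:
    def test_identical_groups_nothing_significant(self):
        vals = np.tile([5.0, 6.0, 7.0], (10, 2))
        expr = _expr([f"t{i}" for i in range(10)], vals)
        de = differential_expression(expr)
        assert not de["significant"].any()

    def test_planted_large_shifts_recovered(self):
        """50 strongly shifted rows among 500: >= 90% flagged, false positives
        consistent with the FWER level."""
        rng = np.random.default_rng(43)
        ids = [f"t{i}" for i in range(500)]
        # with 3 samples per group the Welch t has 2-4 df, so surviving a
        # 500-test Holm-Sidak correction requires a clean two-orders-of-
        # magnitude shift
        vals = 10 ** rng.normal(0.5, 0.02, size=(500, 6))
        vals[:50, 3:] *= 100.0
        de = differential_expression(_expr(ids, vals))
        flagged = set(de.loc[de["significant"], "id"])
        planted = set(ids[:50])
        assert len(flagged & planted) >= 45
        assert len(flagged - planted) <= 2

    def test_zero_variance_equal_means_p_one(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4, 5, 6.0]])
        de = differential_expression(_expr(["flat", "x"], vals))
        row = de.set_index("id").loc["flat"]
        assert row["p_raw"] == 1.0 and row["t"] == 0.0

    def test_adjusted_p_never_below_raw(self, default_bundle):
        de = differential_expression(default_bundle.expression)
        assert (de["p_adj"] >= de["p_raw"] - 1e-12).all()


class TestEase:
    def test_single_gene_overlap_gives_p_one(self):
        frame = ease_enrichment(["a"], {"term": {"a"}}, ["a", "b", "c", "d"])
        assert frame.loc[0, "p"] == 1.0

    def test_total_containment_matches_enumeration(self):
        genes = [f"g{i}" for i in range(6)]
        frame = ease_enrichment(genes, {"term": set(genes)}, genes)
        # k=n=K=N=6: EASE reduces to P(X >= 5) with X ~ Hypergeom(6, 6, 6) = 1
        assert frame.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_fisher_k_minus_one_enumeration(self):
        """100 random configurations agree with exact hypergeometric
        enumeration of P(X >= k-1) to 1e-12."""
        rng = np.random.default_rng(47)
        for _ in range(100):
            N = int(rng.integers(20, 80))
            background = [f"g{i}" for i in range(N)]
            n = int(rng.integers(5, N // 2))
            K = int(rng.integers(3, N // 2))
            targets = list(rng.choice(background, size=n, replace=False))
            term = set(rng.choice(background, size=K, replace=False))
            frame = ease_enrichment(targets, {"t": term}, background)
            k = len(term & set(targets))
            if k <= 1:
                want = 1.0
            else:
                want = sum(
                    math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                    for i in range(k - 1, min(n, K) + 1)
                )
            assert frame.loc[0, "p"] == pytest.approx(min(1.0, want), abs=1e-12)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            ease_enrichment(["x"], {"t": {"x"}}, ["a", "b"])

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            ease_enrichment([], {"t": {"a"}}, [])
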