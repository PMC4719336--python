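"""The screening cascade: structural, known-class and consensus filters."""

from __future__ import annotations

import numpy as np
import pytest

from caprilnc import (
    AnnotationSet,
    CodingCallTable,
    ValidationError,
    consensus_noncoding,
    filter_known_classes,
    filter_structural,
    longest_orf,
    run_identification,
)
from conftest import make_transcript


class TestStructuralFilter:
    def test_length_boundary_199_removed_200_retained(self):
        just_under = make_transcript("u", "chr1", "+", [(0, 150), (200, 249)])  # 199 nt
        exactly = make_transcript("e", "chr1", "+", [(0, 150), (200, 250)])  # 200 nt
        survivors, report = filter_structural(AnnotationSet([just_under, exactly]))
        assert survivors.transcript_ids == ["e"]
        assert report.removed == {"u": "length"}

    def test_single_exon_removed(self):
        mono = make_transcript("m", "chr1", "+", [(0, 1000)])
        survivors, report = filter_structural(AnnotationSet([mono]))
        assert len(survivors) == 0
        assert report.removed == {"m": "exon_count"}

    def test_report_has_two_substeps_and_reconciles(self):
        ts = [make_transcript(f"t{i}", "chr1", "+", [(0, 150), (200, 350)]) for i in range(3)]
        _, report = filter_structural(AnnotationSet(ts))
        assert [s.name for s in report.steps] == ["exon_count", "length"]
        assert report.reconciles()

    def test_matches_brute_force_predicates(self):
        """Survivors equal the set selected by directly applying both
        predicates to 500 random transcripts."""
        rng = np.random.default_rng(5)
        ts = []
        for i in range(500):
            n_ex = int(rng.integers(1, 5))
            pos = int(rng.integers(0, 10_000))
            exons = []
            for _ in range(n_ex):
                ln = int(rng.integers(30, 300))
                exons.append((pos, pos + ln))
                pos += ln + int(rng.integers(50, 500))
            ts.append(make_transcript(f"t{i}", "chr1", "+", exons))
        survivors, report = filter_structural(AnnotationSet(ts))
        want = {t.transcript_id for t in ts if t.n_exons >= 2 and t.length >= 200}
        assert set(survivors.transcript_ids) == want
        assert report.reconciles()


class TestKnownClassFilter:
    def _candidate(self, strand="+", start=1000):
        return make_transcript("c", "chr1", strand, [(start, start + 150), (start + 400, start + 550)])

    def test_rRNA_overlap_removes_either_strand(self):
        ref = AnnotationSet(
            [make_transcript("r", "chr1", "-", [(1100, 1250)], biotype="rRNA")]
        )
        survivors, report = filter_known_classes(
            AnnotationSet([self._candidate("+")]), ref
        )
        assert len(survivors) == 0
        assert report.removed["c"] == "known_class:rRNA"

    def test_mRNA_opposite_strand_overlap_survives(self):
        """Antisense exonic overlap with a coding gene must not be removed here."""
        ref = AnnotationSet(
            [make_transcript("m", "chr1", "-", [(1100, 1250)], biotype="protein_coding")]
        )
        survivors, _ = filter_known_classes(AnnotationSet([self._candidate("+")]), ref)
        assert survivors.transcript_ids == ["c"]

    def test_mRNA_same_strand_overlap_removed(self):
        ref = AnnotationSet(
            [make_transcript("m", "chr1", "+", [(1100, 1250)], biotype="protein_coding")]
        )
        survivors, _ = filter_known_classes(AnnotationSet([self._candidate("+")]), ref)
        assert len(survivors) == 0

    def test_intron_only_overlap_survives(self):
        """Span overlap without exon contact (candidate inside an intron)."""
        ref = AnnotationSet(
            [
                make_transcript(
                    "m", "chr1", "+", [(0, 500), (5000, 5500)], biotype="protein_coding"
                )
            ]
        )
        survivors, _ = filter_known_classes(AnnotationSet([self._candidate("+")]), ref)
        assert survivors.transcript_ids == ["c"]

    def test_unstranded_candidate_rejected(self):
        bad = make_transcript("c", "chr1", ".", [(0, 150), (300, 450)])
        with pytest.raises(ValidationError):
            filter_known_classes(AnnotationSet([bad]), AnnotationSet())

    def test_bundle_removals_match_manifest(self, small_bundle):
        survivors, _ = filter_structural(small_bundle.candidates)
        survivors, report = filter_known_classes(survivors, small_bundle.reference)
        removed = set(report.removed)
        want = {
            tid
            for tid, fate in small_bundle.manifest.filter_fate.items()
            if fate == "known_class"
        }
        assert removed == want


class TestLongestOrf:
    def test_single_complete_orf(self):
        assert longest_orf("ATGAAATAG") == 9

    def test_no_start_codon(self):
        assert longest_orf("CCCCCC") == 0

    def test_start_without_stop_is_not_an_orf(self):
        assert longest_orf("ATGAAAAAA") == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            longest_orf("")

    def test_matches_exhaustive_codon_pair_scan(self):
        """100 random 1-kb sequences agree with a brute-force scan over every
        (start, first in-frame stop) pair."""

        def brute(seq: str) -> int:
            stops = {"TAA", "TAG", "TGA"}
            best = 0
            for i in range(len(seq) - 2):
                if seq[i : i + 3] != "ATG":
                    continue
                for j in range(i, len(seq) - 2, 3):
                    if seq[j : j + 3] in stops:
                        best = max(best, j + 3 - i)
                        break
            return best

        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(bases[rng.integers(0, 4, size=1000)])
            assert longest_orf(seq) == brute(seq)


class TestConsensus:
    def _candidates(self, n=4):
        return AnnotationSet(
            make_transcript(f"t{i}", "chr1", "+", [(i * 1000, i * 1000 + 150), (i * 1000 + 300, i * 1000 + 450)])
            for i in range(n)
        )

    def test_coding_in_any_tool_removes(self):
        cands = self._candidates(1)
        tables = [
            CodingCallTable(f"tool{k}", {"t0": "noncoding"}) for k in range(3)
        ] + [CodingCallTable("tool3", {"t0": "coding"})]
        survivors, report = consensus_noncoding(cands, tables)
        assert len(survivors) == 0
        assert report.removed["t0"] == "coding_potential:tool3"

    def test_noncoding_in_all_tools_retained(self):
        cands = self._candidates(1)
        tables = [CodingCallTable(f"tool{k}", {"t0": "noncoding"}) for k in range(4)]
        survivors, _ = consensus_noncoding(cands, tables)
        assert survivors.transcript_ids == ["t0"]

    def test_matches_set_intersection_oracle(self):
        """Randomized verdict tables over 200 ids agree with the explicit
        intersection of the per-tool noncoding sets."""
        rng = np.random.default_rng(23)
        ids = [f"t{i}" for i in range(200)]
        cands = AnnotationSet(
            make_transcript(t, "chr1", "+", [(i * 10_000, i * 10_000 + 150), (i * 10_000 + 300, i * 10_000 + 500)])
            for i, t in enumerate(ids)
        )
        tables = [
            CodingCallTable(
                f"tool{k}",
                {t: ("noncoding" if rng.random() < 0.8 else "coding") for t in ids},
            )
            for k in range(4)
        ]
        survivors, _ = consensus_noncoding(cands, tables)
        want = set(ids)
        for tbl in tables:
            want &= {t for t, v in tbl.verdicts.items() if v == "noncoding"}
        assert set(survivors.transcript_ids) == want

    def test_missing_id_removed_as_unscored(self):
        cands = self._candidates(1)
        survivors, report = consensus_noncoding(
            cands, [CodingCallTable("tool", {})]
        )
        assert len(survivors) == 0
        assert "unscored" in report.removed["t0"]

    def test_builtin_heuristic_when_no_tables(self):
        cands = self._candidates(2)
        seqs = {
            "t0": "ATG" + "GCA" * 110 + "TAA" + "C" * 50,  # 336-nt ORF: coding
            "t1": "C" * 300,  # no ORF: noncoding
        }
        survivors, report = consensus_noncoding(cands, sequences=seqs)
        assert survivors.transcript_ids == ["t1"]
        assert report.removed["t0"] == "coding_potential:builtin_orf"


class TestCascade:
    def test_order_stability_of_per_transcript_filters(self, small_bundle):
        """Running structural before or after the known-class filter yields
        the same survivor set, and both reports reconcile."""
        a1, r1 = filter_structural(small_bundle.candidates)
        a1, r1b = filter_known_classes(a1, small_bundle.reference)
        b1, r2 = filter_known_classes(small_bundle.candidates, small_bundle.reference)
        b1, r2b = filter_structural(b1)
        assert set(a1.transcript_ids) == set(b1.transcript_ids)
        assert r1.reconciles() and r2.reconciles()

    def test_full_cascade_recovers_manifest_truth(self, small_bundle):
        survivors, report = run_identification(
            small_bundle.candidates,
            small_bundle.reference,
            sequences=small_bundle.sequences,
        )
        fates = small_bundle.manifest.filter_fate
        assert set(survivors.transcript_ids) == {
            t for t, f in fates.items() if f == "pass"
        }
        for tid, reason in report.removed.items():
            assert reason.split(":")[0] == fates[tid], (tid, reason)
        assert report.reconciles()
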