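"""Shared fixtures: synthetic bundles and small hand-built annotation objects."""

from __future__ import annotations

import pytest

from caprilnc import (
    AnnotationSet,
    GenomicInterval,
    SimulationConfig,
    TranscriptModel,
    simulate_bundle,
)

#: Fixed seed of the standard study bundle used across the suite.
BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study bundle: 200 coding genes, 60/20/12 subtypes, 40 decoys."""
    return simulate_bundle(SimulationConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for fast structural tests."""
    return SimulationConfig(
        seed=11,
        n_chroms=1,
        chrom_length=1_200_000,
        n_coding_genes=60,
        n_linc=15,
        n_antisense=5,
        n_intronic=4,
        n_decoy_monoexon=3,
        n_decoy_short=3,
        n_decoy_coding=3,
        n_housekeeping_decoys=3,
        n_planted_trans_pairs=3,
        n_planted_cis_trans=2,
        n_planted_de=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


def make_transcript(
    tid: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    biotype: str = "candidate",
    gene_id: str | None = None,
) -> TranscriptModel:
    """Convenience constructor used throughout the unit tests."""
    return TranscriptModel(
        tid,
        gene_id or tid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype,
    )


@pytest.fixture
def coding_gene():
    """A 3-exon '+' strand coding gene on chr1: exons [1000,1200), [2000,2300),
    [4000,4200); introns [1200,2000) and [2300,4000)."""
    return make_transcript(
        "g1.t1",
        "chr1",
        "+",
        [(1000, 1200), (2000, 2300), (4000, 4200)],
        biotype="protein_coding",
        gene_id="g1",
    )


@pytest.fixture
def coding_set(coding_gene):
    return AnnotationSet([coding_gene])
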