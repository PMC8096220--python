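"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from polpause import GenomeAnnotation, Gene
from polpause import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated data set reused across modules (seed 42)."""
    cfg = sim.SimConfig(seed=42, genome_length=200_000, n_genes=10)
    genome = sim.simulate_genome(cfg)
    ann = sim.simulate_annotation(cfg)
    tracks, truth = sim.simulate_occupancy(cfg, ann, genome)
    return cfg, genome, ann, tracks, truth


@pytest.fixture(scope="session")
def random_genome():
    """One 50-kb random contig for sequence-feature tests."""
    cfg = sim.SimConfig(seed=7, genome_length=50_000)
    return sim.simulate_genome(cfg)


@pytest.fixture()
def hand_annotation():
    """Hand-built two-gene-pair annotation exercising every category.

    Layout on a 100-kb contig:

    * geneA (+): TSS 10000, pA 19999, exons [10000,12000) [14000,16000)
      [18000,20000) — multi-exon sense gene.
    * geneB (-): TSS 39999, pA 30000, exons [30000,33000) [36000,40000).
    * geneC (+): body 60000-69999, single isoform, overlapped by
    * geneD (-): TSS 74999, pA 65000 — C's body overlaps D's antisense
      region and vice versa (conflict locus).
    * enhancer [90000, 90400).
    """
    genes = {
        "geneA": Gene("geneA", "chr1", "+", [10_000], [19_999],
                      [(10_000, 12_000), (14_000, 16_000), (18_000, 20_000)]),
        "geneB": Gene("geneB", "chr1", "-", [39_999], [30_000],
                      [(30_000, 33_000), (36_000, 40_000)]),
        "geneC": Gene("geneC", "chr1", "+", [60_000], [69_999],
                      [(60_000, 70_000)]),
        "geneD": Gene("geneD", "chr1", "-", [74_999], [65_000],
                      [(65_000, 75_000)]),
    }
    return GenomeAnnotation(genes, {"chr1": 100_000},
                            {"chr1": [(90_000, 90_400)]})


class Site:
    """Minimal site object (contig, strand, position[, count])."""

    def __init__(self, contig, strand, position, count=1):
        self.contig = contig
        self.strand = strand
        self.position = position
        self.count = count

    @property
    def key(self):
        return (self.contig, self.strand, self.position)


@pytest.fixture()
def make_site():
    return Site
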