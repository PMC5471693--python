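import numpy as np
import pandas as pd
import pytest

from aphidx import GeneModel, GenomeAnnotation, SimConfig
from aphidx.simulate import simulate_annotation, simulate_counts, simulate_faire_and_control


def make_annotation(scaffolds, chrom_class, genes):
    ann = GenomeAnnotation(scaffolds=dict(scaffolds), chrom_class=dict(chrom_class),
                           genes=list(genes))
    ann.validate()
    return ann


def simple_gene(gid, scaffold, strand, start, end, utr5=None, utr3=None, cds=None):
    """A single-exon gene covering [start, end); optional explicit substructure."""
    return GeneModel(gid, scaffold, strand, start, end,
                     exons=[(start, end)], cds=cds or [], utr5=utr5 or [], utr3=utr3 or [])


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=0, n_genes_A=120, n_genes_X=80, scaffold_length=700_000,
                     lib_sizes=(400_000, 500_000, 450_000, 420_000, 480_000, 460_000),
                     n_frags_faire=200_000, n_frags_control=120_000,
                     n_intergenic_sites=30)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    ann = simulate_annotation(small_cfg)
    expr, truth = simulate_counts(ann, small_cfg)
    return ann, expr, truth


@pytest.fixture(scope="session")
def small_faire(small_cfg, small_sim):
    ann, _expr, truth = small_sim
    return simulate_faire_and_control(ann, truth, small_cfg)
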