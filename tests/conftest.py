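"""Shared fixtures: a small synthetic genome and a default dataset."""

import numpy as np
import pytest

from cichlidvar.core import GeneModel, GenomeAnnotation
from cichlidvar.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_lg=2, lg_length=500_000, n_genes=30)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(), seed=7)


@pytest.fixture()
def toy_annotation():
    """Hand-built two-gene annotation with a known sequence.

    LG1 (20 kb): gene fwd1 on + strand, CDS 101-109 = ATG GGA TAA;
    gene rev1 on - strand, CDS 15001-15009 spelling ATG CCT TGA on the
    minus strand.  One TE interval covers 1-based 12001-12100.
    """
    L = 20_000
    seq = list("A" * L)
    seq[100:109] = list("ATGGGATAA")
    # minus-strand CDS: sense ATGCCTTGA -> genome carries its reverse complement
    seq[15_000:15_009] = list("TCAAGGCAT")
    genes = [
        GeneModel("fwd1", "LG1", "+", exons=[(101, 109)], cds=[(101, 109)]),
        GeneModel("rev1", "LG1", "-", exons=[(15_001, 15_009)],
                  cds=[(15_001, 15_009)]),
    ]
    return GenomeAnnotation(
        lg_lengths={"LG1": L},
        genes=genes,
        te_intervals=[("LG1", 12_000, 12_100)],
        sequences={"LG1": "".join(seq)},
    )
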