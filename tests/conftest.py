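import numpy as np
import pandas as pd
import pytest

from octomap import pipeline, simulate


@pytest.fixture(scope="session")
def midcross(tmp_path_factory):
    """A compact simulated cross run through the whole pipeline.

    32 progeny over 150 genes keeps the run fast while leaving enough
    markers (~300) to exercise calling, QC, binning and mapping; the
    minimum-genotyped threshold is scaled to the population size.
    """
    cfg = simulate.SimConfig(seed=13, n_progeny=32, n_genes=150, snps_per_gene=2.0)
    out = tmp_path_factory.mktemp("midcross")
    return pipeline.run_cross_pipeline(cfg, out, min_genotyped=21)


@pytest.fixture(scope="session")
def midcross_truth(midcross):
    return midcross.dataset.truth


def presence_from_gametes(rng, ploidy, length_cm, positions_cm, n_meioses,
                          carrier=0):
    """Presence matrix (positions x meioses) of a simplex allele on ``carrier``."""
    cols = []
    for _ in range(n_meioses):
        src = simulate.gamete_sources(rng, ploidy, length_cm,
                                      np.asarray(positions_cm, float))
        cols.append((src == carrier).any(axis=0))
    return np.column_stack(cols).astype(np.int8)


@pytest.fixture
def gamete_presence():
    return presence_from_gametes
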