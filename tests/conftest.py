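import numpy as np
import pandas as pd
import pytest

from topotx.normalization import ExpressionMatrix
from topotx.synthetic import MutantSpec, SimulationConfig, simulate_arrays, simulate_genome


@pytest.fixture
def small_config():
    """A quick two-strain configuration with every planted effect switched on."""
    return SimulationConfig(
        seed=7,
        n_genes=400,
        n_spikeins=24,
        n_replicates=3,
        mutants={"mut": MutantSpec(global_scale=0.7, effect_scale=1.0)},
    )


@pytest.fixture
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture
def small_arrays(small_config, small_genome):
    return simulate_arrays(small_config, small_genome.annotation)


def make_matrix(intensities: np.ndarray, spikein_rows, strains_reps) -> ExpressionMatrix:
    """Hand-built ExpressionMatrix for arithmetic tests.

    ``strains_reps`` is a list of (strain, replicate) per column.
    """
    n = intensities.shape[0]
    gene_ids = [f"s{i}" if i in set(spikein_rows) else f"g{i}" for i in range(n)]
    cols = [f"{s}_{r}" for s, r in strains_reps]
    frame = pd.DataFrame(intensities, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    spikein = pd.Series([i in set(spikein_rows) for i in range(n)], index=frame.index)
    arrays = pd.DataFrame(
        {"strain": [s for s, _ in strains_reps], "replicate": [r for _, r in strains_reps]},
        index=pd.Index(cols, name="array"),
    )
    return ExpressionMatrix(intensities=frame, spikein=spikein, arrays=arrays)
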