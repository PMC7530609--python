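import numpy as np
import pytest

import chromsink as cs


@pytest.fixture(scope="session")
def genome():
    """Default toy genome, shared across tests (read-only)."""
    return cs.build_genome_model(seed=1)


@pytest.fixture(scope="session")
def sink():
    return cs.SinkModel()


@pytest.fixture(scope="session")
def xy_experiment(genome, sink):
    """One wildtype-male spike-in experiment with sampling noise."""
    return cs.simulate_chip_experiment(genome, cs.XY, sink, seed=7, depth=10**6)


def make_track(values, width=10, chrom="chr1"):
    """Helper: contiguous fixed-width windows on one chromosome."""
    import pandas as pd

    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(len(values)) * width,
        "end": (np.arange(len(values)) + 1) * width,
        "value": values,
    })
    return cs.WindowTrack(frame)
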