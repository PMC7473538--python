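import numpy as np
import pandas as pd
import pytest

from spcnorm import SpectralCountMatrix, SpikeInConfig, simulate_spikein


def make_matrix(counts, runs=None, proteins=None, conditions=None, pairs=None, lengths=None):
    """Small hand-built SpectralCountMatrix for unit tests."""
    counts = np.asarray(counts, dtype=float)
    n_prot, n_runs = counts.shape
    proteins = proteins or [f"prot{i}" for i in range(n_prot)]
    runs = runs or [f"run{j}" for j in range(n_runs)]
    conditions = conditions or {r: "c" for r in runs}
    pairs = pairs or {r: r for r in runs}
    meta = pd.DataFrame(
        {
            "condition": [conditions[r] for r in runs],
            "replicate": list(range(1, n_runs + 1)),
            "pair": [pairs[r] for r in runs],
        },
        index=pd.Index(runs, name="run_id"),
    )
    lengths_s = None if lengths is None else pd.Series(lengths, index=proteins)
    return SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=proteins, columns=runs),
        run_meta=meta,
        lengths=lengths_s,
    )


@pytest.fixture(scope="session")
def spikein_default():
    """Default spike-in benchmark at the canonical seed, shared per session."""
    return simulate_spikein(SpikeInConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
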