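import numpy as np
import pytest

from duptrace.io import Alignment
from duptrace.simulate import SimConfig, simulate_family

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n_seqs: int,
    n_cols: int,
    gap_frac: float = 0.0,
    n_frac: float = 0.0,
) -> Alignment:
    """Uniform random alignment with optional gaps and Ns."""
    chars = np.array(list(BASES), dtype="<U1")
    arr = chars[rng.integers(4, size=(n_seqs, n_cols))]
    if gap_frac > 0:
        arr[rng.random(arr.shape) < gap_frac] = "-"
    if n_frac > 0:
        arr[rng.random(arr.shape) < n_frac] = "N"
    ids = [f"s{i:03d}" for i in range(n_seqs)]
    return Alignment(ids, ["".join(row) for row in arr])


@pytest.fixture(scope="session")
def no_process_family():
    """Family with no substitutions and no conversion: founder states persist."""
    cfg = SimConfig(
        n_species=6,
        seq_len=60,
        k_diag=8,
        sub_rate=0.0,
        conv_rate=0.0,
        dropout_p=0.0,
        seed=11,
    )
    return cfg, simulate_family(cfg)


@pytest.fixture(scope="session")
def default_family():
    """One family under the default study conditions (no conversion)."""
    cfg = SimConfig(seed=1)
    return cfg, simulate_family(cfg)


@pytest.fixture(scope="session")
def eroded_family():
    """Heavily homogenized family: high conversion rate, long run."""
    cfg = SimConfig(conv_rate=5.0, tract_mean=50.0, seed=7)
    return cfg, simulate_family(cfg)
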