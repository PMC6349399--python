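import numpy as np
import pandas as pd
import pytest

from silacq.synthetic import SimulationConfig


@pytest.fixture
def small_config():
    """Small mixed-class simulation used by several module tests."""
    return SimulationConfig(n_genes=200, seed=11)


@pytest.fixture
def noiseless_config():
    """Noise-free, mislabel-free simulation: downstream estimates must
    recover the generator truth exactly (up to float round-trip)."""
    return SimulationConfig(
        n_genes=200,
        peptide_noise_sd=0.0,
        rna_noise_sd=0.0,
        mislabel_fraction=0.0,
        flag_fraction=0.0,
        seed=5,
    )


def make_psm_frame(rows):
    """Canonical in-memory PSM frame from (gene, flags, hl_ratio, replicate)
    tuples, matching what silacq.psm.read_psm_table produces."""
    return pd.DataFrame(
        {
            "peptide": [f"PEP{i}" for i in range(len(rows))],
            "gene": [r[0] for r in rows],
            "flags": [frozenset(r[1]) for r in rows],
            "hl_ratio": [r[2] for r in rows],
            "heavy": np.nan,
            "light": np.nan,
            "replicate": [r[3] for r in rows],
        }
    )
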