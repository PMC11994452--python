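import warnings

import numpy as np
import pytest

from afmap.simulate import SimConfig, generate_multiome


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """Desk-scale simulation used by most integration-style tests."""
    kwargs = dict(
        seed=seed,
        nuclei_per_donor=150,
        n_genes=700,
        n_peaks=900,
        n_motifs=12,
        markers_per_celltype=10,
        bulk_n_samples=25,
        module_size=50,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_multiome():
    """One shared small multiome draw: (config, gene_counts, peak_counts,
    nuclei, peaks, gc, membership, truth)."""
    cfg = small_config(seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = generate_multiome(cfg)
    return (cfg, *out)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
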