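import numpy as np
import pytest

from odorvs.featurize import compute_gs_vs_batch
from odorvs.synthetic import SyntheticConfig, generate_label_matrix, generate_spectra


@pytest.fixture(scope="session")
def small_dataset():
    """200 molecules, 6 classes: labels, spectra and GS_VS matrix."""
    cfg = SyntheticConfig(n_molecules=200, n_classes=6, seed=7)
    labels = generate_label_matrix(cfg)
    spectra = generate_spectra(labels, cfg)
    gsvs = compute_gs_vs_batch(spectra)
    return cfg, labels, spectra, gsvs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
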