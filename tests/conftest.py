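import os

# pin BLAS to one thread before numpy loads: keeps CNN training and the
# seed-pinned acceptance results bit-identical across machines
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from ramanqc import synth
from ramanqc.spectra import SpectraMatrix


@pytest.fixture(scope="session")
def small_axis():
    return synth.default_axis(resolution=20.0)  # 167 channels, fast


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix(small_axis, rng):
    n = 12
    intensities = np.abs(rng.normal(1.0, 0.3, size=(n, small_axis.size)))
    ids = [f"s{i}" for i in range(n)]
    return SpectraMatrix(small_axis, intensities, ids)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 batches, 2 replicates, coarse axis: quick but full-featured."""
    cfg = synth.GeneratorConfig(
        n_batches=2, replicates=2, drop_last=False,
        outliers=synth.OutlierSpec(count=2), axis_resolution=20.0)
    return synth.generate_dataset(cfg, seed=42)


def make_mixture(n_samples, n_channels, n_components=5, seed=0, noise_sd=0.0):
    """Low-rank nonnegative linear mixtures globally scaled to [0, 1].

    Returns (X, concentrations, profiles); X rows are Sum_k c_k * profile_k
    divided by the global max, so any y linear in the concentrations is
    linear in X as well.
    """
    rng = np.random.default_rng(seed)
    profiles = np.abs(rng.normal(size=(n_components, n_channels)))
    conc = rng.uniform(0.2, 1.0, size=(n_samples, n_components))
    X = conc @ profiles
    if noise_sd:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = X / X.max()
    return X, conc, profiles
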