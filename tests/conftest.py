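import numpy as np
import pytest

from nirleaf import GeneratorSpec, simulate_labeled_set, simulate_leaf_cube
from nirleaf.spectra_io import LabeledSet, SpectrumMatrix, default_wavelength_grid

#: K-element training-design class counts (VL..VH), mu ~ 9.97.
K_TRAIN_COUNTS = (29, 131, 185, 289, 116)


@pytest.fixture(scope="session")
def wavelengths():
    return default_wavelength_grid()


@pytest.fixture(scope="session")
def small_labeled():
    """A small balanced labeled set with clear class signal."""
    spec = GeneratorSpec(class_counts=(12, 12, 12, 12, 12), effect_size=4.0,
                         seed=11)
    return simulate_labeled_set(spec)


@pytest.fixture(scope="session")
def skewed_labeled():
    """Reference-design imbalanced labeled set (K training counts)."""
    spec = GeneratorSpec(class_counts=K_TRAIN_COUNTS, effect_size=3.0, seed=5)
    return simulate_labeled_set(spec)


@pytest.fixture(scope="session")
def leaf_cube():
    spec = GeneratorSpec(class_counts=(10,) * 5, effect_size=3.0, seed=21)
    return simulate_leaf_cube(spec, 40, 56, class_label=2, vein_fraction=0.3)


@pytest.fixture(scope="session")
def unlabeled_pool():
    """Unlabeled spectra drawn from the same population (labels dropped)."""
    spec = GeneratorSpec(class_counts=(60, 60, 60, 60, 60), effect_size=3.0,
                         seed=31)
    return simulate_labeled_set(spec).spectra


def toy_labeled(values, labels, wavelengths=None):
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float)
    return LabeledSet(SpectrumMatrix(values, wavelengths),
                      np.asarray(labels, dtype=int))
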