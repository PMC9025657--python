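import numpy as np
import pandas as pd
import pytest

from spectperf import atlas as atl
from spectperf import datasets


@pytest.fixture(scope="session")
def regions():
    return datasets.load_atlas()


@pytest.fixture(scope="session")
def pi_interictal():
    return datasets.load_perfusion("interictal")


@pytest.fixture(scope="session")
def pi_ictal():
    return datasets.load_perfusion("ictal")


@pytest.fixture(scope="session")
def thresholds():
    return datasets.load_thresholds()


@pytest.fixture(scope="session")
def subjects():
    return datasets.load_subjects()


def make_two_region_table():
    """Minimal bilateral atlas: one name code on each side."""
    return pd.DataFrame({
        "region_id": [1, 2],
        "name": ["R1", "R1"],
        "hemisphere": ["left", "right"],
        "group": ["temporal", "temporal"],
        "is_gray": [True, True],
    })


def make_slab_volume(shape=(8, 6, 6), split=4):
    """Two adjacent slabs along x: label 1 left of the split, 2 right."""
    labels = np.zeros(shape, dtype=np.int32)
    labels[:split] = 1
    labels[split:] = 2
    return atl.LabelVolume(labels, (1.0, 1.0, 1.0))


@pytest.fixture
def slab_volume():
    return make_slab_volume()


@pytest.fixture
def slab_regions():
    return make_two_region_table()


def direct_gaussian_blur(volume, fwhm_mm, voxel_size_mm):
    """Independent dense-summation convolution oracle (reflective boundary).

    Builds the same truncated sampled-Gaussian kernel convention as the
    implementation but applies it by explicit padded summation, axis by
    axis, with no shared code path.
    """
    out = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return out.copy()
    sigma_scale = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for axis, vox in enumerate(voxel_size_mm):
        sigma = fwhm_mm * sigma_scale / vox
        radius = int(np.ceil(4.0 * sigma))
        x = np.arange(-radius, radius + 1, dtype=float)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        moved = np.moveaxis(out, axis, 0)
        padded = np.pad(moved, [(radius, radius)] + [(0, 0)] * (moved.ndim - 1),
                        mode="symmetric")
        acc = np.zeros_like(moved)
        for off, w in enumerate(kernel):
            acc += w * padded[off:off + moved.shape[0]]
        out = np.moveaxis(acc, 0, axis)
    return out
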