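import numpy as np
import pytest

from brachymetrics import BinaryMask, LabeledVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def small_labelmap(rng):
    """Random 8x8x4 label map with labels 0..3, spacing (1, 1, 3) mm."""
    labels = rng.integers(0, 4, size=(8, 8, 4)).astype(np.int32)
    return LabeledVolume(labels=labels, spacing=(1.0, 1.0, 3.0),
                         label_names={1: "CTV_HR", 2: "bladder", 3: "rectum"})


def make_mask(arr, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(mask=np.asarray(arr, dtype=bool), spacing=spacing)


@pytest.fixture
def phantom_pair():
    """Seeded phantom with near- and far-band predictions of the rectum."""
    from brachymetrics import (PerturbSpec, default_phantom_spec,
                               euclidean_distance_map, extract_binary,
                               generate_phantom, perturb_prediction)
    gt, dwells = generate_phantom(default_phantom_spec(seed=7))
    dist = euclidean_distance_map(extract_binary(gt, 1))
    near = perturb_prediction(gt, "rectum", PerturbSpec(0.1, "near", "dilate", seed=7),
                              dist=dist)
    far = perturb_prediction(gt, "rectum", PerturbSpec(0.1, "far", "dilate", seed=7),
                             dist=dist)
    return gt, dwells, dist, near, far
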