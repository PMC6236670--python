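import numpy as np
import pytest

from neuroquant import make_label_phantom
from neuroquant.phantom import GroundTruth


@pytest.fixture(scope="session")
def atlas():
    return make_label_phantom((32, 32, 16), rng_seed=1)


@pytest.fixture(scope="session")
def truth_clean():
    return GroundTruth(sigma_mri=0.0, sigma_pet=0.0)


@pytest.fixture(scope="session")
def truth_noisy():
    return GroundTruth()  # defaults: SNR 40 MRI, additive PET noise


def paint(atlas, value_of):
    """Paint a per-(region, hemisphere) scalar into the atlas geometry."""
    out = np.zeros(atlas.labels.shape)
    for lab, (region, hemi) in atlas.legend.items():
        out[atlas.labels == lab] = value_of(region, hemi)
    return out


@pytest.fixture(scope="session")
def true_maps(atlas, truth_clean):
    t = truth_clean
    return {
        "ADC": paint(atlas, lambda r, h: t.get(t.adc, r, h)),
        "T1s": paint(atlas, t.t1_selective),
        "T1ns": paint(atlas, t.t1_ns),
        "K1": paint(atlas, t.k1),
        "SUV": paint(atlas, lambda r, h: t.get(t.suv, r, h)),
    }
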