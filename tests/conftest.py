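import numpy as np
import pytest

from amypetseg import (
    ThresholdRule,
    background_level,
    default_spec,
    extract_slices,
    generate_phantom,
    make_ground_truth,
    normalize_to_pons,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Piecewise-constant phantom: no blur, no noise, uptake ratio 2.0."""
    spec = default_spec(noise_sigma=0.0, psf_fwhm_mm=0.0, uptake_ratio=2.0, seed=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study-condition phantom: 3 mm PSF, sigma 0.05 noise."""
    return generate_phantom(default_spec(seed=1))


@pytest.fixture(scope="session")
def training_slices(noisy_phantom):
    """Pons-normalized axial slices through the frontal zone with truth masks."""
    ph = noisy_phantom
    norm, _ = normalize_to_pons(ph.volume, ph.pons_mask)
    bg = background_level(norm, ph.background_mask)
    truth = make_ground_truth(
        norm, ph.zone_masks["frontal"], ThresholdRule(1.5), background=bg
    )
    occupancy = ph.zone_masks["frontal"].data.sum(axis=(0, 1))
    idx = np.nonzero(occupancy)[0]
    X = np.stack(extract_slices(norm, "axial", idx))
    y = np.stack(extract_slices(truth.data.astype(np.uint8), "axial", idx))
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
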