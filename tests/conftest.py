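"""Shared phantom fixtures. Everything is generated in-process and cached per
session; grids are kept small so the full suite stays fast."""

import numpy as np
import pytest

from vbmcase import phantom as ph
from vbmcase.segmentation import segment_em


@pytest.fixture(scope="session")
def template():
    return ph.build_template((48, 48, 48), voxel_size_mm=1.5)


@pytest.fixture(scope="session")
def clean_subject(template):
    """Noise-free, bias-free, undeformed subject: images equal class means."""
    rec = ph.SubjectRecord(id="clean", group="control", age=30.0, seed=1)
    var = ph.VariabilitySpec(
        deformation_amplitude_mm=0.0, bias_amplitude=0.0, bias_order=0,
        noise_sd_t1=0.0, noise_sd_flair=0.0,
    )
    return ph.sample_subject(template, rec, var)


@pytest.fixture(scope="session")
def noisy_subject(template):
    """Default-variability subject (2-mm warp, bias field, noise)."""
    rec = ph.SubjectRecord(id="noisy", group="control", age=41.0, seed=42)
    return ph.sample_subject(template, rec, ph.VariabilitySpec())


@pytest.fixture(scope="session")
def noisy_seg(noisy_subject):
    return segment_em(noisy_subject.t1, bias_order=2)


@pytest.fixture(scope="session")
def clean_seg(clean_subject):
    return segment_em(clean_subject.t1, bias_order=0)


@pytest.fixture(scope="session")
def smooth_map_stack():
    """Stack of 21 smoothed unit-noise maps on a 24^3 grid (null 'feature maps')."""
    rng = np.random.default_rng(7)
    from scipy import ndimage as ndi

    maps = rng.standard_normal((21, 24, 24, 24))
    for i in range(len(maps)):
        maps[i] = ndi.gaussian_filter(maps[i], 2.0, mode="constant")
    return maps
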