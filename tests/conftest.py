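import dataclasses

import numpy as np
import pytest

from netquant.image_model import ImageField, SegmentationParams
from netquant.synth import SceneSpec, calibration_field, get_preset
from netquant.thresholding import calibrate_chromatin_threshold


def make_image(pixels, channel="dna", bit_depth=8, **kw) -> ImageField:
    return ImageField(
        pixels=np.asarray(pixels), bit_depth=bit_depth, channel=channel, **kw
    )


@pytest.fixture(scope="session")
def calibrated_threshold() -> int:
    """Chromatin threshold calibrated once on a 10-min-activation field."""
    return calibrate_chromatin_threshold(calibration_field(seed=11)).threshold


@pytest.fixture(scope="session")
def calibrated_params(calibrated_threshold) -> SegmentationParams:
    return SegmentationParams(chromatin_threshold=calibrated_threshold)


@pytest.fixture
def small_scene() -> SceneSpec:
    """A quick-to-render field: 35 resting + 15 NETotic cells in 512x512."""
    return dataclasses.replace(
        get_preset("pma_2h"), shape=(512, 512), n_resting=35, n_netotic=15, seed=101
    )
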