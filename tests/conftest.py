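import dataclasses

import numpy as np
import pytest

from retimorph import (SyntheticSpec, extract_centrelines, generate_retina,
                       segment_vessels)


@pytest.fixture(scope="session")
def default_retina():
    """One default 512x512 synthetic retina (image, ground truth)."""
    return generate_retina(SyntheticSpec.default(seed=0))


@pytest.fixture(scope="session")
def small_retina():
    """A 256x256 synthetic retina for fast tests."""
    return generate_retina(SyntheticSpec.default((256, 256), seed=3))


@pytest.fixture(scope="session")
def segmented_default(default_retina):
    """(image, truth, mask, centreline graph) for the default retina."""
    img, truth = default_retina
    mask = segment_vessels(img, fovea_centre=truth.fovea_centre)
    graph = extract_centrelines(mask)
    return img, truth, mask, graph


def make_retina(seed, regime="normal", size=512, **overrides):
    spec = dataclasses.replace(SyntheticSpec.default((size, size), seed=seed),
                               profile_regime=regime, **overrides)
    return generate_retina(spec)
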