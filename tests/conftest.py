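import numpy as np
import pytest

from flickerscope.segmentation import (AcceptanceCriteria, detect_and_filter,
                                       preprocess)
from flickerscope.synthetic import generate_field_scene, make_default_scene
from flickerscope.thermal import ThermalContext

PIXEL_SIZE_FIELD = 0.103e-6  # m/px


@pytest.fixture(scope="session")
def thermal():
    return ThermalContext()


@pytest.fixture(scope="session")
def default_scene():
    """Rendered 9-cell fixture scene (seed 3) with its manifest."""
    spec = make_default_scene(seed=3)
    img, manifest = generate_field_scene(spec)
    return img, manifest


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    """Preprocessed frame plus acceptance results for the fixture scene."""
    img, manifest = default_scene
    frame = preprocess(img)
    accepted, log = detect_and_filter(frame, AcceptanceCriteria(),
                                      PIXEL_SIZE_FIELD)
    return frame, manifest, accepted, log


def match_log_to_manifest(log, manifest):
    """Map each evaluated component to the nearest planted cell index."""
    out = {}
    for rec in log:
        dists = [np.hypot(rec.centroid[0] - m["center"][0],
                          rec.centroid[1] - m["center"][1]) for m in manifest]
        out[int(np.argmin(dists))] = rec.status
    return out
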