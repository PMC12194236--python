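import math

import numpy as np
import pytest

from flla import LimbAnnotation, Point2D

from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_photo(delta_deg=0.0, side="right", tibia_len=400.0, femur_len=400.0):
    """Photograph annotation with a pure tibial-axis rotation of delta (varus > 0)."""
    knee = np.array([0.0, tibia_len])
    asis = Point2D(0.0, tibia_len + femur_len)
    t = math.radians(delta_deg)
    ankle = knee + tibia_len * np.array([math.sin(t), -math.cos(t)])
    return LimbAnnotation(
        side=side,
        modality="photograph",
        landmarks={
            "ASIS": asis,
            "MED_CONDYLE": Point2D(knee[0] + 50.0, knee[1]),
            "LAT_CONDYLE": Point2D(knee[0] - 50.0, knee[1]),
            "MED_MALLEOLUS": Point2D(ankle[0] + 30.0, ankle[1]),
            "LAT_MALLEOLUS": Point2D(ankle[0] - 30.0, ankle[1]),
        },
    )


def make_radio(delta_deg=0.0, fma_fta_deg=3.0, side="right", tibia_len=400.0, femur_len=400.0):
    """Radiograph annotation with tibial rotation delta and topographic offset."""
    notch = np.array([0.0, tibia_len])
    t = math.radians(delta_deg)
    tib_dir = np.array([math.sin(t), -math.cos(t)])
    f = math.radians(fma_fta_deg)
    asis = notch - (femur_len + 80.0) * np.array([math.sin(f), -math.cos(f)])
    return LimbAnnotation(
        side=side,
        modality="radiograph",
        landmarks={
            "ASIS": Point2D(*asis),
            "FEMORAL_HEAD_CENTER": Point2D(0.0, tibia_len + femur_len),
            "FEMORAL_NOTCH_CENTER": Point2D(*notch),
            "TIBIAL_EMINENCE_CENTER": Point2D(*(notch + 8.0 * tib_dir)),
            "ANKLE_ARTICULAR_CENTER": Point2D(*(notch + tibia_len * tib_dir)),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250614)
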