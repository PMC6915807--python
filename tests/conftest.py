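import numpy as np
import pytest

from bodymap import (
    Affect,
    AvatarSettings,
    BodyMeasurements,
    Cohort,
    ConcernEntry,
    SubjectRecord,
)


def square(x0, y0, side):
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


@pytest.fixture
def small_cohort():
    """Two groups, mixed optional blocks, valid by construction."""
    subjects = [
        SubjectRecord(
            id="a-0",
            group="a",
            concerns=[
                ConcernEntry(
                    polygon=square(4, 4, 10),
                    concern_types=["bloated"],
                    affects=[Affect("frustrated"), Affect("hopeful")],
                    intensity=40.0,
                )
            ],
            avatar=AvatarSettings(sliders={"waist": 0.5, "thighs": 0.25}),
            measured=BodyMeasurements(
                sizes_cm={"shoulders": 33, "bust": 82, "biceps": 24, "waist": 68,
                          "hips": 91, "thighs": 44, "calves": 35}
            ),
            demographics={"age": 24.0, "height_cm": 170.0, "weight_kg": 58.0,
                          "bmi": round(58.0 / 1.70**2, 2)},
        ),
        SubjectRecord(id="a-1", group="a", concerns=[]),
        SubjectRecord(
            id="b-0",
            group="b",
            concerns=[ConcernEntry(polygon=square(20, 20, 8), intensity=10.0)],
        ),
    ]
    return Cohort(subjects=subjects, raster_dims=(64, 64))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masks(rng, n, shape=(16, 12), density=0.4):
    return [(rng.random(shape) < density).astype(np.uint8) for _ in range(n)]
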