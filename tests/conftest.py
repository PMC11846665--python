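import numpy as np
import pytest

from kneedxa import GraderConfig, LandmarkSet, Side


@pytest.fixture(scope="session")
def cfg() -> GraderConfig:
    return GraderConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_landmarks(rng: np.random.Generator, subject_id: str = "R0001") -> LandmarkSet:
    """An arbitrary (not anatomically meaningful) valid 129-point set."""
    return LandmarkSet(
        subject_id=subject_id,
        side=Side.RIGHT,
        points=rng.uniform(0.0, 400.0, size=(129, 2)),
        pixel_spacing_mm=float(rng.uniform(0.1, 0.5)),
    )
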