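from datetime import datetime

import numpy as np
import pytest

from chirpclock import ChirpParams, Photoschedule, synthesize_clip


@pytest.fixture(scope="session")
def chirp() -> ChirpParams:
    return ChirpParams()


@pytest.fixture(scope="session")
def singing_clip(chirp) -> np.ndarray:
    # 10-s clips keep unit tests fast; full 60-s clips are exercised in the
    # pipeline and acceptance tests
    return synthesize_clip(1, chirp, duration_s=10.0, seed=42)


@pytest.fixture(scope="session")
def noise_clip(chirp) -> np.ndarray:
    return synthesize_clip(0, chirp, duration_s=10.0, seed=43)


@pytest.fixture()
def dl_schedule() -> Photoschedule:
    """Reversed photoperiod: lights-on 18:00, recording starts at ZT0."""
    return Photoschedule("DL", lights_on=18.0, start=datetime(2022, 6, 1, 18, 0))


@pytest.fixture()
def dd_schedule() -> Photoschedule:
    """Constant darkness with subjective phases carried from rearing."""
    return Photoschedule("DD", lights_on=6.0, start=datetime(2022, 6, 1, 6, 0))


@pytest.fixture()
def ld_reversal_schedule() -> Photoschedule:
    """LD with a programmed reversal to DL at ZT0 of day 9."""
    return Photoschedule(
        "LD", lights_on=6.0, reversal_day=9, start=datetime(2022, 6, 1, 6, 0)
    )
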