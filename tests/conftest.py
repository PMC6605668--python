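from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture()
def chr3_markers():
    from tetralink.tetrad_data import MarkerDef

    return [
        MarkerDef("HIS4", "III", 1),
        MarkerDef("CEN3", "III", 2),
        MarkerDef("MAT", "III", 3),
    ]


def make_tetrad(tid, pairs, markers=("HIS4", "CEN3"), viable=None):
    """Build a tetrad from per-spore call tuples at the given markers."""
    from tetralink.tetrad_data import SporeGenotype, Tetrad

    viable = viable or [True] * 4
    spores = [
        SporeGenotype(
            f"{tid}{'abcd'[i]}",
            viable[i],
            {m: c for m, c in zip(markers, calls)},
        )
        for i, (calls) in enumerate(pairs)
    ]
    return Tetrad(tid, spores)
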