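import numpy as np
import pytest

from rxnbarrier.data import featurize_reactions
from rxnbarrier.synthetic import FixtureConfig, generate

ETHANE_RXN = (
    "[C:1]([H:3])([H:4])([H:5])[C:2]([H:6])([H:7])[H:8]"
    ">>[C:1]([H:4])([H:5])=[C:2]([H:7])[H:8].[H:3][H:6]"
)


@pytest.fixture(scope="session")
def fixture_population():
    """Sixty synthetic transfer reactions with conformers and barriers."""
    return generate(FixtureConfig(n_reactions=60, seed=11))


@pytest.fixture(scope="session")
def fixture_dataset(fixture_population):
    return featurize_reactions([r.reaction for r in fixture_population])


@pytest.fixture(scope="session")
def small_population():
    """Tiny-molecule population (<= 5 atoms) for loop-oracle comparisons."""
    return generate(FixtureConfig(n_reactions=50, elements=("O", "S"), seed=5))


def rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return coords @ rot.T + rng.normal(scale=5.0, size=3)
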