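import numpy as np
import pytest

from aquaretrieve.ensemble import ModelSpec
from aquaretrieve.geo import Affine
from aquaretrieve.ingest import SceneStack
from aquaretrieve.matchup import MatchupRow, MatchupTable, StationRecord
from aquaretrieve.synthdata import SceneRecipe, make_scene


def tiny_scene(bands: dict, pixel_size: float = 10.0) -> SceneStack:
    """Build a SceneStack from plain 2-D arrays (local metric CRS)."""
    bands = {k: np.asarray(v, dtype=np.float32) for k, v in bands.items()}
    rows = next(iter(bands.values())).shape[0]
    transform = Affine(a=pixel_size, c=0.0, e=-pixel_size, f=rows * pixel_size)
    return SceneStack(bands=bands, transform=transform, crs="LOCAL:metric",
                      sensor_id="SYNTH")


def piecewise_table(seed: int, n: int = 200, noise_sd: float = 1.0) -> MatchupTable:
    """Two-segment piecewise-linear calibration sample: y = 200x for x < 0.1,
    else 20 + 50(x − 0.1), x uniform on [0, 0.3]."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 0.3, n)
    y = np.where(x < 0.1, 200.0 * x, 20.0 + 50.0 * (x - 0.1))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    rows = [
        MatchupRow(
            station=StationRecord(f"S{i:03d}", "2024-01-01T00:00:00Z",
                                  float(i), 0.0, "y", float(yi)),
            predictors={"x": float(xi)}, n_valid=9, flags=frozenset())
        for i, (xi, yi) in enumerate(zip(x, y))
    ]
    return MatchupTable(rows=rows, feature_names=["x"], response_name="y")


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic default synthetic scene shared across tests."""
    recipe = SceneRecipe(seed=11)
    scene, scl, qa, truth = make_scene(recipe)
    return {"recipe": recipe, "scene": scene, "scl": scl, "qa": qa, "truth": truth}


@pytest.fixture
def lr_spec():
    return ModelSpec.make("lr")
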