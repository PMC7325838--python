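import numpy as np
import pandas as pd
import pytest

from parkdiff import (FeatureMatrix, default_effects, generate_cohort,
                      make_fixture_atlas)


@pytest.fixture(scope="session")
def tiny_atlas():
    return make_fixture_atlas((12, 12, 8), n_gm=4, n_wm=4, n_cortical=3)


@pytest.fixture(scope="session")
def small_cohort(tiny_atlas):
    spec = default_effects(tiny_atlas)
    return generate_cohort(spec, 4, tiny_atlas, seed=11)


@pytest.fixture
def null_features():
    """Factory for a two-class feature matrix of iid standard normals."""

    def make(n_per_class=8, n_features=10, seed=0, groups=("Control", "PD")):
        rng = np.random.default_rng(seed)
        ids = [f"{groups[0]}_{i}" for i in range(n_per_class)] + \
              [f"{groups[1]}_{i}" for i in range(n_per_class)]
        labels = pd.Series([groups[0]] * n_per_class + [groups[1]] * n_per_class,
                           index=ids)
        data = pd.DataFrame(rng.normal(size=(2 * n_per_class, n_features)),
                            index=ids,
                            columns=[f"GMvol:f{i:02d}" for i in range(n_features)])
        return FeatureMatrix(data), labels

    return make
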