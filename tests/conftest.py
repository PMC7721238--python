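import numpy as np
import pytest

from scdprog import (
    CsvmConfig,
    FeatureMatrix,
    PlantedBinary,
    PlantedContinuous,
    ReliefConfig,
    SyntheticConfig,
    generate_cohort,
)

#: Hyperparameter grids used by the fast pipeline tests (single combination;
#: the rebalancing cost ratio).
FAST_CSVM = CsvmConfig(C_grid=(1.0,), ratio_grid=(52.0 / 24.0,))

#: Reduced grids used by the simulation studies (see docs/methods.md).
SIM_CSVM = CsvmConfig(C_grid=(0.1, 1.0, 10.0), ratio_grid=(1.0, 52.0 / 24.0, 3.0))


def small_cohort_config(seed: int = 0, effect_scale: float = 1.0) -> SyntheticConfig:
    """A 20-subject, 12-feature cohort with two planted effects, for fast tests."""
    return SyntheticConfig(
        n_total=20,
        n_positive=7,
        n_clinical=4,
        n_mri=8,
        planted=(
            PlantedContinuous("clin_000", 10.0, 2.0, 13.0, 2.0),
            PlantedContinuous("mri_000", 5.0, 1.0, 3.5, 1.0),
        ),
        effect_scale=effect_scale,
        seed=seed,
    )


@pytest.fixture
def small_cohort():
    return generate_cohort(small_cohort_config(seed=3, effect_scale=2.0))


@pytest.fixture
def small_relief_cfg():
    # k grid must respect the smallest class (7 positives -> k <= 6)
    return ReliefConfig(k_min=1, k_max=5, top_m=6)


@pytest.fixture
def separable_matrix():
    """Two well-separated Gaussian clusters, 2 features."""
    rng = np.random.default_rng(7)
    X = np.vstack(
        [rng.normal(0.0, 0.3, size=(10, 2)), rng.normal(3.0, 0.3, size=(8, 2))]
    )
    y = np.array([0] * 10 + [1] * 8)
    return X, y


def as_matrix(X, y, prefix="f"):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        subject_ids=[f"s{i}" for i in range(X.shape[0])],
        feature_names=[f"{prefix}{j}" for j in range(X.shape[1])],
        values=X,
        labels=y,
    )
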