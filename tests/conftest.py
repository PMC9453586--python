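import numpy as np
import pytest

import labwatch as lw
from labwatch.preprocessing import OBSERVED, GriddedStay
from labwatch.synthetic import Demographics


@pytest.fixture(scope="session")
def demo():
    return Demographics(age=60.0, sex="male", weight=80.0)


@pytest.fixture(scope="session")
def panel():
    return lw.default_panel()


@pytest.fixture(scope="session")
def ranges(panel):
    return lw.reference_ranges(panel)


def make_gridded(values: np.ndarray, demo: Demographics,
                 channel_names=None, stay_id="s0") -> GriddedStay:
    """Fully observed GriddedStay from a raw (L, C) value matrix."""
    values = np.asarray(values, dtype=float)
    if channel_names is None:
        channel_names = [f"c{j}" for j in range(values.shape[1])]
    mask = np.full(values.shape, OBSERVED, dtype=np.int8)
    return GriddedStay(stay_id, demo, values.copy(), mask,
                       list(channel_names))


@pytest.fixture(scope="session")
def bench_dataset():
    """Small noiseless persistence cohort, fully preprocessed and windowed."""
    cohort = lw.generate_cohort(lw.persistence_benchmark_config(), 80, seed=11)
    stays = lw.PreprocessingPipeline().fit_transform(cohort)
    return lw.build_dataset(stays, 6, lw.reference_ranges(cohort.channel_specs),
                            seed=3)
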