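import numpy as np
import pandas as pd
import pytest


def random_quantities(n_targets=5, n_samples=8, seed=0, spread=0.6) -> pd.DataFrame:
    """Log-normal samples x targets relative-quantity matrix."""
    rng = np.random.default_rng(seed)
    arr = np.exp2(rng.normal(0.0, spread, size=(n_samples, n_targets)))
    return pd.DataFrame(
        arr,
        index=[f"s{i + 1}" for i in range(n_samples)],
        columns=[f"t{j + 1}" for j in range(n_targets)],
    )


@pytest.fixture
def q_fixture() -> pd.DataFrame:
    """The seeded 5-target x 8-sample matrix used for oracle comparisons."""
    return random_quantities(seed=41)


def as_dict_of_lists(q: pd.DataFrame) -> dict[str, list[float]]:
    return {t: q[t].tolist() for t in q.columns}
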