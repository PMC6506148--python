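import numpy as np
import pytest

from kinscreen import DockingScoreTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_table(rng, n, m, target_id="T1", na_frac=0.0):
    scores = rng.normal(size=(n, m))
    if na_frac:
        mask = rng.random(size=(n, m)) < na_frac
        # keep at least one value per column so every model ranks
        mask[rng.integers(0, n, size=m), np.arange(m)] = False
        scores = np.where(mask, np.nan, scores)
    return DockingScoreTable(
        target_id=target_id,
        compound_ids=tuple(f"c{i:03d}" for i in range(n)),
        model_ids=tuple(f"m{j}" for j in range(m)),
        scores=scores,
    )
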