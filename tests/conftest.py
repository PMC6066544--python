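import numpy as np
import pandas as pd
import pytest

from phaseaudit import PhenotypeTable, TraitMeta


def make_table(
    X: np.ndarray,
    y: np.ndarray,
    event: str = "greg",
    nonevent: str = "sol",
    domain: str = "behavioral",
    prefix: str = "v",
) -> PhenotypeTable:
    """Build a PhenotypeTable from a design array and 0/1 outcomes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    cols = {f"{prefix}{j}": X[:, j] for j in range(X.shape[1])}
    df = pd.DataFrame(cols)
    df["phase"] = np.where(np.asarray(y) == 1, event, nonevent)
    meta = {
        c: TraitMeta(domain=domain, timescale="fast" if domain == "behavioral" else "slow")
        for c in cols
    }
    return PhenotypeTable(data=df, environment="phase", trait_meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
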