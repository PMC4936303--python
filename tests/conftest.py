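import numpy as np
import pandas as pd
import pytest

from gapdecomp import Block, MicroData, ModelSpec


@pytest.fixture
def toy_spec():
    """Two-block spec: one binary, one 3-level categorical (partner block)."""
    return ModelSpec(
        [
            Block("urban", "binary", ("0", "1"), "0"),
            Block("edu", "categorical", ("low", "mid", "high"), "low", partner=True),
        ]
    )


def make_micro(
    outcome,
    weight=None,
    psu=None,
    group=None,
    seed=0,
    **covariates,
) -> MicroData:
    """Assemble a MicroData table from aligned arrays (helper, not a fixture)."""
    n = len(outcome)
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "outcome": np.asarray(outcome, dtype=int),
            "weight": np.ones(n) if weight is None else np.asarray(weight, dtype=float),
            "stratum": ["s0"] * n,
            "psu": [f"c{i % 3}" for i in range(n)] if psu is None else list(psu),
        }
    )
    if group is not None:
        frame["group"] = list(group)
        frame["wealth_quintile"] = np.where(frame["group"] == "poor", 1, 4)
    for name, vals in covariates.items():
        frame[name] = [str(v) for v in vals]
    return MicroData(frame)


@pytest.fixture
def toy_micro(toy_spec):
    """12 deterministic records spanning both groups and all levels."""
    rng = np.random.default_rng(5)
    n = 12
    return make_micro(
        outcome=rng.integers(0, 2, n),
        psu=[f"c{i % 4}" for i in range(n)],
        group=["poor"] * 6 + ["nonpoor"] * 6,
        urban=rng.integers(0, 2, n),
        edu=rng.choice(["low", "mid", "high"], n),
    )
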