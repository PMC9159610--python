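import numpy as np
import pandas as pd
import pytest

from ddmeta.data_model import EXP1_SCALE, Dataset
from ddmeta.ddm.wfpt import DDMParams, simulate_ddm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trials(
    n: int = 10,
    subject: str = "s01",
    rt: float | list = 0.6,
    correct: bool | list = True,
    rating: int | list = 3,
    emphasis: str | list = "speed",
) -> pd.DataFrame:
    def rep(x):
        return list(x) if isinstance(x, (list, np.ndarray)) else [x] * n

    return pd.DataFrame(
        {
            "subject": rep(subject),
            "group": ["action"] * n,
            "task": ["RDM"] * n,
            "emphasis": rep(emphasis),
            "stimulus": ["left"] * n,
            "response": ["correct"] * n,
            "correct": rep(correct),
            "rt": rep(rt),
            "rating": rep(rating),
        }
    )


@pytest.fixture
def tiny_dataset():
    return Dataset(make_trials(), EXP1_SCALE)


def simulate_flat_rdm(
    n_subjects: int,
    trials_per_cell: int = 81,
    a_delta: float = 0.0,
    seed: int = 0,
    v: float = 0.45,
    a: float = 1.6,
    ter: float = 0.35,
) -> Dataset:
    """RDM-style dataset straight from known DDM parameters (no deadline,
    no confidence structure) for fitting/selection studies."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        grp = "action" if s < n_subjects // 2 else "state"
        vs = rng.normal(v, 0.1)
        as_ = max(rng.normal(a, 0.15), 0.6)
        ts = max(rng.normal(ter, 0.04), 0.15)
        for emph, adj in (("speed", -a_delta / 2), ("accuracy", +a_delta / 2)):
            ch, rt = simulate_ddm(
                DDMParams(vs, as_ + adj, 0.5, ts),
                trials_per_cell,
                seed=int(rng.integers(2**31 - 1)),
            )
            for c, t in zip(ch, rt):
                rows.append(
                    dict(
                        subject=f"s{s:02d}",
                        group=grp,
                        task="RDM",
                        emphasis=emph,
                        stimulus="left",
                        response="x",
                        correct=bool(c == 1),
                        rt=float(t),
                        rating=3,
                    )
                )
    return Dataset(pd.DataFrame(rows), EXP1_SCALE)
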