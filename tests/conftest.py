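import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

sys.path.insert(0, str(Path(__file__).parent))

from unchosen.hierarchical_inference import SamplerConfig
from unchosen.rl_models import ModelParams, simulate_cohort
from unchosen.synthetic_task import TaskConfig


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_task_config():
    return TaskConfig(n_blocks=2, trials_per_block=30)


@pytest.fixture(scope="session")
def fast_sampler():
    return SamplerConfig(chains=2, warmup=200, draws=150, seed=0)


def example_params(model: str) -> ModelParams:
    base = {
        "baseline": dict(alpha_chosen=0.3, beta=4.0),
        "double_two_pe": dict(alpha_chosen=0.3, alpha_unchosen=0.1, beta=4.0),
        "double_one_pe": dict(alpha_chosen=0.3, alpha_unchosen=0.1, beta=4.0),
        "select_reject": dict(alpha_chosen=0.3, omega=0.7, beta=4.0),
    }[model]
    return ModelParams(model=model, **base)


@pytest.fixture(scope="session")
def tiny_cohort(small_task_config):
    """6 select-reject agents on a 2x30 task; shared by slow-ish tests."""
    params = [example_params("select_reject") for _ in range(6)]
    return simulate_cohort("select_reject", params, small_task_config, seed=42)


def random_block(rng: np.random.Generator, n_trials: int = 50, n_arms: int = 4,
                 participant_id: str = "p0", block: int = 1,
                 block_type: str = "win") -> pd.DataFrame:
    """A random (not model-generated) block of answered trials."""
    from unchosen.synthetic_task import PAYOFF_MAP

    rows = []
    for t in range(n_trials):
        a, b = rng.choice(n_arms, size=2, replace=False)
        choice = a if rng.random() < 0.5 else b
        reward = int(rng.random() < 0.5)
        rows.append(
            {
                "participant_id": participant_id,
                "block": block,
                "block_type": block_type,
                "trial": t + 1,
                "offer_a": int(a),
                "offer_b": int(b),
                "choice": int(choice),
                "payoff": PAYOFF_MAP[(block_type, reward)],
                "reward01": reward,
                "rt_ms": None,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("choice", "payoff", "reward01", "rt_ms"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df


def frame_to_trial_dicts(df: pd.DataFrame) -> list[dict]:
    return [
        {
            "offer_a": int(r.offer_a),
            "offer_b": int(r.offer_b),
            "choice": int(r.choice),
            "reward01": int(r.reward01),
        }
        for r in df.itertuples(index=False)
        if pd.notna(r.choice)
    ]
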