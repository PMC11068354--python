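"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from bmprl import bmp_task, rl_models, synthetic_data as sd


@pytest.fixture(scope="session")
def uniform_opponent():
    return bmp_task.OpponentConfig(exploit_mode="uniform")


@pytest.fixture(scope="session")
def task_p():
    """Payoff magnitudes of the one-gain / two-loss animal."""
    return bmp_task.TaskConfig(gain_tokens=1, loss_tokens=2)


@pytest.fixture(scope="session")
def df_spec():
    return rl_models.ModelSpec("DF")


@pytest.fixture(scope="session")
def p_saline():
    return sd.saline_paramset("P")


@pytest.fixture(scope="session")
def saline_sessions(task_p, uniform_opponent, df_spec, p_saline):
    """Ten 600-trial sessions simulated from the published P-saline DF model."""
    return [rl_models.simulate_agent(task_p, uniform_opponent, df_spec, p_saline,
                                     600, seed, session_id=f"sal_{seed:02d}")
            for seed in range(10)]


@pytest.fixture(scope="session")
def one_session(saline_sessions):
    return saline_sessions[0]


def random_session(seed: int, n_trials: int = 150) -> list[tuple[str, str, int]]:
    """A random (choice, outcome, asset) sequence for likelihood oracles."""
    rng = np.random.default_rng(seed)
    choices = rng.choice(["L", "R"], n_trials)
    outcomes = rng.choice(["gain", "neutral", "loss"], n_trials)
    assets = rng.integers(0, 6, n_trials)
    return list(zip(choices.tolist(), outcomes.tolist(), assets.tolist()))


def session_frame(triples, session_id="s0", condition="saline") -> pd.DataFrame:
    """Wrap raw (choice, outcome, asset) triples into a minimal trial table."""
    rows = []
    for i, (c, o, a) in enumerate(triples, start=1):
        rows.append({"session_id": session_id, "animal_id": "x",
                     "condition": condition, "route": "IM", "trial_index": i,
                     "time_from_injection": 8.0 * i, "risky_side": "L",
                     "animal_choice": c, "computer_choice": "L",
                     "outcome_class": o,
                     "token_delta": {"gain": 1, "neutral": 0, "loss": -2}[o],
                     "asset_pre": a, "asset_post": a, "juice_delivered": False})
    return pd.DataFrame(rows)
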