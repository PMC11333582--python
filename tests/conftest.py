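import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    from comprank.config import GeneratorConfig

    return GeneratorConfig(seed=11, n_units=40, n_groups=2)


@pytest.fixture()
def pair_trials():
    """Hand-built 10-trial fixture for one pair; A wins 8 pellets of 10."""
    winners = ["A", "A", "A", "B", "A", "A", "B", "A", "A", "A"]
    rows = []
    for i, w in enumerate(winners):
        t0 = 30.0 * i
        for m, opp in (("A", "B"), ("B", "A")):
            first = m == w
            rows.append(
                {
                    "group_id": "g0",
                    "day": 0,
                    "session_id": "g0-d0",
                    "pair_id": "A-B",
                    "trial_idx": i,
                    "subject_id": m,
                    "opponent_id": opp,
                    "start_area": "A",
                    "t_gate_open_s": t0,
                    "t_exit_sa_s": t0 + (0.5 if first else 0.9),
                    "t_reach_rz_s": t0 + (2.0 if first else 3.5),
                    "pellet_winner_id": w,
                    "opponent_relative_rank": "dominant" if m == "B" else "subordinate",
                }
            )
    return pd.DataFrame(rows)


def make_bouts(outcomes, day=1, group_id="g0"):
    """Build a round-robin bout table from {(a, b): winner}."""
    rows = [
        {
            "group_id": group_id,
            "day": day,
            "mouse_a": a,
            "mouse_b": b,
            "winner": w,
            "duration_s": 10.0,
        }
        for (a, b), w in outcomes.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
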