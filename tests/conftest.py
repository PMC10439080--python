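import numpy as np
import pandas as pd
import pytest

from picnorm.coding import UnificationMaps
from picnorm.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def maps() -> UnificationMaps:
    """Small hand-built unification maps with Polish-flavoured examples."""
    return UnificationMaps(
        infinitive_map={"czyta": "czytać", "umył": "umyć"},
        merge_map={"umyć": "myć", "myć": "myć"},
        root_map={"pies": "pies", "piesek": "pies", "kot": "kot"},
        synonym_map={"auto": "samochód"},
        lexicon={"kot", "pies", "piesek", "auto", "samochód", "czyta",
                 "czytać", "umył", "umyć", "myć", "krzesło"},
    )


@pytest.fixture
def trials_3pics() -> pd.DataFrame:
    """Three object pictures x four participants, with known tallies."""
    rows = []
    # pic1: unanimous "kot"; pic2: a,a,b + one invalid; pic3: a,a,b,no_response
    naming = {
        "pic1": [("kot", "valid"), ("kot", "valid"), ("kot", "valid"), ("kot", "valid")],
        "pic2": [("pies", "valid"), ("pies", "valid"), ("kot", "valid"), ("pies", "invalid")],
        "pic3": [("auto", "valid"), ("auto", "valid"), ("samochód", "valid"), ("", "no_response")],
    }
    for pic, answers in naming.items():
        for i, (name, validity) in enumerate(answers):
            rows.append(
                {
                    "participant": f"p{i}",
                    "picture": pic,
                    "word_class": "object",
                    "raw_name": name,
                    "latency_ms": 800.0 + 10 * i if validity == "valid" else np.nan,
                    "validity": validity,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_experiment():
    """One small but complete synthetic experiment, shared across tests."""
    cfg = SimulationConfig(
        n_participants=15,
        n_pictures_objects=8,
        n_pictures_actions=8,
        name_pool_size=3,
        predictor_sd=0.3,
        seed=42,
    )
    return simulate_experiment(cfg)
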