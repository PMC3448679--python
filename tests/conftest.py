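import numpy as np
import pandas as pd
import pytest

from seekpaths import SyntheticConfig, build_profiles, find_pairs, simulate_log
from seekpaths.cohort import partition_severity


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic dataset shared by the slower tests."""
    config = SyntheticConfig(n_users=20_000, seed=7)
    events, contacts, lexicon = simulate_log(config)
    lex = partition_severity(lexicon)
    profiles, tally = build_profiles(events, lex)
    return {
        "config": config,
        "events": events,
        "contacts": contacts,
        "lexicon": lex,
        "profiles": profiles,
        "tally": tally,
    }


@pytest.fixture(scope="session")
def default_pairs(default_sim):
    return find_pairs(default_sim["profiles"], default_sim["contacts"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_log(rows):
    """Build a small query-event DataFrame from (user, day, text, page, cat)."""
    return pd.DataFrame(
        rows, columns=["user_id", "day", "query_text", "page_id", "category"]
    )
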