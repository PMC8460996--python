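import numpy as np
import pandas as pd
import pytest

from scdmort import sibling_linkage
from scdmort.synthetic_data import SimConfig, simulate_survey


def make_roster(rows: list[dict]) -> pd.DataFrame:
    """Tiny tested-children roster with defaults for boilerplate columns."""
    defaults = {
        "stratum_id": 0,
        "cluster_id": 0,
        "household_id": 0,
        "mother_id": pd.NA,
        "zone": "Z1",
        "urban": 0,
        "age_months": 24,
        "alive": True,
        "age_at_death_months": np.nan,
        "genotype": "AA",
        "weight": 1.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_birth_history(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "mother_id": "m0",
        "household_id": 0,
        "child_id": "c0",
        "birth_offset_months": 24,
        "alive": True,
        "age_at_death_months": np.nan,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture(scope="session")
def small_survey():
    """A small but structurally complete synthetic survey (about 5k children)."""
    cfg = SimConfig(seed=20240, n_strata=12)
    roster, bh, truth = simulate_survey(cfg)
    return cfg, roster, bh, truth


@pytest.fixture(scope="session")
def full_children():
    """Linked, labelled child table at the full survey scale (~34k children)."""
    roster, bh, _ = simulate_survey(SimConfig(seed=42))
    children = sibling_linkage.link_siblings(roster, bh)
    children = sibling_linkage.assign_slc(children)
    children = sibling_linkage.add_under5_death(children)
    return children


@pytest.fixture(scope="session")
def small_children(small_survey):
    """Linked, labelled child table for the small survey."""
    _, roster, bh, _ = small_survey
    children = sibling_linkage.link_siblings(roster, bh)
    children = sibling_linkage.assign_slc(children)
    children = sibling_linkage.add_under5_death(children)
    return children
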