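"""Linking tested children to maternal birth histories and labelling sibling groups.

The survey genotypes only living children aged 6-59 months, but mortality must
be measured on children whose under-5 survival is fully observed.  The bridge
is the sibling group: full siblings (same household and same mother) share
both parents, so a tested child's genotype is informative about its untested
siblings.  Each full-sibling group receives a sibling-group label category
(SLC) from the most severe genotype among its tested members, with the
ordering SCD (SS/SC) > Trait (AS/AC) > AA.  Half-siblings (sharing exactly one
of household or mother) transmit a weaker version of the label: an SCD
half-sibling label is capped at Trait, because only one parent is shared.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype_model import GENOTYPE_CLASS

__all__ = [
    "COHORT_PRESETS",
    "SEVERITY",
    "link_siblings",
    "assign_slc",
    "cohort_filter",
    "add_under5_death",
]

logger = logging.getLogger(__name__)

#: severity rank of the three label classes
SEVERITY = {"AA": 0, "Trait": 1, "SCD": 2}
_SEV_TO_LABEL = {v: k for k, v in SEVERITY.items()}

#: named birth-offset windows (completed months before the interview),
#: half-open [lo, hi)
COHORT_PRESETS = {
    "tested": (6, 60),
    "older": (60, 180),
    "km": (0, 180),
}

_CHILD_COLS = [
    "child_id",
    "household_id",
    "mother_id",
    "cluster_id",
    "stratum_id",
    "zone",
    "urban",
    "birth_offset_months",
    "alive",
    "age_at_death_months",
    "genotype",
    "weight",
    "tested",
    "linked",
    "sibling_group_id",
]


def link_siblings(roster: pd.DataFrame, birth_history: pd.DataFrame) -> pd.DataFrame:
    """Merge the test roster with maternal birth histories into one child table.

    Full siblings share (household_id, mother_id); that pair is the
    ``sibling_group_id``.  Tested children absent from any mother's birth
    history are retained (they still inform prevalence) but flagged
    ``linked=False``; each forms a singleton group.  Birth-history children in
    households where nobody was tested inherit their mother's modal household
    design variables.

    Parameters
    ----------
    roster
        Tested children: columns ``stratum_id, cluster_id, household_id,
        child_id, zone, urban, age_months, genotype, weight``.
    birth_history
        All births reported by interviewed mothers: columns ``mother_id,
        household_id, child_id, birth_offset_months, alive,
        age_at_death_months``.
    """
    for df, name in ((roster, "roster"), (birth_history, "birth_history")):
        if df["child_id"].duplicated().any():
            raise ValueError(f"duplicate child ids in {name}")

    bh = birth_history.set_index("child_id")
    tested = roster.copy()
    tested["tested"] = True
    in_bh = tested["child_id"].isin(bh.index)
    tested["linked"] = in_bh.to_numpy()
    if (~in_bh).any():
        logger.info("%d tested children not matched to a mother interview", (~in_bh).sum())
    tested["mother_id"] = tested["child_id"].map(bh["mother_id"])
    # age at interview doubles as birth offset for children alive at interview
    tested["birth_offset_months"] = tested["child_id"].map(
        bh["birth_offset_months"]
    ).fillna(tested["age_months"])
    tested["alive"] = True
    tested["age_at_death_months"] = np.nan

    untested = birth_history.loc[
        ~birth_history["child_id"].isin(set(roster["child_id"]))
    ].copy()
    untested["tested"] = False
    untested["linked"] = True
    untested["genotype"] = pd.NA

    # design variables propagate from tested children: first by household,
    # then by the mother's modal household
    hh_design = (
        roster.groupby("household_id")[["cluster_id", "stratum_id", "zone", "urban", "weight"]]
        .first()
    )
    mother_hh = (
        tested.dropna(subset=["mother_id"])
        .groupby("mother_id")["household_id"]
        .agg(lambda s: s.mode().iloc[0])
    )
    fallback_hh = untested["mother_id"].map(mother_hh)
    for col in ("cluster_id", "stratum_id", "zone", "urban", "weight"):
        primary = untested["household_id"].map(hh_design[col])
        untested[col] = primary.where(primary.notna(), fallback_hh.map(hh_design[col]))

    orphan = untested["weight"].isna()
    if orphan.any():
        logger.info(
            "%d birth-history children have no design information (kept)",
            int(orphan.sum()),
        )

    children = pd.concat([tested, untested], ignore_index=True, sort=False)

    has_mother = children["mother_id"].notna()
    gid = pd.Series(pd.NA, index=children.index, dtype="object")
    gid[has_mother] = (
        children.loc[has_mother, "household_id"].astype(str)
        + "|"
        + children.loc[has_mother, "mother_id"].astype(str)
    )
    # unlinked children form singleton groups so they never borrow a label
    gid[~has_mother] = (
        children.loc[~has_mother, "household_id"].astype(str)
        + "|child:"
        + children.loc[~has_mother, "child_id"].astype(str)
    )
    children["sibling_group_id"] = gid
    return children[_CHILD_COLS + [c for c in children.columns if c not in _CHILD_COLS]]


def _tested_severity(children: pd.DataFrame) -> pd.Series:
    """Severity code of each child's tested genotype; -1 when untested/Other."""
    cls = children["genotype"].map(GENOTYPE_CLASS)
    return cls.map(SEVERITY).fillna(-1).astype(int)


def assign_slc(children: pd.DataFrame) -> pd.DataFrame:
    """Assign sibling-group label categories (SLC) to every child.

    Rules, applied group-wise (a group is a set of full siblings):

    1. a group with at least one tested member takes the most severe tested
       genotype class among them (SCD > Trait > AA);
    2. a group with no tested member but with tested half-siblings takes the
       most severe half-sibling group label, capped at Trait when that label
       is SCD;
    3. a group labelled AA from its own members is promoted to Trait when any
       half-sibling group is labelled SCD;
    4. groups with no tested relative stay unlabelled (``slc_label`` NA) and
       are excluded from mortality models.

    Children with an Other (CC) test result are excluded from the evidence and
    receive no label themselves.  Returns a copy with ``slc_label`` added.
    """
    children = children.copy()
    sev = _tested_severity(children)

    grp = pd.DataFrame(
        {
            "sibling_group_id": children["sibling_group_id"],
            "household_id": children["household_id"],
            "mother_id": children["mother_id"],
            "sev": sev,
        }
    )
    groups = (
        grp.groupby("sibling_group_id")
        .agg(
            household_id=("household_id", "first"),
            mother_id=("mother_id", "first"),
            own=("sev", "max"),
        )
        .reset_index()
    )

    def _related_max(key: str) -> pd.Series:
        """Per group: max own-severity over *other* groups sharing `key`."""
        sub = groups.dropna(subset=[key])
        keys = sub[key]
        mx = sub.groupby(key)["own"].transform("max")
        is_max = sub["own"].eq(mx)
        n_at_max = is_max.astype(int).groupby(keys).transform("sum")
        # max over the non-maximal groups, for the unique argmax's benefit
        runner_up = sub["own"].where(~is_max, -1).groupby(keys).transform("max")
        size = sub.groupby(key)["own"].transform("size")
        others = np.where(is_max & (n_at_max == 1), runner_up, mx)
        others = np.where(size == 1, -1, others)
        return pd.Series(others, index=sub.index)

    half = pd.Series(-1, index=groups.index)
    for key in ("household_id", "mother_id"):
        rel = _related_max(key)
        half.loc[rel.index] = np.maximum(half.loc[rel.index], rel)

    own = groups["own"].to_numpy()
    half_v = half.to_numpy()
    label = np.full(len(groups), -1)
    has_own = own >= 0
    label[has_own] = own[has_own]
    # rule 2: borrow capped half-sibling label
    borrow = ~has_own & (half_v >= 0)
    label[borrow] = np.minimum(half_v[borrow], SEVERITY["Trait"])
    # rule 3: AA groups with an SCD half-sibling group become Trait
    promote = has_own & (own == SEVERITY["AA"]) & (half_v == SEVERITY["SCD"])
    label[promote] = SEVERITY["Trait"]

    lab = pd.Series(label, index=groups["sibling_group_id"]).map(
        lambda v: _SEV_TO_LABEL.get(v, pd.NA)
    )
    children["slc_label"] = children["sibling_group_id"].map(lab)
    # Other-genotype children carry no label and exit mortality analyses
    other = children["genotype"].map(GENOTYPE_CLASS) == "Other"
    children.loc[other, "slc_label"] = pd.NA
    return children


def cohort_filter(
    children: pd.DataFrame, window: str | tuple[float, float]
) -> pd.DataFrame:
    """Subset children by birth offset (months before interview), half-open.

    ``window`` is a ``(lo, hi)`` pair or one of the presets ``"tested"``
    ([6, 60)), ``"older"`` ([60, 180): under-5 survival fully observed, and a
    child's untested status cannot be caused by its own death) or ``"km"``
    ([0, 180)).
    """
    if isinstance(window, str):
        try:
            lo, hi = COHORT_PRESETS[window]
        except KeyError:
            raise ValueError(
                f"unknown cohort preset {window!r}; options: {sorted(COHORT_PRESETS)}"
            ) from None
    else:
        lo, hi = window
    if hi <= lo:
        raise ValueError(f"inverted cohort window ({lo}, {hi})")
    off = children["birth_offset_months"]
    return children.loc[(off >= lo) & (off < hi)]


def add_under5_death(children: pd.DataFrame) -> pd.DataFrame:
    """Add ``died_u5``: death before 60 completed months of age."""
    children = children.copy()
    dead = ~children["alive"].astype(bool)
    children["died_u5"] = (
        dead & (children["age_at_death_months"].astype(float) < 60)
    ).astype(int)
    return children
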