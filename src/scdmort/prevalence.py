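"""Survey-weighted HBB allele frequencies, HWE prevalences and bootstrap CIs.

Estimation follows complex-survey practice: every tested child contributes two
allele-count units scaled by its household sample weight, and uncertainty is
assessed with a stratified cluster bootstrap (clusters resampled with
replacement within each sampling stratum), which respects the clustering of
children within households and households within enumeration areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_model import (
    ALLELES,
    GENOTYPES,
    AlleleFrequencies,
    hwe_genotypes,
)

__all__ = [
    "BootstrapResult",
    "weighted_allele_frequencies",
    "stratified_cluster_bootstrap",
    "hwe_prevalence_with_ci",
    "hwe_consistency_check",
    "births_affected",
]

logger = logging.getLogger(__name__)

#: allele counts contributed by each genotype code
_ALLELE_COUNTS = {
    "AA": (2, 0, 0),
    "AS": (1, 1, 0),
    "AC": (1, 0, 1),
    "SS": (0, 2, 0),
    "SC": (0, 1, 1),
    "CC": (0, 0, 2),
}


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate and percentile CI from a cluster bootstrap.

    ``point`` is the median of the replicate values (the convention used for
    survey tables built this way); ``plugin`` is the estimator applied to the
    unresampled data.
    """

    point: float
    lower: float
    upper: float
    plugin: float
    replicates: np.ndarray
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("bootstrap bounds must bracket the point estimate")


def _map_other(genotypes: pd.Series, other_as_cc: bool) -> pd.Series:
    g = genotypes.astype(str).str.upper()
    if other_as_cc:
        g = g.replace({"OTHER": "CC"})
    else:
        g = g.replace({"OTHER": pd.NA})
    return g


def weighted_allele_frequencies(
    children: pd.DataFrame, other_as_cc: bool = True
) -> AlleleFrequencies:
    """Weighted A/S/C allele frequencies from tested children.

    Each child contributes ``2 * weight`` allele-count units.  ``OTHER`` test
    results are counted as CC (two C alleles) by default — the point-of-care
    device has no CC readout, and "other" results cluster where the C allele
    is common — or dropped when ``other_as_cc`` is False.

    Parameters
    ----------
    children
        DataFrame with columns ``genotype`` and ``weight``.
    """
    if len(children) == 0:
        raise ValueError("no tested children supplied")
    g = _map_other(children["genotype"], other_as_cc)
    keep = g.isin(GENOTYPES)
    w = children.loc[keep, "weight"].to_numpy(dtype=float)
    if len(w) == 0 or w.sum() <= 0:
        raise ValueError("no usable genotyped children with positive weight")
    counts = np.array([_ALLELE_COUNTS[x] for x in g[keep]], dtype=float)
    totals = w @ counts
    return AlleleFrequencies(*(totals / totals.sum()))


def _cluster_row_indices(
    data: pd.DataFrame,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Row-index arrays per cluster, sorted by (stratum, cluster), and the
    stratum code of each cluster."""
    order = data[["stratum_id", "cluster_id"]].copy()
    order["_row"] = np.arange(len(data))
    grouped = order.groupby(["stratum_id", "cluster_id"], sort=True)["_row"]
    idx = [v.to_numpy() for _, v in grouped]
    strata = np.array([k[0] for k in grouped.groups.keys()])
    return idx, strata


def stratified_cluster_bootstrap(
    data: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], float],
    n_reps: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap resampling clusters with replacement within strata.

    Within each sampling stratum the clusters present in ``data`` are resampled
    with replacement, keeping the stratum's cluster count; the resampled rows
    are concatenated and the estimator applied.  The point estimate is the
    replicate median and the CI the 2.5/97.5 percentiles.  Deterministic given
    ``seed``; independent of input row order (clusters are sorted by
    (stratum, cluster) before resampling).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cluster_idx, strata = _cluster_row_indices(data)
    uniq_strata = pd.unique(strata)
    per_stratum = [np.flatnonzero(strata == s) for s in uniq_strata]
    empty = [s for s, pos in zip(uniq_strata, per_stratum) if len(pos) == 0]
    if empty:
        logger.warning("strata with no eligible clusters excluded: %s", empty)
        per_stratum = [p for p in per_stratum if len(p)]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        chosen: list[np.ndarray] = []
        for pos in per_stratum:
            draw = rng.integers(0, len(pos), size=len(pos))
            chosen.extend(cluster_idx[c] for c in pos[draw])
        reps[r] = estimator(data.take(np.concatenate(chosen)))
    lo, mid, hi = np.percentile(reps, [2.5, 50.0, 97.5])
    return BootstrapResult(
        point=float(mid),
        lower=float(lo),
        upper=float(hi),
        plugin=float(estimator(data)),
        replicates=reps,
        n_reps=n_reps,
        seed=seed,
    )


def hwe_prevalence_with_ci(
    children: pd.DataFrame,
    genotypes: Sequence[str] = ("SS", "SC"),
    n_reps: int = 1000,
    seed: int = 0,
    other_as_cc: bool = True,
) -> dict[str, BootstrapResult]:
    """HWE birth prevalence of the requested genotypes with bootstrap CIs.

    Composes :func:`weighted_allele_frequencies` and HWE genotype expansion
    inside the stratified cluster bootstrap.  Subset ``children`` first to get
    zone- or state-level estimates.
    """
    out: dict[str, BootstrapResult] = {}
    for k, g in enumerate(genotypes):
        def est(df: pd.DataFrame, _g: str = g) -> float:
            return hwe_genotypes(weighted_allele_frequencies(df, other_as_cc))[_g]

        out[g] = stratified_cluster_bootstrap(children, est, n_reps, seed + k)
    return out


def hwe_consistency_check(
    children: pd.DataFrame, by: str = "zone", other_as_cc: bool = True
) -> pd.DataFrame:
    """Observed vs HWE-expected HbSS frequency per group.

    Returns a tidy frame with the weighted observed SS proportion among tested
    children, the expected pS^2 from the group's allele frequencies, and their
    ratio (NaN when the group carries no S alleles).  A ratio below 1 in the
    tested cohort is consistent with mortality attrition of SS children before
    testing age.
    """
    rows = []
    for key, grp in children.groupby(by, sort=True):
        w = grp["weight"].to_numpy(dtype=float)
        g = _map_other(grp["genotype"], other_as_cc)
        obs = float(w[(g == "SS").to_numpy()].sum() / w.sum()) if w.sum() else np.nan
        try:
            exp = weighted_allele_frequencies(grp, other_as_cc).pS ** 2
        except ValueError:
            exp = np.nan
        ratio = obs / exp if exp and exp > 0 else np.nan
        rows.append({by: key, "observed_ss": obs, "expected_ss": exp, "ratio": ratio})
    return pd.DataFrame(rows)


def births_affected(
    prevalence: pd.DataFrame, births: pd.DataFrame, on: str = "region"
) -> pd.DataFrame:
    """Expected affected births per region: prevalence x annual births.

    ``prevalence`` needs columns ``[on, "point", "lower", "upper"]`` (as
    proportions); ``births`` needs ``[on, "births"]``.  CI bounds scale with
    the point estimate.  A ``"Total"`` row sums the regions.
    """
    merged = prevalence.merge(births, on=on, validate="one_to_one")
    if (merged["births"] < 0).any():
        raise ValueError("births must be nonnegative")
    out = merged[[on]].copy()
    for col in ("point", "lower", "upper"):
        out[col] = merged[col] * merged["births"]
    total = out[["point", "lower", "upper"]].sum()
    out = pd.concat(
        [out, pd.DataFrame([{on: "Total", **total.to_dict()}])], ignore_index=True
    )
    return out
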