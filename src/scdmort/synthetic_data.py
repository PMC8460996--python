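"""Seeded generator of DHS-like household surveys with known ground truth.

Emulates the statistical structure the estimation pipeline relies on: a
stratified two-stage sample (strata -> clusters -> households) with household
sample weights; mothers and fathers drawn from zone-specific Hardy-Weinberg
allele frequencies with SCD parents thinned by a survival-to-parenthood
factor; children inheriting alleles Mendelianly, born at uniform offsets over
the 15 years before the interview; genotype-dependent under-5 mortality
modulated by a lognormal cluster frailty; and genotype testing restricted to
living children aged 6-59 months in the selected third of households.

The generator writes the same two flat tables the pipeline consumes (test
roster and maternal birth history) plus a ground-truth table that the
pipeline never reads, enabling closed-loop parameter-recovery tests without
the restricted survey microdata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_model import GENOTYPE_CLASS, GENOTYPES, AlleleFrequencies, hwe_genotypes

__all__ = ["NIGERIA_ZONE_FREQS", "SimConfig", "simulate_survey", "apply_test_error", "truth_report"]

#: zone-level (A, S, C) allele frequencies patterned on Nigeria's six
#: geopolitical zones (C common only in the south-west)
NIGERIA_ZONE_FREQS: dict[str, AlleleFrequencies] = {
    "North Central": AlleleFrequencies(0.889, 0.100, 0.011),
    "North East": AlleleFrequencies(0.884, 0.113, 0.003),
    "North West": AlleleFrequencies(0.882, 0.111, 0.007),
    "South East": AlleleFrequencies(0.893, 0.106, 0.001),
    "South South": AlleleFrequencies(0.900, 0.099, 0.001),
    "South West": AlleleFrequencies(0.845, 0.121, 0.034),
}

_GT_INDEX = {g: i for i, g in enumerate(GENOTYPES)}
#: allele indices (A=0, S=1, C=2) carried by each genotype, genotype order
_GT_ALLELES = np.array([[0, 0], [0, 1], [0, 2], [1, 1], [1, 2], [2, 2]])
#: genotype index from an unordered allele pair
_PAIR_TO_GT = np.empty((3, 3), dtype=int)
for _g, (_a, _b) in enumerate(_GT_ALLELES):
    _PAIR_TO_GT[_a, _b] = _g
    _PAIR_TO_GT[_b, _a] = _g


@dataclass(frozen=True)
class SimConfig:
    """Survey-generator configuration; the defaults emulate the 2018 Nigeria
    DHS scale (74 strata, ~1400 clusters, a third of 30 households per cluster
    tested, ~27 000 children in the matched modelling dataset).

    Mortality parameters are per 1000 livebirths; ``gamma_*`` are excesses
    over the AA baseline ``m_aa``.  ``f_scd`` thins SCD genotypes among
    parents (survival to parenthood).  ``sensitivity``/``specificity`` control
    optional test misclassification (1.0 = perfect, the default, so recovery
    tests are clean).  ``seed`` is mandatory.
    """

    seed: int
    zone_freqs: dict[str, AlleleFrequencies] = field(
        default_factory=lambda: dict(NIGERIA_ZONE_FREQS)
    )
    n_strata: int = 74
    clusters_per_stratum: int = 19
    households_per_cluster: int = 30
    tested_household_fraction: float = 1.0 / 3.0
    p_mother: float = 0.66
    mean_children: float = 3.9
    m_aa: float = 120.0
    gamma_trait: float = 0.0
    gamma_scd: float = 370.0
    cluster_frailty_sd: float = 0.3
    f_scd: float = 0.5
    sensitivity: float = 1.0
    specificity: float = 1.0
    weight_dispersion: float = 0.3
    urban_fraction: float = 0.4
    half_sibling_rate: float = 0.0
    mother_match_failure: float = 0.09

    def __post_init__(self) -> None:
        if self.n_strata < 1 or self.clusters_per_stratum < 1:
            raise ValueError("need at least one stratum and one cluster")
        if self.households_per_cluster < 1:
            raise ValueError("need at least one household per cluster")
        for name in ("tested_household_fraction", "p_mother", "sensitivity",
                     "specificity", "urban_fraction", "half_sibling_rate",
                     "mother_match_failure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("m_aa", "gamma_trait", "gamma_scd"):
            v = getattr(self, name)
            if not (-1000.0 <= v <= 1000.0):
                raise ValueError(f"{name} must be a per-1000 rate, got {v}")
        if not (0.0 < self.f_scd <= 1.0):
            raise ValueError("f_scd must be in (0, 1]")

    def scaled(self, factor: float) -> "SimConfig":
        """A smaller survey with the same structure (fewer strata)."""
        return replace(self, n_strata=max(1, round(self.n_strata * factor)))


def _parent_genotype_probs(freqs: AlleleFrequencies, f_scd: float) -> np.ndarray:
    p = hwe_genotypes(freqs).probs.copy()
    p[_GT_INDEX["SS"]] *= f_scd
    p[_GT_INDEX["SC"]] *= f_scd
    return p / p.sum()


def apply_test_error(
    true_genotypes: np.ndarray,
    sensitivity: float,
    specificity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Misclassify genotype calls like an imperfect point-of-care test.

    SCD genotypes are reported as the corresponding trait (SS -> AS,
    SC -> AC) with probability 1 - sensitivity; non-SCD genotypes are reported
    as the corresponding SCD genotype (AA/AS -> SS, AC -> SC) with probability
    1 - specificity.  Identity when both rates are 1.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    g = np.asarray(true_genotypes, dtype=object).copy()
    is_scd = np.isin(g, ("SS", "SC"))
    miss = is_scd & (rng.random(len(g)) > sensitivity)
    g[miss & (g == "SS")] = "AS"
    g[miss & (g == "SC")] = "AC"
    false_pos = ~is_scd & (rng.random(len(g)) > specificity)
    g[false_pos & np.isin(g, ("AA", "AS"))] = "SS"
    g[false_pos & np.isin(g, ("AC", "CC"))] = "SC"
    return g


def simulate_survey(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (roster, birth_history, ground_truth) tables.

    Deterministic given ``config.seed``.  The roster contains one row per
    tested child (living, aged 6-59 months, in a selected household); the
    birth history one row per child ever born to a matched mother; the ground
    truth one row per child with its true genotype, parents and latent death
    time (never read by the pipeline).
    """
    rng = np.random.default_rng(config.seed)
    zones = list(config.zone_freqs)
    n_zones = len(zones)

    # --- design: strata in zone blocks, clusters, selected households -----
    n_clusters = config.n_strata * config.clusters_per_stratum
    stratum_of_cluster = np.repeat(np.arange(config.n_strata), config.clusters_per_stratum)
    zone_of_stratum = (np.arange(config.n_strata) * n_zones) // config.n_strata
    zone_of_cluster = zone_of_stratum[stratum_of_cluster]
    urban_of_cluster = rng.random(n_clusters) < config.urban_fraction
    frailty_sd = config.cluster_frailty_sd
    frailty = np.exp(rng.normal(-0.5 * frailty_sd**2, frailty_sd, n_clusters))

    n_sel = max(1, round(config.households_per_cluster * config.tested_household_fraction))
    n_hh = n_clusters * n_sel
    cluster_of_hh = np.repeat(np.arange(n_clusters), n_sel)
    stratum_mean = np.exp(rng.normal(0.0, config.weight_dispersion, config.n_strata))
    weight_hh = stratum_mean[stratum_of_cluster[cluster_of_hh]] * np.exp(
        rng.normal(0.0, config.weight_dispersion, n_hh)
    )
    weight_hh /= weight_hh.mean()

    # --- mothers and fathers ---------------------------------------------
    has_mother = rng.random(n_hh) < config.p_mother
    hh_ids = np.flatnonzero(has_mother)
    if config.half_sibling_rate > 0:
        # polygynous households: a second mother sharing the household
        second = hh_ids[rng.random(len(hh_ids)) < config.half_sibling_rate]
        hh_ids = np.concatenate([hh_ids, second])
    n_mothers = len(hh_ids)
    mother_cluster = cluster_of_hh[hh_ids]
    mother_zone = zone_of_cluster[mother_cluster]
    mother_gt = np.empty(n_mothers, dtype=int)
    father_gt = np.empty(n_mothers, dtype=int)
    for z, zone in enumerate(zones):
        mask = mother_zone == z
        if not mask.any():
            continue
        p = _parent_genotype_probs(config.zone_freqs[zone], config.f_scd)
        mother_gt[mask] = rng.choice(len(GENOTYPES), size=int(mask.sum()), p=p)
        father_gt[mask] = rng.choice(len(GENOTYPES), size=int(mask.sum()), p=p)

    # --- children ---------------------------------------------------------
    n_per_mother = rng.poisson(config.mean_children, n_mothers)
    n_children = int(n_per_mother.sum())
    mother_idx = np.repeat(np.arange(n_mothers), n_per_mother)
    pick_m = rng.integers(0, 2, n_children)
    pick_f = rng.integers(0, 2, n_children)
    allele_m = _GT_ALLELES[mother_gt[mother_idx], pick_m]
    allele_f = _GT_ALLELES[father_gt[mother_idx], pick_f]
    child_gt = _PAIR_TO_GT[allele_m, allele_f]
    birth_offset = rng.integers(0, 180, n_children)

    child_cluster = mother_cluster[mother_idx]
    cls = np.array([GENOTYPE_CLASS[GENOTYPES[g]] for g in child_gt])
    m_g = np.full(n_children, config.m_aa)
    m_g[cls == "Trait"] += config.gamma_trait
    m_g[cls == "SCD"] += config.gamma_scd
    p_die = np.clip(m_g / 1000.0 * frailty[child_cluster], 0.0, 1.0)
    died_u5 = rng.random(n_children) < p_die
    # death-age distribution: 60% of under-5 deaths in infancy
    infancy = rng.random(n_children) < 0.6
    death_age = np.where(
        infancy, rng.integers(0, 12, n_children), rng.integers(12, 60, n_children)
    ).astype(float)
    death_age[~died_u5] = np.nan

    dead_at_interview = died_u5 & (death_age < birth_offset)
    alive = ~dead_at_interview

    child_hh = hh_ids[mother_idx]
    # optional half-siblings: a slice of children live in a different
    # household than their mother's (shared mother only), and a slice of
    # households receive a second mother (shared household only)
    if config.half_sibling_rate > 0:
        foster = rng.random(n_children) < config.half_sibling_rate
        child_hh = child_hh.copy()
        child_hh[foster] = n_hh + np.arange(int(foster.sum()))  # new household ids

    child_id = np.array([f"c{i:07d}" for i in range(n_children)])
    mother_id = np.array([f"m{i:06d}" for i in range(n_mothers)])

    # --- testing ----------------------------------------------------------
    age = birth_offset  # completed months since birth, for the living
    eligible = alive & (age >= 6) & (age < 60) & (child_hh < n_hh)
    observed = np.array([GENOTYPES[g] for g in child_gt], dtype=object)
    if config.sensitivity < 1.0 or config.specificity < 1.0:
        observed[eligible] = apply_test_error(
            observed[eligible], config.sensitivity, config.specificity, rng
        )

    def _hh_weight(hh: np.ndarray) -> np.ndarray:
        w = np.full(len(hh), np.nan)
        ok = hh < n_hh
        w[ok] = weight_hh[hh[ok]]
        return w

    roster = pd.DataFrame(
        {
            "stratum_id": stratum_of_cluster[child_cluster[eligible]],
            "cluster_id": child_cluster[eligible],
            "household_id": child_hh[eligible],
            "child_id": child_id[eligible],
            "mother_id": pd.NA,
            "zone": [zones[z] for z in zone_of_cluster[child_cluster[eligible]]],
            "urban": urban_of_cluster[child_cluster[eligible]].astype(int),
            "age_months": age[eligible],
            "alive": True,
            "age_at_death_months": np.nan,
            "genotype": observed[eligible],
            "weight": _hh_weight(child_hh[eligible]),
        }
    )

    matched_mother = rng.random(n_mothers) >= config.mother_match_failure
    in_bh = matched_mother[mother_idx]
    birth_history = pd.DataFrame(
        {
            "mother_id": mother_id[mother_idx[in_bh]],
            "household_id": child_hh[in_bh],
            "child_id": child_id[in_bh],
            "birth_offset_months": birth_offset[in_bh],
            "alive": alive[in_bh],
            "age_at_death_months": death_age[in_bh],
        }
    )

    ground_truth = pd.DataFrame(
        {
            "child_id": child_id,
            "true_genotype": [GENOTYPES[g] for g in child_gt],
            "mother_genotype": [GENOTYPES[g] for g in mother_gt[mother_idx]],
            "father_genotype": [GENOTYPES[g] for g in father_gt[mother_idx]],
            "birth_offset_months": birth_offset,
            "died_u5": died_u5,
            "death_age_months": death_age,
            "cluster_id": child_cluster,
            "zone": [zones[z] for z in zone_of_cluster[child_cluster]],
        }
    )
    return roster, birth_history, ground_truth


def truth_report(ground_truth: pd.DataFrame, config: SimConfig) -> dict[str, float]:
    """Exact bookkeeping of the generated population for recovery tests."""
    gt = ground_truth["true_genotype"]
    cls = gt.map(GENOTYPE_CLASS)
    n = len(ground_truth)
    died = ground_truth["died_u5"].astype(bool)
    out = {
        "n_children": float(n),
        "prev_ss_birth": float((gt == "SS").mean()),
        "prev_scd_birth": float(cls.eq("SCD").mean()),
        "gamma_trait_true": config.gamma_trait,
        "gamma_scd_true": config.gamma_scd,
        "m_aa_true": config.m_aa,
        "death_rate_aa": float(1000.0 * died[cls == "AA"].mean()),
        "death_rate_scd": float(1000.0 * died[cls == "SCD"].mean())
        if cls.eq("SCD").any()
        else float("nan"),
    }
    return out
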