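"""Empirical-Bayes decomposition of SLC mortality into genotype mortality.

The excess-mortality regression yields beta: extra under-5 deaths per 1000
livebirths in the Trait and SCD sibling-group label categories relative to the
AA SLC.  But an SLC is a *mixture* of true genotypes — an untested sibling of
a child who tested SS is far from certain to have SCD itself.  The composition
matrix M gives, per SLC, the expected share of members in each genotype class
(AA, Trait, SCD), obtained by Mendelian parent-pair posteriors: for every
full-sibling group the tested members' genotypes update a Hardy-Weinberg prior
over the 21 parent-pair states, and each untested member contributes its
implied sibling genotype-class probabilities.

With gamma_AA fixed at 0 (reference coding), expected SLC-level excess is

    beta_s = sum_g (M[s, g] - M[AA-SLC, g]) * gamma_g,   s in {Trait, SCD},

a 2x2 linear system D gamma = beta whose solution converts label-level excess
into genotype-level excess mortality.  Uncertainty is propagated by a single
stratified cluster bootstrap over the whole pipeline (allele frequencies,
posteriors, M, beta and the solve are all recomputed in every replicate),
optionally redrawing the parental SCD-fitness parameter per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .genotype_model import (
    CLASS_MAP,
    CLASSES,
    GENOTYPE_CLASS,
    GENOTYPES,
    TRANSMISSION,
    AlleleFrequencies,
    FitnessModel,
    InconsistentObservationError,
    parent_pair_prior,
)
from .mortality_models import ExcessEstimates, build_lpm_design, fit_excess_mortality
from .prevalence import weighted_allele_frequencies
from .sibling_linkage import cohort_filter

__all__ = [
    "CompositionMatrix",
    "GenotypeMortality",
    "BurdenAttribution",
    "GammaBootstrap",
    "composition_matrix",
    "child_class_probs",
    "scd_population_shares",
    "solve_genotype_mortality",
    "bootstrap_gamma",
    "attributable_burden",
]

logger = logging.getLogger(__name__)

_GT_INDEX = {g: i for i, g in enumerate(GENOTYPES)}
SLC_ORDER = ("AA", "Trait", "SCD")


@dataclass(frozen=True)
class CompositionMatrix:
    """Expected genotype-class composition of each SLC (rows sum to 1).

    ``matrix`` rows are SLCs (AA, Trait, SCD) and columns genotype classes
    (AA, Trait, SCD); ``row_weights`` are the weighted child counts behind
    each row (the SLC sizes in the cohort).
    """

    matrix: pd.DataFrame
    row_weights: pd.Series

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.shape != (3, 3):
            raise ValueError("composition matrix must be 3x3")
        if (m < -1e-9).any() or (m > 1 + 1e-9).any():
            raise ValueError("composition entries must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")

    def difference_system(self) -> np.ndarray:
        """The 2x2 matrix D of row differences vs the AA SLC, columns
        (Trait, SCD) genotype classes."""
        m = self.matrix.to_numpy()
        return m[1:, 1:] - m[0, 1:]


@dataclass(frozen=True)
class GenotypeMortality:
    """Genotype-level excess under-5 mortality per 1000 livebirths.

    ``gamma`` holds the Trait and SCD excesses vs the AA genotype;
    ``m_aa`` is the baseline AA-genotype mortality (the AA-SLC crude rate
    purged of its non-AA members' excess), ``m_scd = m_aa + gamma_SCD`` and
    ``relative_risk = m_scd / m_aa``.  ``m_aa_slc_crude`` is the naive AA-SLC
    crude rate, reported alongside.
    """

    gamma: pd.Series
    m_aa: float | None
    m_scd: float | None
    relative_risk: float | None
    m_aa_slc_crude: float | None
    condition_number: float

    def __post_init__(self) -> None:
        if self.m_aa is not None and self.m_scd is not None:
            if abs(self.m_scd - (self.m_aa + self.gamma["SCD"])) > 1e-6:
                raise ValueError("m_scd inconsistent with m_aa + gamma_SCD")


@dataclass(frozen=True)
class BurdenAttribution:
    """Share of national under-5 mortality carried by children with SCD."""

    prev_scd: float
    m_overall: float
    total_share_pct: float
    excess_share_pct: float
    annual_excess_deaths: float | None = None

    def __post_init__(self) -> None:
        if self.excess_share_pct > self.total_share_pct + 1e-9:
            raise ValueError("excess share cannot exceed total share")


def _family_evidence(children: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Factorize full-sibling groups and compute parent-pair likelihoods.

    Returns (family code per child, F x 21 likelihood matrix).  The likelihood
    of a parent pair is the product of Mendelian transmission probabilities of
    the family's tested (non-Other) genotypes.
    """
    fam_codes, uniques = pd.factorize(children["sibling_group_id"])
    n_fam = len(uniques)
    counts = np.zeros((n_fam, len(GENOTYPES)))
    tested = children["tested"].astype(bool).to_numpy()
    geno = children["genotype"]
    informative = tested & geno.map(GENOTYPE_CLASS).isin(CLASSES).to_numpy()
    gt_idx = geno[informative].map(_GT_INDEX).to_numpy(dtype=int)
    np.add.at(counts, (fam_codes[informative], gt_idx), 1.0)
    # L[f, pair] = prod_g T[pair, g] ** count[f, g]; 0**0 == 1 handles zeros
    lik = np.ones((n_fam, TRANSMISSION.shape[0]))
    for g in range(len(GENOTYPES)):
        col = counts[:, g]
        if col.any():
            lik *= TRANSMISSION[:, g][None, :] ** col[:, None]
    return fam_codes, lik


def _sibling_class_matrix(prior: np.ndarray, lik: np.ndarray) -> np.ndarray:
    """Per family: class probabilities (AA, Trait, SCD) of an untested sibling.

    Families whose evidence has zero mass under the prior fall back to a
    uniform prior over the supported parent pairs (this only occurs when a
    resampled allele frequency degenerates to zero).
    """
    post = prior[None, :] * lik
    norm = post.sum(axis=1)
    bad = norm <= 0
    if bad.any():
        logger.warning(
            "%d families impossible under prior; using likelihood-only posterior",
            int(bad.sum()),
        )
        fallback = lik[bad]
        fnorm = fallback.sum(axis=1)
        if (fnorm <= 0).any():
            raise InconsistentObservationError(
                "family evidence impossible under every parent pair"
            )
        post[bad] = fallback
        norm[bad] = fnorm
    post /= norm[:, None]
    cls = (post @ TRANSMISSION) @ CLASS_MAP
    cls /= cls.sum(axis=1, keepdims=True)
    return cls


def child_class_probs(
    children: pd.DataFrame,
    freqs: AlleleFrequencies | None = None,
    fitness: FitnessModel = FitnessModel(),
) -> pd.DataFrame:
    """Genotype-class probabilities (AA, Trait, SCD) for every child.

    Tested children contribute a point mass on their observed class; untested
    children the Mendelian sibling distribution implied by their full-sibling
    group's parent-pair posterior.  Children with an Other (CC) result get
    NaN.  When ``freqs`` is omitted the prior uses the national weighted
    allele frequencies of the tested children in ``children``.
    """
    if freqs is None:
        freqs = weighted_allele_frequencies(
            children.loc[children["tested"].astype(bool)]
        )
    fam_codes, lik = _family_evidence(children)
    cls_fam = _sibling_class_matrix(parent_pair_prior(freqs, fitness).probs, lik)
    probs = cls_fam[fam_codes]

    tested = children["tested"].astype(bool).to_numpy()
    child_class = children["genotype"].map(GENOTYPE_CLASS)
    for k, c in enumerate(CLASSES):
        probs[tested, k] = (child_class[tested] == c).to_numpy(dtype=float)
    other = (child_class == "Other").to_numpy()
    probs[other] = np.nan
    return pd.DataFrame(
        probs, index=children.index, columns=[f"p_{c}" for c in CLASSES]
    )


def composition_matrix(
    children: pd.DataFrame,
    freqs: AlleleFrequencies | None = None,
    fitness: FitnessModel = FitnessModel(),
    cohort: str | tuple[float, float] = "older",
    label_col: str = "slc_label",
) -> CompositionMatrix:
    """Expected genotype-class composition M of each SLC in a cohort.

    Parent-pair posteriors use the tested members of every full-sibling group
    (whatever their cohort); only cohort members' class probabilities are
    aggregated, weighted by sample weight, into the M rows.
    """
    probs = child_class_probs(children, freqs, fitness)
    cohort_children = cohort_filter(children, cohort)
    rows, weights = {}, {}
    for slc in SLC_ORDER:
        members = cohort_children.loc[
            (cohort_children[label_col] == slc) & cohort_children["weight"].notna()
        ]
        p = probs.loc[members.index].dropna()
        w = members.loc[p.index, "weight"].to_numpy(dtype=float)
        if len(w) == 0 or w.sum() <= 0:
            raise ValueError(f"SLC {slc!r} has no weighted members in the cohort")
        rows[slc] = w @ p.to_numpy() / w.sum()
        weights[slc] = float(w.sum())
    matrix = pd.DataFrame(rows, index=list(CLASSES)).T.loc[list(SLC_ORDER)]
    matrix.columns = list(CLASSES)
    return CompositionMatrix(matrix=matrix, row_weights=pd.Series(weights))


def scd_population_shares(
    m: CompositionMatrix | pd.DataFrame, row_weights: pd.Series | None = None
) -> pd.Series:
    """Share of all SCD-genotype children found in each SLC.

    share_s = w_s M[s, SCD] / sum_s w_s M[s, SCD]: even though the SCD SLC is
    enriched for SCD genotypes, its small size means most children with SCD
    sit in the much larger AA and Trait SLCs.
    """
    if isinstance(m, CompositionMatrix):
        matrix, row_weights = m.matrix, m.row_weights
    else:
        matrix = m
        if row_weights is None:
            raise ValueError("row_weights required with a bare matrix")
    contrib = row_weights.loc[list(SLC_ORDER)] * matrix["SCD"].loc[list(SLC_ORDER)]
    total = contrib.sum()
    if total <= 0:
        raise ValueError("no SCD mass in any SLC")
    return contrib / total


def solve_genotype_mortality(
    beta: ExcessEstimates | pd.Series,
    m: CompositionMatrix,
    m_aa_slc_crude: float | None = None,
    det_tol: float = 1e-10,
) -> GenotypeMortality:
    """Solve D gamma = beta for genotype-level excess mortality.

    D is the matrix of M-row differences vs the AA SLC over the Trait and SCD
    genotype columns (gamma_AA = 0 by reference coding).  When the AA-SLC
    crude rate (per 1000) is supplied, the AA-genotype baseline is recovered
    as that rate minus the solved excess contributions of the AA SLC's non-AA
    members.
    """
    b = beta.beta if isinstance(beta, ExcessEstimates) else beta
    b = np.asarray([b["Trait"], b["SCD"]], dtype=float)
    d = m.difference_system()
    det = float(np.linalg.det(d))
    if abs(det) < det_tol:
        raise np.linalg.LinAlgError(
            f"composition difference system is singular (det={det:.3e}); "
            f"M=\n{m.matrix}"
        )
    gamma = np.linalg.solve(d, b)
    cond = float(np.linalg.cond(d))
    gamma_s = pd.Series(gamma, index=["Trait", "SCD"])
    m_aa = m_scd = rr = None
    if m_aa_slc_crude is not None:
        aa_row = m.matrix.loc["AA"]
        m_aa = float(
            m_aa_slc_crude - aa_row["Trait"] * gamma[0] - aa_row["SCD"] * gamma[1]
        )
        m_scd = m_aa + float(gamma[1])
        rr = m_scd / m_aa if m_aa > 0 else np.nan
    return GenotypeMortality(
        gamma=gamma_s,
        m_aa=m_aa,
        m_scd=m_scd,
        relative_risk=rr,
        m_aa_slc_crude=m_aa_slc_crude,
        condition_number=cond,
    )


def attributable_burden(
    prev_scd: float,
    gamma_scd: float,
    m_scd: float,
    m_overall: float,
    annual_deaths: float | None = None,
) -> BurdenAttribution:
    """Population burden shares attributable to sickle cell disease.

    All mortality rates are per 1000 livebirths; ``prev_scd`` is the SCD birth
    prevalence as a proportion.  Total share = prev * m_scd / m_overall;
    excess share replaces m_scd with the excess gamma_scd.  When UNICEF-style
    annual under-5 deaths are supplied, the absolute excess death count is
    excess share x annual deaths.
    """
    if m_overall <= 0:
        raise ValueError("overall mortality must be positive")
    total = 100.0 * prev_scd * m_scd / m_overall
    excess = 100.0 * prev_scd * gamma_scd / m_overall
    absolute = annual_deaths * excess / 100.0 if annual_deaths is not None else None
    return BurdenAttribution(
        prev_scd=prev_scd,
        m_overall=m_overall,
        total_share_pct=total,
        excess_share_pct=excess,
        annual_excess_deaths=absolute,
    )


# ---------------------------------------------------------------------------
# end-to-end cluster bootstrap
# ---------------------------------------------------------------------------


@dataclass
class GammaBootstrap:
    """Point estimates and bootstrap percentile CIs for the decomposition."""

    point: GenotypeMortality
    beta_point: ExcessEstimates
    m_point: CompositionMatrix
    summary: pd.DataFrame
    replicates: pd.DataFrame = field(repr=False)
    n_reps: int
    n_dropped: int
    seed: int

    def ci(self, quantity: str) -> tuple[float, float]:
        row = self.summary.loc[quantity]
        return float(row["lower"]), float(row["upper"])


class _BootstrapEngine:
    """Precomputed survey structure for fast whole-pipeline replicates.

    Cluster resampling within strata only changes the multiplicity of each
    cluster, so every pipeline quantity is precomputed as per-cluster sums
    (allele counts, regression Gram matrices, weighted class-probability
    aggregates, death/birth totals) and a replicate reduces to a handful of
    small matrix products.
    """

    def __init__(self, children: pd.DataFrame, label_col: str = "slc_label"):
        self.label_col = label_col
        clusters = (
            children[["stratum_id", "cluster_id"]]
            .drop_duplicates()
            .sort_values(["stratum_id", "cluster_id"])
            .reset_index(drop=True)
        )
        key = list(zip(clusters["stratum_id"], clusters["cluster_id"]))
        self.n_clusters = len(key)
        code_of = {k: i for i, k in enumerate(key)}
        child_key = list(zip(children["stratum_id"], children["cluster_id"]))
        self.child_cluster = np.array([code_of[k] for k in child_key])
        strat_codes, self.strata = pd.factorize(clusters["stratum_id"], sort=True)
        self.clusters_by_stratum = [
            np.flatnonzero(strat_codes == s) for s in range(len(self.strata))
        ]

        # allele-count totals per cluster from tested children
        tested = children["tested"].astype(bool).to_numpy()
        self.allele_per_cluster = np.zeros((self.n_clusters, 3))
        gmap = {"AA": (2, 0, 0), "AS": (1, 1, 0), "AC": (1, 0, 1),
                "SS": (0, 2, 0), "SC": (0, 1, 1), "CC": (0, 0, 2),
                "OTHER": (0, 0, 2)}
        gt = children["genotype"].astype("string").str.upper()
        ok = tested & gt.isin(gmap).to_numpy()
        counts = np.array([gmap[x] for x in gt[ok]], dtype=float)
        wt = children.loc[ok, "weight"].to_numpy(dtype=float)
        np.add.at(self.allele_per_cluster, self.child_cluster[ok], counts * wt[:, None])

        # family evidence over the full table
        self.fam_codes, self.lik = _family_evidence(children)

        # older-cohort modelling rows
        older = cohort_filter(children, "older")
        older = older.dropna(
            subset=[label_col, "weight", "died_u5", "zone", "urban", "cluster_id"]
        )
        older = older.loc[older[label_col].isin(SLC_ORDER)]
        self.older = older
        y, X, w, _, self.design_names = build_lpm_design(older, label_col)
        pos = children.index.get_indexer(older.index)
        ocl = self.child_cluster[pos]
        p = X.shape[1]
        self.gram = np.zeros((self.n_clusters, p, p))
        np.add.at(self.gram, ocl, np.einsum("ni,nj->nij", X * w[:, None], X))
        self.xty = np.zeros((self.n_clusters, p))
        np.add.at(self.xty, ocl, X * (w * y)[:, None])

        # composition aggregation: key = cluster * 3 + slc
        slc_code = older[label_col].map({s: i for i, s in enumerate(SLC_ORDER)})
        keys = ocl * 3 + slc_code.to_numpy(dtype=int)
        self.weight_by_key = np.bincount(keys, weights=w, minlength=self.n_clusters * 3)
        self.deaths_by_key = np.bincount(
            keys, weights=w * y, minlength=self.n_clusters * 3
        )
        o_tested = older["tested"].astype(bool).to_numpy()
        o_class = older["genotype"].map(GENOTYPE_CLASS)
        self.g_tested = np.zeros((self.n_clusters * 3, 3))
        for k, c in enumerate(CLASSES):
            mask = o_tested & (o_class == c).to_numpy()
            np.add.at(self.g_tested[:, k], keys[mask], w[mask])
        unt = ~o_tested
        self.u_matrix = sparse.csr_matrix(
            (w[unt], (keys[unt], self.fam_codes[pos][unt])),
            shape=(self.n_clusters * 3, len(self.lik)),
        )

    def multiplicities(self, rng: np.random.Generator) -> np.ndarray:
        m = np.zeros(self.n_clusters)
        for members in self.clusters_by_stratum:
            draw = members[rng.integers(0, len(members), size=len(members))]
            np.add.at(m, draw, 1.0)
        return m

    def replicate(self, m: np.ndarray, f_scd: float) -> dict[str, float] | None:
        totals = m @ self.allele_per_cluster
        if totals.sum() <= 0 or totals[0] <= 0:
            return None
        freqs = AlleleFrequencies(*(totals / totals.sum()))
        prior = parent_pair_prior(freqs, FitnessModel(f_scd)).probs
        cls_fam = _sibling_class_matrix(prior, self.lik)

        g = self.g_tested + self.u_matrix @ cls_fam  # (ncl*3, 3)
        mk = np.repeat(m, 3)
        num = (g * mk[:, None]).reshape(self.n_clusters, 3, 3).sum(axis=0)
        den = (self.weight_by_key * mk).reshape(self.n_clusters, 3).sum(axis=0)
        if (den <= 0).any():
            return None
        rows = num / den[:, None]
        rows /= rows.sum(axis=1, keepdims=True)

        deaths = (self.deaths_by_key * mk).reshape(self.n_clusters, 3).sum(axis=0)
        crude = 1000.0 * deaths / den  # per SLC
        m_overall = 1000.0 * deaths.sum() / den.sum()

        a_mat = np.tensordot(m, self.gram, axes=1)
        b_vec = m @ self.xty
        try:
            coef = np.linalg.solve(a_mat, b_vec)
        except np.linalg.LinAlgError:
            return None
        i_t = self.design_names.index("slc_Trait")
        i_s = self.design_names.index("slc_SCD")
        beta = np.array([coef[i_t], coef[i_s]]) * 1000.0

        d = rows[1:, 1:] - rows[0, 1:]
        if abs(np.linalg.det(d)) < 1e-10 or np.linalg.cond(d) > 1e8:
            return None
        gamma = np.linalg.solve(d, beta)
        m_aa = crude[0] - rows[0, 1] * gamma[0] - rows[0, 2] * gamma[1]
        m_scd = m_aa + gamma[1]
        prev = freqs.pS**2 + 2 * freqs.pS * freqs.pC
        return {
            "beta_Trait": beta[0],
            "beta_SCD": beta[1],
            "gamma_Trait": gamma[0],
            "gamma_SCD": gamma[1],
            "m_aa": m_aa,
            "m_scd": m_scd,
            "relative_risk": m_scd / m_aa if m_aa > 0 else np.nan,
            "prev_scd": prev,
            "m_overall": m_overall,
            "total_share_pct": 100.0 * prev * m_scd / m_overall,
            "excess_share_pct": 100.0 * prev * gamma[1] / m_overall,
        }


def bootstrap_gamma(
    children: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    fitness: FitnessModel = FitnessModel(),
    draw_fitness: bool = False,
    fitness_bounds: tuple[float, float] = (0.2, 0.8),
    label_col: str = "slc_label",
    point_method: str = "auto",
) -> GammaBootstrap:
    """End-to-end uncertainty for the genotype-mortality decomposition.

    Every replicate resamples survey clusters with replacement within strata
    and recomputes allele frequencies, parent-pair posteriors, the composition
    matrix M, the excess-mortality regression beta and the solved gamma, plus
    baseline and burden quantities.  With ``draw_fitness`` the parental SCD
    survival ``f_scd`` is redrawn uniformly from ``fitness_bounds`` in each
    replicate, propagating prior uncertainty about SCD survival to parenthood.

    ``children`` is the full linked, labelled table (all cohorts) with
    ``died_u5`` present.  Replicates use the WLS fixed-effects regression (the
    resampling itself carries the cluster correlation); the point estimate
    uses the full estimation ladder.  Replicates with a singular composition
    system are dropped and counted; more than 10% drops triggers a warning.
    """
    # children without design information (no tested child in their family's
    # household) carry no evidence and no weight; they cannot enter any stage
    children = children.dropna(subset=["cluster_id", "stratum_id"]).reset_index(
        drop=True
    )
    engine = _BootstrapEngine(children, label_col)
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for _ in range(n_reps):
        m = engine.multiplicities(rng)
        f = rng.uniform(*fitness_bounds) if draw_fitness else fitness.f_scd
        rep = engine.replicate(m, f)
        if rep is None:
            n_dropped += 1
        else:
            rows.append(rep)
    if n_dropped > 0.1 * n_reps:
        logger.warning(
            "%d of %d bootstrap replicates dropped (singular systems)",
            n_dropped,
            n_reps,
        )
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    reps = pd.DataFrame(rows)

    # point estimates from the unresampled data with the full ladder
    freqs = weighted_allele_frequencies(
        children.loc[children["tested"].astype(bool)]
    )
    m_point = composition_matrix(children, freqs, fitness, "older", label_col)
    older = engine.older
    beta_point = fit_excess_mortality(older, label_col, method=point_method)
    from .mortality_models import crude_rates

    crude = crude_rates(older, label_col)
    aa_crude = 1000.0 * crude.loc["AA", "deaths_weighted"] / crude.loc["AA", "births_weighted"]
    point = solve_genotype_mortality(beta_point, m_point, m_aa_slc_crude=aa_crude)

    q = reps.quantile([0.025, 0.5, 0.975])
    summary = pd.DataFrame(
        {"lower": q.loc[0.025], "median": q.loc[0.5], "upper": q.loc[0.975]}
    )
    return GammaBootstrap(
        point=point,
        beta_point=beta_point,
        m_point=m_point,
        summary=summary,
        replicates=reps,
        n_reps=n_reps,
        n_dropped=n_dropped,
        seed=seed,
    )
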