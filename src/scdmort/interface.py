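"""File schemas, configuration and the assembled analysis pipeline.

Two plain-CSV tables are the data contract:

``roster`` — one row per genotype-tested child::

    stratum_id, cluster_id, household_id, child_id, mother_id, zone, urban,
    age_months, alive, age_at_death_months, genotype, weight

with ``genotype`` in {AA, AS, AC, SS, SC, CC, OTHER, NA}.

``birth_history`` — one row per child ever born to an interviewed mother::

    mother_id, household_id, child_id, birth_offset_months, alive,
    age_at_death_months

Ages and offsets are completed months; the interview date is the time origin.
``run_pipeline`` chains prevalence estimation, sibling linkage and labelling,
the mortality models and the genotype decomposition, and writes tidy CSV/JSON
outputs plus a manifest (input hashes, configuration, seed) so every number
is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decomposition, mortality_models, prevalence, sibling_linkage
from .genotype_model import FitnessModel

__all__ = [
    "ROSTER_COLUMNS",
    "BIRTH_HISTORY_COLUMNS",
    "VALID_GENOTYPES",
    "TableRead",
    "PipelineConfig",
    "read_roster",
    "read_birth_history",
    "write_roster",
    "write_birth_history",
    "run_pipeline",
    "dhs_recode_adapter",
]

logger = logging.getLogger(__name__)

ROSTER_COLUMNS = [
    "stratum_id",
    "cluster_id",
    "household_id",
    "child_id",
    "mother_id",
    "zone",
    "urban",
    "age_months",
    "alive",
    "age_at_death_months",
    "genotype",
    "weight",
]
BIRTH_HISTORY_COLUMNS = [
    "mother_id",
    "household_id",
    "child_id",
    "birth_offset_months",
    "alive",
    "age_at_death_months",
]
VALID_GENOTYPES = {"AA", "AS", "AC", "SS", "SC", "CC", "OTHER"}


@dataclass
class TableRead:
    """A parsed table plus its row-level validation report."""

    data: pd.DataFrame
    quarantined: pd.DataFrame
    messages: list[str] = field(default_factory=list)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing mandatory column(s): {missing}")


def read_roster(path: str | Path) -> TableRead:
    """Read and validate the tested-children roster CSV.

    Rows with an unrecognised genotype code or a negative weight are
    quarantined (returned separately, excluded from ``data``).
    """
    df = pd.read_csv(path, dtype={"child_id": str, "mother_id": str})
    _require_columns(df, [c for c in ROSTER_COLUMNS if c != "mother_id"], "roster")
    if "mother_id" not in df.columns:
        df["mother_id"] = pd.NA
    messages: list[str] = []
    geno = df["genotype"].astype("string").str.upper()
    bad_geno = ~(geno.isin(VALID_GENOTYPES) | geno.isna())
    bad_weight = pd.to_numeric(df["weight"], errors="coerce").fillna(-1) < 0
    bad = bad_geno | bad_weight
    if bad.any():
        messages.append(f"quarantined {int(bad.sum())} roster rows")
        logger.warning("%s", messages[-1])
    data = df.loc[~bad].copy()
    data["genotype"] = geno[~bad]
    data["weight"] = pd.to_numeric(data["weight"])
    data["urban"] = pd.to_numeric(data["urban"]).astype(int)
    data["age_months"] = pd.to_numeric(data["age_months"])
    return TableRead(data=data.reset_index(drop=True), quarantined=df.loc[bad], messages=messages)


def read_birth_history(path: str | Path) -> TableRead:
    """Read and validate the maternal birth-history CSV."""
    df = pd.read_csv(path, dtype={"child_id": str, "mother_id": str})
    _require_columns(df, BIRTH_HISTORY_COLUMNS, "birth_history")
    offset = pd.to_numeric(df["birth_offset_months"], errors="coerce")
    bad = offset.isna() | (offset < 0)
    messages: list[str] = []
    if bad.any():
        messages.append(f"quarantined {int(bad.sum())} birth-history rows")
        logger.warning("%s", messages[-1])
    data = df.loc[~bad].copy()
    data["birth_offset_months"] = offset[~bad]
    data["alive"] = data["alive"].astype(bool)
    data["age_at_death_months"] = pd.to_numeric(data["age_at_death_months"])
    return TableRead(data=data.reset_index(drop=True), quarantined=df.loc[bad], messages=messages)


def write_roster(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=ROSTER_COLUMNS)


def write_birth_history(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=BIRTH_HISTORY_COLUMNS)


#: minimal DHS recode variable mapping (optional adapter; untested against
#: real recode exports — provided as a convenience only)
_DHS_ROSTER_MAP = {
    "v023": "stratum_id",
    "v001": "cluster_id",
    "v002": "household_id",
    "v024": "zone",
    "v025": "urban",
    "hv005": "weight",
    "hc1": "age_months",
    "hml35": "genotype",
}


def dhs_recode_adapter(df: pd.DataFrame, mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Rename standard DHS recode variables to the roster schema."""
    return df.rename(columns={**_DHS_ROSTER_MAP, **(mapping or {})})


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; all defaults end up in the manifest."""

    roster_path: str
    birth_history_path: str
    out_dir: str
    n_reps: int = 1000
    seed: int = 0
    f_scd: float = 0.5
    draw_fitness: bool = False
    fitness_bounds: tuple[float, float] = (0.2, 0.8)
    other_as_cc: bool = True
    older_cohort_months: tuple[int, int] = (60, 180)
    annual_under5_deaths: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.fitness_bounds, list):
            cfg.fitness_bounds = tuple(cfg.fitness_bounds)
        if isinstance(cfg.older_cohort_months, list):
            cfg.older_cohort_months = tuple(cfg.older_cohort_months)
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute prevalence -> linkage -> mortality -> decomposition.

    Writes ``prevalence.csv``, ``children.csv`` (linked + labelled),
    ``km_curves.csv``, ``summary.json`` and ``manifest.json`` under
    ``config.out_dir`` and returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    roster_read = read_roster(config.roster_path)
    bh_read = read_birth_history(config.birth_history_path)
    roster, bh = roster_read.data, bh_read.data

    # --- stage 1: prevalence ---------------------------------------------
    freqs = prevalence.weighted_allele_frequencies(roster, config.other_as_cc)
    prev = prevalence.hwe_prevalence_with_ci(
        roster, ("SS", "SC"), n_reps=config.n_reps, seed=config.seed,
        other_as_cc=config.other_as_cc,
    )
    prev_rows = [
        {
            "group": "national",
            "quantity": f"prev_{g}",
            "point": r.point,
            "lo95": r.lower,
            "hi95": r.upper,
            "plugin": r.plugin,
            "n_reps": r.n_reps,
            "seed": r.seed,
        }
        for g, r in prev.items()
    ]
    pd.DataFrame(prev_rows).to_csv(out / "prevalence.csv", index=False)

    # --- stage 2: linkage and labelling ----------------------------------
    children = sibling_linkage.link_siblings(roster, bh)
    children = sibling_linkage.assign_slc(children)
    children = sibling_linkage.add_under5_death(children)
    children.to_csv(out / "children.csv", index=False)

    # --- stage 3: mortality models ---------------------------------------
    km_cohort = sibling_linkage.cohort_filter(children, "km")
    curves = mortality_models.weighted_km(km_cohort)
    pd.concat([c.to_frame() for c in curves.values()]).to_csv(
        out / "km_curves.csv", index=False
    )
    older = sibling_linkage.cohort_filter(children, config.older_cohort_months)
    crude = mortality_models.crude_rates(older)
    hr = mortality_models.fit_hazard_ratio(km_cohort)

    # --- stage 4: decomposition with end-to-end bootstrap -----------------
    boot = decomposition.bootstrap_gamma(
        children,
        n_reps=config.n_reps,
        seed=config.seed,
        fitness=FitnessModel(config.f_scd),
        draw_fitness=config.draw_fitness,
        fitness_bounds=config.fitness_bounds,
    )
    prev_scd_point = (
        prev["SS"].point + prev["SC"].point if "SC" in prev else prev["SS"].point
    )
    m_overall = float(boot.summary.loc["m_overall", "median"])
    burden = decomposition.attributable_burden(
        prev_scd=prev_scd_point,
        gamma_scd=float(boot.point.gamma["SCD"]),
        m_scd=float(boot.point.m_scd),
        m_overall=float(
            1000.0 * crude["deaths_weighted"].sum() / crude["births_weighted"].sum()
        ),
        annual_deaths=config.annual_under5_deaths,
    )

    summary = {
        "prevalence": {
            "allele_freqs": {"pA": freqs.pA, "pS": freqs.pS, "pC": freqs.pC},
            **{
                f"prev_{g}": {"point": r.point, "lo95": r.lower, "hi95": r.upper}
                for g, r in prev.items()
            },
        },
        "slc_counts": crude.reset_index().to_dict(orient="records"),
        "beta": {
            "Trait": boot.beta_point.beta["Trait"],
            "SCD": boot.beta_point.beta["SCD"],
            "method": boot.beta_point.method,
            "ci": boot.beta_point.conf_int().to_dict(orient="index"),
        },
        "M": boot.m_point.matrix.to_dict(orient="index"),
        "slc_weights": boot.m_point.row_weights.to_dict(),
        "scd_population_shares": decomposition.scd_population_shares(
            boot.m_point
        ).to_dict(),
        "gamma": {
            "Trait": boot.point.gamma["Trait"],
            "SCD": boot.point.gamma["SCD"],
            "ci_Trait": list(boot.ci("gamma_Trait")),
            "ci_SCD": list(boot.ci("gamma_SCD")),
            "m_aa": boot.point.m_aa,
            "m_scd": boot.point.m_scd,
            "relative_risk": boot.point.relative_risk,
            "m_aa_slc_crude": boot.point.m_aa_slc_crude,
        },
        "hazard_ratios": hr.to_dict(orient="index"),
        "attribution": {
            "prev_scd": burden.prev_scd,
            "m_overall": burden.m_overall,
            "total_share_pct": burden.total_share_pct,
            "excess_share_pct": burden.excess_share_pct,
            "annual_excess_deaths": burden.annual_excess_deaths,
        },
        "diagnostics": {
            "condition_number": boot.point.condition_number,
            "beta_method": boot.beta_point.method,
            "bootstrap_dropped": boot.n_dropped,
            "n_reps": boot.n_reps,
            "roster_quarantined": roster_read.n_quarantined,
            "birth_history_quarantined": bh_read.n_quarantined,
        },
    }
    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "inputs": {
            "roster": {"path": str(config.roster_path), "sha256": _sha256(config.roster_path)},
            "birth_history": {
                "path": str(config.birth_history_path),
                "sha256": _sha256(config.birth_history_path),
            },
        },
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
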