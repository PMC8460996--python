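"""Mendelian and Hardy-Weinberg machinery for the HBB locus.

The sickle locus carries three alleles of interest: the normal A allele and
the two haemoglobinopathy alleles S and C.  Six unordered genotypes follow
(AA, AS, AC, SS, SC, CC); clinically they collapse into the classes
AA (normal), Trait (AS/AC, asymptomatic carriers), SCD (SS/SC, sickle cell
disease) and Other (CC, excluded from mortality inference).

This module provides the genotype distribution implied by Hardy-Weinberg
equilibrium (HWE), Mendelian transmission from a parent pair to a child,
priors and Bayesian posteriors over the 21 unordered parent-pair states given
the tested genotypes of a sibling group, and the implied genotype distribution
of an untested full sibling.  All distributions are small fixed-length numpy
vectors; everything is exact arithmetic (no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ALLELES",
    "GENOTYPES",
    "GENOTYPE_CLASS",
    "CLASSES",
    "PARENT_PAIRS",
    "TRANSMISSION",
    "AlleleFrequencies",
    "FitnessModel",
    "GenotypeDistribution",
    "ParentPairDistribution",
    "InconsistentObservationError",
    "hwe_genotypes",
    "child_given_parents",
    "parent_pair_prior",
    "parent_pair_posterior",
    "sibling_genotype_probs",
    "class_probabilities",
]

ALLELES = ("A", "S", "C")
GENOTYPES = ("AA", "AS", "AC", "SS", "SC", "CC")
#: clinical class of each genotype; CC ("Other") is excluded from mortality work
GENOTYPE_CLASS = {
    "AA": "AA",
    "AS": "Trait",
    "AC": "Trait",
    "SS": "SCD",
    "SC": "SCD",
    "CC": "Other",
}
CLASSES = ("AA", "Trait", "SCD")

_GT_INDEX = {g: i for i, g in enumerate(GENOTYPES)}
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

#: the two alleles carried by each genotype
_GT_ALLELES = {
    "AA": ("A", "A"),
    "AS": ("A", "S"),
    "AC": ("A", "C"),
    "SS": ("S", "S"),
    "SC": ("S", "C"),
    "CC": ("C", "C"),
}


def _genotype_from_alleles(a: str, b: str) -> str:
    i, j = sorted((_ALLELE_INDEX[a], _ALLELE_INDEX[b]))
    return {(0, 0): "AA", (0, 1): "AS", (0, 2): "AC",
            (1, 1): "SS", (1, 2): "SC", (2, 2): "CC"}[(i, j)]


#: the 21 unordered parent-pair states, canonical order
PARENT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(GENOTYPES, 2)
)
_PAIR_INDEX = {p: i for i, p in enumerate(PARENT_PAIRS)}


def _canonical_pair(g1: str, g2: str) -> tuple[str, str]:
    i, j = sorted((_GT_INDEX[g1], _GT_INDEX[g2]))
    return (GENOTYPES[i], GENOTYPES[j])


def _transmission_matrix() -> np.ndarray:
    """21 x 6 matrix: P(child genotype | parent pair) by Mendelian draws."""
    out = np.zeros((len(PARENT_PAIRS), len(GENOTYPES)))
    for pi, (g1, g2) in enumerate(PARENT_PAIRS):
        for a in _GT_ALLELES[g1]:
            for b in _GT_ALLELES[g2]:
                out[pi, _GT_INDEX[_genotype_from_alleles(a, b)]] += 0.25
    return out


TRANSMISSION = _transmission_matrix()
TRANSMISSION.setflags(write=False)

#: 6 x 3 map from genotype probabilities to (AA, Trait, SCD) class probabilities;
#: CC maps to none of the three (class Other)
CLASS_MAP = np.zeros((len(GENOTYPES), len(CLASSES)))
for _g, _c in GENOTYPE_CLASS.items():
    if _c in CLASSES:
        CLASS_MAP[_GT_INDEX[_g], CLASSES.index(_c)] = 1.0
CLASS_MAP.setflags(write=False)


class InconsistentObservationError(ValueError):
    """Observed genotypes are impossible under every parent pair in the prior."""


@dataclass(frozen=True)
class AlleleFrequencies:
    """Population frequencies of the A, S and C alleles at HBB.

    Frequencies must be in [0, 1] and sum to 1 (tolerance 1e-12 on the sum,
    which is then exactly renormalised).
    """

    pA: float
    pS: float
    pC: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.pA, self.pS, self.pC)
        if any(v < -1e-15 or v > 1 + 1e-12 for v in vals):
            raise ValueError(f"allele frequencies must lie in [0, 1]: {vals}")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must sum to 1, got {total!r}")
        object.__setattr__(self, "pA", self.pA / total)
        object.__setattr__(self, "pS", self.pS / total)
        object.__setattr__(self, "pC", self.pC / total)

    def as_array(self) -> np.ndarray:
        return np.array([self.pA, self.pS, self.pC])


@dataclass(frozen=True)
class FitnessModel:
    """Relative survival to parenthood of individuals with an SCD genotype.

    ``f_scd`` multiplies the HWE probability that a *parent* carries SS or SC,
    before renormalisation: untreated sickle cell disease sharply reduces the
    chance of surviving to reproductive age, so SCD parents are rarer than HWE
    alone predicts.  1.0 means no penalty.
    """

    f_scd: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.f_scd <= 1.0):
            raise ValueError(f"f_scd must be in (0, 1], got {self.f_scd}")


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probability distribution over the six HBB genotypes."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(GENOTYPES),):
            raise ValueError(f"expected {len(GENOTYPES)} probabilities")
        if (p < -1e-12).any():
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    def __getitem__(self, genotype: str) -> float:
        return float(self.probs[_GT_INDEX[genotype]])

    def as_dict(self) -> dict[str, float]:
        return {g: float(p) for g, p in zip(GENOTYPES, self.probs)}

    def class_probs(self, renormalise: bool = False) -> dict[str, float]:
        """Collapse to (AA, Trait, SCD); optionally condition on not-Other."""
        c = self.probs @ CLASS_MAP
        if renormalise:
            tot = c.sum()
            if tot <= 0:
                raise ValueError("all mass on class Other")
            c = c / tot
        return {k: float(v) for k, v in zip(CLASSES, c)}


@dataclass(frozen=True)
class ParentPairDistribution:
    """Probability distribution over the 21 unordered parent genotype pairs."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(PARENT_PAIRS),):
            raise ValueError(f"expected {len(PARENT_PAIRS)} probabilities")
        if (p < -1e-12).any():
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    def __getitem__(self, pair: Sequence[str]) -> float:
        g1, g2 = pair
        return float(self.probs[_PAIR_INDEX[_canonical_pair(g1, g2)]])


def hwe_genotypes(freqs: AlleleFrequencies) -> GenotypeDistribution:
    """Genotype distribution under Hardy-Weinberg equilibrium.

    P(XX) = pX^2 and P(XY) = 2 pX pY for X != Y.  This is the birth-cohort
    genotype distribution under random mating, used to turn survey allele
    frequencies into birth prevalences (e.g. pS = 0.11 gives an HbSS birth
    prevalence of 1.21%).
    """
    p = freqs.as_array()
    out = np.empty(len(GENOTYPES))
    for g, i in _GT_INDEX.items():
        a, b = _GT_ALLELES[g]
        ia, ib = _ALLELE_INDEX[a], _ALLELE_INDEX[b]
        out[i] = p[ia] ** 2 if ia == ib else 2.0 * p[ia] * p[ib]
    return GenotypeDistribution(out)


def child_given_parents(pair: Sequence[str]) -> GenotypeDistribution:
    """Mendelian offspring distribution: one allele drawn uniformly per parent."""
    g1, g2 = pair
    return GenotypeDistribution(TRANSMISSION[_PAIR_INDEX[_canonical_pair(g1, g2)]])


def individual_parent_probs(
    freqs: AlleleFrequencies, fitness: FitnessModel = FitnessModel()
) -> GenotypeDistribution:
    """Genotype distribution of a single parent: HWE thinned by SCD fitness."""
    p = hwe_genotypes(freqs).probs.copy()
    for g in ("SS", "SC"):
        p[_GT_INDEX[g]] *= fitness.f_scd
    return GenotypeDistribution(p / p.sum())


def parent_pair_prior(
    freqs: AlleleFrequencies, fitness: FitnessModel = FitnessModel()
) -> ParentPairDistribution:
    """Prior over unordered parent pairs: independent thinned-HWE parents.

    Each parent's genotype probability is the HWE probability, multiplied by
    ``f_scd`` when the genotype is SS or SC, renormalised over individuals,
    and the two parents are paired independently (factor 2 for heterotypic
    pairs).
    """
    ind = individual_parent_probs(freqs, fitness).probs
    out = np.empty(len(PARENT_PAIRS))
    for pi, (g1, g2) in enumerate(PARENT_PAIRS):
        p = ind[_GT_INDEX[g1]] * ind[_GT_INDEX[g2]]
        out[pi] = p if g1 == g2 else 2.0 * p
    return ParentPairDistribution(out)


def pair_likelihood(observed: Iterable[str]) -> np.ndarray:
    """Likelihood of each of the 21 parent pairs given observed child genotypes.

    The likelihood is the product over observed children of the Mendelian
    transmission probability of their genotype.  Returned unnormalised.
    """
    lik = np.ones(len(PARENT_PAIRS))
    for g in observed:
        if GENOTYPE_CLASS[g] == "Other":
            raise ValueError(
                "genotype CC/Other must be excluded before posterior inference"
            )
        lik *= TRANSMISSION[:, _GT_INDEX[g]]
    return lik


def parent_pair_posterior(
    prior: ParentPairDistribution, observed: Iterable[str]
) -> ParentPairDistribution:
    """Bayes update of the parent-pair prior given tested children's genotypes.

    An empty observation list returns the prior unchanged.  Raises
    :class:`InconsistentObservationError` when every pair with prior support
    has zero likelihood (the observations are Mendelian-impossible under the
    prior).
    """
    observed = list(observed)
    if not observed:
        return prior
    post = prior.probs * pair_likelihood(observed)
    norm = post.sum()
    if norm <= 0.0:
        raise InconsistentObservationError(
            f"observed genotypes {observed} impossible under prior support"
        )
    return ParentPairDistribution(post / norm)


def sibling_genotype_probs(posterior: ParentPairDistribution) -> GenotypeDistribution:
    """Marginal genotype distribution of an untested full sibling.

    Mixture of Mendelian offspring distributions weighted by the parent-pair
    posterior.
    """
    return GenotypeDistribution(posterior.probs @ TRANSMISSION)


def class_probabilities(dist: GenotypeDistribution) -> np.ndarray:
    """(AA, Trait, SCD) probabilities conditioned on the genotype not being Other."""
    c = dist.probs @ CLASS_MAP
    tot = c.sum()
    if tot <= 0:
        raise ValueError("distribution has all mass on class Other")
    return c / tot
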