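"""Two-locus haplotype frequency estimation and linkage disequilibrium.

Unphased diploid genotypes identify the gametes of every subject except
the double heterozygote, which is compatible with two phase
resolutions.  The EM algorithm treats phase as the latent variable:
starting from linkage equilibrium it alternates expected-gamete-count
imputation with frequency re-estimation until the multinomial
log-likelihood stabilises.  From the fitted haplotype frequencies the
usual summaries follow: the covariance D, Lewontin's normalized |D'|,
the squared allelic correlation r^2, and a base-10 LOD comparing the
fitted model with linkage equilibrium at the same allele frequencies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    Cohort,
    SNPDef,
    UndefinedStatisticError,
    ValidationError,
)
from .stats import AssociationResult, odds_ratio_wald, predicate_table

log = logging.getLogger(__name__)

# genotype-class index: 3 * (dosage at locus 1) + (dosage at locus 2);
# dosage counts the "A"/"B" allele whose haplotype frequency is p_AB.


@dataclass
class HaplotypeFreqs:
    """MLE haplotype frequencies of a two-locus system (alleles A/a, B/b)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])

    @property
    def pA(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def pB(self) -> float:
        return self.p_AB + self.p_aB


@dataclass
class LDStats:
    D: float
    D_prime: float
    r2: float
    lod: float
    pA: float
    pB: float
    n: int


def _genotype_class_counts(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """9-vector of genotype-pair counts over pairwise-complete subjects."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    mask = ~(np.isnan(d1) | np.isnan(d2))
    d1, d2 = d1[mask].astype(int), d2[mask].astype(int)
    if len(d1) < 2:
        raise UndefinedStatisticError("fewer than two pairwise-complete subjects")
    return np.bincount(3 * d1 + d2, minlength=9).astype(float)


def _class_probs(p: np.ndarray) -> np.ndarray:
    """Genotype-class probabilities given haplotype frequencies (AB,Ab,aB,ab)."""
    pAB, pAb, paB, pab = p
    return np.array([
        pab * pab,                      # (0,0)
        2 * paB * pab,                  # (0,1)
        paB * paB,                      # (0,2)
        2 * pAb * pab,                  # (1,0)
        2 * pAB * pab + 2 * pAb * paB,  # (1,1) double het: both phases
        2 * pAB * paB,                  # (1,2)
        pAb * pAb,                      # (2,0)
        2 * pAB * pAb,                  # (2,1)
        pAB * pAB,                      # (2,2)
    ])


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    probs = _class_probs(p)
    mask = counts > 0
    if (probs[mask] <= 0).any():
        return -np.inf
    return float((counts[mask] * np.log(probs[mask])).sum())


def em_haplotypes(g1: Sequence[float], g2: Sequence[float],
                  tol: float = 1e-10, max_iter: int = 1000) -> HaplotypeFreqs:
    """EM estimate of two-locus haplotype frequencies from dosage vectors.

    ``g1``/``g2`` hold per-subject counts (0/1/2, NaN = missing) of the
    allele labelled A (locus 1) and B (locus 2).  Initialization is at
    linkage equilibrium; symmetric likelihood ties (data consisting of
    double heterozygotes only) are therefore resolved deterministically
    toward independence.  The log-likelihood is checked to be
    non-decreasing at every iteration.
    """
    counts = _genotype_class_counts(g1, g2)
    n = counts.sum()
    nA = counts @ np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
    nB = counts @ np.array([0, 1, 2, 0, 1, 2, 0, 1, 2])
    pA, pB = nA / (2 * n), nB / (2 * n)
    if counts[4] == 0 and (pA in (0.0, 1.0) or pB in (0.0, 1.0)):
        # a monomorphic marker leaves no phase ambiguity: count gametes
        # directly (LD itself is undefined downstream, not the frequencies)
        fixed = np.array([[0, 0, 0, 2], [0, 0, 1, 1], [0, 0, 2, 0],
                          [0, 1, 0, 1], [0, 0, 0, 0], [1, 0, 1, 0],
                          [0, 2, 0, 0], [1, 1, 0, 0], [2, 0, 0, 0]],
                         dtype=float)
        p = counts @ fixed / (2 * n)
        ll = _loglik(counts, p)
        return HaplotypeFreqs(*map(float, p), loglik=ll, loglik_null=ll,
                              n_iter=0, converged=True)

    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    ll = _loglik(counts, p)
    ll_null = ll  # equilibrium start is the null model at observed marginals
    converged = False
    it = 0
    # deterministic gamete contributions per genotype class (AB, Ab, aB, ab)
    fixed = np.array([
        [0, 0, 0, 2],  # (0,0)
        [0, 0, 1, 1],  # (0,1)
        [0, 0, 2, 0],  # (0,2)
        [0, 1, 0, 1],  # (1,0)
        [0, 0, 0, 0],  # (1,1) handled via E-step
        [1, 0, 1, 0],  # (1,2)
        [0, 2, 0, 0],  # (2,0)
        [1, 1, 0, 0],  # (2,1)
        [2, 0, 0, 0],  # (2,2)
    ], dtype=float)
    for it in range(1, max_iter + 1):
        w_cis = p[0] * p[3]
        w_trans = p[1] * p[2]
        denom = w_cis + w_trans
        frac_cis = 0.5 if denom == 0 else w_cis / denom
        gametes = counts @ fixed
        n_dh = counts[4]
        gametes += n_dh * np.array([frac_cis, 1 - frac_cis, 1 - frac_cis, frac_cis])
        p_new = gametes / (2 * n)
        ll_new = _loglik(counts, p_new)
        if ll_new < ll - 1e-8:
            raise AssertionError(
                f"EM log-likelihood decreased: {ll} -> {ll_new}")
        delta = ll_new - ll
        p, ll = p_new, ll_new
        if delta < tol:
            converged = True
            break
    return HaplotypeFreqs(p_AB=float(p[0]), p_Ab=float(p[1]), p_aB=float(p[2]),
                          p_ab=float(p[3]), loglik=ll, loglik_null=ll_null,
                          n_iter=it, converged=converged)


def ld_from_freqs(p_AB: float, pA: float, pB: float) -> tuple[float, float, float]:
    """(D, |D'|, r^2) from a haplotype frequency and its marginals."""
    for p in (pA, pB):
        if not 0 < p < 1:
            raise UndefinedStatisticError("boundary marginal: LD undefined")
    D = p_AB - pA * pB
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, d_prime, r2


def ld_stats(h: HaplotypeFreqs, n: int) -> LDStats:
    """LD summaries of an EM fit; LOD compares the fit with independence."""
    D, d_prime, r2 = ld_from_freqs(h.p_AB, h.pA, h.pB)
    lod = max(0.0, (h.loglik - h.loglik_null) / math.log(10))
    return LDStats(D=D, D_prime=d_prime, r2=r2, lod=lod,
                   pA=h.pA, pB=h.pB, n=n)


def pairwise_ld_matrix(cohort: Cohort, panel: Optional[Sequence[SNPDef]] = None
                       ) -> dict[tuple[str, str], Optional[LDStats]]:
    """LD for every unordered marker pair; failed pairs map to None."""
    panel = list(cohort.panel if panel is None else panel)
    if len(panel) < 2:
        raise ValidationError("need at least two markers for pairwise LD")
    out: dict[tuple[str, str], Optional[LDStats]] = {}
    dosages = {s.rsid: cohort.minor_dosage(s.rsid).to_numpy() for s in panel}
    for s1, s2 in itertools.combinations(panel, 2):
        key = (s1.rsid, s2.rsid)
        try:
            h = em_haplotypes(dosages[s1.rsid], dosages[s2.rsid])
            mask = ~(np.isnan(dosages[s1.rsid]) | np.isnan(dosages[s2.rsid]))
            out[key] = ld_stats(h, int(mask.sum()))
        except UndefinedStatisticError as exc:
            log.info("LD undefined for %s-%s: %s", s1.rsid, s2.rsid, exc)
            out[key] = None
    return out


def compound_genotype_or(cohort: Cohort, predicate: Callable[[Cohort], pd.Series],
                         name: str = "compound genotype") -> AssociationResult:
    """Odds ratio of an arbitrary compound-genotype predicate vs case status.

    ``predicate`` maps the cohort to a boolean per-subject Series
    (e.g. -491 AA and -219 TT and E4 carrier).  Degenerate predicates
    (constant over subjects) raise.
    """
    mask = predicate(cohort).astype(bool)
    if mask.all() or (~mask).all():
        raise UndefinedStatisticError(f"{name}: predicate constant over cohort")
    table = predicate_table(cohort, mask, name=name)
    return odds_ratio_wald(table, marker=name, model="compound")


def risk_genotype_predicate(cohort: Cohort) -> pd.Series:
    """The -491 AA / -219 TT / E4-carrier compound genotype."""
    aa = cohort.genotype_strings("rs449647") == "A/A"
    tt = cohort.genotype_strings("rs405509") == "T/T"
    e4 = cohort.epsilon_carrier("E4")
    return (aa & tt & e4).fillna(False)
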