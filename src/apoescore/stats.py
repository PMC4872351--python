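"""Univariable association statistics for case-control marker data.

Implements the test battery used for per-marker screening: allele-,
genotype- and carrier-level contingency tables, Wald odds ratios with
Haldane-Anscombe correction, Yates-corrected chi-square, the
Freeman-Halton exact test for 2xC tables, exact and chi-square
Hardy-Weinberg tests, Bonferroni adjustment, and nonparametric
location/correlation tests (Mann-Whitney, Kruskal-Wallis, Spearman).

The exact tests (Hardy-Weinberg, Freeman-Halton) are computed by full
conditional enumeration: all outcomes compatible with the observed
margins are enumerated and the tail is the total probability of
outcomes no more probable than the observed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .genotypes import (
    GROUP_CASE,
    GROUP_CONTROL,
    Cohort,
    SNPDef,
    UndefinedStatisticError,
    ValidationError,
)

log = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


class DegenerateTableError(UndefinedStatisticError):
    """A contingency table has a zero margin or a constant classification."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts with row (group) and column (category) labels."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.rows), len(self.cols)):
            raise ValidationError("table shape does not match labels")
        if (counts < 0).any():
            raise ValidationError("negative cell count")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def require_positive_margins(self) -> None:
        if (self.counts.sum(axis=1) <= 0).any() or (self.counts.sum(axis=0) <= 0).any():
            raise DegenerateTableError(
                f"zero margin in table rows={self.rows} cols={self.cols}")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    effect: Optional[float] = None
    note: str = ""


@dataclass
class AssociationResult:
    marker_or_factor: str
    model: str
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_raw: float
    p_adjusted: Optional[float]
    test_used: str
    table: Optional[ContingencyTable] = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def allele_table(cohort: Cohort, snp: SNPDef) -> ContingencyTable:
    """2x2 minor/major allele counts by group (two alleles per subject)."""
    dosage = cohort.minor_dosage(snp.rsid)
    rows, counts = [], []
    for group in (GROUP_CASE, GROUP_CONTROL):
        d = dosage[cohort.group_mask(group)].dropna()
        minor = int(d.sum())
        total = 2 * len(d)
        rows.append(group)
        counts.append([minor, total - minor])
    snp_ = snp
    table = ContingencyTable(tuple(rows),
                             (snp_.minor_allele, snp_.major_allele),
                             np.array(counts))
    if (table.counts.sum(axis=0) <= 0).any():
        raise DegenerateTableError(f"{snp.rsid}: monomorphic in pooled data")
    table.require_positive_margins()
    return table


def genotype_table(cohort: Cohort, snp: SNPDef) -> ContingencyTable:
    """2x3 genotype counts (hom-major, het, hom-minor) by group."""
    dosage = cohort.minor_dosage(snp.rsid)
    counts = []
    for group in (GROUP_CASE, GROUP_CONTROL):
        d = dosage[cohort.group_mask(group)].dropna()
        counts.append([int((d == k).sum()) for k in (0, 1, 2)])
    return ContingencyTable((GROUP_CASE, GROUP_CONTROL),
                            snp.genotype_strings(), np.array(counts))


def carrier_table(cohort: Cohort, snp: SNPDef) -> ContingencyTable:
    """2x2 dominant-model table: >=1 minor allele vs none, by group."""
    dosage = cohort.minor_dosage(snp.rsid)
    counts = []
    for group in (GROUP_CASE, GROUP_CONTROL):
        d = dosage[cohort.group_mask(group)].dropna()
        carrier = int((d > 0).sum())
        counts.append([carrier, len(d) - carrier])
    return ContingencyTable((GROUP_CASE, GROUP_CONTROL),
                            ("carrier", "non-carrier"), np.array(counts))


def predicate_table(cohort: Cohort, mask: pd.Series, name: str = "predicate"
                    ) -> ContingencyTable:
    """2x2 table of an arbitrary boolean subject predicate vs group."""
    counts = []
    for group in (GROUP_CASE, GROUP_CONTROL):
        g = cohort.group_mask(group)
        counts.append([int((mask & g).sum()), int((~mask & g).sum())])
    return ContingencyTable((GROUP_CASE, GROUP_CONTROL),
                            (name, f"not {name}"), np.array(counts))


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

def odds_ratio_wald(table: ContingencyTable, alpha: float = 0.05,
                    marker: str = "", model: str = "allele") -> AssociationResult:
    """Cross-product odds ratio with a Wald log-scale confidence interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), which is flagged in the result notes.
    """
    c = np.asarray(table.counts, dtype=float)
    if c.shape != (2, 2):
        raise ValidationError("odds ratio requires a 2x2 table")
    notes = []
    if (c == 0).any():
        c = c + 0.5
        notes.append("haldane_anscombe")
        log.info("Haldane-Anscombe correction applied to %s (%s)", marker, model)
    a, b = c[0]
    d, e = c[1]
    or_ = (a * e) / (b * d)
    se = math.sqrt((1 / c).sum())
    z = sps.norm.ppf(1 - alpha / 2)
    lo, hi = or_ * math.exp(-z * se), or_ * math.exp(z * se)
    return AssociationResult(
        marker_or_factor=marker, model=model, odds_ratio=or_,
        ci_low=lo, ci_high=hi, p_raw=float("nan"), p_adjusted=None,
        test_used="wald", table=table, notes=notes)


def odds_ratio_from_freqs(p_case: float, p_control: float) -> float:
    """Odds ratio implied by two allele (or carrier) frequencies."""
    for p in (p_case, p_control):
        if not 0 < p < 1:
            raise ValidationError(f"frequency {p} not in (0, 1)")
    return (p_case / (1 - p_case)) / (p_control / (1 - p_control))


def carrier_freq_hwe(allele_freq: float) -> float:
    """Carrier (>=1 copy) frequency implied by Hardy-Weinberg proportions."""
    if not 0 <= allele_freq <= 1:
        raise ValidationError(f"allele frequency {allele_freq} outside [0, 1]")
    return 1.0 - (1.0 - allele_freq) ** 2


# ---------------------------------------------------------------------------
# chi-square / exact tests
# ---------------------------------------------------------------------------

def chi2_cc_test(table: ContingencyTable) -> TestResult:
    """Yates-corrected chi-square on a 2x2 table, two-sided, 1 df."""
    table.require_positive_margins()
    if table.counts.shape != (2, 2):
        raise ValidationError("continuity correction applies to 2x2 tables")
    stat, p, _, expected = sps.chi2_contingency(table.counts, correction=True)
    note = ""
    if (expected < 5).any():
        note = "expected cell < 5: prefer exact test"
        log.info("chi2_cc on %s/%s: %s", table.rows, table.cols, note)
    return TestResult(float(stat), float(p), "chi2 (Yates)", note=note)


def freeman_halton_test(table: ContingencyTable, budget: int = 500) -> TestResult:
    """Exact conditional test for a 2xC table (Freeman-Halton extension).

    The p value is the total conditional probability, given both
    margins, of all tables whose probability does not exceed the
    observed table's.  For a two-row table the conditional probability
    of first row (x_1..x_k) is prod_j C(col_j, x_j) / C(n, row_1).
    Complexity grows with the product of column margins; a ``budget``
    on the table total guards runaway inputs.
    """
    counts = np.asarray(table.counts).astype(int)
    if counts.shape[0] != 2:
        raise ValidationError("implemented for two-row tables")
    table.require_positive_margins()
    n = int(counts.sum())
    if n > budget:
        raise UndefinedStatisticError(
            f"table total {n} exceeds enumeration budget {budget}; "
            "use the chi-square approximation")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    k = len(col)
    log_norm = gammaln(n + 1) - gammaln(row[0] + 1) - gammaln(row[1] + 1)

    def first_row_logprob(x: np.ndarray) -> np.ndarray:
        return (gammaln(col + 1) - gammaln(x + 1)
                - gammaln(col - x + 1)).sum(axis=-1) - log_norm

    # enumerate first rows x with 0 <= x_j <= col_j and sum = row[0]
    grids = np.meshgrid(*[np.arange(c + 1) for c in col[:-1]], indexing="ij")
    x_last = row[0] - sum(grids)
    valid = (x_last >= 0) & (x_last <= col[-1])
    first_rows = np.stack([g[valid] for g in grids] + [x_last[valid]], axis=-1)
    logp = first_row_logprob(first_rows)
    logp_obs = float(first_row_logprob(counts[0][None, :])[0])
    p = float(np.exp(logp[logp <= logp_obs + 1e-9]).sum())
    return TestResult(float("nan"), min(p, 1.0),
                      f"Freeman-Halton exact (2x{k})")


def hwe_test(genotype_counts: Sequence[int], mode: str = "auto") -> TestResult:
    """Hardy-Weinberg test from (hom-major, het, hom-minor) counts.

    ``chi2``: 1-df goodness of fit against p^2 / 2pq / q^2 expectations.
    ``exact``: conditional enumeration over all heterozygote counts
    compatible with the observed allele totals; the p value sums the
    probabilities of counts no more probable than the observed one.
    ``auto`` picks exact when any chi-square expected cell is < 5.
    """
    n0, n1, n2 = (int(x) for x in genotype_counts)
    n = n0 + n1 + n2
    if n < 1:
        raise UndefinedStatisticError("empty genotype vector")
    n_minor = n1 + 2 * n2
    if n_minor == 0 or n_minor == 2 * n:
        return TestResult(float("nan"), float("nan"), "not applicable",
                          note="monomorphic marker")
    q = n_minor / (2 * n)
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    if mode == "auto":
        mode = "exact" if (expected < 5).any() else "chi2"
        log.debug("HWE mode auto -> %s (min expected %.2f)", mode, expected.min())
    if mode == "chi2":
        observed = np.array([n0, n1, n2], dtype=float)
        stat = float(((observed - expected) ** 2 / expected).sum())
        return TestResult(stat, float(sps.chi2.sf(stat, df=1)), "HWE chi2")
    if mode != "exact":
        raise ValidationError(f"unknown HWE mode {mode!r}")
    # conditional distribution of the het count given allele totals
    rare = min(n_minor, 2 * n - n_minor)
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (gammaln(n + 1)
            - gammaln((rare - hets) // 2 + 1)
            - gammaln(hets + 1)
            - gammaln(n - (rare + hets) // 2 + 1)
            + hets * math.log(2)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1][0]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return TestResult(float("nan"), min(p, 1.0), "HWE exact")


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """p_adj = min(1, m * p); m defaults to the number of tests supplied."""
    p_values = list(p_values)
    m = len(p_values) if m is None else m
    if m < len(p_values):
        raise ValidationError(f"family size {m} smaller than number of tests")
    return [min(1.0, m * p) for p in p_values]


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def mann_whitney(levels_a: Sequence[float], levels_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U; exact for small tie-free samples, else
    normal approximation with tie correction."""
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedStatisticError("empty group in Mann-Whitney test")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"Mann-Whitney U ({method})")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    if any(len(g) == 0 for g in groups):
        raise UndefinedStatisticError("empty group in Kruskal-Wallis test")
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), float(p), "Kruskal-Wallis")


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation on mid-ranks, p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float("nan"), float(p), "Spearman", effect=float(rho))


# ---------------------------------------------------------------------------
# per-marker association driver
# ---------------------------------------------------------------------------

def marker_association(cohort: Cohort, snp: SNPDef, model: str = "allele",
                       exact_budget: int = 500) -> AssociationResult:
    """Association of one marker with case status under a given model.

    ``allele``: 2x2 minor/major allele counts (the additive comparison);
    ``genotypic``: 2x3 genotype table, Freeman-Halton exact test;
    ``dominant``: 2x2 carrier table.  2x2 models report the odds ratio
    and use Yates chi-square unless an expected cell is < 5, in which
    case the exact test is used.
    """
    if model == "allele":
        table = allele_table(cohort, snp)
    elif model == "dominant":
        table = carrier_table(cohort, snp)
    elif model == "genotypic":
        table = genotype_table(cohort, snp)
    else:
        raise ValidationError(f"unknown model {model!r}")

    if model == "genotypic":
        nonzero = table.counts.sum(axis=0) > 0
        trimmed = ContingencyTable(table.rows,
                                   tuple(np.array(table.cols)[nonzero]),
                                   table.counts[:, nonzero])
        if trimmed.counts.shape[1] < 2:
            raise DegenerateTableError(f"{snp.rsid}: single genotype class")
        test = freeman_halton_test(trimmed, budget=max(exact_budget, int(trimmed.n)))
        return AssociationResult(snp.rsid, model, None, None, None,
                                 test.p_value, None, test.method, table)

    result = odds_ratio_wald(table, marker=snp.rsid, model=model)
    try:
        chi = chi2_cc_test(table)
        use_exact = bool(chi.note)
    except (DegenerateTableError, ValueError):
        chi = None
        use_exact = True
    if use_exact:
        test = freeman_halton_test(table, budget=max(exact_budget, int(table.n)))
        result.notes.append("exact test (small expected counts)")
    else:
        test = chi
    result.p_raw = test.p_value
    result.test_used = test.method
    return result


def adjust_family(results: Sequence[AssociationResult],
                  m: Optional[int] = None) -> None:
    """Attach Bonferroni-adjusted p values across a family of results."""
    adj = bonferroni([r.p_raw for r in results], m=m)
    for r, p in zip(results, adj):
        r.p_adjusted = p
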