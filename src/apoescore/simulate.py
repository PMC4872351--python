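"""Synthetic case-control cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes, so the whole pipeline can run with no external data:

* group-specific six-locus haplotype pools over the analysed markers
  (rs449647, rs769446, rs405509, rs440446, rs429358, rs7412) whose
  one-locus marginals equal the published group allele frequencies by
  construction, calibrated by iterative proportional fitting (IPF) to
  two pairwise |D'| targets (rs440446-rs429358 0.956, with the
  rs440446-C allele on the rs429358-T background, and
  rs440446-rs405509 0.925, with rs440446-C coupled to rs405509-G) and
  a structural zero on the rs429358-C/rs7412-T (E1) haplotype;
* eight rare promoter-region markers drawn independently with minor
  allele frequencies below the 5 % analysis threshold;
* serum ApoE concentration drawn conditionally on the epsilon genotype
  (means/SDs in mg/dl per genotype), truncated at zero by redraw;
* demographic covariates (sex, age, onset, education, residence) drawn
  from group-specific marginal distributions.

Subjects are two independent haplotype draws from their group's pool;
pairs forming an E2/E2 genotype are rejected and redrawn, since that
genotype is absent from the emulated study population.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotypes import (
    COVARIATE_COLUMNS,
    GROUP_CASE,
    GROUP_CONTROL,
    MAIN_SNPS,
    RARE_SNPS,
    Cohort,
    SNPDef,
    ValidationError,
)

log = logging.getLogger(__name__)

LOCI: list[SNPDef] = list(MAIN_SNPS)
LOCUS_INDEX = {s.rsid: i for i, s in enumerate(LOCI)}

#: published group minor-allele frequencies for the six analysed markers
GROUP_MAFS = {
    GROUP_CASE: {
        "rs449647": 0.150, "rs769446": 0.059, "rs405509": 0.398,
        "rs440446": 0.335, "rs429358": 0.289, "rs7412": 0.039,
    },
    GROUP_CONTROL: {
        "rs449647": 0.218, "rs769446": 0.068, "rs405509": 0.559,
        "rs440446": 0.386, "rs429358": 0.091, "rs7412": 0.064,
    },
}

#: signed D' targets: (rsid_a, rsid_b, signed D' for the minor/minor cell)
LD_TARGETS: list[tuple[str, str, float]] = [
    ("rs440446", "rs429358", -0.956),
    ("rs440446", "rs405509", +0.925),
]

#: minor-allele frequencies of the rare screened markers (below threshold)
RARE_MAFS = {
    "rs439382": 0.005, "rs1799981": 0.009, "rs1081103": 0.013,
    "rs72654465": 0.017, "rs1799982": 0.021, "rs72654466": 0.024,
    "rs72654467": 0.027, "rs9282609": 0.030,
}

#: serum ApoE mean/SD (mg/dl) per epsilon genotype
APOE_LEVEL_PARAMS = {
    "E4/E4": (3.72, 0.80),
    "E3/E4": (5.54, 1.20),
    "E3/E3": (6.38, 1.48),
    "E2/E3": (7.04, 1.36),
    "E2/E4": (7.23, 0.50),
}

RESIDENCE_LEVELS = ("large_city", "town", "rural")
EDUCATION_LEVELS = (1, 2, 3, 4)  # 1 primary ... 4 higher/university


@dataclass
class CovariateParams:
    """Group-specific marginal distributions of the demographic covariates."""

    female_prob: float
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    education_probs: tuple[float, ...]  # over EDUCATION_LEVELS (1..4)
    residence_probs: tuple[float, ...]  # over RESIDENCE_LEVELS
    onset_lag_mean: Optional[float] = None  # years before interview; cases only
    onset_lag_sd: Optional[float] = None
    onset_lag_range: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        for probs, what in ((self.education_probs, "education"),
                            (self.residence_probs, "residence")):
            if abs(sum(probs) - 1) > 1e-9:
                raise ValidationError(f"{what} probabilities must sum to 1")
        if not 0 <= self.female_prob <= 1:
            raise ValidationError("female_prob outside [0, 1]")
        if self.age_sd <= 0:
            raise ValidationError("age_sd must be positive")


@dataclass
class SimulationConfig:
    n_case: int
    n_control: int
    haplotype_pool_case: dict[str, float]
    haplotype_pool_control: dict[str, float]
    rare_mafs: dict[str, float]
    apoe_level_params: dict[str, tuple[float, float]]
    covariates: dict[str, CovariateParams]
    seed: Optional[int] = None
    forbid_e2e2: bool = True

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("need at least one subject per group")
        for name, pool in (("case", self.haplotype_pool_case),
                           ("control", self.haplotype_pool_control)):
            total = sum(pool.values())
            if abs(total - 1) > 1e-9:
                raise ValidationError(f"{name} pool frequencies sum to {total}")
            if any(f < 0 for f in pool.values()):
                raise ValidationError(f"{name} pool has a negative frequency")
            for hap in pool:
                if len(hap) != len(LOCI):
                    raise ValidationError(f"haplotype {hap!r} has wrong length")
        for gt, (mu, sd) in self.apoe_level_params.items():
            if sd <= 0:
                raise ValidationError(f"apoe_level sd for {gt} must be positive")

    def pool(self, group: str) -> dict[str, float]:
        return (self.haplotype_pool_case if group == GROUP_CASE
                else self.haplotype_pool_control)

    def pool_marginal(self, group: str, rsid: str) -> float:
        """Minor-allele frequency implied by the group's haplotype pool."""
        i = LOCUS_INDEX[rsid]
        minor = LOCI[i].minor_allele
        return sum(f for hap, f in self.pool(group).items() if hap[i] == minor)

    def expected_allele_freq(self, group: str, rsid: str) -> float:
        """Expected realized minor-allele frequency in simulated subjects.

        With ``forbid_e2e2`` the E2/E2 rejection step slightly reweights
        haplotypes: a haplotype h is sampled with probability
        proportional to f(h) * (1 - 1{h is E2} * f(E2)), normalized by
        (1 - f(E2)^2).  Without rejection this equals the pool marginal.
        """
        if not self.forbid_e2e2:
            return self.pool_marginal(group, rsid)
        pool = self.pool(group)
        i = LOCUS_INDEX[rsid]
        minor = LOCI[i].minor_allele
        f_e2 = sum(f for hap, f in pool.items() if _hap_epsilon(hap) == "E2")
        f_m = sum(f for hap, f in pool.items() if hap[i] == minor)
        f_m_e2 = sum(f for hap, f in pool.items()
                     if hap[i] == minor and _hap_epsilon(hap) == "E2")
        return (f_m - f_m_e2 * f_e2) / (1.0 - f_e2 ** 2)

    def to_yaml(self, path) -> None:
        payload = {
            "n_case": self.n_case, "n_control": self.n_control,
            "seed": self.seed, "forbid_e2e2": self.forbid_e2e2,
            "haplotype_pool_case": {k: float(v) for k, v
                                    in self.haplotype_pool_case.items()},
            "haplotype_pool_control": {k: float(v) for k, v
                                       in self.haplotype_pool_control.items()},
            "rare_mafs": {k: float(v) for k, v in self.rare_mafs.items()},
            "apoe_level_params": {k: [float(a), float(b)] for k, (a, b)
                                  in self.apoe_level_params.items()},
            "covariates": {g: vars(c).copy() for g, c in self.covariates.items()},
        }
        for c in payload["covariates"].values():
            for key in ("education_probs", "residence_probs", "age_range",
                        "onset_lag_range"):
                c[key] = list(c[key]) if c[key] is not None else None
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cov = {}
        for g, c in payload["covariates"].items():
            c = dict(c)
            for key in ("education_probs", "residence_probs", "age_range",
                        "onset_lag_range"):
                if c.get(key) is not None:
                    c[key] = tuple(c[key])
            cov[g] = CovariateParams(**c)
        return cls(
            n_case=payload["n_case"], n_control=payload["n_control"],
            haplotype_pool_case=payload["haplotype_pool_case"],
            haplotype_pool_control=payload["haplotype_pool_control"],
            rare_mafs=payload["rare_mafs"],
            apoe_level_params={k: (v[0], v[1]) for k, v
                               in payload["apoe_level_params"].items()},
            covariates=cov, seed=payload.get("seed"),
            forbid_e2e2=payload.get("forbid_e2e2", True),
        )


# ---------------------------------------------------------------------------
# pool calibration (iterative proportional fitting)
# ---------------------------------------------------------------------------

@dataclass
class PoolDiagnostics:
    """Residual discrepancies of a calibrated pool."""

    margin_error: float
    achieved_dprime: dict[tuple[str, str], float]
    target_dprime: dict[tuple[str, str], float]
    n_iter: int
    converged: bool

    @property
    def max_dprime_error(self) -> float:
        return max((abs(abs(self.target_dprime[k]) - self.achieved_dprime[k])
                    for k in self.target_dprime), default=0.0)


def _pair_target(qi: float, qj: float, signed_dprime: float) -> np.ndarray:
    """2x2 minor/minor joint table implied by marginals and a signed D'."""
    if not -1 <= signed_dprime <= 1:
        raise ValidationError(f"|D'| target {signed_dprime} outside [0, 1]")
    if signed_dprime >= 0:
        d_max = min(qi * (1 - qj), (1 - qi) * qj)
    else:
        d_max = min(qi * qj, (1 - qi) * (1 - qj))
    D = signed_dprime * d_max
    p11 = qi * qj + D
    table = np.array([[1 - qi - qj + p11, qj - p11],
                      [qi - p11, p11]])
    if (table < -1e-12).any():
        raise ValidationError("infeasible D' target for given marginals")
    return np.clip(table, 0.0, None)


def _pool_dprime(p: np.ndarray, i: int, j: int) -> float:
    axes = tuple(k for k in range(p.ndim) if k not in (i, j))
    m = p.sum(axis=axes)
    if i > j:
        m = m.T
    qi, qj = m[1].sum(), m[:, 1].sum()
    D = m[1, 1] - qi * qj
    if D > 0:
        d_max = min(qi * (1 - qj), (1 - qi) * qj)
    else:
        d_max = min(qi * qj, (1 - qi) * (1 - qj))
    return 0.0 if d_max == 0 else abs(D) / d_max


def calibrate_pool(
    target_mafs: dict[str, float],
    target_ld: Sequence[tuple[str, str, float]] = (),
    forbidden: Sequence[dict[str, str]] = ({"rs429358": "C", "rs7412": "T"},),
    loci: Sequence[SNPDef] = tuple(LOCI),
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> tuple[dict[str, float], PoolDiagnostics]:
    """Fit a haplotype frequency table to marginals and pairwise D' targets.

    Starts from the independence pool and applies IPF cycles over the
    one-locus margins and the target two-locus margins, with structural
    zeros on ``forbidden`` haplotype patterns (allele at rsid).  The
    one-locus marginals are matched exactly (up to ``tol``); the D'
    targets are matched as closely as the joint constraints allow, and
    the residual is returned rather than hidden.
    """
    loci = list(loci)
    index = {s.rsid: i for i, s in enumerate(loci)}
    L = len(loci)
    q = np.array([target_mafs[s.rsid] for s in loci])
    if ((q <= 0) | (q >= 1)).any():
        raise ValidationError("marginal frequencies must lie in (0, 1)")

    p = np.ones((2,) * L)
    for i in range(L):
        shape = [1] * L
        shape[i] = 2
        p = p * np.array([1 - q[i], q[i]]).reshape(shape)
    for pattern in forbidden:
        sel = [slice(None)] * L
        for rsid, allele in pattern.items():
            i = index[rsid]
            sel[i] = 1 if allele == loci[i].minor_allele else 0
        p[tuple(sel)] = 0.0
    p /= p.sum()

    pair_specs = []
    for rsid_a, rsid_b, dp in target_ld:
        i, j = index[rsid_a], index[rsid_b]
        target = _pair_target(q[i], q[j], dp)  # indexed [x_i][x_j]
        if i > j:
            i, j, target = j, i, target.T
        pair_specs.append((i, j, target))

    it = 0
    err = np.inf
    for it in range(1, max_iter + 1):
        for i in range(L):
            axes = tuple(k for k in range(L) if k != i)
            margin = p.sum(axis=axes)
            factor = np.divide([1 - q[i], q[i]], margin,
                               out=np.zeros(2), where=margin > 0)
            shape = [1] * L
            shape[i] = 2
            p = p * factor.reshape(shape)
        for i, j, target in pair_specs:  # i < j; target indexed [x_i][x_j]
            axes = tuple(k for k in range(L) if k not in (i, j))
            margin = p.sum(axis=axes)
            factor = np.divide(target, margin, out=np.zeros((2, 2)),
                               where=margin > 0)
            p = p * factor.reshape(tuple(2 if k in (i, j) else 1
                                         for k in range(L)))
        p /= p.sum()
        # margin deviation
        err = 0.0
        for i in range(L):
            axes = tuple(k for k in range(L) if k != i)
            err = max(err, abs(p.sum(axis=axes)[1] - q[i]))
        if err < tol and it > 1:
            break

    achieved = {}
    targets = {}
    for rsid_a, rsid_b, dp in target_ld:
        i, j = index[rsid_a], index[rsid_b]
        achieved[(rsid_a, rsid_b)] = _pool_dprime(p, i, j)
        targets[(rsid_a, rsid_b)] = dp
    diag = PoolDiagnostics(margin_error=float(err), achieved_dprime=achieved,
                           target_dprime=targets, n_iter=it,
                           converged=err < tol)
    if diag.max_dprime_error > 0.02:
        log.warning("calibrated pool misses a D' target by %.3f "
                    "(best-effort fit returned)", diag.max_dprime_error)

    pool: dict[str, float] = {}
    for idx in np.ndindex(*p.shape):
        f = float(p[idx])
        if f <= 0:
            continue
        hap = "".join(loci[k].minor_allele if idx[k] == 1
                      else loci[k].major_allele for k in range(L))
        pool[hap] = f
    total = sum(pool.values())
    pool = {h: f / total for h, f in pool.items()}
    return pool, diag


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

def default_config(n_case: int = 110, n_control: int = 110,
                   seed: Optional[int] = 0) -> SimulationConfig:
    """The shipped study conditions: published frequencies and covariates.

    The rs7412 calibration target is pre-compensated for the E2/E2
    rejection step (pool frequency t/(1-t) for a desired realized
    frequency t; rs7412-T marks exactly the E2 haplotype once E1 is
    excluded), so realized allele frequencies in simulated cohorts
    match the published group values in expectation at every locus.
    """
    pools = {}
    for group in (GROUP_CASE, GROUP_CONTROL):
        mafs = dict(GROUP_MAFS[group])
        t = mafs["rs7412"]
        mafs["rs7412"] = t / (1.0 - t)
        pools[group], diag = calibrate_pool(mafs, LD_TARGETS)
        log.debug("%s pool: %d haplotypes, margin err %.1e, D' residual %.4f",
                  group, len(pools[group]), diag.margin_error,
                  diag.max_dprime_error)
    covariates = {
        GROUP_CASE: CovariateParams(
            female_prob=51 / 110, age_mean=71.2, age_sd=9.0,
            age_range=(40.0, 100.0),
            education_probs=(22 / 110, 18 / 110, 45 / 110, 25 / 110),
            residence_probs=(0.25, 0.45, 0.30),
            onset_lag_mean=3.6, onset_lag_sd=1.9, onset_lag_range=(1.0, 10.0)),
        GROUP_CONTROL: CovariateParams(
            female_prob=85 / 110, age_mean=66.8, age_sd=7.5,
            age_range=(40.0, 100.0),
            education_probs=(2 / 110, 4 / 110, 40 / 110, 64 / 110),
            residence_probs=(0.55, 0.30, 0.15)),
    }
    return SimulationConfig(
        n_case=n_case, n_control=n_control,
        haplotype_pool_case=pools[GROUP_CASE],
        haplotype_pool_control=pools[GROUP_CONTROL],
        rare_mafs=dict(RARE_MAFS),
        apoe_level_params=dict(APOE_LEVEL_PARAMS),
        covariates=covariates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_EPS_CLASS = {("T", "C"): "E3", ("T", "T"): "E2", ("C", "C"): "E4"}


def _hap_epsilon(hap: str) -> str:
    i358, i7412 = LOCUS_INDEX["rs429358"], LOCUS_INDEX["rs7412"]
    key = (hap[i358], hap[i7412])
    try:
        return _EPS_CLASS[key]
    except KeyError:
        raise ValidationError(f"haplotype {hap!r} carries the unmodelled E1 "
                              "allele combination") from None


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _simulate_group(config: SimulationConfig, group: str, n: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    pool = config.pool(group)
    haps = sorted(pool)  # draw order independent of dict insertion order
    freqs = np.array([pool[h] for h in haps])
    freqs = freqs / freqs.sum()
    hap_eps = np.array([_hap_epsilon(h) for h in haps])
    hap_mat = np.array([list(h) for h in haps])  # (n_hap, L) of allele chars

    idx = rng.choice(len(haps), size=(n, 2), p=freqs)
    if config.forbid_e2e2:
        bad = (hap_eps[idx[:, 0]] == "E2") & (hap_eps[idx[:, 1]] == "E2")
        while bad.any():
            idx[bad] = rng.choice(len(haps), size=(int(bad.sum()), 2), p=freqs)
            bad = (hap_eps[idx[:, 0]] == "E2") & (hap_eps[idx[:, 1]] == "E2")

    a1 = hap_mat[idx[:, 0]]  # (n, L)
    a2 = hap_mat[idx[:, 1]]
    swap = a1 > a2
    lo = np.where(swap, a2, a1)
    hi = np.where(swap, a1, a2)
    genotype_cols = {}
    for k, snp in enumerate(LOCI):
        genotype_cols[snp.rsid] = np.char.add(np.char.add(lo[:, k], "/"), hi[:, k])

    for snp in RARE_SNPS:
        maf = config.rare_mafs[snp.rsid]
        dosage = rng.binomial(2, maf, n)
        strings = np.array(snp.genotype_strings())
        genotype_cols[snp.rsid] = strings[dosage]

    eps_pairs = np.sort(np.stack([hap_eps[idx[:, 0]], hap_eps[idx[:, 1]]],
                                 axis=1), axis=1)
    eps_gt = np.char.add(np.char.add(eps_pairs[:, 0], "/"), eps_pairs[:, 1])
    apoe = np.empty(n)
    for gt, (mu, sd) in config.apoe_level_params.items():
        mask = eps_gt == gt
        if mask.any():
            apoe[mask] = _truncated_normal(rng, mu, sd, 0.0, np.inf,
                                           int(mask.sum()))
    unknown = ~np.isin(eps_gt, list(config.apoe_level_params))
    if unknown.any():
        raise ValidationError(
            f"no serum parameters for epsilon genotype(s) "
            f"{sorted(set(eps_gt[unknown]))}")

    cov = config.covariates[group]
    sex = np.where(rng.random(n) < cov.female_prob, "F", "M")
    age = np.round(_truncated_normal(rng, cov.age_mean, cov.age_sd,
                                     *cov.age_range, n), 1)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=cov.education_probs)
    residence = rng.choice(RESIDENCE_LEVELS, size=n, p=cov.residence_probs)

    prefix = "AD" if group == GROUP_CASE else "CT"
    df = pd.DataFrame({
        "subject_id": [f"{prefix}{i + 1:05d}" for i in range(n)],
        "group": group,
        "sex": sex,
        "age": age,
        "education": education,
        "residence": residence,
        "apoe_level": np.round(apoe, 3),
    })
    if group == GROUP_CASE and cov.onset_lag_mean is not None:
        lag = _truncated_normal(rng, cov.onset_lag_mean, cov.onset_lag_sd,
                                *cov.onset_lag_range, n)
        df["age_at_onset"] = np.round(np.maximum(age - lag, 18.0), 1)
    else:
        df["age_at_onset"] = np.nan
    for rsid, colvals in genotype_cols.items():
        df[rsid] = colvals
    return df


def simulate_cohort(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> Cohort:
    """Draw a cohort from the configured pools; deterministic given seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = [
        _simulate_group(config, GROUP_CASE, config.n_case, rng),
        _simulate_group(config, GROUP_CONTROL, config.n_control, rng),
    ]
    data = pd.concat(frames, ignore_index=True)
    panel = MAIN_SNPS + [s for s in RARE_SNPS if s.rsid in config.rare_mafs]
    cols = [c for c in COVARIATE_COLUMNS if c in data.columns] \
        + [s.rsid for s in panel]
    return Cohort(data[cols], panel)
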