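"""The preventive score: an additive protective-genotype score.

Each subject receives integer relative scores for protective promoter
genotypes — one point per heterozygous, two per homozygous protective
genotype at -491A/T (rs449647, protective allele T) and -219T/G
(rs405509, protective allele G) — and the preventive score is their
sum (0 to 4 with the default table).  With the default table the score
equals the protective-allele dosage, so the group mean score is twice
the sum of the two protective-allele frequencies; this identity is the
basis of several consistency checks.

Scores are compared between cases and controls (Mann-Whitney) and
correlated (Spearman) with epsilon-allele carriership and serum ApoE.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import (
    GROUP_CASE,
    GROUP_CONTROL,
    Cohort,
    SubjectRecord,
    UndefinedStatisticError,
    normalize_genotype_string,
)
from . import stats

log = logging.getLogger(__name__)


def _norm_gt(genotype: str) -> str:
    g = normalize_genotype_string(genotype)
    if g is None:
        raise ValueError(f"bad genotype key {genotype!r}")
    return g


@dataclass(frozen=True)
class ScoreTable:
    """Map (rsid, unordered genotype) -> nonnegative integer relative score."""

    entries: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        norm = {}
        for (rsid, gt), s in self.entries.items():
            if s < 0:
                raise ValueError(f"negative score for {rsid} {gt}")
            norm[(rsid, _norm_gt(gt))] = int(s)
        object.__setattr__(self, "entries", norm)

    @property
    def rsids(self) -> list[str]:
        return sorted({rsid for rsid, _ in self.entries})

    def lookup(self, rsid: str, genotype: Optional[str]) -> Optional[int]:
        """Score contribution of one genotype; None when the call is missing."""
        g = normalize_genotype_string(genotype)
        if g is None:
            return None
        return self.entries.get((rsid, g), 0)


#: the shipped scoring: protective promoter genotypes at -491 and -219
DEFAULT_SCORE_TABLE = ScoreTable({
    ("rs449647", "A/T"): 1,
    ("rs449647", "T/T"): 2,
    ("rs405509", "T/G"): 1,
    ("rs405509", "G/G"): 2,
})


@dataclass
class ScoreResult:
    subject_id: str
    score: Optional[int]
    components: dict[str, Optional[int]] = field(default_factory=dict)


def preventive_score(subject: SubjectRecord,
                     table: ScoreTable = DEFAULT_SCORE_TABLE) -> ScoreResult:
    """Score one subject; any missing scored genotype voids the score."""
    components = {}
    for rsid in table.rsids:
        call = subject.genotypes.get(rsid)
        components[rsid] = table.lookup(rsid, None if call is None else str(call))
    if any(c is None for c in components.values()):
        log.info("subject %s: missing scored genotype, excluded from score "
                 "analyses", subject.subject_id)
        return ScoreResult(subject.subject_id, None, components)
    return ScoreResult(subject.subject_id, sum(components.values()), components)


def score_cohort(cohort: Cohort, table: ScoreTable = DEFAULT_SCORE_TABLE
                 ) -> pd.DataFrame:
    """Per-subject scores: columns subject_id, group, per-marker parts, score.

    Subjects with a missing scored genotype get NaN and are excluded
    from downstream score analyses.
    """
    out = cohort.data[["subject_id", "group"]].copy()
    total = np.zeros(len(out))
    for rsid in table.rsids:
        part = cohort.genotype_strings(rsid).map(
            lambda g: table.lookup(rsid, g), na_action=None)
        part = pd.to_numeric(part, errors="coerce")
        out[f"score_{rsid}"] = part
        total = total + part.to_numpy(dtype=float)
    out["score"] = total
    return out


@dataclass
class ScoreGroupSummary:
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    distribution: pd.DataFrame  # counts per score value per group
    test: stats.TestResult
    n_scored: dict[str, int]


def score_group_comparison(cohort: Cohort,
                           table: ScoreTable = DEFAULT_SCORE_TABLE
                           ) -> ScoreGroupSummary:
    """Group means and a two-sided Mann-Whitney comparison of the score."""
    scores = score_cohort(cohort, table)
    by = {}
    for group in (GROUP_CASE, GROUP_CONTROL):
        s = scores.loc[scores["group"] == group, "score"].dropna()
        if len(s) == 0:
            raise UndefinedStatisticError(f"no scored subjects in group {group}")
        by[group] = s
    if scores["score"].dropna().nunique() <= 1:
        test = stats.TestResult(float("nan"), 1.0, "Mann-Whitney U",
                                note="constant score: comparison degenerate")
    else:
        test = stats.mann_whitney(by[GROUP_CASE], by[GROUP_CONTROL])
    dist = (scores.dropna(subset=["score"])
            .groupby(["group", "score"]).size().unstack(fill_value=0))
    return ScoreGroupSummary(
        mean_case=float(by[GROUP_CASE].mean()),
        mean_control=float(by[GROUP_CONTROL].mean()),
        sd_case=float(by[GROUP_CASE].std()),
        sd_control=float(by[GROUP_CONTROL].std()),
        distribution=dist,
        test=test,
        n_scored={g: int(len(s)) for g, s in by.items()},
    )


def score_correlations(cohort: Cohort, table: ScoreTable = DEFAULT_SCORE_TABLE
                       ) -> dict[str, stats.TestResult]:
    """Spearman correlations of the score with E2/E4 carriership and serum ApoE."""
    scores = score_cohort(cohort, table)["score"]
    has_eps = {"rs429358", "rs7412"} <= set(cohort.data.columns)
    correlates = {
        "E2_carrier": cohort.epsilon_carrier("E2").astype(float) if has_eps
        else None,
        "E4_carrier": cohort.epsilon_carrier("E4").astype(float) if has_eps
        else None,
        "apoe_level": cohort.data.get("apoe_level"),
    }
    out: dict[str, stats.TestResult] = {}
    for name, values in correlates.items():
        if values is None:
            out[name] = stats.TestResult(float("nan"), float("nan"),
                                         "Spearman", note="correlate absent")
            continue
        mask = scores.notna() & pd.Series(values).notna()
        try:
            out[name] = stats.spearman(scores[mask], pd.Series(values)[mask])
        except UndefinedStatisticError as exc:
            out[name] = stats.TestResult(float("nan"), float("nan"),
                                         "Spearman", note=str(exc))
            log.info("score correlation with %s undefined: %s", name, exc)
    return out


def max_score(table: ScoreTable = DEFAULT_SCORE_TABLE) -> int:
    """Maximum attainable score, by enumeration over genotype combinations."""
    per_marker: dict[str, list[int]] = {}
    for (rsid, _), s in table.entries.items():
        per_marker.setdefault(rsid, [0]).append(s)
    best = 0
    for combo in itertools.product(*per_marker.values()) if per_marker else [()]:
        best = max(best, sum(combo))
    return best
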