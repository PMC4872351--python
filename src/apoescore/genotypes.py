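"""Core data model for APOE case-control genotype analysis.

The unit of analysis is a biallelic SNP in or near the *APOE* gene:
three promoter variants (-491A/T rs449647, -427T/C rs769446, -219T/G
rs405509), one intron-1 variant (+113G/C rs440446) and the two exon-4
coding variants rs429358 and rs7412 whose haplotypes define the classic
epsilon isoforms (E2 = rs429358-T/rs7412-T, E3 = T/C, E4 = C/C).

This module holds the marker and subject containers, epsilon genotype
calling from the two coding SNPs, per-marker allele-frequency summaries
and the minor-allele-frequency (MAF) exclusion filter.  The "minor"
allele of a marker is fixed once per panel (by convention from the
pooled cohort) and never re-assigned per group, so a group-specific
frequency above 50 % is legal and preserved.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: tokens interpreted as a missing genotype in text inputs
MISSING_TOKENS = {"", ".", "NA", "N/A", "NAN", "./.", "././."}

#: fixed covariate columns of the cohort table, in canonical order
COVARIATE_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age",
    "age_at_onset",
    "education",
    "residence",
    "apoe_level",
]

GROUP_CASE = "case"
GROUP_CONTROL = "control"


class CohortFormatError(ValueError):
    """A cohort file violates the expected layout (missing columns etc.)."""


class ValidationError(ValueError):
    """Input data violate a structural invariant (duplicate ids, bad GT...)."""


class UndefinedStatisticError(ValueError):
    """A summary or test is undefined for the given data (e.g. all missing)."""


@dataclass(frozen=True)
class SNPDef:
    """A biallelic marker: identity, allele pair and its fixed minor allele."""

    rsid: str
    label: str
    ref_allele: str
    alt_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.rsid}: ref and alt allele identical")
        if self.minor_allele not in (self.ref_allele, self.alt_allele):
            raise ValidationError(
                f"{self.rsid}: minor allele {self.minor_allele!r} is neither "
                f"{self.ref_allele!r} nor {self.alt_allele!r}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    @property
    def major_allele(self) -> str:
        return self.alt_allele if self.minor_allele == self.ref_allele else self.ref_allele

    def genotype_strings(self) -> tuple[str, str, str]:
        """(hom-major, het, hom-minor) normalized genotype strings."""
        a, b = self.major_allele, self.minor_allele
        return (
            normalize_genotype_string(f"{a}/{a}"),
            normalize_genotype_string(f"{a}/{b}"),
            normalize_genotype_string(f"{b}/{b}"),
        )


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid call; ``allele1``/``allele2`` are None when missing."""

    allele1: Optional[str] = None
    allele2: Optional[str] = None

    @property
    def missing(self) -> bool:
        return self.allele1 is None or self.allele2 is None

    @classmethod
    def from_string(cls, text: object) -> "GenotypeCall":
        if text is None or (isinstance(text, float) and np.isnan(text)):
            return cls()
        s = str(text).strip().upper()
        if s in MISSING_TOKENS:
            return cls()
        parts = s.split("/") if "/" in s else list(s)
        if len(parts) != 2 or not all(p.isalpha() and len(p) == 1 for p in parts):
            raise ValidationError(f"unparseable genotype {text!r}")
        a, b = sorted(parts)
        return cls(a, b)

    def count(self, allele: str) -> int:
        if self.missing:
            raise UndefinedStatisticError("allele count of a missing call")
        return int(self.allele1 == allele) + int(self.allele2 == allele)

    def __str__(self) -> str:
        if self.missing:
            return "NA"
        return f"{self.allele1}/{self.allele2}"


def normalize_genotype_string(text: object) -> Optional[str]:
    """Canonical 'X/Y' form (alleles sorted) or None if missing/unparseable."""
    try:
        call = GenotypeCall.from_string(text)
    except ValidationError:
        return None
    return None if call.missing else str(call)


EPSILON_ALLELES = ("E2", "E3", "E4")


@dataclass(frozen=True)
class EpsilonGenotype:
    """Unordered pair of epsilon alleles with a phase-ambiguity flag."""

    allele_a: str
    allele_b: str
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.allele_a not in EPSILON_ALLELES or self.allele_b not in EPSILON_ALLELES:
            raise ValidationError(f"epsilon alleles must be E2/E3/E4, got "
                                  f"{self.allele_a}/{self.allele_b}")
        a, b = sorted((self.allele_a, self.allele_b))
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    def carries(self, allele: str) -> bool:
        return allele in (self.allele_a, self.allele_b)

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"


def derive_epsilon(g358: GenotypeCall, g7412: GenotypeCall) -> Optional[EpsilonGenotype]:
    """Call the epsilon genotype from the rs429358 and rs7412 diploid calls.

    The mapping follows the haplotype definitions E2 = (rs429358 T,
    rs7412 T), E3 = (T, C), E4 = (C, C).  The rs429358-C/rs7412-T
    haplotype (the rare E1 variant) is not modelled; genotype
    combinations that force it raise :class:`ValidationError`.

    The double heterozygote (C/T at both sites) is phase-ambiguous
    between E2/E4 and E1/E3; it is called E2/E4 with
    ``ambiguous=True``, the standard clinical convention given that E1
    is essentially absent from European populations.

    Returns None when either call is missing.
    """
    if g358.missing or g7412.missing:
        return None
    for call, snp_alleles, rsid in ((g358, {"T", "C"}, "rs429358"),
                                    (g7412, {"C", "T"}, "rs7412")):
        if not {call.allele1, call.allele2} <= snp_alleles:
            raise ValidationError(f"{rsid}: unexpected alleles in {call}")
    n_c358 = g358.count("C")
    n_t7412 = g7412.count("T")
    table = {
        (0, 0): ("E3", "E3", False),
        (0, 1): ("E2", "E3", False),
        (0, 2): ("E2", "E2", False),
        (1, 0): ("E3", "E4", False),
        (1, 1): ("E2", "E4", True),
        (2, 0): ("E4", "E4", False),
    }
    try:
        a, b, amb = table[(n_c358, n_t7412)]
    except KeyError:
        raise ValidationError(
            f"rs429358 {g358} with rs7412 {g7412} requires the unmodelled E1 "
            "(rs429358-C/rs7412-T) haplotype"
        ) from None
    return EpsilonGenotype(a, b, ambiguous=amb)


@dataclass(frozen=True)
class SubjectRecord:
    """One participant; a convenience view over a cohort row."""

    subject_id: str
    group: str
    sex: Optional[str]
    age: Optional[float]
    age_at_onset: Optional[float]
    education: Optional[int]
    residence: Optional[str]
    apoe_level: Optional[float]
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CASE, GROUP_CONTROL):
            raise ValidationError(f"{self.subject_id}: bad group {self.group!r}")
        if self.group == GROUP_CONTROL and self.age_at_onset is not None:
            raise ValidationError(f"{self.subject_id}: age_at_onset on a control")
        if self.apoe_level is not None and self.apoe_level < 0:
            raise ValidationError(f"{self.subject_id}: negative apoe_level")


@dataclass
class Cohort:
    """A genotyped case-control study: one DataFrame row per subject.

    ``data`` carries the covariate columns (:data:`COVARIATE_COLUMNS`)
    plus one string column per marker holding canonical 'X/Y' calls
    (NaN = missing); ``panel`` fixes marker identity and minor alleles.
    """

    data: pd.DataFrame
    panel: list[SNPDef]

    def __post_init__(self) -> None:
        for col in ("subject_id", "group"):
            if col not in self.data.columns:
                raise CohortFormatError(f"cohort table lacks mandatory column {col!r}")
        if self.data["subject_id"].duplicated().any():
            dups = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise ValidationError(f"duplicate subject ids: {sorted(set(dups))}")
        bad = set(self.data["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        missing = [s.rsid for s in self.panel if s.rsid not in self.data.columns]
        if missing:
            raise CohortFormatError(f"panel markers absent from table: {missing}")
        self._by_rsid = {s.rsid: s for s in self.panel}
        if len(self._by_rsid) != len(self.panel):
            raise ValidationError("duplicate rsids in panel")

    # -- accessors ---------------------------------------------------------
    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.panel]

    def snp(self, rsid: str) -> SNPDef:
        return self._by_rsid[rsid]

    @property
    def n_case(self) -> int:
        return int((self.data["group"] == GROUP_CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.data["group"] == GROUP_CONTROL).sum())

    def group_mask(self, group: str) -> pd.Series:
        return self.data["group"] == group

    def genotype_strings(self, rsid: str) -> pd.Series:
        return self.data[rsid]

    def minor_dosage(self, rsid: str) -> pd.Series:
        """Per-subject count of the marker's minor allele (NaN when missing)."""
        snp = self.snp(rsid)
        return self.data[rsid].str.count(snp.minor_allele).astype(float)

    def epsilon_genotypes(self) -> pd.Series:
        """Epsilon genotype per subject (None where either coding SNP missing)."""
        g358 = self.data["rs429358"]
        g7412 = self.data["rs7412"]
        cache: dict[tuple, Optional[EpsilonGenotype]] = {}
        out = []
        for a, b in zip(g358, g7412):
            key = (a, b)
            if key not in cache:
                cache[key] = derive_epsilon(GenotypeCall.from_string(a),
                                            GenotypeCall.from_string(b))
            out.append(cache[key])
        return pd.Series(out, index=self.data.index, name="epsilon")

    def epsilon_carrier(self, allele: str) -> pd.Series:
        """Boolean carrier indicator for an epsilon allele (NaN-free; missing→False)."""
        eps = self.epsilon_genotypes()
        return eps.map(lambda e: e is not None and e.carries(allele)).astype(bool)

    def subject_records(self) -> list[SubjectRecord]:
        records = []
        for _, row in self.data.iterrows():
            def opt(v):
                return None if pd.isna(v) else v
            records.append(SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                sex=opt(row.get("sex")),
                age=opt(row.get("age")),
                age_at_onset=opt(row.get("age_at_onset")),
                education=None if pd.isna(row.get("education")) else int(row["education"]),
                residence=opt(row.get("residence")),
                apoe_level=opt(row.get("apoe_level")),
                genotypes={r: GenotypeCall.from_string(row[r]) for r in self.rsids},
            ))
        return records

    def subset(self, mask: pd.Series) -> "Cohort":
        return Cohort(self.data.loc[mask].reset_index(drop=True), list(self.panel))


@dataclass(frozen=True)
class SNPSummary:
    """Per-marker allele/genotype summary; MAFs are for the fixed minor allele."""

    snp: SNPDef
    maf_case: float
    maf_control: float
    maf_pooled: float
    genotype_counts: dict[str, tuple[int, int, int]]  # group -> (hom-maj, het, hom-min)
    call_rate: float


def _allele_counts(dosage: pd.Series) -> tuple[int, int]:
    """(minor allele count, total non-missing alleles)."""
    d = dosage.dropna()
    return int(d.sum()), 2 * len(d)


def summarize_snp(cohort: Cohort, snp: SNPDef) -> SNPSummary:
    """Allele counting over non-missing calls, per group and pooled."""
    dosage = cohort.minor_dosage(snp.rsid)
    counts = {}
    mafs = {}
    for group in (GROUP_CASE, GROUP_CONTROL):
        d = dosage[cohort.group_mask(group)]
        minor, total = _allele_counts(d)
        if total == 0:
            raise UndefinedStatisticError(
                f"{snp.rsid}: no non-missing calls in group {group!r}")
        mafs[group] = minor / total
        dd = d.dropna()
        counts[group] = (int((dd == 0).sum()), int((dd == 1).sum()), int((dd == 2).sum()))
    minor_all, total_all = _allele_counts(dosage)
    return SNPSummary(
        snp=snp,
        maf_case=mafs[GROUP_CASE],
        maf_control=mafs[GROUP_CONTROL],
        maf_pooled=minor_all / total_all,
        genotype_counts=counts,
        call_rate=dosage.notna().mean(),
    )


def summarize_panel(cohort: Cohort) -> list[SNPSummary]:
    return [summarize_snp(cohort, snp) for snp in cohort.panel]


def filter_by_maf(
    summaries: Iterable[SNPSummary], threshold: float = 0.05
) -> tuple[list[SNPSummary], list[SNPSummary]]:
    """Split summaries into (retained, excluded) by pooled MAF >= threshold.

    The pooled (both groups combined) frequency is the filter statistic:
    a marker rare in one group but common pooled stays in, which is the
    only reading consistent with keeping a marker whose case MAF is
    below the cut while its pooled MAF is not.
    """
    if not 0 < threshold <= 0.5:
        raise ValidationError(f"MAF threshold must be in (0, 0.5], got {threshold}")
    retained, excluded = [], []
    for s in summaries:
        if s.maf_pooled >= threshold:
            retained.append(s)
            log.debug("MAF filter: retained %s (pooled %.4f >= %.3f)",
                      s.snp.rsid, s.maf_pooled, threshold)
        else:
            excluded.append(s)
            log.info("MAF filter: excluded %s (pooled %.4f < %.3f)",
                     s.snp.rsid, s.maf_pooled, threshold)
    return retained, excluded


def infer_snpdef(rsid: str, genotypes: pd.Series) -> SNPDef:
    """Build a SNPDef from observed calls, minor allele from pooled counts.

    Ties are broken toward the alphabetically later allele; monomorphic
    columns get a placeholder alternate allele 'N'.
    """
    counts: dict[str, int] = {}
    for cell in genotypes.dropna():
        call = GenotypeCall.from_string(cell)
        if call.missing:
            continue
        for a in (call.allele1, call.allele2):
            counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts)
    if len(alleles) > 2:
        raise ValidationError(f"{rsid}: more than two alleles observed: {alleles}")
    if len(alleles) == 0:
        raise UndefinedStatisticError(f"{rsid}: no callable genotypes")
    if len(alleles) == 1:
        alleles.append("N")
        counts["N"] = 0
    ref, alt = alleles
    minor = alt if counts[alt] <= counts[ref] else ref
    return SNPDef(rsid=rsid, label=rsid, ref_allele=ref, alt_allele=alt,
                  minor_allele=minor)


# ---------------------------------------------------------------------------
# The default marker panel.
#
# Six analysed markers: three promoter SNPs, one intron-1 SNP, and the two
# exon-4 SNPs coding the epsilon isoforms.  Eight further promoter-region
# variants from the screened set are carried as rare markers (their minor
# alleles fall below the 5 % analysis threshold).
# ---------------------------------------------------------------------------

MAIN_SNPS: list[SNPDef] = [
    SNPDef("rs449647", "-491A/T", "A", "T", "T"),
    SNPDef("rs769446", "-427T/C", "T", "C", "C"),
    SNPDef("rs405509", "-219T/G", "T", "G", "G"),
    SNPDef("rs440446", "+113G/C", "G", "C", "C"),
    SNPDef("rs429358", "exon4 T/C", "T", "C", "C"),
    SNPDef("rs7412", "exon4 C/T", "C", "T", "T"),
]

RARE_SNPS: list[SNPDef] = [
    SNPDef("rs439382", "promoter region", "C", "T", "T"),
    SNPDef("rs1799981", "promoter region", "A", "G", "G"),
    SNPDef("rs1081103", "promoter region", "T", "C", "C"),
    SNPDef("rs72654465", "promoter region", "G", "A", "A"),
    SNPDef("rs1799982", "promoter region", "C", "G", "G"),
    SNPDef("rs72654466", "promoter region", "A", "C", "C"),
    SNPDef("rs72654467", "promoter region", "G", "T", "T"),
    SNPDef("rs9282609", "promoter region", "T", "A", "A"),
]

DEFAULT_PANEL: list[SNPDef] = MAIN_SNPS + RARE_SNPS
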