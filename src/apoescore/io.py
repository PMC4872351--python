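"""Reading and writing cohort tables.

The native interchange format is a plain TSV with the covariate columns
(subject_id, group, sex, age, age_at_onset, education, residence,
apoe_level) followed by one column per marker holding unordered 'X/Y'
genotype strings; 'NA', '.' and the empty string mean missing.  Lines
starting with '#' are comments (used for provenance blocks).  Genotypes
can alternatively be pulled from a VCF (GT field, markers matched by ID).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    COVARIATE_COLUMNS,
    DEFAULT_PANEL,
    Cohort,
    CohortFormatError,
    GenotypeCall,
    SNPDef,
    ValidationError,
    infer_snpdef,
    normalize_genotype_string,
)

log = logging.getLogger(__name__)

_DEFAULT_BY_RSID = {s.rsid: s for s in DEFAULT_PANEL}

_FLOAT_FORMATS = {"age": "%.1f", "age_at_onset": "%.1f", "apoe_level": "%.3f"}


def read_cohort_tsv(path, panel: Optional[Sequence[SNPDef]] = None) -> Cohort:
    """Load a cohort TSV.

    Unparseable genotype cells become missing calls (logged).  When
    ``panel`` is not given, marker definitions for known rsIDs come
    from the default panel; otherwise the minor allele is inferred
    from pooled allele counts at load time and kept fixed thereafter.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing mandatory column {col!r}")
    if df["subject_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate subject_id values")

    marker_cols = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    for col in marker_cols:
        normalized = []
        for cell in df[col]:
            norm = normalize_genotype_string(cell)
            if norm is None and not (pd.isna(cell) or str(cell).strip().upper()
                                     in ("", ".", "NA", "N/A", "NAN")):
                log.warning("%s: unparseable genotype %r at %s set to missing",
                            path, cell, col)
            normalized.append(norm if norm is not None else np.nan)
        df[col] = normalized

    for col in ("age", "age_at_onset", "apoe_level"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "education" in df.columns:
        df["education"] = pd.to_numeric(df["education"], errors="coerce").astype("Int64")

    if panel is None:
        panel = []
        for rsid in marker_cols:
            if rsid in _DEFAULT_BY_RSID:
                panel.append(_DEFAULT_BY_RSID[rsid])
            else:
                snp = infer_snpdef(rsid, df[rsid])
                log.info("%s: inferred marker %s (minor allele %s from pooled counts)",
                         path, rsid, snp.minor_allele)
                panel.append(snp)
    else:
        panel = list(panel)
    return Cohort(df, panel)


def write_cohort_tsv(cohort: Cohort, path, header_comments: Sequence[str] = ()) -> None:
    """Write a cohort TSV; inverse of :func:`read_cohort_tsv` on valid cohorts."""
    cols = [c for c in COVARIATE_COLUMNS if c in cohort.data.columns] + cohort.rsids
    df = cohort.data[cols].copy()
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for _, row in df.iterrows():
            cells = []
            for col in cols:
                v = row[col]
                if pd.isna(v):
                    cells.append("NA")
                elif col in _FLOAT_FORMATS:
                    cells.append(_FLOAT_FORMATS[col] % float(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_genotypes_vcf(path, panel: Sequence[SNPDef]) -> dict[str, dict[str, GenotypeCall]]:
    """Extract unordered diploid calls for ``panel`` markers from a VCF.

    Markers are matched by ID; panel markers absent from the VCF are
    reported as fully missing (with a warning).  Non-diploid GT fields
    raise :class:`ValidationError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, dict[str, GenotypeCall]] = {s: {} for s in samples}
    wanted = {s.rsid: s for s in panel}
    seen: set[str] = set()
    for variant in vcf:
        rsid = variant.ID
        if rsid not in wanted:
            continue
        seen.add(rsid)
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(samples, variant.genotypes):
            # cyvcf2 genotype rows are [allele_idx..., phased_flag]
            idx = list(gt[:-1])
            if len(idx) != 2:
                raise ValidationError(
                    f"{path}: non-diploid GT for {sample} at {rsid}: {idx}")
            if any(i < 0 for i in idx):
                calls[sample][rsid] = GenotypeCall()
            else:
                a, b = sorted(alleles[i] for i in idx)
                calls[sample][rsid] = GenotypeCall(a, b)
    for rsid in wanted:
        if rsid not in seen:
            log.warning("%s: marker %s absent from VCF; calls set to missing",
                        path, rsid)
            for sample in samples:
                calls[sample][rsid] = GenotypeCall()
    return calls
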