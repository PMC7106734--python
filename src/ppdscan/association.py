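"""Allelic case-control association, derived allele frequencies and
genotype-phenotype segregation concordance.

The allelic test is the Pearson chi-square (1 df, no continuity correction)
on the 2x2 table of allele counts — the "basic allelic test" of standard GWAS
toolkits. Missing genotypes are dropped per site, so the effective allele
total varies across sites. No multiple-testing correction is applied.

The derived allele is resolved by a policy: ``reference`` (default; the
reference allele is taken as ancestral, so derived = alternate) or ``AA``
(an ancestral-allele INFO annotation carried on the record).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import GenotypeMatrix, Pedigree, VariantRecord

__all__ = [
    "AllelicTable",
    "AssocResult",
    "DafResult",
    "ConcordanceResult",
    "allelic_chisq",
    "association_scan",
    "daf",
    "daf_scan",
    "concordance",
    "concordance_scan",
]


@dataclass(frozen=True)
class AllelicTable:
    """2x2 allele-count table from non-missing genotypes."""

    case_ref: int
    case_alt: int
    control_ref: int
    control_alt: int

    @property
    def total(self) -> int:
        return self.case_ref + self.case_alt + self.control_ref + self.control_alt

    def chisq(self) -> float:
        """Pearson chi-square, closed form n(ad-bc)^2 / (row x column products).

        0 for degenerate (monomorphic or empty-margin) tables.
        """
        a, b = self.case_ref, self.case_alt
        c, d = self.control_ref, self.control_alt
        n = self.total
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            return 0.0
        return n * (a * d - b * c) ** 2 / denom


@dataclass(frozen=True)
class AssocResult:
    chrom: str
    pos: int
    table: AllelicTable
    chisq: float
    p: float
    df: int = 1
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DafResult:
    chrom: str
    pos: int
    daf_overall: float
    daf_case: float
    daf_control: float
    derived_allele: str
    policy: str


@dataclass(frozen=True)
class ConcordanceResult:
    chrom: str
    pos: int
    model: str
    concordant: bool
    violation: str = ""


def _group_allele_counts(
    alleles: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(ref_count, alt_count) per site over one group; missing dropped per
    individual (an individual with any missing allele contributes nothing)."""
    g = alleles[:, idx, :]
    ok = (g >= 0).all(axis=2)
    alt = np.where(ok[:, :, None], g == 1, False).sum(axis=(1, 2))
    ref = np.where(ok[:, :, None], g == 0, False).sum(axis=(1, 2))
    return ref.astype(np.int64), alt.astype(np.int64)


def allelic_chisq(
    record: VariantRecord,
    genotypes: GenotypeMatrix,
    groups: Pedigree,
    site_index: int = 0,
) -> AssocResult:
    """Basic allelic chi-square (1 df) at one site.

    Monomorphic pooled tables give chisq = 0 / p = 1 with a ``monomorphic``
    flag; a ``sparse_table`` flag is attached when any expected cell count
    is below 5 (asymptotic p-values are then unreliable, but no minimum-count
    gate is applied).
    """
    case_idx = genotypes.sample_index(groups.cases)
    ctrl_idx = genotypes.sample_index(groups.controls)
    from .fst import _project_biallelic

    proj = _project_biallelic(genotypes.alleles[site_index : site_index + 1])
    cr, ca = _group_allele_counts(proj, case_idx)
    ur, ua = _group_allele_counts(proj, ctrl_idx)
    table = AllelicTable(int(cr[0]), int(ca[0]), int(ur[0]), int(ua[0]))
    flags: set[str] = set()
    if table.case_alt + table.control_alt == 0 or table.case_ref + table.control_ref == 0:
        flags.add("monomorphic")
        return AssocResult(record.chrom, record.pos, table, 0.0, 1.0, flags=frozenset(flags))
    n = table.total
    row1 = table.case_ref + table.case_alt
    row2 = table.control_ref + table.control_alt
    col1 = table.case_ref + table.control_ref
    col2 = table.case_alt + table.control_alt
    if n > 0 and min(row1 * col1, row1 * col2, row2 * col1, row2 * col2) / n < 5:
        flags.add("sparse_table")
    x = table.chisq()
    p = float(stats.chi2.sf(x, df=1))
    return AssocResult(record.chrom, record.pos, table, x, p, flags=frozenset(flags))


def association_scan(
    records: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    groups: Pedigree,
) -> pd.DataFrame:
    """Vectorized allelic test over all sites.

    Returns a PLINK-style table: CHR, SNP, BP, A1 (alt), F_A, F_U, A2 (ref),
    CHISQ, P.
    """
    case_idx = genotypes.sample_index(groups.cases)
    ctrl_idx = genotypes.sample_index(groups.controls)
    from .fst import _project_biallelic

    proj = _project_biallelic(genotypes.alleles)
    cr, ca = _group_allele_counts(proj, case_idx)
    ur, ua = _group_allele_counts(proj, ctrl_idx)
    n = (cr + ca + ur + ua).astype(float)
    denom = (cr + ca) * (ur + ua) * (cr + ur) * (ca + ua)
    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = np.where(denom > 0, n * (cr * ua - ca * ur).astype(float) ** 2 / denom, 0.0)
        f_a = np.where(cr + ca > 0, ca / (cr + ca), np.nan)
        f_u = np.where(ur + ua > 0, ua / (ur + ua), np.nan)
    p = stats.chi2.sf(chisq, df=1)
    p = np.where(denom > 0, p, 1.0)
    return pd.DataFrame(
        {
            "CHR": [r.chrom for r in records],
            "SNP": [r.id or f"{r.chrom}:{r.pos}" for r in records],
            "BP": [r.pos for r in records],
            "A1": [r.alts[0] for r in records],
            "F_A": f_a,
            "F_U": f_u,
            "A2": [r.ref for r in records],
            "CHISQ": chisq,
            "P": p,
        }
    )


def _derived_index(record: VariantRecord, policy: str) -> int:
    """Allele index (0 = ref, 1 = alt projection) of the derived allele."""
    if policy == "reference":
        return 1  # reference taken as ancestral
    if policy == "AA":
        aa = record.annotations.get("AA")
        if aa is None:
            raise ValueError(f"{record.chrom}:{record.pos}: no AA annotation for policy 'AA'")
        if str(aa) == record.ref:
            return 1
        if str(aa) in record.alts:
            return 0
        raise ValueError(
            f"{record.chrom}:{record.pos}: ancestral allele {aa!r} not among observed alleles"
        )
    raise ValueError(f"unknown ancestral policy {policy!r}")


def daf(
    record: VariantRecord,
    genotypes: GenotypeMatrix,
    groups: Pedigree,
    ancestral_policy: str = "reference",
    site_index: int = 0,
) -> DafResult:
    """Derived allele frequency overall and per group (missing dropped)."""
    der = _derived_index(record, ancestral_policy)
    case_idx = genotypes.sample_index(groups.cases)
    ctrl_idx = genotypes.sample_index(groups.controls)
    from .fst import _project_biallelic

    proj = _project_biallelic(genotypes.alleles[site_index : site_index + 1])
    cr, ca = _group_allele_counts(proj, case_idx)
    ur, ua = _group_allele_counts(proj, ctrl_idx)
    if der == 1:
        dc, da = int(cr[0] + ca[0]), int(ca[0])
        uc, ua_ = int(ur[0] + ua[0]), int(ua[0])
    else:
        dc, da = int(cr[0] + ca[0]), int(cr[0])
        uc, ua_ = int(ur[0] + ua[0]), int(ur[0])
    total = dc + uc
    derived_total = da + ua_
    return DafResult(
        record.chrom,
        record.pos,
        derived_total / total if total else float("nan"),
        da / dc if dc else float("nan"),
        ua_ / uc if uc else float("nan"),
        derived_allele=record.alts[0] if der == 1 else record.ref,
        policy=ancestral_policy,
    )


def daf_scan(
    records: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    groups: Pedigree,
    ancestral_policy: str = "reference",
) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        r = daf(rec, genotypes, groups, ancestral_policy, site_index=i)
        rows.append(
            {
                "CHROM": r.chrom,
                "POS": r.pos,
                "DAF_ALL": r.daf_overall,
                "DAF_A": r.daf_case,
                "DAF_U": r.daf_control,
                "DERIVED": r.derived_allele,
            }
        )
    return pd.DataFrame(rows)


def concordance(
    record: VariantRecord,
    genotypes: GenotypeMatrix,
    groups: Pedigree,
    model: str = "recessive",
    ancestral_policy: str = "reference",
    site_index: int = 0,
    strict_dominant: bool = False,
) -> ConcordanceResult:
    """Genotype-phenotype concordance under a recessive or dominant model.

    Recessive: every affected individual is homozygous for the derived
    allele AND no unaffected individual is. Dominant: every affected carries
    at least one derived allele AND no unaffected is homozygous derived
    (``strict_dominant``: no unaffected carries any copy). Missing genotypes
    are ignored. A monomorphic site (no derived allele observed) is never
    concordant.
    """
    if model not in ("recessive", "dominant"):
        raise ValueError(f"unknown concordance model {model!r}")
    der = _derived_index(record, ancestral_policy)
    from .fst import _project_biallelic

    proj = _project_biallelic(genotypes.alleles[site_index : site_index + 1])[0]
    case_idx = genotypes.sample_index(groups.cases)
    ctrl_idx = genotypes.sample_index(groups.controls)

    def classify(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = proj[idx]
        ok = (g >= 0).all(axis=1)
        dose = (g == der).sum(axis=1)
        return dose[ok], ok

    case_dose, _ = classify(case_idx)
    ctrl_dose, _ = classify(ctrl_idx)
    if (case_dose > 0).sum() + (ctrl_dose > 0).sum() == 0:
        return ConcordanceResult(record.chrom, record.pos, model, False,
                                 "no derived allele observed")
    if model == "recessive":
        if not (case_dose == 2).all():
            return ConcordanceResult(record.chrom, record.pos, model, False,
                                     "affected not all homozygous derived")
        if (ctrl_dose == 2).any():
            return ConcordanceResult(record.chrom, record.pos, model, False,
                                     "unaffected homozygous derived")
        return ConcordanceResult(record.chrom, record.pos, model, True)
    # dominant
    if not (case_dose >= 1).all():
        return ConcordanceResult(record.chrom, record.pos, model, False,
                                 "affected without derived allele")
    bad = (ctrl_dose >= 1).any() if strict_dominant else (ctrl_dose == 2).any()
    if bad:
        return ConcordanceResult(record.chrom, record.pos, model, False,
                                 "unaffected carries derived allele")
    return ConcordanceResult(record.chrom, record.pos, model, True)


def concordance_scan(
    records: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    groups: Pedigree,
    model: str = "recessive",
    ancestral_policy: str = "reference",
) -> pd.DataFrame:
    """Vectorized concordance over all sites (same semantics as ``concordance``)."""
    if model not in ("recessive", "dominant"):
        raise ValueError(f"unknown concordance model {model!r}")
    from .fst import _project_biallelic

    proj = _project_biallelic(genotypes.alleles)
    case_idx = genotypes.sample_index(groups.cases)
    ctrl_idx = genotypes.sample_index(groups.controls)
    der = np.array([_derived_index(r, ancestral_policy) for r in records])

    def doses(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = proj[:, idx, :]
        ok = (g >= 0).all(axis=2)
        dose = (g == der[:, None, None]).sum(axis=2)
        return dose, ok

    case_dose, case_ok = doses(case_idx)
    ctrl_dose, ctrl_ok = doses(ctrl_idx)
    seg = ((case_dose > 0) & case_ok).any(axis=1) | ((ctrl_dose > 0) & ctrl_ok).any(axis=1)
    if model == "recessive":
        cases_hom = ((case_dose == 2) | ~case_ok).all(axis=1)
        no_ctrl_hom = ~((ctrl_dose == 2) & ctrl_ok).any(axis=1)
        conc = seg & cases_hom & no_ctrl_hom
    else:
        cases_carry = ((case_dose >= 1) | ~case_ok).all(axis=1)
        no_ctrl_hom = ~((ctrl_dose == 2) & ctrl_ok).any(axis=1)
        conc = seg & cases_carry & no_ctrl_hom
    return pd.DataFrame(
        {
            "CHROM": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "MODEL": model,
            "CONCORDANT": conc.astype(int),
        }
    )
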