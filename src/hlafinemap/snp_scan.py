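"""Dominant-model SNP association and the carrier-exclusion conditional scan.

Each biallelic SNP is tested under *two* dominant codings — carries at least
one ALT copy, and carries at least one REF copy — and the coding with the
smaller Pearson chi-square p is reported (with its Woolf OR/CI).  The two
codings carve out different carrier sets, so neither subsumes the other; the
reported minimum is deliberately not multiplicity-corrected, and the plain
5e-8 genome-wide cutoff is applied to it.

The conditional analysis is a *carrier-exclusion* scan: every subject (case
or control) carrying any allele of an exclusion set is dropped and the whole
region re-scanned.  A SNP whose signal merely tags an excluded allele's
haplotype loses its signal; a signal that survives is independent of that
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .assoc_core import (
    GENOME_WIDE_P,
    AssocResult,
    Contingency2x2,
    woolf_or,
)
from .genotype_io import SNP_MISSING, AlleleCall, Cohort, SnpRecord, Subject


@dataclass
class SnpAssoc:
    """Min-p dominant-model association for one SNP."""

    snp: SnpRecord
    coding_used: str  # "major_dominant" | "minor_dominant"
    table: Contingency2x2 | None
    or_: float
    ci_low: float
    ci_high: float
    p: float
    p_other_coding: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.p) and self.table is not None

    @property
    def neglog10_p(self) -> float:
        if not self.defined or self.p <= 0:
            return math.nan
        return -math.log10(self.p)


@dataclass
class ScanSummary:
    """One row of a stepwise-exclusion scan: subset sizes and signal counts."""

    excluded_alleles: tuple[str, ...]
    n_cases: int
    n_controls: int
    n_tested: int
    n_genome_wide: int
    top_snp: SnpAssoc | None


def _vector_chi2(a, b, c, d):
    """Vectorised uncorrected Pearson chi-square over parallel 2x2 cells."""
    a, b, c, d = (x.astype(np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    stat = np.where(denom > 0, stat, np.nan)
    p = np.where(np.isfinite(stat), _chi2_dist.sf(stat, df=1), np.nan)
    return stat, p


def _scan_counts(cohort: Cohort, subset: np.ndarray):
    """Per-SNP 2x2 counts for both dominant codings over a subject subset.

    Returns dict of count arrays plus the combined-sample ALT frequency.
    """
    G = cohort.snp_matrix
    if G is None:
        raise ValueError("cohort has no SNP matrix")
    cases = cohort.case_mask() & subset
    controls = ~cohort.case_mask() & subset
    valid = G != SNP_MISSING
    alt_car = (G >= 1) & valid
    ref_car = (G <= 1) & valid

    def counts(mask):
        m = mask.astype(np.float64)
        return {
            "n": m @ valid,
            "alt": m @ alt_car,
            "ref": m @ ref_car,
            "alt_copies": m @ np.where(valid, G, 0),
        }

    ca, co = counts(cases), counts(controls)
    tot_n = ca["n"] + co["n"]
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = (ca["alt_copies"] + co["alt_copies"]) / (2 * tot_n)
    return ca, co, alt_freq


def _assemble(
    snp: SnpRecord,
    ca_n: float,
    co_n: float,
    ca_alt: float,
    co_alt: float,
    ca_ref: float,
    co_ref: float,
    p_alt: float,
    p_ref: float,
    alt_freq: float,
) -> SnpAssoc:
    sentinel = SnpAssoc(
        snp=snp,
        coding_used="minor_dominant",
        table=None,
        or_=math.nan,
        ci_low=math.nan,
        ci_high=math.nan,
        p=1.0,
        p_other_coding=1.0,
    )
    if ca_n == 0 or co_n == 0:
        return sentinel
    alt_defined = math.isfinite(p_alt)
    ref_defined = math.isfinite(p_ref)
    if not alt_defined and not ref_defined:
        return sentinel  # monomorphic SNP
    if alt_defined and (not ref_defined or p_alt <= p_ref):
        use_alt, p, p_other = True, p_alt, (p_ref if ref_defined else 1.0)
    else:
        use_alt, p, p_other = False, p_ref, (p_alt if alt_defined else 1.0)
    if use_alt:
        a, c = ca_alt, co_alt
        dominant_is_major = alt_freq > 0.5
    else:
        a, c = ca_ref, co_ref
        dominant_is_major = alt_freq <= 0.5
    t = Contingency2x2(int(a), int(ca_n - a), int(c), int(co_n - c))
    orci = woolf_or(t)
    return SnpAssoc(
        snp=snp,
        coding_used="major_dominant" if dominant_is_major else "minor_dominant",
        table=t,
        or_=orci.or_,
        ci_low=orci.ci_low,
        ci_high=orci.ci_high,
        p=float(p),
        p_other_coding=float(p_other),
    )


SubsetPredicate = Callable[[Subject], bool]


def _subset_mask(cohort: Cohort, subset_predicate: SubsetPredicate | None):
    if subset_predicate is None:
        return np.ones(len(cohort.subjects), dtype=bool)
    return np.fromiter(
        (bool(subset_predicate(s)) for s in cohort.subjects),
        dtype=bool,
        count=len(cohort.subjects),
    )


def dominant_minp(
    cohort: Cohort, snp_index: int, subset_mask: np.ndarray | None = None
) -> SnpAssoc:
    """Min-p dominant association for a single SNP (see module docstring)."""
    subset = (
        subset_mask
        if subset_mask is not None
        else np.ones(len(cohort.subjects), dtype=bool)
    )
    ca, co, alt_freq = _scan_counts(cohort, subset)
    j = snp_index
    _, p_alt = _vector_chi2(
        ca["alt"][j : j + 1],
        ca["n"][j : j + 1] - ca["alt"][j : j + 1],
        co["alt"][j : j + 1],
        co["n"][j : j + 1] - co["alt"][j : j + 1],
    )
    _, p_ref = _vector_chi2(
        ca["ref"][j : j + 1],
        ca["n"][j : j + 1] - ca["ref"][j : j + 1],
        co["ref"][j : j + 1],
        co["n"][j : j + 1] - co["ref"][j : j + 1],
    )
    return _assemble(
        cohort.snps[j],
        ca["n"][j],
        co["n"][j],
        ca["alt"][j],
        co["alt"][j],
        ca["ref"][j],
        co["ref"][j],
        p_alt[0],
        p_ref[0],
        alt_freq[j],
    )


def region_scan(
    cohort: Cohort,
    subset_predicate: SubsetPredicate | None = None,
    gw_threshold: float = GENOME_WIDE_P,
) -> tuple[list[SnpAssoc], ScanSummary]:
    """Min-p dominant scan over every SNP on a subject subset.

    The summary counts SNPs below the genome-wide threshold; the top SNP is
    the smallest p with ties broken toward the smaller genomic position.
    """
    subset = _subset_mask(cohort, subset_predicate)
    cases = cohort.case_mask() & subset
    n_cases, n_controls = int(cases.sum()), int((subset & ~cases).sum())
    ca, co, alt_freq = _scan_counts(cohort, subset)
    _, p_alt = _vector_chi2(
        ca["alt"], ca["n"] - ca["alt"], co["alt"], co["n"] - co["alt"]
    )
    _, p_ref = _vector_chi2(
        ca["ref"], ca["n"] - ca["ref"], co["ref"], co["n"] - co["ref"]
    )
    results = [
        _assemble(
            cohort.snps[j],
            ca["n"][j],
            co["n"][j],
            ca["alt"][j],
            co["alt"][j],
            ca["ref"][j],
            co["ref"][j],
            p_alt[j],
            p_ref[j],
            alt_freq[j],
        )
        for j in range(len(cohort.snps))
    ]
    defined = [r for r in results if r.defined]
    n_gw = sum(1 for r in defined if r.p < gw_threshold)
    top = min(defined, key=lambda r: (r.p, r.snp.pos), default=None)
    summary = ScanSummary(
        excluded_alleles=(),
        n_cases=n_cases,
        n_controls=n_controls,
        n_tested=len(results),
        n_genome_wide=n_gw,
        top_snp=top,
    )
    return results, summary


def exclusion_mask(cohort: Cohort, alleles: Sequence[AlleleCall]) -> np.ndarray:
    """Subjects retained after dropping carriers of any listed allele.

    A subject untyped at an allele's locus cannot be shown to carry it and
    is retained, matching the use of known-carrier exclusion.
    """
    keep = np.ones(len(cohort.subjects), dtype=bool)
    for allele in alleles:
        keep &= ~cohort.carrier_mask(allele)
    return keep


def stepwise_exclusion_scan(
    cohort: Cohort,
    exclusion_sets: Sequence[Sequence[AlleleCall]],
    gw_threshold: float = GENOME_WIDE_P,
) -> list[ScanSummary]:
    """Baseline scan plus one re-scan per carrier-exclusion set.

    The first summary is always the no-exclusion baseline.  Exclusion drops
    both cases and controls carrying any allele of the set.
    """
    summaries: list[ScanSummary] = []
    _, baseline = region_scan(cohort, None, gw_threshold)
    summaries.append(baseline)
    for alleles in exclusion_sets:
        keep = exclusion_mask(cohort, alleles)
        keep_set = {s.id for s, k in zip(cohort.subjects, keep) if k}
        _, summary = region_scan(
            cohort, lambda s: s.id in keep_set, gw_threshold
        )
        summary.excluded_alleles = tuple(str(a) for a in alleles)
        summaries.append(summary)
    return summaries


def manhattan_export(
    results: Sequence[SnpAssoc],
    path: str | Path,
    hla_points: Sequence[AssocResult] | None = None,
    gw_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Write a plotting-ready TSV of -log10 p per marker.

    SNP rows carry (rsid, chrom, pos, neglog10_p, coding, genome_wide flag);
    optional HLA-allele association points are appended with marker type
    ``hla``.  Sentinel SNPs get an NA score.  The genome-wide flag is
    exclusive at the boundary (p = 5e-8 is *not* flagged).
    """
    rows = []
    for r in results:
        score = r.neglog10_p if r.defined else math.nan
        rows.append(
            {
                "marker": r.snp.rsid,
                "type": "snp",
                "chrom": r.snp.chrom,
                "pos": r.snp.pos,
                "neglog10_p": score,
                "coding": r.coding_used if r.defined else "NA",
                "genome_wide": bool(r.defined and r.p < gw_threshold),
            }
        )
    for h in hla_points or ():
        score = -math.log10(h.p) if h.defined and h.p > 0 else math.nan
        rows.append(
            {
                "marker": h.factor,
                "type": "hla",
                "chrom": "6",
                "pos": "",
                "neglog10_p": score,
                "coding": "carrier",
                "genome_wide": bool(h.defined and h.p < gw_threshold),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df
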