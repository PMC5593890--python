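"""The 2x2 association engine.

Every statistic in the pipeline reduces to a 2x2 contingency table of
carrier status against group membership.  The conventions are fixed:

* odds ratio by Woolf's formula, OR = ad/bc, with the 95% CI from the
  log-scale standard error sqrt(1/a + 1/b + 1/c + 1/d);
* Pearson chi-square on 1 d.f. *without* continuity correction,
  chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d));
* carrier (dominant) coding: a subject is exposed if at least one of its
  two alleles matches the allele of interest — homozygotes count once;
* alleles enter multi-allele screens only when carried by more than
  ``min_carrier_freq`` (default 1%) of cases or of controls, and the
  Bonferroni divisor is the number of alleles actually screened.

Zero cells get the Haldane–Anscombe +0.5 correction (flagged) for the OR and
CI only; degenerate tables (no exposure variation, or an empty margin for the
chi-square) yield NaN sentinels rather than exceptions so that screens over
many factors can proceed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

from scipy.stats import chi2 as _chi2_dist

from .genotype_io import LOCI, AlleleCall, Cohort, Subject

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b) for group 1 exposed/unexposed, (c, d) for group 2."""

    a: int
    b: int
    c: int
    d: int
    group_labels: tuple[str, str] = ("case", "control")
    exposure_labels: tuple[str, str] = ("carrier", "non-carrier")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each group needs at least one subject")

    def swapped_groups(self) -> "Contingency2x2":
        return Contingency2x2(
            self.c, self.d, self.a, self.b,
            (self.group_labels[1], self.group_labels[0]),
            self.exposure_labels,
        )


class OddsRatioCI(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied

    @property
    def defined(self) -> bool:
        return math.isfinite(self.or_)


class Chi2Result(NamedTuple):
    chi2: float
    p: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.chi2)


_UNDEFINED_OR = OddsRatioCI(math.nan, math.nan, math.nan, False)
_UNDEFINED_CHI2 = Chi2Result(math.nan, math.nan)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def woolf_or(t: Contingency2x2) -> OddsRatioCI:
    """Woolf odds ratio with 95% CI; +0.5 Haldane correction on zero cells.

    Returns the NaN sentinel when there is no exposure variation at all
    (a = c = 0 or b = d = 0), where no correction rescues the estimate.
    """
    if (t.a == 0 and t.c == 0) or (t.b == 0 and t.d == 0):
        return _UNDEFINED_OR
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = 0 in (t.a, t.b, t.c, t.d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioCI(
        or_, or_ * math.exp(-_Z95 * se), or_ * math.exp(_Z95 * se), corrected
    )


def chi2_2x2(t: Contingency2x2) -> Chi2Result:
    """Pearson 1-d.f. chi-square without continuity correction."""
    n = t.a + t.b + t.c + t.d
    m1, m2 = t.a + t.b, t.c + t.d
    e1, e2 = t.a + t.c, t.b + t.d
    if min(m1, m2, e1, e2) == 0:
        return _UNDEFINED_CHI2
    num = n * (t.a * t.d - t.b * t.c) ** 2
    stat = num / (m1 * m2 * e1 * e2)
    return Chi2Result(float(stat), float(_chi2_dist.sf(stat, df=1)))


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha/m for m tested factors."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Carrier screens
# ---------------------------------------------------------------------------


class CarrierCounts(NamedTuple):
    case_carriers: int
    control_carriers: int
    case_n: int
    control_n: int

    @property
    def case_freq(self) -> float:
        return self.case_carriers / self.case_n if self.case_n else math.nan

    @property
    def control_freq(self) -> float:
        return (
            self.control_carriers / self.control_n if self.control_n else math.nan
        )


@dataclass
class AssocResult:
    """One tested factor's 2x2 association (counts, OR, CI, chi2, p, flags)."""

    factor: str
    n1: int
    n2: int
    carriers1: int
    carriers2: int
    or_: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    flags: set[str] = field(default_factory=set)

    @property
    def freq1(self) -> float:
        return self.carriers1 / self.n1 if self.n1 else math.nan

    @property
    def freq2(self) -> float:
        return self.carriers2 / self.n2 if self.n2 else math.nan

    @property
    def defined(self) -> bool:
        return math.isfinite(self.p)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.defined and self.p < alpha


_SENTINEL = (math.nan,) * 5


def assoc_from_table(factor: str, t: Contingency2x2) -> AssocResult:
    """Assemble an AssocResult from a carrier-vs-group table."""
    orci = woolf_or(t)
    chi = chi2_2x2(t)
    res = AssocResult(
        factor=factor,
        n1=t.a + t.b,
        n2=t.c + t.d,
        carriers1=t.a,
        carriers2=t.c,
        or_=orci.or_,
        ci_low=orci.ci_low,
        ci_high=orci.ci_high,
        chi2=chi.chi2,
        p=chi.p,
    )
    if orci.corrected:
        res.flags.add("haldane_corrected")
    if not orci.defined or not chi.defined:
        res.flags.add("undefined")
    return res


def carrier_matrix(cohort: Cohort, locus: str) -> dict[AlleleCall, CarrierCounts]:
    """Per-allele carrier counts at one locus (non-missing denominators).

    A subject with a non-missing genotype carries allele X iff X equals either
    of its two alleles; homozygotes count once.  Subjects untyped at the locus
    are excluded from both numerator and denominator.
    """
    if locus not in LOCI:
        raise ValueError(f"unsupported locus {locus!r}")
    typed = cohort.typed_mask(locus)
    cases = cohort.case_mask()
    case_n = int((typed & cases).sum())
    control_n = int((typed & ~cases).sum())
    out: dict[AlleleCall, CarrierCounts] = {}
    if case_n + control_n == 0:
        import logging

        logging.getLogger(__name__).warning("locus %s entirely missing", locus)
        return out
    for allele in cohort.alleles_at(locus):
        carrier = cohort.carrier_mask(allele)
        out[allele] = CarrierCounts(
            int((carrier & cases).sum()),
            int((carrier & ~cases).sum()),
            case_n,
            control_n,
        )
    return out


def common_alleles(
    matrix: dict[AlleleCall, CarrierCounts], min_carrier_freq: float = 0.01
) -> list[AlleleCall]:
    """Alleles carried by > ``min_carrier_freq`` of cases OR of controls.

    Deterministic order: descending case carrier frequency, then name.
    """
    kept = [
        (a, c)
        for a, c in matrix.items()
        if c.case_freq > min_carrier_freq or c.control_freq > min_carrier_freq
    ]
    kept.sort(key=lambda ac: (-ac[1].case_freq, ac[0].name))
    return [a for a, _ in kept]


def carrier_association(
    cohort: Cohort,
    loci: Sequence[str] = LOCI,
    min_carrier_freq: float = 0.01,
    alpha: float = 0.05,
    gw_threshold: float = GENOME_WIDE_P,
) -> list[AssocResult]:
    """Case-vs-control carrier association for every common allele.

    The Bonferroni divisor is the total number of common alleles across all
    tested loci in this run.  Results carry ``bonferroni_significant`` and
    ``genome_wide`` flags and come back sorted by p (undefined last).
    """
    tested: list[tuple[AlleleCall, CarrierCounts]] = []
    for locus in loci:
        matrix = carrier_matrix(cohort, locus)
        for allele in common_alleles(matrix, min_carrier_freq):
            tested.append((allele, matrix[allele]))
    if not tested:
        return []
    threshold = bonferroni_threshold(len(tested), alpha)
    results: list[AssocResult] = []
    for allele, cc in tested:
        t = Contingency2x2(
            cc.case_carriers,
            cc.case_n - cc.case_carriers,
            cc.control_carriers,
            cc.control_n - cc.control_carriers,
        )
        res = assoc_from_table(str(allele), t)
        if res.defined and res.p < threshold:
            res.flags.add("bonferroni_significant")
        if res.defined and res.p < gw_threshold:
            res.flags.add("genome_wide")
        results.append(res)
    results.sort(key=lambda r: (not r.defined, r.p if r.defined else 1.0))
    return results


SubjectPredicate = Callable[[Subject], "bool | None"]


def two_group_table(
    cohort: Cohort,
    split: SubjectPredicate,
    outcome: SubjectPredicate,
    subset: SubjectPredicate | None = None,
) -> Contingency2x2:
    """2x2 of split x outcome over subjects where both predicates resolve.

    Predicates return True/False, or None for "data unavailable"; subjects
    with any None are dropped from the denominators.  ``subset`` restricts
    the comparison (e.g. cases only for clinical contrasts).
    """
    a = b = c = d = 0
    for s in cohort.subjects:
        if subset is not None:
            inc = subset(s)
            if not inc:
                continue
        sp, oc = split(s), outcome(s)
        if sp is None or oc is None:
            continue
        if sp:
            a, b = (a + 1, b) if oc else (a, b + 1)
        else:
            c, d = (c + 1, d) if oc else (c, d + 1)
    return Contingency2x2(a, b, c, d)
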