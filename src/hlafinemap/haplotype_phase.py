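"""DRB1–DQB1 phase assignment and recombinant-class decomposition.

With only two loci, an unphased genotype {x1,x2} x {y1,y2} admits at most two
phase configurations: (x1-y1, x2-y2) or (x1-y2, x2-y1).  Each subject is
assigned the configuration maximising the product of the two haplotypes'
reference frequencies, with haplotypes absent from the reference table
contributing a small pseudo-frequency ``epsilon``.  This per-subject
maximum-likelihood rule mirrors empirical phasing against published
population haplotype tables; no cohort-level EM is attempted.

The recombinant-class decomposition then splits carriers of a linked allele
pair (A at DRB1, B at DQB1) into three haplotype classes — A-with-B,
A-without-B, B-without-A — and associates each class with disease.  When a
pair is in near-complete linkage, the allele whose recombinant class retains
a same-direction effect is the primary one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .assoc_core import AssocResult, Contingency2x2, assoc_from_table
from .genotype_io import AlleleCall, Cohort, HaplotypeFreqTable, Subject

logger = logging.getLogger(__name__)

Haplotype = tuple[AlleleCall, AlleleCall]  # (DRB1, DQB1)

#: Relative tolerance below which the two configuration likelihoods tie.
AMBIGUITY_RTOL = 1e-9


@dataclass
class PhaseAssignment:
    """The chosen phase configuration for one subject."""

    subject_id: str
    haplotypes: tuple[Haplotype, Haplotype]
    config_likelihood: float
    alt_likelihood: float
    ambiguous: bool


class PhaseError(ValueError):
    pass


def _hap_key(h: Haplotype) -> tuple[str, str]:
    return (h[0].name, h[1].name)


def assign_phase(
    subject: Subject, ref: HaplotypeFreqTable, epsilon: float = 1e-6
) -> PhaseAssignment:
    """Maximum-likelihood phase for one subject under the reference table.

    Ties (relative likelihood difference below ``AMBIGUITY_RTOL``) are marked
    ambiguous and broken toward the lexicographically smaller configuration.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    g_dr = subject.genotype("DRB1")
    g_dq = subject.genotype("DQB1")
    if g_dr is None or g_dq is None:
        raise PhaseError(f"subject {subject.id} missing DRB1 or DQB1")
    x1, x2 = g_dr
    y1, y2 = g_dq

    def lik(cfg: tuple[Haplotype, Haplotype]) -> float:
        (d1, q1), (d2, q2) = cfg
        f1 = ref.freq(d1.name, q1.name, epsilon)
        f2 = ref.freq(d2.name, q2.name, epsilon)
        return f1 * f2

    cfg1 = ((x1, y1), (x2, y2))
    cfg2 = ((x1, y2), (x2, y1))
    single = x1 == x2 or y1 == y2  # either locus homozygous: one configuration
    if single:
        chosen, alt = cfg1, cfg1
        l_chosen = l_alt = lik(cfg1)
        ambiguous = False
    else:
        l1, l2 = lik(cfg1), lik(cfg2)
        tied = abs(l1 - l2) <= AMBIGUITY_RTOL * max(l1, l2)
        if tied:
            chosen, alt = sorted(
                (cfg1, cfg2), key=lambda c: sorted(map(_hap_key, c))
            )
            l_chosen = l_alt = max(l1, l2)
            ambiguous = True
        elif l1 > l2:
            chosen, alt, l_chosen, l_alt, ambiguous = cfg1, cfg2, l1, l2, False
        else:
            chosen, alt, l_chosen, l_alt, ambiguous = cfg2, cfg1, l2, l1, False
    # canonical within-pair order for reproducible output
    h1, h2 = sorted(chosen, key=_hap_key)
    return PhaseAssignment(
        subject_id=subject.id,
        haplotypes=(h1, h2),
        config_likelihood=l_chosen,
        alt_likelihood=l_alt,
        ambiguous=ambiguous,
    )


def assign_phases(
    cohort: Cohort, ref: HaplotypeFreqTable, epsilon: float = 1e-6
) -> list[PhaseAssignment]:
    """Phase every subject typed at both loci; skip (and log) the rest."""
    out: list[PhaseAssignment] = []
    skipped = 0
    for s in cohort.subjects:
        try:
            out.append(assign_phase(s, ref, epsilon))
        except PhaseError:
            skipped += 1
    if skipped:
        logger.info("phase assignment skipped %d subjects missing a locus", skipped)
    return out


# ---------------------------------------------------------------------------
# Recombinant-class association
# ---------------------------------------------------------------------------

CLASS_LABELS = ("A_and_B", "A_not_B", "notA_B")


@dataclass
class HaploClassResult:
    """Carrier association for one haplotype class of a linked pair."""

    class_label: str
    carriers_case: int
    carriers_control: int
    assoc: AssocResult | None  # None when the class has no carriers at all


def _class_of(h: Haplotype, a: AlleleCall, b: AlleleCall) -> str | None:
    has_a, has_b = h[0] == a, h[1] == b
    if has_a and has_b:
        return "A_and_B"
    if has_a:
        return "A_not_B"
    if has_b:
        return "notA_B"
    return None


def haplotype_class_assoc(
    cohort: Cohort,
    phases: Sequence[PhaseAssignment],
    alleleA: AlleleCall,
    alleleB: AlleleCall,
) -> list[HaploClassResult]:
    """Carrier association of the three haplotype classes of pair (A, B).

    A subject carries a class iff at least one assigned haplotype falls in
    it; a subject may carry two classes.  Denominators are all subjects
    typed at both loci (i.e. all phased subjects), and each class is
    compared against its own non-carriers.
    """
    if alleleA.locus != "DRB1" or alleleB.locus != "DQB1":
        raise ValueError("pair must be (DRB1 allele, DQB1 allele)")
    phen = {s.id: s.is_case for s in cohort.subjects}
    n_case = sum(1 for p in phases if phen[p.subject_id])
    n_control = len(phases) - n_case
    counts = {lab: [0, 0] for lab in CLASS_LABELS}
    for p in phases:
        classes = {
            c
            for c in (_class_of(h, alleleA, alleleB) for h in p.haplotypes)
            if c is not None
        }
        idx = 0 if phen[p.subject_id] else 1
        for c in classes:
            counts[c][idx] += 1
    results: list[HaploClassResult] = []
    for lab in CLASS_LABELS:
        ca, co = counts[lab]
        if ca == 0 and co == 0:
            results.append(HaploClassResult(lab, 0, 0, None))
            continue
        t = Contingency2x2(ca, n_case - ca, co, n_control - co)
        results.append(
            HaploClassResult(lab, ca, co, assoc_from_table(lab, t))
        )
    return results


@dataclass
class PrimaryAlleleVerdict:
    """Which member of a linked pair carries the association."""

    alleleA: str
    alleleB: str
    verdict: str  # A_primary | B_primary | inseparable | insufficient_recombinants
    a_not_b_carriers: int
    notA_b_carriers: int
    detail: dict[str, object]


def primary_allele_report(
    results: Sequence[HaploClassResult],
    allele_result_a: AssocResult,
    allele_result_b: AssocResult,
    alpha: float = 0.05,
    min_recombinant_carriers: int = 10,
) -> PrimaryAlleleVerdict:
    """Decide the primary allele of a linked pair from its recombinant classes.

    The allele whose *absence* leaves a same-direction nominally significant
    recombinant-class effect is secondary; the other is primary.  When both
    recombinant classes are too thin (< ``min_recombinant_carriers`` total
    carriers each) no verdict is attempted.
    """
    by_label = {r.class_label: r for r in results}
    ab = by_label["A_and_B"]
    a_only = by_label["A_not_B"]
    b_only = by_label["notA_B"]

    def total(r: HaploClassResult) -> int:
        return r.carriers_case + r.carriers_control

    def same_direction_sig(r: HaploClassResult) -> bool:
        if r.assoc is None or not r.assoc.significant(alpha):
            return False
        if ab.assoc is None or not ab.assoc.defined:
            return False
        return (r.assoc.or_ > 1) == (ab.assoc.or_ > 1)

    detail: dict[str, object] = {
        "A_and_B": ab.assoc,
        "A_not_B": a_only.assoc,
        "notA_B": b_only.assoc,
        "allele_A": allele_result_a,
        "allele_B": allele_result_b,
    }
    kw = dict(
        alleleA=allele_result_a.factor,
        alleleB=allele_result_b.factor,
        a_not_b_carriers=total(a_only),
        notA_b_carriers=total(b_only),
        detail=detail,
    )
    if (
        total(a_only) < min_recombinant_carriers
        and total(b_only) < min_recombinant_carriers
    ):
        return PrimaryAlleleVerdict(verdict="insufficient_recombinants", **kw)
    a_sig = same_direction_sig(a_only)  # A keeps its effect without B
    b_sig = same_direction_sig(b_only)  # B keeps its effect without A
    a_adequate = total(a_only) >= min_recombinant_carriers
    b_adequate = total(b_only) >= min_recombinant_carriers
    if a_sig and b_sig:
        verdict = "inseparable"
    elif a_sig:
        verdict = "A_primary"
    elif b_sig:
        verdict = "B_primary"
    # Neither recombinant class shows the effect: a *null* class with adequate
    # carriers refutes its allele's independent contribution, implicating the
    # other member of the pair.
    elif a_adequate and not b_adequate:
        verdict = "B_primary"
    elif b_adequate and not a_adequate:
        verdict = "A_primary"
    else:
        verdict = "inseparable"
    return PrimaryAlleleVerdict(verdict=verdict, **kw)
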