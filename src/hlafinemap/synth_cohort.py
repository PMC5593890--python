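"""Synthetic case-control cohorts with DR-DQ haplotype structure.

The generator draws two DRB1–DQB1 haplotypes per subject independently from
a frequency pool (Hardy–Weinberg), assigns disease by a logistic model on
*carrier* indicators, and fills case/control quotas by rejection — the
retrospective sampling of a case-control design.  Disease odds are attached
to haplotypes:

    logit P(case) = logit(baseline_prevalence)
                    + sum over carried haplotypes h of ln(OR_h)
                    + ln(or_modifier) if the epistasis condition holds,

where "carried" is dominant coding (one or two copies count once), matching
the scale on which the analysis estimates odds ratios.  With a low baseline
prevalence the marginal case-control carrier OR approximates the planted
value.

SNP LD arises mechanistically: each SNP tags one haplotype of the pool and
its ALT allele is painted chromosome-wise onto every chromosome carrying
that haplotype, with a per-SNP flip ("discordance") probability.  Ground
truth — per-subject phase, per-haplotype OR, per-SNP tag — is emitted
alongside the cohort and never feeds back into the analysis inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from . import genotype_io as gio
from .genotype_io import (
    AlleleCall,
    Cohort,
    HaplotypeFreqTable,
    SnpRecord,
    Subject,
)


class HapSpec(NamedTuple):
    """One pool haplotype: DRB1 name, DQB1 name, frequency, disease OR."""

    drb1: str
    dqb1: str
    freq: float
    or_: float


class EpistasisSpec(NamedTuple):
    """Multiplies the odds by ``or_modifier`` when both alleles are carried."""

    target: AlleleCall
    background: AlleleCall
    or_modifier: float


class SnpTag(NamedTuple):
    snp_index: int
    hap_index: int
    discordance: float


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_cases: int
    n_controls: int
    haplotypes: tuple[HapSpec, ...]
    epistasis: EpistasisSpec | None = None
    snps: int = 0
    snp_tag_map: tuple[SnpTag, ...] = ()
    baseline_prevalence: float = 0.02
    region: tuple[str, int, int] = ("6", 29507426, 33505746)
    max_attempts: int = 200

    def __post_init__(self) -> None:
        total = sum(h.freq for h in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(h.or_ <= 0 for h in self.haplotypes):
            raise ValueError("all haplotype ORs must be > 0")
        if any(not (0 <= t.discordance <= 0.5) for t in self.snp_tag_map):
            raise ValueError("discordance must lie in [0, 0.5]")
        if not (0 < self.baseline_prevalence < 1):
            raise ValueError("baseline_prevalence must lie in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth emitted with a simulated cohort (test access only)."""

    hap_pairs: np.ndarray  # (n_subjects, 2) indices into config.haplotypes
    haplotypes: tuple[HapSpec, ...]
    snp_tags: tuple[SnpTag, ...]

    def true_phase(self, i: int) -> tuple[tuple[str, str], tuple[str, str]]:
        h1 = self.haplotypes[self.hap_pairs[i, 0]]
        h2 = self.haplotypes[self.hap_pairs[i, 1]]
        pair = sorted([(h1.drb1, h1.dqb1), (h2.drb1, h2.dqb1)])
        return (pair[0], pair[1])


def _carrier_indicator(hap_idx: np.ndarray, n_haps: int) -> np.ndarray:
    """(n, n_haps) boolean: subject carries >=1 copy of each pool haplotype."""
    n = hap_idx.shape[0]
    out = np.zeros((n, n_haps), dtype=bool)
    rows = np.arange(n)
    out[rows, hap_idx[:, 0]] = True
    out[rows, hap_idx[:, 1]] = True
    return out


def _allele_carrier(
    hap_idx: np.ndarray, haps: Sequence[HapSpec], allele: AlleleCall
) -> np.ndarray:
    names = np.array(
        [h.drb1 if allele.locus == "DRB1" else h.dqb1 for h in haps]
    )
    hit = names == allele.name
    return hit[hap_idx[:, 0]] | hit[hap_idx[:, 1]]


def simulate_cohort(config: SimConfig) -> tuple[Cohort, TruthRecord]:
    """Draw a case-control cohort (and its ground truth) from a SimConfig."""
    rng = np.random.default_rng(config.seed)
    haps = config.haplotypes
    n_haps = len(haps)
    cum = np.cumsum([h.freq for h in haps])
    log_or = np.array([math.log(h.or_) for h in haps])
    base_logit = math.log(
        config.baseline_prevalence / (1 - config.baseline_prevalence)
    )

    need_cases, need_controls = config.n_cases, config.n_controls
    case_pairs: list[np.ndarray] = []
    control_pairs: list[np.ndarray] = []
    batch = max(4 * (need_cases + need_controls), 1000)
    attempts = 0
    while need_cases > 0 or need_controls > 0:
        attempts += 1
        if attempts > config.max_attempts:
            raise RuntimeError(
                "could not fill case/control quotas within attempt cap; "
                "baseline_prevalence may be too extreme"
            )
        draws = np.searchsorted(cum, rng.random((batch, 2)), side="right")
        draws = np.minimum(draws, n_haps - 1)
        carrier = _carrier_indicator(draws, n_haps)
        logit = base_logit + carrier @ log_or
        if config.epistasis is not None:
            epi = config.epistasis
            both = _allele_carrier(draws, haps, epi.target) & _allele_carrier(
                draws, haps, epi.background
            )
            logit = logit + both * math.log(epi.or_modifier)
        disease = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        if need_cases > 0:
            take = draws[disease][:need_cases]
            case_pairs.append(take)
            need_cases -= len(take)
        if need_controls > 0:
            take = draws[~disease][:need_controls]
            control_pairs.append(take)
            need_controls -= len(take)

    hap_idx = np.concatenate(case_pairs + control_pairs)
    n_case, n_control = config.n_cases, config.n_controls
    n_total = n_case + n_control

    subjects = []
    width = len(str(n_total))
    for i in range(n_total):
        h1, h2 = haps[hap_idx[i, 0]], haps[hap_idx[i, 1]]
        subjects.append(
            Subject(
                id=f"S{i + 1:0{width}d}",
                phenotype="case" if i < n_case else "control",
                sex="U",
                hla={
                    "DRB1": (
                        AlleleCall("DRB1", h1.drb1),
                        AlleleCall("DRB1", h2.drb1),
                    ),
                    "DQB1": (
                        AlleleCall("DQB1", h1.dqb1),
                        AlleleCall("DQB1", h2.dqb1),
                    ),
                },
            )
        )

    snps: list[SnpRecord] = []
    matrix = None
    if config.snps > 0:
        chrom, lo, hi = config.region
        positions = np.linspace(lo, hi, config.snps).astype(np.int64)
        positions = np.unique(positions)
        snps = [
            SnpRecord(f"rs{900000 + j}", chrom, int(p), "A", "G")
            for j, p in enumerate(positions)
        ]
        tag = np.full(len(snps), -1, dtype=np.int64)
        disc = np.zeros(len(snps))
        for t in config.snp_tag_map:
            if t.snp_index < len(snps):
                tag[t.snp_index] = t.hap_index
                disc[t.snp_index] = t.discordance
        alt0 = hap_idx[:, [0]] == tag[None, :]
        alt1 = hap_idx[:, [1]] == tag[None, :]
        flip0 = rng.random(alt0.shape, dtype=np.float32) < disc[None, :]
        flip1 = rng.random(alt1.shape, dtype=np.float32) < disc[None, :]
        matrix = ((alt0 ^ flip0).astype(np.int8) + (alt1 ^ flip1)).astype(
            np.int8
        )

    cohort = Cohort(subjects=subjects, snps=snps, snp_matrix=matrix)
    truth = TruthRecord(
        hap_pairs=hap_idx,
        haplotypes=haps,
        snp_tags=config.snp_tag_map,
    )
    return cohort, truth


def reference_table(config: SimConfig) -> HaplotypeFreqTable:
    """The haplotype frequency table implied by a config's pool."""
    merged: dict[tuple[str, str], float] = {}
    for h in config.haplotypes:
        merged[(h.drb1, h.dqb1)] = merged.get((h.drb1, h.dqb1), 0.0) + h.freq
    entries = [
        (AlleleCall("DRB1", d), AlleleCall("DQB1", q), f)
        for (d, q), f in sorted(merged.items())
    ]
    return HaplotypeFreqTable(entries=entries)


def simulate_to_files(
    config: SimConfig, outdir: str | Path
) -> tuple[Cohort, TruthRecord]:
    """Simulate, serialise through the genotype writers, and read back.

    Writes ``hla.tsv``, ``snps.tsv`` (if any SNPs), ``ref_haplotypes.tsv``
    and ``truth.json``; returns the cohort as re-read from disk so that the
    files exercise the readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(config)
    gio.write_hla_table(cohort, outdir / "hla.tsv")
    if cohort.snp_matrix is not None:
        gio.write_snp_table(cohort, outdir / "snps.tsv")
    gio.write_haplotype_freqs(reference_table(config), outdir / "ref_haplotypes.tsv")
    truth_doc = {
        "haplotypes": [h._asdict() for h in truth.haplotypes],
        "hap_pairs": truth.hap_pairs.tolist(),
        "snp_tags": [t._asdict() for t in truth.snp_tags],
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc))
    reread = gio.read_hla_table(outdir / "hla.tsv")
    if cohort.snp_matrix is not None:
        reread = gio.read_snp_table(outdir / "snps.tsv", reread)
    return reread, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Pool emulating the Japanese DR-DQ landscape relevant here: near-complete
# DRB1*13:02-DQB1*06:04 and DRB1*08:03-DQB1*06:01 linkage with recombinant
# haplotypes at the few-per-thousand scale, protection attached to DQB1*06:04
# (OR 0.19) and DQB1*03:01 (OR 0.50), risk to DRB1*08:03 (OR 1.75) and
# DQB1*04:01 (OR 1.50).  Frequencies are tuned so control carrier rates land
# near the motivating study's values (e.g. 14.3% for DQB1*06:04 carriers).
_STUDY_POOL: tuple[HapSpec, ...] = (
    HapSpec("13:02", "06:04", 0.0720, 0.19),
    HapSpec("08:03", "06:01", 0.0780, 1.75),
    HapSpec("14:03", "03:01", 0.0130, 0.50),
    HapSpec("11:01", "03:01", 0.0500, 0.50),
    HapSpec("12:01", "03:01", 0.0500, 0.50),
    HapSpec("04:05", "04:01", 0.1250, 1.50),
    HapSpec("15:02", "06:01", 0.1080, 1.00),
    # rare recombinants of the major pairs
    HapSpec("13:02", "06:09", 0.0035, 1.00),
    HapSpec("13:01", "06:04", 0.0008, 0.19),
    HapSpec("08:03", "03:03", 0.0017, 1.75),
    HapSpec("08:02", "04:01", 0.0015, 1.50),
    HapSpec("04:05", "03:02", 0.0060, 1.00),
    # neutral filler
    HapSpec("09:01", "03:03", 0.2405, 1.00),
    HapSpec("15:01", "06:02", 0.2500, 1.00),
)

_DISCORDANCE_CYCLE = (0.0, 0.005, 0.01, 0.02, 0.05)


def study_like_preset(
    seed: int = 20170911, snps: int = 4103, with_epistasis: bool = True
) -> SimConfig:
    """The study-scale preset: 1200 cases / 1196 controls, 4103 tagged SNPs.

    Every SNP tags one pool haplotype (cycling through the pool) with a small
    cycling discordance, so SNPs tagging effect haplotypes inherit their
    association and filler-tagged SNPs are null.  The epistasis term nullifies
    DRB1*08:03's risk inside DQB1*06:04 carriers.
    """
    tags = tuple(
        SnpTag(j, j % len(_STUDY_POOL), _DISCORDANCE_CYCLE[j % len(_DISCORDANCE_CYCLE)])
        for j in range(snps)
    )
    epi = None
    if with_epistasis:
        epi = EpistasisSpec(
            target=AlleleCall("DRB1", "08:03"),
            background=AlleleCall("DQB1", "06:04"),
            or_modifier=1.0 / 1.75,
        )
    return SimConfig(
        seed=seed,
        n_cases=1200,
        n_controls=1196,
        haplotypes=_STUDY_POOL,
        epistasis=epi,
        snps=snps,
        snp_tag_map=tags,
        baseline_prevalence=0.02,
    )


def single_effect_config(
    seed: int,
    drb1: str,
    dqb1: str,
    freq: float,
    or_: float,
    n_cases: int = 1200,
    n_controls: int = 1196,
) -> SimConfig:
    """One planted effect haplotype on a neutral filler background.

    The parameter-recovery configuration: with a single effect the marginal
    case-control carrier OR equals the planted conditional OR, which two
    co-planted effects would not give (haplotypes compete for chromosomes,
    so each effect confounds the other).
    """
    return SimConfig(
        seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
        haplotypes=(
            HapSpec(drb1, dqb1, freq, or_),
            HapSpec("15:01", "06:02", 1.0 - freq, 1.00),
        ),
        baseline_prevalence=0.02,
    )


def scaled_preset(
    seed: int,
    n_cases: int,
    n_controls: int,
    with_epistasis: bool = True,
    baseline_prevalence: float = 0.1,
) -> SimConfig:
    """The study pool (no SNPs) at an arbitrary cohort size.

    Used for experiments that need within-stratum power the study scale
    cannot provide (see the interaction-classifier validation).
    """
    epi = None
    if with_epistasis:
        epi = EpistasisSpec(
            target=AlleleCall("DRB1", "08:03"),
            background=AlleleCall("DQB1", "06:04"),
            or_modifier=1.0 / 1.75,
        )
    return SimConfig(
        seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
        haplotypes=_STUDY_POOL,
        epistasis=epi,
        baseline_prevalence=baseline_prevalence,
    )
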