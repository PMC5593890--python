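"""End-to-end run orchestration and report assembly.

A :class:`RunConfig` (usually loaded from YAML) names the input tables and
the analysis plan; :func:`run_pipeline` executes the stages in order —
clinical contrasts, allele carrier association, haplotype decomposition,
stratified interaction, SNP scans — writing one TSV per report plus a JSON
summary and a log of every denominator and threshold used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc_core import (
    GENOME_WIDE_P,
    AssocResult,
    assoc_from_table,
    carrier_association,
    two_group_table,
)
from .genotype_io import (
    LOCI,
    Cohort,
    parse_allele,
    read_haplotype_freqs,
    read_hla_table,
    read_snp_table,
)
from .haplotype_phase import (
    assign_phases,
    haplotype_class_assoc,
    primary_allele_report,
)
from .snp_scan import manhattan_export, region_scan, stepwise_exclusion_scan
from .stratified_interaction import interaction_classifier, stratified_effect

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (see ``from_yaml`` for the file schema)."""

    hla_table: Path
    out_dir: Path
    snp_table: Path | None = None
    haplotype_freqs: Path | None = None
    loci: tuple[str, ...] = LOCI
    min_carrier_freq: float = 0.01
    alpha: float = 0.05
    gw_threshold: float = GENOME_WIDE_P
    epsilon: float = 1e-6
    haplotype_pairs: tuple[tuple[str, str], ...] = ()
    interaction_pairs: tuple[tuple[str, str], ...] = ()
    exclusion_sets: tuple[tuple[str, ...], ...] = ()
    clinical_fields: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.hla_table, self.snp_table, self.haplotype_freqs):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        for thr in (self.min_carrier_freq, self.alpha):
            if not (0 < thr < 1):
                raise ConfigError(f"threshold {thr} outside (0, 1)")
        if not (0 < self.gw_threshold < 1):
            raise ConfigError("gw_threshold outside (0, 1)")
        bad = [l for l in self.loci if l not in LOCI]
        if bad:
            raise ConfigError(f"unsupported loci {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"run config {path} is not a mapping")
        kwargs: dict = {}
        simple = {
            "min_carrier_freq",
            "alpha",
            "gw_threshold",
            "epsilon",
            "seed",
        }
        for key, value in doc.items():
            if key in ("hla_table", "snp_table", "haplotype_freqs", "out_dir"):
                kwargs[key] = Path(value)
            elif key == "loci":
                kwargs[key] = tuple(value)
            elif key in ("haplotype_pairs", "interaction_pairs"):
                kwargs[key] = tuple((str(a), str(b)) for a, b in value)
            elif key == "exclusion_sets":
                kwargs[key] = tuple(tuple(str(a) for a in s) for s in value)
            elif key == "clinical_fields":
                kwargs[key] = tuple(value)
            elif key in simple:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config key {key!r}")
        missing = {"hla_table", "out_dir"} - kwargs.keys()
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**kwargs)

    def digest(self) -> str:
        # out_dir does not affect results, so it stays out of the digest
        doc = {k: str(v) for k, v in vars(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


def _fmt(x: float, nd: int = 4) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "NA"
    return f"{x:.{nd}g}"


def _assoc_row(r: AssocResult) -> dict:
    return {
        "factor": r.factor,
        "n_cases": r.n1,
        "n_controls": r.n2,
        "carriers_cases": r.carriers1,
        "carriers_controls": r.carriers2,
        "freq_cases_pct": f"{100 * r.freq1:.1f}" if r.n1 else "NA",
        "freq_controls_pct": f"{100 * r.freq2:.1f}" if r.n2 else "NA",
        "odds_ratio": _fmt(r.or_, 3),
        "ci_low": _fmt(r.ci_low, 3),
        "ci_high": _fmt(r.ci_high, 3),
        "chi2": _fmt(r.chi2, 4),
        "p": _fmt(r.p, 3),
        "flags": ",".join(sorted(r.flags)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; return the summary dict.

    Outputs land in ``config.out_dir``: ``clinical_contrasts.tsv``,
    ``allele_association.tsv``, ``haplotype_classes.tsv``,
    ``interactions.tsv``, ``snp_scan.tsv``, ``manhattan.tsv``,
    ``summary.json`` and ``run.log``.  Stage failures abort with a
    stage-tagged :class:`DataError`; the summary marks completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"hlafinemap {__version__}",
        f"config sha256:{config.digest()}",
        f"thresholds: min_carrier_freq={config.min_carrier_freq} "
        f"alpha={config.alpha} gw={config.gw_threshold} eps={config.epsilon}",
    ]
    summary: dict = {
        "version": __version__,
        "config_digest": config.digest(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
                summary["stages"][name] = "complete"
            except (ConfigError, DataError):
                summary["stages"][name] = "failed"
                raise
            except Exception as exc:  # noqa: BLE001 - stage-tag and re-raise
                summary["stages"][name] = "failed"
                raise DataError(f"stage {name}: {exc}") from exc

        return deco

    cohort_box: dict[str, Cohort] = {}

    @stage("load")
    def _load():
        cohort = read_hla_table(config.hla_table)
        if config.snp_table is not None:
            cohort = read_snp_table(config.snp_table, cohort)
        cohort_box["cohort"] = cohort
        log_lines.append(
            f"cohort: {cohort.n_cases} cases / {cohort.n_controls} controls"
        )
        for locus in config.loci:
            typed = cohort.typed_mask(locus)
            cm = cohort.case_mask()
            log_lines.append(
                f"  {locus}: typed {int((typed & cm).sum())} cases / "
                f"{int((typed & ~cm).sum())} controls"
            )

    cohort = cohort_box["cohort"]

    @stage("clinical")
    def _clinical():
        rows = []
        for fld in config.clinical_fields:
            def outcome(s, fld=fld):
                v = s.clinical.get(fld)
                return None if v is None else v == "1"

            try:
                t = two_group_table(
                    cohort,
                    split=lambda s: {"F": True, "M": False}.get(s.sex),
                    outcome=outcome,
                    subset=lambda s: s.is_case,
                )
            except ValueError:
                continue
            r = assoc_from_table(fld, t)
            row = _assoc_row(r)
            row["factor"] = f"{fld} (female vs male, cases)"
            rows.append(row)
        if rows:
            pd.DataFrame(rows).to_csv(
                out / "clinical_contrasts.tsv", sep="\t", index=False
            )
        else:
            log_lines.append("clinical: no fields configured; skipped")

    allele_results: list[AssocResult] = []

    @stage("allele_association")
    def _alleles():
        allele_results.extend(
            carrier_association(
                cohort,
                loci=config.loci,
                min_carrier_freq=config.min_carrier_freq,
                alpha=config.alpha,
                gw_threshold=config.gw_threshold,
            )
        )
        m = len(allele_results)
        log_lines.append(
            f"allele association: {m} common alleles tested, "
            f"bonferroni p<{config.alpha / m if m else 'NA'}"
        )
        pd.DataFrame([_assoc_row(r) for r in allele_results]).to_csv(
            out / "allele_association.tsv", sep="\t", index=False
        )

    @stage("haplotypes")
    def _haplotypes():
        if config.haplotype_freqs is None or not config.haplotype_pairs:
            log_lines.append("haplotypes: not configured; skipped")
            return
        ref = read_haplotype_freqs(config.haplotype_freqs)
        phases = assign_phases(cohort, ref, config.epsilon)
        log_lines.append(f"haplotypes: {len(phases)} subjects phased")
        by_factor = {r.factor: r for r in allele_results}
        rows = []
        verdicts = {}
        for a_txt, b_txt in config.haplotype_pairs:
            a = parse_allele(a_txt, "DRB1")
            b = parse_allele(b_txt, "DQB1")
            classes = haplotype_class_assoc(cohort, phases, a, b)
            for c in classes:
                if c.assoc is not None:
                    row = _assoc_row(c.assoc)
                else:
                    row = {"factor": c.class_label}
                row["factor"] = f"{a}-{b}:{c.class_label}"
                rows.append(row)
            ra, rb = by_factor.get(str(a)), by_factor.get(str(b))
            if ra is not None and rb is not None:
                v = primary_allele_report(classes, ra, rb, config.alpha)
                verdicts[f"{a}/{b}"] = v.verdict
        pd.DataFrame(rows).to_csv(
            out / "haplotype_classes.tsv", sep="\t", index=False
        )
        summary["primary_allele_verdicts"] = verdicts

    @stage("interactions")
    def _interactions():
        if not config.interaction_pairs:
            log_lines.append("interactions: not configured; skipped")
            return
        rows = []
        verdicts = {}
        for t_txt, b_txt in config.interaction_pairs:
            t_allele = parse_allele(t_txt)
            b_allele = parse_allele(b_txt)
            e1 = stratified_effect(cohort, t_allele, b_allele)
            e2 = stratified_effect(cohort, b_allele, t_allele)
            verdicts[f"{t_allele}|{b_allele}"] = interaction_classifier(
                e1, e2, config.alpha
            ).verdict
            for e in (e1, e2):
                for stratum, r in (
                    ("present", e.in_presence),
                    ("absent", e.in_absence),
                ):
                    row = _assoc_row(r)
                    row["factor"] = (
                        f"{e.target} | {e.background} {stratum}"
                    )
                    row["heterogeneity_p"] = _fmt(e.heterogeneity_p, 3)
                    rows.append(row)
        pd.DataFrame(rows).to_csv(
            out / "interactions.tsv", sep="\t", index=False
        )
        summary["interaction_verdicts"] = verdicts

    @stage("snp_scan")
    def _snps():
        if cohort.snp_matrix is None:
            log_lines.append("snp scan: no SNP table; skipped")
            summary["snp_scan"] = "skipped"
            return
        sets = [
            [parse_allele(a) for a in s] for s in config.exclusion_sets
        ]
        summaries = stepwise_exclusion_scan(cohort, sets, config.gw_threshold)
        rows = []
        for s in summaries:
            rows.append(
                {
                    "excluded": ";".join(s.excluded_alleles) or "(none)",
                    "n_cases": s.n_cases,
                    "n_controls": s.n_controls,
                    "gw_snps": f"{s.n_genome_wide}/{s.n_tested}",
                    "top_snp": s.top_snp.snp.rsid if s.top_snp else "NA",
                    "top_p": _fmt(s.top_snp.p, 3) if s.top_snp else "NA",
                    "top_or": _fmt(s.top_snp.or_, 3) if s.top_snp else "NA",
                }
            )
            log_lines.append(
                f"snp scan [{rows[-1]['excluded']}]: "
                f"{s.n_cases}/{s.n_controls} subjects, "
                f"{s.n_genome_wide}/{s.n_tested} genome-wide"
            )
        pd.DataFrame(rows).to_csv(out / "snp_scan.tsv", sep="\t", index=False)
        results, _ = region_scan(cohort, None, config.gw_threshold)
        manhattan_export(
            results,
            out / "manhattan.tsv",
            hla_points=allele_results,
            gw_threshold=config.gw_threshold,
        )
        summary["snp_scan"] = rows

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
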