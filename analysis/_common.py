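"""Shared plumbing for the numbered analysis drivers.

The simulated cohort (large) lives under ``scratch/sim``; only small summary
tables go to ``results/``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SEED = 20170911


def load_or_simulate():
    """Read the simulated study cohort from scratch/, creating it if absent."""
    from hlafinemap.genotype_io import read_hla_table, read_snp_table
    from hlafinemap.synth_cohort import simulate_to_files, study_like_preset

    preset = study_like_preset(seed=SEED)
    if not (SCRATCH / "hla.tsv").exists():
        print(f"[simulating study-like cohort into {SCRATCH}]")
        return preset, simulate_to_files(preset, SCRATCH)[0]
    cohort = read_hla_table(SCRATCH / "hla.tsv")
    cohort = read_snp_table(SCRATCH / "snps.tsv", cohort)
    return preset, cohort


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
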