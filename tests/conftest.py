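import numpy as np
import pytest

from hlafinemap.genotype_io import AlleleCall, Cohort, Subject
from hlafinemap.synth_cohort import simulate_cohort, study_like_preset

#: One seed drives every fixed-seed check in the suite.
SUITE_SEED = 20170911


def make_subject(sid, phenotype, drb1=None, dqb1=None, sex="U", clinical=None):
    hla = {}
    if drb1 is not None:
        hla["DRB1"] = (AlleleCall("DRB1", drb1[0]), AlleleCall("DRB1", drb1[1]))
    if dqb1 is not None:
        hla["DQB1"] = (AlleleCall("DQB1", dqb1[0]), AlleleCall("DQB1", dqb1[1]))
    return Subject(
        id=sid, phenotype=phenotype, sex=sex, hla=hla, clinical=clinical or {}
    )


@pytest.fixture(scope="session")
def preset():
    return study_like_preset(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def preset_cohort(preset):
    """The study-scale synthetic cohort with SNPs and ground truth."""
    return simulate_cohort(preset)


@pytest.fixture
def tiny_cohort():
    """Six subjects, strong DR-DQ linkage, one untyped locus."""
    subs = [
        make_subject("P1", "case", ("13:02", "08:03"), ("06:04", "06:01")),
        make_subject("P2", "case", ("08:03", "08:03"), ("06:01", "06:01")),
        make_subject("P3", "case", ("08:03", "04:05"), ("06:01", "04:01")),
        make_subject("C1", "control", ("13:02", "14:03"), ("06:04", "03:01")),
        make_subject("C2", "control", ("13:02", "13:02"), ("06:04", "06:04")),
        make_subject("C3", "control", None, ("06:01", "03:01")),
    ]
    return Cohort(subjects=subs)
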