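"""Published carrier counts from the motivating PBC case-control study.

The study compared 1200 Japanese patients with primary biliary cholangitis
against 1196 controls at seven HLA loci.  Its printed per-allele carrier
counts and per-locus denominators are *inputs* here: re-running the 2x2
engine on them must reproduce the printed odds ratios at printed precision.

Each entry is ``(case_carriers, case_n, control_carriers, control_n,
printed_or)``.  Per-locus denominators differ because typing coverage
differed by locus (e.g. DQA1 controls n = 783).
"""

from __future__ import annotations

from .assoc_core import Contingency2x2

# HLA allele -> (case_carriers, case_n, control_carriers, control_n, printed OR)
HLA_CARRIER_COUNTS: dict[str, tuple[int, int, int, int, float]] = {
    "A*33:03": (88, 1200, 199, 1196, 0.40),
    "A*02:01/07/18": (395, 1200, 293, 1196, 1.51),
    "B*44:03": (66, 1200, 187, 1196, 0.31),
    "B*07:02": (90, 1200, 146, 1196, 0.58),
    "DRB1*13:02": (47, 1200, 175, 1194, 0.24),
    "DRB1*08:03": (283, 1200, 179, 1194, 1.75),
    "DRB1*14:03": (7, 1200, 32, 1194, 0.21),
    "DRB1*04:05": (390, 1200, 292, 1194, 1.49),
    "DQA1*01:02": (173, 1198, 208, 783, 0.47),
    "DQB1*06:04": (37, 1199, 171, 1195, 0.19),
    "DQB1*03:01": (144, 1199, 256, 1195, 0.50),
    "DQB1*06:01": (520, 1199, 403, 1195, 1.51),
    "DQB1*04:01": (378, 1199, 280, 1195, 1.50),
    "DQB1*04:02": (137, 1199, 87, 1195, 1.64),
    "DPA1*01:03": (585, 1200, 495, 783, 0.55),
    "DPB1*04:01": (35, 1200, 131, 1196, 0.24),
    "DPB1*02:01": (378, 1200, 485, 1196, 0.67),
    "DPB1*05:01": (815, 1200, 729, 1196, 1.36),
}

#: Printed p value for the strongest protective allele, DQB1*06:04.
DQB1_0604_PRINTED_P = 1.91e-22

# Female-vs-male contrasts among patients:
# key -> (females_with, females_n, males_with, males_n, printed OR)
CLINICAL_SEX_COUNTS: dict[str, tuple[int, int, int, int, float]] = {
    "sjogren": (169, 922, 8, 121, 3.17),
    "rheumatoid_arthritis": (43, 922, 1, 121, 5.87),
    "AMA": (839, 960, 117, 125, 0.47),
    "ANA": (693, 926, 59, 116, 2.87),
    "CENP_B": (302, 1031, 22, 135, 2.13),
    "SS_A": (166, 1031, 12, 135, 1.97),
}

#: Number of common (>1% carrier) alleles screened, hence the Bonferroni m.
N_COMMON_ALLELES = 87


def table_of(entry: tuple[int, int, int, int, float]) -> Contingency2x2:
    """Build the carrier 2x2 from a published (carriers, n) quadruple."""
    x1, n1, x2, n2, _ = entry
    return Contingency2x2(x1, n1 - x1, x2, n2 - x2)
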