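"""Published worked-example inputs for the SCNN1B locus.

Small data tables from the CF modifier study of the SCNN1B region that the
package's worked examples and acceptance checks consume as inputs: the
Sanger-resequencing haplotype alignment of the contrasting
rs168748-rs2303153-rs4968000 haplotypes, and the rs2303153 allele-frequency
table across the mild/severe patient contrasts and birth cohorts.
"""

from __future__ import annotations

from .association_scan import HaplotypeAlignment

#: marker order of the resequenced rs168748-rs4968000 fragment (5' to 3')
RESEQUENCED_MARKERS = [
    "rs168748", "rs250570", "rs62029389", "rs62029390", "rs62029391",
    "rs61379932", "rs2303153", "rs4968000", "rs3743966",
]

#: alignment boundary used for fine-mapping (closed interval)
MAPPED_FRAGMENT = ("rs168748", "rs4968000")

_ALIGNMENT_ROWS = [
    # (label at rs168748-rs2303153-rs4968000, severity class, alleles 5'->3')
    ("CCA", "severe", "CCGGGGCAT"),
    ("TCA", "severe", "TGGGGGCAT"),
    ("TGC", "mild",   "TGATAAGCA"),
    ("TGA", "mild",   "TCATAAGAA"),
]


def scnn1b_resequencing_alignment() -> list[HaplotypeAlignment]:
    """The four resequenced SCNN1B haplotypes (two severe, two mild)."""
    return [
        HaplotypeAlignment(
            haplotype_label=label, severity_class=cls,
            alleles=dict(zip(RESEQUENCED_MARKERS, alleles)))
        for label, cls, alleles in _ALIGNMENT_ROWS
    ]


#: rs2303153 allele frequencies by contrast: mild vs severe group
RS2303153_CONTRAST_FREQS = {
    "interpair": {  # 11 CON+ pairs vs 10 CON- pairs
        "mild": {"G": 0.577, "C": 0.423},
        "severe": {"G": 0.283, "C": 0.717},
    },
    "intrapair": {  # mild vs severe sibs of 14 discordant pairs
        "mild": {"G": 0.579, "C": 0.421},
        "severe": {"G": 0.395, "C": 0.605},
    },
}

#: rs2303153-G frequency in unrelated patients by birth cohort
#: (34 patients born 1959-1977 vs 33 born 1978-1994, FEV1 above median)
RS2303153_BIRTH_COHORT_G_FREQ = {"born_1959_1977": 0.54, "born_1978_1994": 0.39}
RS2303153_BIRTH_COHORT_N = {"born_1959_1977": 34, "born_1978_1994": 33}
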