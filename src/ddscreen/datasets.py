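"""Published external quality-assessment panels bundled as worked examples.

These small tables carry the measured values and reference classifications
of CDC NSQAP proficiency specimens (SMN1 exon 7 analysis and the TREC
dried-blood-spot proficiency-testing scheme), a set of MLPA-confirmed SMA
patient specimens with their second-tier Sanger outcomes, and the SMN1/SMN2
copy-number distribution observed in a screening population of 1867
newborns. They serve as fixed inputs for concordance checks of the decision
engine and for distribution arithmetic; they are data, not code paths.
"""

from __future__ import annotations

from .screening import AssayA, AssayB, SangerOutcome

#: NSQAP SMN1 exon 7 proficiency specimens: first-tier copy-number results
#: (one-decimal, as reported) with the program's reference classification.
NSQAP_SMN_PANEL = [
    {"specimen": 1, "reference_class": "Normal", "smn1_cn": 2.0, "smn2_cn": 1.0},
    {"specimen": 2, "reference_class": "SMA", "smn1_cn": 0.0, "smn2_cn": 1.9},
    {"specimen": 3, "reference_class": "Carrier", "smn1_cn": 0.9, "smn2_cn": 1.9},
    {"specimen": 4, "reference_class": "SMA", "smn1_cn": 0.0, "smn2_cn": 1.9},
    {"specimen": 5, "reference_class": "Carrier", "smn1_cn": 0.9, "smn2_cn": 1.9},
]

#: MLPA-confirmed SMA patient specimens: MLPA reference copy numbers,
#: first-tier ddPCR copy numbers, and second-tier Sanger outcomes
#: (assay A SMN1-specific, assay B amplifies SMN1 and SMN2).
SMA_PATIENT_PANEL = [
    {"specimen": 1, "mlpa_smn1": 0, "mlpa_smn2": 2, "smn1_cn": 0.0, "smn2_cn": 2.0},
    {"specimen": 2, "mlpa_smn1": 0, "mlpa_smn2": 2, "smn1_cn": 0.0, "smn2_cn": 2.0},
    {"specimen": 3, "mlpa_smn1": 0, "mlpa_smn2": 3, "smn1_cn": 0.0, "smn2_cn": 3.0},
    {"specimen": 4, "mlpa_smn1": 0, "mlpa_smn2": 3, "smn1_cn": 0.0, "smn2_cn": 3.1},
    {"specimen": 5, "mlpa_smn1": 0, "mlpa_smn2": 4, "smn1_cn": 0.0, "smn2_cn": 4.0},
    {"specimen": 6, "mlpa_smn1": 0, "mlpa_smn2": 4, "smn1_cn": 0.0, "smn2_cn": 4.0},
]

#: Sanger outcome shared by all confirmed patient specimens: assay A shows
#: no peak, assay B homozygous c.840T (SMN1 exon 7 absent).
SMA_PATIENT_SANGER = SangerOutcome(assay_a=AssayA.NO_AMPLICON, assay_b=AssayB.HOM_C840T)

#: NSQAP TRECPT proficiency specimens: measured TREC and RPP30 in
#: copies/µL blood with the program's reference classification.
TRECPT_PANEL = [
    {"specimen": 1, "trec_blood": 326, "rpp30_blood": 10_932, "reference_class": "Negative"},
    {"specimen": 2, "trec_blood": 130, "rpp30_blood": 14_472, "reference_class": "Negative"},
    {"specimen": 3, "trec_blood": 141, "rpp30_blood": 15_927, "reference_class": "Negative"},
    {"specimen": 4, "trec_blood": 168, "rpp30_blood": 9_998, "reference_class": "Negative"},
    {"specimen": 5, "trec_blood": 0, "rpp30_blood": 144_892, "reference_class": "Positive"},
    {"specimen": 6, "trec_blood": 0, "rpp30_blood": 122_741, "reference_class": "Positive"},
    {"specimen": 7, "trec_blood": 0, "rpp30_blood": 120_351, "reference_class": "Positive"},
    {"specimen": 8, "trec_blood": 0, "rpp30_blood": 73_699, "reference_class": "Positive"},
    {"specimen": 9, "trec_blood": 0, "rpp30_blood": 0, "reference_class": "Unqualified"},
    {"specimen": 10, "trec_blood": 0, "rpp30_blood": 4, "reference_class": "Unqualified"},
]

#: SMN1/SMN2 integer copy-number counts in 1867 screened newborns.
SMN_CN_DISTRIBUTION = {
    "SMN1": {1: 43, 2: 1707, 3: 111, 4: 4, 5: 2},
    "SMN2": {0: 90, 1: 669, 2: 1040, 3: 57, 4: 5, 5: 5, 6: 1},
}
SMN_CN_DISTRIBUTION_N = 1867
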