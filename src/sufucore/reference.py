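"""Documented expected outputs of the source study.

These are *reference notes*, not computable results: apart from the
flavor-table screen (which this package reproduces exactly from the
bundled table), every number below depends on raw sequencing data
(NCBI SRR19152823-SRR19152843) that this package does not consume.
They are recorded so users can compare their own runs on the real data
against what the study reports.
"""

from __future__ import annotations

#: Per-class counts of characteristic compounds in the bundled flavor
#: table (reproduced exactly by the OAV screen).
TABLE1_CLASS_COUNTS = {
    "ester": 14,
    "alcohol": 8,
    "aldehyde": 11,
    "ketone": 3,
    "phenol": 2,
    "acid": 1,
    "furan": 1,
    "pyrazine": 1,
}

TABLE1_N_CHARACTERISTIC = 41

#: Study-reported outputs that require the external sequencing data.
STUDY_EXPECTED = {
    "n_dominant_early": 11,
    "n_dominant_late": 19,
    "core_early": [
        "Pseudomonas",
        "Tetragenococcus",
        "Lysinibacillus",
        "Pantoea",
        "Burkholderia-Caballeronia-Paraburkholderia",
    ],
    "core_late": ["Exiguobacterium", "Bacillus", "Pseudomonas"],
    "flavor_correlated_early": [
        "Pseudomonas",
        "Tetragenococcus",
        "Lysinibacillus",
        "Bacillus",
        "Pantoea",
        "Staphylococcus",
        "Burkholderia-Caballeronia-Paraburkholderia",
    ],
    "flavor_correlated_late": [
        "Exiguobacterium",
        "Pseudomonas",
        "Lactococcus",
        "Bacillus",
    ],
    "pca_explained_pc1_pc2": (53.8, 19.7),  # percent, flavor PCA d0-d30
    "rda_constrained_percent_early": 73.39,
    "cca_constrained_percent_late": 46.3,
    "optimized_reads_total": 802_520,
    "n_samples_sequenced": 21,
}
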