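"""Published cohort marginals used to reconstruct the 119-patient fixture.

The study cohort (82 nevogenic + 37 CSD cutaneous melanomas) is not
deposited; what is printed are per-gene mutation counts by etiopathogenic
group, the pairwise driver-gene overlaps, and the molecular-subtype
partition. Those marginals are enough to rebuild a status matrix that is
exact on every printed count, which is what :func:`melanoma_cohort_fixture`
does (see :mod:`melpath.cohort`).
"""

from __future__ import annotations

N_NEVOGENIC = 82
N_CSD = 37
N_TOTAL = N_NEVOGENIC + N_CSD

#: Targeted panel: 21 genes plus the TERT promoter locus.
PANEL_GENES = (
    "BRAF", "NRAS", "HRAS", "KRAS", "NF1",
    "TP53", "ROS1", "ARID2", "CDKN2A", "RAC1", "IDH1", "KIT",
    "RB1", "PIK3R1", "GNA11", "CDK4", "PPP6C", "PTEN",
    "MAP2K2", "GNAQ", "PIK3CA",
    "TERTp",
)

RAS_GENES = ("NRAS", "HRAS", "KRAS")
DRIVER_CLASSES = ("BRAF", "RAS", "NF1")

#: Per-gene mutated counts (nevogenic, CSD) from the published prevalence table.
GROUP_MUTATION_COUNTS: dict[str, tuple[int, int]] = {
    "TP53": (6, 7),
    "NF1": (6, 14),
    "BRAF": (46, 14),
    "ROS1": (4, 10),
    "NRAS": (12, 4),
    "CDK4": (3, 1),
    "ARID2": (5, 6),
    "CDKN2A": (6, 3),
    "KIT": (2, 3),
    "RB1": (3, 2),
    "PPP6C": (3, 1),
    "PTEN": (2, 1),
    "IDH1": (4, 2),
    "GNA11": (1, 4),
    "GNAQ": (0, 1),
    "RAC1": (1, 6),
    "KRAS": (1, 0),
    "HRAS": (1, 1),
    "MAP2K2": (0, 2),
    "PIK3CA": (0, 1),
    "PIK3R1": (2, 3),
    "TERTp": (38, 21),
}

#: Tumors with no informative TERT-promoter status (nevogenic, CSD):
#: 113 of 119 are informative.
MISSING_STATUS_COUNTS: dict[str, tuple[int, int]] = {"TERTp": (3, 3)}

#: Pairwise driver-class overlaps (cohort totals): patients mutated in both.
DRIVER_OVERLAPS: dict[tuple[str, str], int] = {
    ("BRAF", "RAS"): 3,
    ("BRAF", "NF1"): 9,
    ("RAS", "NF1"): 1,
}

#: Published molecular-subtype partition of the 119 tumors.
SUBTYPE_PARTITION = {"BRAF+": 48, "RAS+": 15, "NF1+": 10, "3wt": 33}
N_OVERLAP_EXCLUDED = 13

#: Per-group per-gene mutation probabilities implied by the prevalence table,
#: used as synthetic-cohort defaults.
GENE_MUT_PROBS: dict[str, tuple[float, float]] = {
    g: (nev / N_NEVOGENIC, csd / N_CSD)
    for g, (nev, csd) in GROUP_MUTATION_COUNTS.items()
}

#: The ten canonical acquired capabilities of tumors, used as the hallmark
#: annotation vocabulary.
CANONICAL_HALLMARKS = (
    "sustaining proliferative signaling",
    "evading growth suppressors",
    "resisting cell death",
    "enabling replicative immortality",
    "inducing angiogenesis",
    "activating invasion and metastasis",
    "genome instability and mutation",
    "tumor-promoting inflammation",
    "deregulating cellular energetics",
    "avoiding immune destruction",
)
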