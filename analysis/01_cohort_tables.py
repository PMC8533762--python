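#!/usr/bin/env python
"""Rebuild the 119-patient cohort from its printed marginals and reproduce
the prevalence and molecular-subtype tables.

Finds: 48 BRAF+, 15 RAS+, 10 NF1+, 33 3wt, 13 tumors excluded for
overlapping driver mutations; NF1/ROS1/GNA11/RAC1 mutations concentrate in
the CSD group. Writes results/cohort_fixture.tsv, results/subtype_partition.tsv
and results/prevalence.tsv.
"""

from pathlib import Path

import pandas as pd

from melpath.association import prevalence_table, render_prevalence_table
from melpath.cohort import (
    is_overlap_label,
    melanoma_cohort_fixture,
    subtype_counts,
    write_cohort_tsv,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

matrix, records = melanoma_cohort_fixture(seed=0)
write_cohort_tsv(OUT / "cohort_fixture.tsv", matrix, records)

counts = subtype_counts(matrix)
part = pd.Series(counts, name="n").rename_axis("subtype").to_frame()
part["excluded"] = [is_overlap_label(s) for s in part.index]
part.to_csv(OUT / "subtype_partition.tsv", sep="\t")
print("molecular subtype partition:")
print(part.sort_values("n", ascending=False).to_string())
print(f"excluded for overlapping drivers: "
      f"{sum(v for k, v in counts.items() if is_overlap_label(k))}/119")

groups = pd.Series({r.tumor_id: r.group for r in records})
prev = render_prevalence_table(prevalence_table(matrix, groups))
prev.to_csv(OUT / "prevalence.tsv", sep="\t")
print("\nper-group prevalence (selected genes):")
cols = ["pct_mutated", "pct_mutated_nev", "pct_mutated_csd", "p_value"]
print(prev.loc[["BRAF", "NF1", "ROS1", "RAC1", "GNA11", "TERTp"], cols].to_string())
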