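#!/usr/bin/env python
"""Generate the synthetic mechanistic inputs with a planted effect.

Emulates the unavailable upstream resources (normal-skin expression,
curated pathway topologies, hallmark scores) with a scenario where every
CSD tumor carries a loss-of-function NF1 mutation and NF1 sits on the
inhibitory edge of the designed PLANT1 circuit. Writes
results/synthetic_run/{cohort,expr,hallmarks,node_map}.tsv, pathways.sif,
truth.json.
"""

from pathlib import Path

from melpath.cohort import CSD
from melpath.synth import SyntheticScenario, write_run_dir

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_run"

scenario = SyntheticScenario(
    seed=42,
    n_nevogenic=8,
    n_csd=8,
    gene_mut_probs={
        "NF1": (0.0, 1.0), "BRAF": (0.55, 0.0),
        "NRAS": (0.15, 0.1), "HRAS": (0.02, 0.02), "KRAS": (0.01, 0.0),
    },
    n_pathways=4,
    n_normal_samples=20,
    planted_effects=[("NF1", CSD, "inhibitor")],
)
path = write_run_dir(OUT, scenario)
print(f"wrote synthetic inputs to {path}:")
for p in sorted(path.iterdir()):
    print(f"  {p.name}  ({p.stat().st_size} bytes)")
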