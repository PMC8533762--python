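"""Reference in-silico experiments over the synthetic generators.

Two standing experiments characterise the mechanistic pipeline:

* **Null calibration** — two groups with identical (all wild-type)
  mutational profiles, so their activity columns are exchangeable draws from
  the same normal pool; any circuit selected is a false positive. Run at
  about 200 circuits with the standard 50-iteration bootstrap.
* **Planted recovery** — the CSD group carries a loss-of-function mutation
  in a highly expressed gene sitting on the inhibitory edge of a designed
  circuit; knocking it down disinhibits the effector, so the circuit must be
  selected with direction "up" in the CSD-vs-nevogenic comparison.

Both are pure functions of their seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CSD, NEVOGENIC
from .diffact import DiffConfig, bootstrap_diff
from .synth import (
    SyntheticScenario,
    gen_cohort,
    gen_expression,
    gen_pathways,
    scenario_gene_means,
)


def _scenario_inputs(s: SyntheticScenario):
    matrix, records = gen_cohort(s)
    graphs = gen_pathways(s)
    genes = sorted({g for gr in graphs for g in gr.genes} | set(matrix.genes))
    expr = gen_expression(genes, s.n_normal_samples, seed=s.seed,
                          gene_means=scenario_gene_means(s))
    groups = pd.Series({r.tumor_id: r.group for r in records})
    return matrix, groups, expr, graphs


def null_pipeline(
    seed: int,
    n_per_group: int = 15,
    n_pathways: int = 90,
    n_bootstrap: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full bootstrap pipeline on exchangeable groups (no mutations).

    Defaults give roughly 200 circuits; the returned table's ``selected``
    column counts false positives at the stated alpha.
    """
    s = SyntheticScenario(
        seed=seed, n_nevogenic=n_per_group, n_csd=n_per_group,
        gene_mut_probs={"NF1": (0.0, 0.0)}, n_pathways=n_pathways,
    )
    matrix, groups, expr, graphs = _scenario_inputs(s)
    return bootstrap_diff(
        matrix, groups, expr, graphs, NEVOGENIC, CSD,
        cfg=DiffConfig(n_bootstrap=n_bootstrap, alpha=alpha),
        seed=seed + 1,
    )


def planted_scenario(seed: int, n_per_group: int = 8) -> SyntheticScenario:
    """CSD tumors all carry a loss-of-function NF1 mutation; NF1 sits on the
    inhibitory edge of the designed PLANT1 circuit."""
    return SyntheticScenario(
        seed=seed, n_nevogenic=n_per_group, n_csd=n_per_group,
        gene_mut_probs={"NF1": (0.0, 1.0), "BRAF": (0.0, 0.0)},
        n_pathways=2, planted_effects=[("NF1", CSD, "inhibitor")],
    )


def planted_recovery(
    seed: int, n_replicates: int = 20, n_bootstrap: int = 50
) -> pd.DataFrame:
    """Repeat the planted-inhibitor scenario; per replicate record whether
    the planted circuit was selected with direction up."""
    rows = []
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2**31)
    for r in range(n_replicates):
        s = planted_scenario(int(rep_seeds[2 * r]))
        matrix, groups, expr, graphs = _scenario_inputs(s)
        res = bootstrap_diff(
            matrix, groups, expr, graphs, NEVOGENIC, CSD,
            cfg=DiffConfig(n_bootstrap=n_bootstrap),
            seed=int(rep_seeds[2 * r + 1]),
        )
        row = res.loc["PLANT1:PLANT1_E"]
        rows.append(
            {
                "replicate": r,
                "logFC": row["logFC"],
                "combined_p": row["combined_p"],
                "concordance": row["concordance"],
                "direction": row["direction"],
                "recovered": bool(row["selected"]) and row["direction"] == "up",
            }
        )
    return pd.DataFrame(rows).set_index("replicate")
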