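"""In-silico knockdowns of mutated genes on normal-tissue expression.

Each tumor's mutational profile is applied to one randomly drawn
normal-tissue expression sample by multiplying every mutated gene's raw
expression by a small factor (0.01 by default), which emulates loss of
function. The perturbed columns from all profiles (plus, optionally, an
equal number of unperturbed "normal" columns) are assembled into one matrix,
rank-rescaled jointly, and propagated into circuit activities.

Knocking down a gene that sits on an inhibitory edge raises its circuit's
effector activity — the mechanism by which loss-of-function mutations
produce upregulated circuits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GeneStatusMatrix
from .pathways import ActivityDataset, PathwayGraph, RescaleConfig, activity_matrix, rank_rescale

NORMAL = "normal"


@dataclass(frozen=True)
class KnockdownConfig:
    """``factor`` multiplies the expression of every knocked-down gene.

    By default every mutated panel gene is knocked down, oncogenic ones
    included (set ``lof_only`` to restrict to genes flagged loss-of-function
    via ``lof_genes``). Genes with no expression proxy (the TERT promoter)
    are skipped via ``ignore_genes``.
    """

    factor: float = 0.01
    lof_only: bool = False
    lof_genes: frozenset[str] = frozenset()
    ignore_genes: frozenset[str] = frozenset({"TERTp"})

    def __post_init__(self) -> None:
        if not 0.0 < self.factor <= 1.0:
            raise ValueError("knockdown factor must be in (0, 1]")


def apply_knockdown(
    profile: pd.Series,
    expression: pd.Series,
    cfg: KnockdownConfig = KnockdownConfig(),
) -> pd.Series:
    """Multiply the expression of each mutated gene in ``profile`` by the
    knockdown factor; raw (pre-rescale) scale expected.

    Raises if a gene to knock down is absent from the expression vector,
    listing the genes.
    """
    mutated = [g for g in profile.index if profile[g] == 1 and g not in cfg.ignore_genes]
    if cfg.lof_only:
        mutated = [g for g in mutated if g in cfg.lof_genes]
    missing = [g for g in mutated if g not in expression.index]
    if missing:
        raise KeyError(f"mutated gene(s) absent from expression matrix: {missing}")
    out = expression.copy()
    out.loc[mutated] *= cfg.factor
    return out


def build_group_dataset(
    matrix: GeneStatusMatrix,
    groups: pd.Series,
    expression: pd.DataFrame,
    graphs: list[PathwayGraph],
    cfg: KnockdownConfig = KnockdownConfig(),
    seed: int | np.random.Generator = 0,
    include_normal: bool = True,
    rescale_cfg: RescaleConfig = RescaleConfig(),
) -> ActivityDataset:
    """One bootstrap realisation of the group-labelled activity dataset.

    For every tumor profile one normal-tissue sample is drawn (with
    replacement) and perturbed by the profile's knockdowns; when
    ``include_normal`` an equal number of unperturbed columns labelled
    ``"normal"`` is drawn as the reference arm. The assembled matrix is
    rank-rescaled jointly before propagation, so perturbed and reference
    columns share one rank scale. Deterministic for a fixed seed.
    """
    if matrix.df.empty:
        raise ValueError("empty cohort")
    if expression.shape[1] < 1:
        raise ValueError("need at least one normal expression sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pool = list(expression.columns)
    cols: dict[str, pd.Series] = {}
    labels: dict[str, str] = {}
    for tumor_id, profile in matrix.df.iterrows():
        src = pool[int(rng.integers(len(pool)))]
        cols[tumor_id] = apply_knockdown(profile.fillna(0), expression[src], cfg)
        labels[tumor_id] = groups.loc[tumor_id]
    if include_normal:
        for i in range(len(matrix.df)):
            src = pool[int(rng.integers(len(pool)))]
            sid = f"{NORMAL}{i + 1:03d}"
            cols[sid] = expression[src].copy()
            labels[sid] = NORMAL

    combined = pd.DataFrame(cols)
    rescaled = rank_rescale(combined, rescale_cfg)
    return activity_matrix(graphs, rescaled, pd.Series(labels))
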