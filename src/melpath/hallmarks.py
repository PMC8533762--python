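"""Cancer-hallmark annotation of circuits, dysregulation ratios, pathway-level
combined significance, and hallmark enrichment.

Circuit-to-hallmark scores (text-mining output consumed as input) are
thresholded — a hallmark annotates a circuit only when its score is strictly
above the cut (a fixed 0.18 by default, which on the original score table is
the 90th percentile; a recomputed-percentile mode is available for synthetic
tables). Per comparison group the summary counts, for each hallmark, the
selected (significantly dysregulated) circuits annotated to it and the
ratio over all circuits annotated to it — the radar-plot table. Pathway-level
significance pools a pathway's circuit p-values with Fisher's method, and
hallmark enrichment fits a logistic regression of hallmark membership on
the circuits' ranking statistic (the moderated t), reporting the Wald p of
the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import SEPARATION_BETA, LogisticResult, _fit_logit
from .diffact import fisher_combine
from .reference import CANONICAL_HALLMARKS

__all__ = [
    "HallmarkConfig",
    "load_hallmark_scores",
    "threshold_annotations",
    "hallmark_counts",
    "pathway_combine",
    "hallmark_enrichment",
    "CANONICAL_HALLMARKS",
]


@dataclass(frozen=True)
class HallmarkConfig:
    score_threshold: float = 0.18
    threshold_is_percentile: bool = False
    percentile: float = 90.0

    def __post_init__(self) -> None:
        if self.score_threshold < 0:
            raise ValueError("score threshold must be >= 0")


def load_hallmark_scores(path_or_df) -> pd.DataFrame:
    """Validated score table with columns (circuit_id, hallmark, score)."""
    t = (
        path_or_df.copy()
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t")
    )
    required = {"circuit_id", "hallmark", "score"}
    if not required <= set(t.columns):
        raise ValueError(f"hallmark table must have columns {sorted(required)}")
    if not np.isfinite(t["score"].to_numpy(dtype=float)).all() or (t["score"] < 0).any():
        raise ValueError("hallmark scores must be finite and non-negative")
    if t.duplicated(["circuit_id", "hallmark"]).any():
        dup = t[t.duplicated(["circuit_id", "hallmark"])]
        raise ValueError(f"duplicate (circuit, hallmark) rows: {dup.iloc[0].tolist()}")
    return t


def threshold_annotations(
    table: pd.DataFrame, cfg: HallmarkConfig = HallmarkConfig()
) -> dict[str, set[str]]:
    """circuit -> set of hallmarks with score strictly above the threshold."""
    table = load_hallmark_scores(table)
    if table.empty:
        return {}
    cut = (
        float(np.percentile(table["score"], cfg.percentile))
        if cfg.threshold_is_percentile
        else cfg.score_threshold
    )
    kept = table[table["score"] > cut]
    out: dict[str, set[str]] = {}
    for cid, sub in kept.groupby("circuit_id"):
        out[cid] = set(sub["hallmark"])
    return out


def hallmark_counts(
    selected_by_group: dict[str, set[str]],
    annotations: dict[str, set[str]],
) -> pd.DataFrame:
    """Radar table: per group and hallmark, selected-circuit count and ratio.

    The denominator is the number of circuits annotated to the hallmark
    (shared across groups); a second column gives the alternative
    normalisation over each group's total selected circuits.
    """
    hallmark_members: dict[str, set[str]] = {}
    for cid, hms in annotations.items():
        for h in hms:
            hallmark_members.setdefault(h, set()).add(cid)
    rows = []
    for group, selected in selected_by_group.items():
        n_sel_total = len(selected)
        for h in sorted(hallmark_members):
            members = hallmark_members[h]
            n_sig = len(members & selected)
            rows.append(
                {
                    "hallmark": h,
                    "group": group,
                    "n_significant": n_sig,
                    "n_annotated": len(members),
                    "ratio": n_sig / len(members),
                    "ratio_of_selected": n_sig / n_sel_total if n_sel_total else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["hallmark", "group", "n_significant", "n_annotated",
                       "ratio", "ratio_of_selected"]
    )


def pathway_combine(circuit_pvalues) -> float:
    """Pathway-level dysregulation: Fisher combination of its circuits' p."""
    return fisher_combine(circuit_pvalues)


def hallmark_enrichment(statistic: pd.Series, membership: pd.Series) -> LogisticResult:
    """Logistic regression of hallmark membership on the ranking statistic.

    ``statistic`` is a per-circuit ranking value (e.g. moderated t);
    ``membership`` is boolean per circuit. Requires both members and
    non-members; complete separation is flagged rather than fitted.
    """
    membership = membership.reindex(statistic.index).astype(bool)
    n_mem = int(membership.sum())
    if n_mem == 0 or n_mem == len(membership):
        raise ValueError("enrichment needs both member and non-member circuits")
    res = _fit_logit(
        membership.to_numpy(dtype=float),
        statistic.to_numpy(dtype=float).reshape(-1, 1),
    )
    if res is None or abs(res.params[1]) > SEPARATION_BETA:
        return LogisticResult(np.nan, np.nan, np.nan, separation=True)
    beta = float(res.params[1])
    return LogisticResult(beta, float(np.exp(beta)), float(res.pvalues[1]))
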