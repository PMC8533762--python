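"""End-to-end orchestration: cohort report and mechanistic stages.

``run_cohort_report`` writes the prevalence/association table and the
molecular-subtype partition for a cohort. ``run_mechanistic`` executes the
knockdown -> activity -> bootstrap differential-activation pipeline for the
three comparisons (CSD vs nevogenic, CSD vs normal, nevogenic vs normal),
then the hallmark summary, writing TSVs plus a plain-text run log with the
seed and per-stage timings. A full run is reproducible bit-for-bit from
(inputs, config, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .association import adjusted_logistic, prevalence_table, render_prevalence_table
from .cohort import (
    CSD,
    NEVOGENIC,
    ClassificationRules,
    GeneStatusMatrix,
    PatientRecord,
    classify_group,
    classify_subtype,
    is_overlap_label,
    read_cohort_tsv,
)
from .diffact import DiffConfig, bootstrap_diff
from .hallmarks import HallmarkConfig, hallmark_counts, load_hallmark_scores, pathway_combine, threshold_annotations
from .knockdown import NORMAL, KnockdownConfig
from .pathways import parse_pathways

COMPARISONS = ((NEVOGENIC, CSD), (NORMAL, CSD), (NORMAL, NEVOGENIC))


@dataclass
class RunConfig:
    cohort_tsv: str
    out_dir: str
    expression_tsv: str | None = None
    sif: str | None = None
    node_map_tsv: str | None = None
    hallmarks_tsv: str | None = None
    seed: int = 0
    diff: DiffConfig = field(default_factory=DiffConfig)
    knockdown: KnockdownConfig = field(default_factory=KnockdownConfig)
    hallmark: HallmarkConfig = field(default_factory=HallmarkConfig)
    rules: ClassificationRules = field(default_factory=ClassificationRules)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kd = raw.pop("knockdown", {})
        diff = raw.pop("diff", {})
        hm = raw.pop("hallmark", {})
        return cls(
            **raw,
            diff=DiffConfig(**diff),
            knockdown=KnockdownConfig(**kd),
            hallmark=HallmarkConfig(**hm),
        )

    def check_inputs(self) -> None:
        for p in (self.cohort_tsv, self.expression_tsv, self.sif,
                  self.node_map_tsv, self.hallmarks_tsv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _groups(records: list[PatientRecord], matrix: GeneStatusMatrix,
            rules: ClassificationRules) -> pd.Series:
    labels = {}
    for r in records:
        labels[r.tumor_id] = r.group if r.group else classify_group(r, rules)
    return pd.Series(labels).reindex(matrix.df.index)


def run_cohort_report(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Prevalence table, subtype partition, and adjusted logistic model."""
    cfg.check_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, records = read_cohort_tsv(cfg.cohort_tsv)
    if matrix.df.empty:
        raise ValueError("empty cohort")
    groups = _groups(records, matrix, cfg.rules)

    prev = prevalence_table(matrix, groups)
    render_prevalence_table(prev).to_csv(out / "prevalence.tsv", sep="\t")

    labels = matrix.df.apply(lambda row: classify_subtype(row, cfg.rules), axis=1)
    part = labels.value_counts().rename_axis("subtype").to_frame("n")
    part["excluded_from_subtypes"] = [is_overlap_label(s) for s in part.index]
    part.to_csv(out / "subtype_partition.tsv", sep="\t")

    drivers = ["NF1", "ROS1", "BRAF", "RAC1", "GNA11"]
    X = matrix.df[[g for g in drivers if g in matrix.df.columns]].fillna(0)
    adj = adjusted_logistic(groups, X)
    adj.to_csv(out / "adjusted_logistic.tsv", sep="\t")
    return {"prevalence": prev, "subtype_partition": part, "adjusted_logistic": adj}


def run_mechanistic(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Knockdown simulation, bootstrap differential activation for each
    comparison, pathway-level combination, and the hallmark radar table."""
    cfg.check_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={cfg.seed}", f"n_bootstrap={cfg.diff.n_bootstrap}",
                 f"knockdown_factor={cfg.knockdown.factor}"]

    matrix, records = read_cohort_tsv(cfg.cohort_tsv)
    groups = _groups(records, matrix, cfg.rules)
    expr = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
    graphs = parse_pathways(cfg.sif, cfg.node_map_tsv)

    results: dict[str, pd.DataFrame] = {}
    selected_by_group: dict[str, set[str]] = {}
    for i, (g1, g2) in enumerate(COMPARISONS):
        t0 = time.perf_counter()
        sub = matrix.df.index[(groups == g1) | (groups == g2) | (groups.isna() & False)]
        use = GeneStatusMatrix(matrix.df.loc[matrix.df.index.isin(sub)])
        res = bootstrap_diff(
            use, groups, expr, graphs, g1, g2,
            cfg=cfg.diff, kd_cfg=cfg.knockdown, seed=cfg.seed + i,
        )
        name = f"{g2}_vs_{g1}"
        res.to_csv(out / f"diff_circuits_{name}.tsv", sep="\t")
        results[name] = res
        if g1 == NORMAL:
            selected_by_group[g2] = set(res.index[res["selected"]])
        log_lines.append(f"{name}: {time.perf_counter() - t0:.1f}s, "
                         f"{int(res['selected'].sum())}/{len(res)} circuits selected")

        pw = (
            res.groupby("pathway_id")["combined_p"]
            .apply(lambda p: pathway_combine(p.to_numpy()))
            .to_frame("pathway_p")
        )
        pw.to_csv(out / f"pathway_level_{name}.tsv", sep="\t")
        results[f"pathway_{name}"] = pw

    if cfg.hallmarks_tsv:
        scores = load_hallmark_scores(cfg.hallmarks_tsv)
        annot = threshold_annotations(scores, cfg.hallmark)
        radar = hallmark_counts(selected_by_group, annot)
        radar.to_csv(out / "hallmark_radar.tsv", sep="\t", index=False)
        results["hallmark_radar"] = radar

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
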