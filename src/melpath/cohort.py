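"""Cohort ingest, variant filtering, and the two melanoma classification rules.

Two independent classifications are applied to every tumor:

* **Etiopathogenic group** — from phenotype: *nevogenic* (more than 50
  melanocytic nevi, no solar elastosis) versus *CSD* (fewer than 20 nevi,
  moderate-to-severe solar elastosis on the surrounding skin). Patients
  satisfying neither rule are *unclassifiable*; the two rules are mutually
  exclusive by construction.
* **Molecular subtype** — from the mutation-status matrix: BRAF+, RAS+
  (NRAS/HRAS/KRAS), NF1+, or triple wild type (3wt) when exactly one (or
  none) of the three driver classes is mutated; tumors mutated in more than
  one class get a concatenated overlap label (e.g. ``BRAF+NF1+``) and are
  excluded from the four mutually exclusive subtypes.

:func:`fixture_from_marginals` rebuilds a status matrix that is exact on
published per-gene group counts and pairwise driver overlaps, which is how
the 119-patient cohort is reconstructed from its printed tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    DRIVER_OVERLAPS,
    GROUP_MUTATION_COUNTS,
    MISSING_STATUS_COUNTS,
    N_CSD,
    N_NEVOGENIC,
    PANEL_GENES,
    RAS_GENES,
)

NEVOGENIC = "nevogenic"
CSD = "CSD"
UNCLASSIFIABLE = "unclassifiable"

PATHOGENIC_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "predicted_pathogenic"}
)
ALL_PATHOGENICITY = PATHOGENIC_CLASSES | {"benign", "vus"}

#: Solar-elastosis bands; the underlying histological score has 11 degrees
#: (0 up to 3+), collapsed here by leading digit.
ELASTOSIS_BANDS = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class VariantCall:
    tumor_id: str
    gene: str
    vaf: float
    pathogenicity: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1] for {self.tumor_id}/{self.gene}")
        if self.pathogenicity not in ALL_PATHOGENICITY:
            raise ValueError(f"unknown pathogenicity class {self.pathogenicity!r}")


@dataclass(frozen=True)
class VariantFilterConfig:
    """Ingest filter: keep variants with VAF above 5% in a pathogenic class."""

    min_vaf: float = 0.05
    retained_pathogenicity: frozenset[str] = PATHOGENIC_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 < self.min_vaf < 1.0:
            raise ValueError("min_vaf must be in (0, 1)")


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds for both classification rules.

    Nevus-count inequalities are strict (``> 50`` / ``< 20``); the boundary
    counts 50 and 20 are therefore unclassifiable.
    """

    nevogenic_min_nevi: int = 50
    csd_max_nevi: int = 20
    csd_min_elastosis: str = "moderate"
    ras_genes: tuple[str, ...] = RAS_GENES

    def __post_init__(self) -> None:
        if self.nevogenic_min_nevi <= self.csd_max_nevi:
            raise ValueError("nevogenic_min_nevi must exceed csd_max_nevi")
        if self.csd_min_elastosis not in ELASTOSIS_BANDS:
            raise ValueError(f"unknown elastosis band {self.csd_min_elastosis!r}")


@dataclass
class PatientRecord:
    tumor_id: str
    nevus_count: int | None = None
    elastosis_grade: str | int | None = None
    group: str | None = None


@dataclass
class GeneStatusMatrix:
    """Binary per-tumor mutation status (1 = at least one retained variant).

    Backed by a tumors x genes DataFrame; NaN marks non-informative status
    (e.g. tumors without TERT-promoter coverage).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("status entries must be 0, 1 or NA")

    @property
    def tumors(self) -> list[str]:
        return list(self.df.index)

    @property
    def genes(self) -> list[str]:
        return list(self.df.columns)

    def mutated(self, gene: str) -> pd.Series:
        return self.df[gene] == 1


def elastosis_band(grade: str | int | None) -> str | None:
    """Collapse an 11-degree elastosis grade (0..3+) into four bands."""
    if grade is None or (isinstance(grade, float) and np.isnan(grade)):
        return None
    if isinstance(grade, (int, np.integer)):
        if not 0 <= grade <= 10:
            raise ValueError(f"elastosis ordinal {grade} outside 0..10")
        return ("none", "mild", "moderate", "severe")[
            0 if grade == 0 else 1 if grade <= 3 else 2 if grade <= 6 else 3
        ]
    g = str(grade).strip()
    if g in ELASTOSIS_BANDS:
        return g
    if g and g[0] in "0123":
        return ("none", "mild", "moderate", "severe")[int(g[0])]
    raise ValueError(f"unrecognised elastosis grade {grade!r}")


def filter_variants(
    calls: Iterable[VariantCall],
    cfg: VariantFilterConfig = VariantFilterConfig(),
    panel: Sequence[str] = PANEL_GENES,
) -> list[VariantCall]:
    """Keep calls with ``vaf > min_vaf`` in a retained pathogenicity class.

    Calls on genes outside the panel are rejected with a warning naming the
    record (never silently dropped). Order is preserved; the operation is
    idempotent.
    """
    panel_set = set(panel)
    kept: list[VariantCall] = []
    unknown: list[VariantCall] = []
    for c in calls:
        if c.gene not in panel_set:
            unknown.append(c)
            continue
        if c.vaf > cfg.min_vaf and c.pathogenicity in cfg.retained_pathogenicity:
            kept.append(c)
    if unknown:
        warnings.warn(
            "rejected variant calls on genes outside the panel: "
            + ", ".join(f"{c.tumor_id}/{c.gene}" for c in unknown),
            stacklevel=2,
        )
    return kept


def classify_group(
    rec: PatientRecord,
    rules: ClassificationRules = ClassificationRules(),
    with_reason: bool = False,
):
    """Assign the etiopathogenic group from nevus count and elastosis band."""
    if rec.nevus_count is None:
        out, reason = UNCLASSIFIABLE, "missing_nevus_count"
    else:
        try:
            band = elastosis_band(rec.elastosis_grade)
        except ValueError:
            band = None
        if band is None:
            out, reason = UNCLASSIFIABLE, "missing_elastosis"
        elif rec.nevus_count > rules.nevogenic_min_nevi and band == "none":
            out, reason = NEVOGENIC, "rule_nevogenic"
        elif rec.nevus_count < rules.csd_max_nevi and ELASTOSIS_BANDS.index(
            band
        ) >= ELASTOSIS_BANDS.index(rules.csd_min_elastosis):
            out, reason = CSD, "rule_csd"
        else:
            out, reason = UNCLASSIFIABLE, "neither_rule"
    return (out, reason) if with_reason else out


def classify_subtype(
    row: Mapping[str, object],
    rules: ClassificationRules = ClassificationRules(),
) -> str:
    """Molecular subtype from driver-gene status.

    Returns one of BRAF+/RAS+/NF1+/3wt, or a concatenated overlap label
    (``BRAF+RAS+`` ...) for tumors mutated in more than one driver class.
    """
    required = ("BRAF", "NF1") + tuple(rules.ras_genes)
    missing = [g for g in required if g not in row]
    if missing:
        raise KeyError(f"status row lacks required driver gene(s): {missing}")
    braf = row["BRAF"] == 1
    ras = any(row[g] == 1 for g in rules.ras_genes)
    nf1 = row["NF1"] == 1
    parts = [name for name, hit in (("BRAF", braf), ("RAS", ras), ("NF1", nf1)) if hit]
    if not parts:
        return "3wt"
    return "".join(p + "+" for p in parts)


SINGLE_SUBTYPES = ("BRAF+", "RAS+", "NF1+", "3wt")


def is_overlap_label(label: str) -> bool:
    """True for concatenated labels that exclude a tumor from the 4 subtypes."""
    return label.count("+") > 1


def subtype_counts(
    matrix: GeneStatusMatrix, rules: ClassificationRules = ClassificationRules()
) -> dict[str, int]:
    """Partition counts over subtypes, overlap labels included."""
    counts: dict[str, int] = {}
    for _, row in matrix.df.iterrows():
        lbl = classify_subtype(row, rules)
        counts[lbl] = counts.get(lbl, 0) + 1
    return counts


# --------------------------------------------------------------------------
# Fixture reconstruction from printed marginals


class InfeasibleMarginalsError(ValueError):
    pass


def _normalise_overlap_key(key: Sequence[str]) -> tuple[str, ...]:
    order = {"BRAF": 0, "RAS": 1, "NF1": 2}
    names = tuple(sorted(key, key=order.__getitem__))
    if len(set(names)) != len(names) or any(n not in order for n in names):
        raise ValueError(f"bad overlap key {key!r}")
    return names


def _split_overlaps(
    class_counts: dict[str, list[int]],
    overlaps: dict[tuple[str, ...], int],
    group_sizes: tuple[int, int],
) -> dict[tuple[str, ...], tuple[int, int]]:
    """Choose how many patients of each overlap go to each group.

    The published tables give overlap totals only; any split consistent with
    the per-group class marginals is acceptable. The feasible split that
    maximises the minimum remaining single-driver count is chosen (ties
    broken lexicographically), which is deterministic.
    """
    keys = sorted(overlaps, key=lambda k: (len(k), k))
    ranges = [range(overlaps[k] + 1) for k in keys]
    best = None
    for nev_shares in itertools.product(*ranges):
        remaining = {c: list(class_counts[c]) for c in class_counts}
        used = [0, 0]
        ok = True
        for k, nev in zip(keys, nev_shares):
            shares = (nev, overlaps[k] - nev)
            for g in (0, 1):
                used[g] += shares[g]
                for cls in k:
                    remaining[cls][g] -= shares[g]
        singles = [remaining[c][g] for c in class_counts for g in (0, 1)]
        if any(s < 0 for s in singles):
            continue
        for g in (0, 1):
            if used[g] + sum(remaining[c][g] for c in class_counts) > group_sizes[g]:
                ok = False
        if not ok:
            continue
        score = (min(singles), nev_shares)
        if best is None or score > best[0]:
            best = (score, dict(zip(keys, [(n, overlaps[k] - n) for k, n in zip(keys, nev_shares)])))
    if best is None:
        raise InfeasibleMarginalsError(
            f"no group split of overlaps {overlaps} is consistent with class "
            f"marginals {class_counts} and group sizes {group_sizes}"
        )
    return best[1]


def fixture_from_marginals(
    per_gene_counts: Mapping[str, tuple[int, int]],
    overlaps: Mapping[Sequence[str], int],
    n_nev: int,
    n_csd: int,
    seed: int = 0,
    na_counts: Mapping[str, tuple[int, int]] | None = None,
    ras_genes: Sequence[str] = RAS_GENES,
) -> tuple[GeneStatusMatrix, list[PatientRecord]]:
    """Reconstruct a cohort exactly matching printed marginal counts.

    ``per_gene_counts`` maps gene -> (mutated in nevogenic, mutated in CSD);
    ``overlaps`` maps driver-class pairs/triples (e.g. ``("BRAF", "NF1")``)
    to the number of patients mutated in exactly those classes. Driver
    columns reproduce every marginal and overlap exactly; non-driver columns
    are filled group-wise by exact count with patients drawn at random
    (independently per gene). Deterministic for a fixed seed.
    """
    na_counts = dict(na_counts or {})
    rng = np.random.default_rng(seed)
    group_sizes = (n_nev, n_csd)
    for gene, (a, b) in per_gene_counts.items():
        na = na_counts.get(gene, (0, 0))
        if a < 0 or b < 0 or a + na[0] > n_nev or b + na[1] > n_csd:
            raise InfeasibleMarginalsError(
                f"{gene}: counts {(a, b)} (+NA {na}) exceed group sizes {group_sizes}"
            )

    class_genes = {"BRAF": ("BRAF",), "RAS": tuple(ras_genes), "NF1": ("NF1",)}
    class_counts = {
        c: [sum(per_gene_counts.get(g, (0, 0))[i] for g in genes) for i in (0, 1)]
        for c, genes in class_genes.items()
    }
    norm_overlaps = {_normalise_overlap_key(k): v for k, v in overlaps.items() if v}
    for k, v in norm_overlaps.items():
        for cls in k:
            if v > sum(class_counts[cls]):
                raise InfeasibleMarginalsError(
                    f"overlap {k}={v} exceeds total {cls} marginal {sum(class_counts[cls])}"
                )
    split = _split_overlaps(class_counts, norm_overlaps, group_sizes) if norm_overlaps else {}

    # Remaining single-class counts per group after overlap placement.
    singles = {c: list(class_counts[c]) for c in class_genes}
    for k, shares in split.items():
        for cls in k:
            for g in (0, 1):
                singles[cls][g] -= shares[g]

    # RAS patients are attributed to a specific gene, consuming printed
    # per-gene counts in panel order within each group.
    ras_pool = {
        g: {gene: per_gene_counts.get(gene, (0, 0))[g] for gene in ras_genes}
        for g in (0, 1)
    }

    def take_ras_gene(g: int) -> str:
        for gene, left in ras_pool[g].items():
            if left > 0:
                ras_pool[g][gene] -= 1
                return gene
        raise InfeasibleMarginalsError("RAS gene counts exhausted during assignment")

    driver_cols = set(itertools.chain.from_iterable(class_genes.values()))
    genes_out = [g for g in per_gene_counts]
    if set(genes_out) <= set(PANEL_GENES):  # panel order when applicable
        genes_out = [g for g in PANEL_GENES if g in per_gene_counts]

    rows: list[dict[str, float]] = []
    records: list[PatientRecord] = []
    group_names = (NEVOGENIC, CSD)
    prefixes = ("NEV", "CSD")
    for g in (0, 1):
        profiles: list[tuple[str, ...]] = []
        for k in sorted(split, key=lambda k: (len(k), k)):
            profiles.extend([k] * split[k][g])
        for cls in ("BRAF", "RAS", "NF1"):
            profiles.extend([(cls,)] * singles[cls][g])
        if len(profiles) > group_sizes[g]:
            raise InfeasibleMarginalsError(
                f"{group_names[g]}: {len(profiles)} driver-mutated patients exceed "
                f"group size {group_sizes[g]}"
            )
        profiles.extend([()] * (group_sizes[g] - len(profiles)))
        for i, classes in enumerate(profiles, start=1):
            tid = f"{prefixes[g]}{i:03d}"
            row = {gene: 0.0 for gene in genes_out}
            for cls in classes:
                gene = take_ras_gene(g) if cls == "RAS" else cls
                row[gene] = 1.0
            rows.append(row)
            if g == 0:
                nevi = int(rng.integers(51, 151))
                grade: str | int = "0"
            else:
                nevi = int(rng.integers(0, 20))
                grade = str(rng.choice(["2-", "2", "2+", "3-", "3", "3+"]))
            records.append(
                PatientRecord(tid, nevus_count=nevi, elastosis_grade=grade, group=group_names[g])
            )

    df = pd.DataFrame(rows, index=[r.tumor_id for r in records], dtype=float)

    # Non-driver columns: exact group-wise counts, random patient choice.
    slices = {0: slice(0, n_nev), 1: slice(n_nev, n_nev + n_csd)}
    for gene in genes_out:
        if gene in driver_cols:
            continue
        for g in (0, 1):
            ids = df.index[slices[g]]
            n_na = na_counts.get(gene, (0, 0))[g]
            n_mut = per_gene_counts[gene][g]
            chosen = rng.choice(ids, size=n_na + n_mut, replace=False)
            df.loc[chosen[:n_na], gene] = np.nan
            df.loc[chosen[n_na:], gene] = 1.0
    return GeneStatusMatrix(df), records


def melanoma_cohort_fixture(seed: int = 0) -> tuple[GeneStatusMatrix, list[PatientRecord]]:
    """The 119-patient cohort (82 nevogenic / 37 CSD) rebuilt from its
    printed per-gene counts and driver overlaps."""
    return fixture_from_marginals(
        GROUP_MUTATION_COUNTS,
        DRIVER_OVERLAPS,
        N_NEVOGENIC,
        N_CSD,
        seed=seed,
        na_counts=MISSING_STATUS_COUNTS,
    )


def read_cohort_tsv(path) -> tuple[GeneStatusMatrix, list[PatientRecord]]:
    """Read a cohort TSV (tumor_id, nevus_count, elastosis_grade, [group],
    one {0,1,NA} column per panel gene)."""
    t = pd.read_csv(path, sep="\t", dtype={"tumor_id": str})
    meta_cols = [c for c in ("tumor_id", "nevus_count", "elastosis_grade", "group") if c in t]
    genes = [c for c in t.columns if c not in meta_cols]
    records = [
        PatientRecord(
            r["tumor_id"],
            nevus_count=None if pd.isna(r.get("nevus_count")) else int(r["nevus_count"]),
            elastosis_grade=None if pd.isna(r.get("elastosis_grade")) else str(r["elastosis_grade"]),
            group=r.get("group") if "group" in meta_cols else None,
        )
        for _, r in t.iterrows()
    ]
    df = t.set_index("tumor_id")[genes].astype(float)
    return GeneStatusMatrix(df), records


def write_cohort_tsv(path, matrix: GeneStatusMatrix, records: list[PatientRecord]) -> None:
    meta = pd.DataFrame(
        {
            "tumor_id": [r.tumor_id for r in records],
            "nevus_count": [r.nevus_count for r in records],
            "elastosis_grade": [r.elastosis_grade for r in records],
            "group": [r.group for r in records],
        }
    ).set_index("tumor_id")
    out = meta.join(matrix.df)
    out.to_csv(path, sep="\t", na_rep="NA")
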