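"""Group-association statistics: prevalence tables, exact 2x2 tests, and
logistic regression of group membership on mutation status.

The default 2x2 test is the two-sided Fisher exact test with the
probability-mass two-sided convention (sum the hypergeometric probabilities
of all tables with the observed margins whose probability does not exceed
the observed table's); printed cohort p-values match this test rather than
the chi-square. A chi-square variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CSD, NEVOGENIC, GeneStatusMatrix

#: Coefficient magnitude above which a logistic fit is treated as separated.
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: rows mutated/WT, columns nevogenic/CSD -> (a, b; c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class AssociationResult:
    p_value: float
    odds_ratio: float
    test_name: str
    degenerate: bool = False


def fisher_exact_two_sided(t: TwoByTwo) -> AssociationResult:
    """Two-sided Fisher exact test; OR is the sample odds ratio ad/bc."""
    arr = t.array
    degenerate = (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any()
    if degenerate:
        return AssociationResult(1.0, _sample_or(t), "fisher_exact", degenerate=True)
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return AssociationResult(min(p, 1.0), _sample_or(t), "fisher_exact")


def chi_square(t: TwoByTwo, correction: bool = False) -> AssociationResult:
    res = stats.chi2_contingency(t.array, correction=correction)
    return AssociationResult(float(res[1]), _sample_or(t), "chi_square")


def _sample_or(t: TwoByTwo) -> float:
    if t.b * t.c == 0:
        return np.inf if t.a * t.d > 0 else np.nan
    return (t.a * t.d) / (t.b * t.c)


def round_half_up(x: float, decimals: int = 1) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    )


def format_p(p: float) -> str:
    return "<0.001" if p < 0.0005 else f"{round_half_up(p, 3):.3f}"


def prevalence_table(matrix: GeneStatusMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per-gene mutation counts and percentages, overall and by group.

    Percentages are over informative (non-NA) tumors; the Fisher p compares
    mutated/WT between the nevogenic and CSD groups. Raw (unrounded) values
    are returned; use :func:`render_prevalence_table` for display rounding.
    """
    groups = groups.reindex(matrix.df.index)
    rows = []
    for gene in matrix.genes:
        col = matrix.df[gene]
        inf = col.notna()
        n_inf = int(inf.sum())
        mut = col == 1
        n_mut = int(mut.sum())
        parts = {}
        for gname, key in ((NEVOGENIC, "nev"), (CSD, "csd")):
            gmask = (groups == gname) & inf
            parts[f"n_{key}"] = int(gmask.sum())
            parts[f"mut_{key}"] = int((mut & gmask).sum())
        tab = TwoByTwo(
            parts["mut_nev"],
            parts["n_nev"] - parts["mut_nev"],
            parts["mut_csd"],
            parts["n_csd"] - parts["mut_csd"],
        )
        rows.append(
            {
                "gene": gene,
                "n_informative": n_inf,
                "n_mutated": n_mut,
                "pct_mutated": 100.0 * n_mut / n_inf if n_inf else np.nan,
                "n_mutated_nev": parts["mut_nev"],
                "pct_mutated_nev": 100.0 * parts["mut_nev"] / parts["n_nev"]
                if parts["n_nev"]
                else np.nan,
                "n_mutated_csd": parts["mut_csd"],
                "pct_mutated_csd": 100.0 * parts["mut_csd"] / parts["n_csd"]
                if parts["n_csd"]
                else np.nan,
                "p_value": fisher_exact_two_sided(tab).p_value,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def render_prevalence_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display form: percentages rounded half-up to 1 decimal, p to 3."""
    out = table.copy()
    for c in out.columns:
        if c.startswith("pct_"):
            out[c] = out[c].map(lambda x: round_half_up(x, 1) if np.isfinite(x) else x)
    out["p_value"] = out["p_value"].map(format_p)
    return out


@dataclass(frozen=True)
class LogisticResult:
    coef: float
    odds_ratio: float
    p_value: float
    separation: bool = False


def _encode(y: pd.Series | np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":  # group labels: CSD coded 1
        return (y == CSD).astype(float)
    return y.astype(float)


def logistic_univariate(y, x) -> LogisticResult:
    """ML logistic fit of P(CSD) on one binary predictor; Wald p for the slope.

    Complete (or quasi-complete) separation is detected via a diverging
    coefficient and reported as a flagged result without a numeric OR.
    """
    res = _fit_logit(_encode(y), np.asarray(x, dtype=float).reshape(-1, 1))
    if res is None or abs(res.params[1]) > SEPARATION_BETA:
        return LogisticResult(np.nan, np.nan, np.nan, separation=True)
    beta = float(res.params[1])
    return LogisticResult(beta, float(np.exp(beta)), float(res.pvalues[1]))


def adjusted_logistic(y, X: pd.DataFrame) -> pd.DataFrame:
    """Joint ML logistic fit; per-column adjusted OR and Wald p.

    Raises on rank-deficient design, naming the collinear columns.
    """
    Xm = X.astype(float)
    rank = np.linalg.matrix_rank(Xm.to_numpy())
    if rank < Xm.shape[1]:
        dup = [
            c2
            for i, c1 in enumerate(Xm.columns)
            for c2 in Xm.columns[i + 1 :]
            if np.allclose(Xm[c1], Xm[c2])
        ]
        raise ValueError(f"design matrix rank-deficient (collinear columns: {dup or 'unknown'})")
    res = _fit_logit(_encode(y), Xm.to_numpy())
    rows = []
    for j, col in enumerate(Xm.columns, start=1):
        if res is None or abs(res.params[j]) > SEPARATION_BETA:
            rows.append({"gene": col, "coef": np.nan, "odds_ratio": np.nan,
                         "p_value": np.nan, "separation": True})
        else:
            beta = float(res.params[j])
            rows.append({"gene": col, "coef": beta, "odds_ratio": float(np.exp(beta)),
                         "p_value": float(res.pvalues[j]), "separation": False})
    return pd.DataFrame(rows).set_index("gene")


def _fit_logit(y: np.ndarray, X: np.ndarray):
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    design = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            return sm.Logit(y, design).fit(disp=0, maxiter=100)
    except Exception:
        return None
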