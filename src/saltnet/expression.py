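"""Differential expression on a normalized two-condition matrix.

The pipeline's contract starts at a gene-level log2 expression matrix that
has already been background-corrected and normalized. Genes are selected as
differentially expressed (DEGs) by an unpaired two-sample t-test between the
control and case (disease) sample groups, with Benjamini-Hochberg step-up
control of the false discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
CONDITIONS = (CONTROL, CASE)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression with condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample ID.
        Symbols are upper-cased on construction; duplicates are an error
        rather than being silently averaged.
    condition_of
        Series mapping every sample ID to ``"control"`` or ``"case"``.
    """

    values: pd.DataFrame
    condition_of: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.duplicated().any():
            dups = sorted(self.values.index[self.values.index.duplicated()])
            raise ValidationError(f"duplicate gene symbols: {dups[:10]}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample IDs")
        self.condition_of = self.condition_of.astype(str)
        missing = [s for s in self.values.columns if s not in self.condition_of.index]
        if missing:
            raise ValidationError(f"samples without a condition label: {missing[:10]}")
        bad = set(self.condition_of.loc[list(self.values.columns)]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"conditions must be one of {CONDITIONS}, got {sorted(bad)}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def subset(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.condition_of)


def t_test_per_gene(matrix: ExpressionMatrix, welch: bool = False) -> pd.DataFrame:
    """Two-sample t statistic and two-sided p per gene (case vs control).

    Student's pooled-variance test by default; Welch's unequal-variance
    variant when ``welch`` is true. The statistic is signed as
    ``mean_case - mean_control``, so swapping the group labels negates ``t``
    and leaves ``p`` unchanged.

    Degenerate-variance policy: a gene with zero variance in both groups
    gets ``t = 0, p = 1`` when the group means are equal, and ``p = 0``
    (with an infinite ``t`` carrying the sign of the difference, and a
    logged warning) when they differ.
    """
    ctrl = matrix.samples_in(CONTROL)
    case = matrix.samples_in(CASE)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValidationError(
            f"need >= 2 samples per condition, got control={len(ctrl)} case={len(case)}"
        )
    a = matrix.values[case].to_numpy(dtype=float)
    b = matrix.values[ctrl].to_numpy(dtype=float)
    mean_case = a.mean(axis=1)
    mean_ctrl = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = degenerate & np.isclose(mean_case, mean_ctrl)
    diff_means = degenerate & ~equal_means
    t[equal_means] = 0.0
    p[equal_means] = 1.0
    if diff_means.any():
        genes = [g for g, m in zip(matrix.genes, diff_means) if m]
        logger.warning(
            "%d gene(s) with zero variance in both groups but unequal means "
            "(p recorded as 0): %s", len(genes), genes[:10]
        )
        t[diff_means] = np.sign(mean_case[diff_means] - mean_ctrl[diff_means]) * np.inf
        p[diff_means] = 0.0

    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_control": mean_ctrl,
            "mean_case": mean_case,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the ascending order
    statistics, mapped back to the original positions.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_table(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    welch: bool = False,
) -> pd.DataFrame:
    """Full DEG table: t, p, BH-adjusted p, group means and a pass flag."""
    if not 0 <= alpha <= 1:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")
    table = t_test_per_gene(matrix, welch=welch)
    table["p_adj"] = bh_adjust(table["p"])
    crit = table["p_adj"] if use_adjusted else table["p"]
    table["passes"] = crit <= alpha
    return table


def select_degs(
    table: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = True
) -> set[str]:
    """Genes whose (adjusted, by default) p value is at most ``alpha``."""
    if not 0 <= alpha <= 1:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")
    col = "p_adj" if use_adjusted else "p"
    if col not in table.columns:
        raise ValidationError(f"DEG table lacks a {col!r} column")
    return set(table.index[table[col] <= alpha])
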