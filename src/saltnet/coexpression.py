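"""Condition-contrasted Pearson co-expression and candidate prioritization.

Per-condition Pearson correlation maps are computed over the SS-PIN gene
set; gene pairs strongly positively correlated in the disease condition
(r >= 0.8 by default) form the disease co-expression network. The same
pairs' correlations in the control condition are attached for contrast,
connectivity to the disease-annotated partners is counted, and unreported
salt-sensitivity genes with sufficient connectivity are prioritized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

CONTRAST_COLUMNS = ["gene_1", "gene_2", "r_disease", "r_control"]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN when either vector has zero variance.

    ``r = sum (x_i - x_bar)(y_i - y_bar) / sqrt(sum (x_i - x_bar)^2
    sum (y_i - y_bar)^2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r requires two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError(f"pearson_r requires n >= 3, got n = {x.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


@dataclass
class CorrelationMap:
    """Symmetric per-condition gene-gene correlation matrix.

    ``r`` is indexed by gene on both axes; entries are NaN where the
    correlation is undefined (zero-variance genes), never coerced to 0.
    """

    condition: str
    r: pd.DataFrame = field(repr=False)

    @property
    def genes(self) -> list[str]:
        return list(self.r.index)

    def lookup(self, a: str, b: str) -> float:
        if a not in self.r.index or b not in self.r.index:
            return float("nan")
        return float(self.r.at[a, b])


def correlation_map(
    matrix: ExpressionMatrix, condition: str, genes: Iterable[str] | None = None
) -> CorrelationMap:
    """All pairwise Pearson correlations among ``genes``, one condition only.

    Genes absent from the matrix are skipped with a warning; zero-variance
    genes stay in the map with NaN rows/columns (diagonal included).
    """
    samples = matrix.samples_in(condition)
    if len(samples) < 3:
        raise ValidationError(
            f"correlation requires >= 3 samples in condition {condition!r}, "
            f"got {len(samples)}"
        )
    if genes is None:
        keep = matrix.genes
    else:
        wanted = [str(g).upper() for g in genes]
        present = set(matrix.genes)
        missing = sorted(set(wanted) - present)
        if missing:
            logger.warning(
                "%d requested gene(s) absent from the expression matrix, "
                "skipped: %s", len(missing), missing[:10]
            )
        keep = [g for g in dict.fromkeys(wanted) if g in present]
    values = matrix.values.loc[keep, samples].to_numpy(dtype=float)
    sd = values.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "%d zero-variance gene(s) in condition %r: correlations undefined",
            int(zero_var.sum()), condition,
        )
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, np.where(zero_var, np.nan, 1.0))
    # rounding at 1e-12 removes BLAS float noise so that identical profiles
    # sit exactly at r = 1 and boundary thresholds behave deterministically
    frame = pd.DataFrame(
        np.clip(np.round(corr, 12), -1.0, 1.0), index=keep, columns=keep
    )
    return CorrelationMap(condition=condition, r=frame)


def threshold_network(
    cmap: CorrelationMap, threshold: float = 0.8, sign: str = "positive"
) -> pd.DataFrame:
    """Gene pairs whose correlation passes the threshold, with r as weight.

    ``positive`` mode keeps pairs with ``r >= threshold`` (the screen for
    strong positive co-expression); ``absolute`` keeps ``|r| >= threshold``.
    Undefined (NaN) correlations never pass.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    if sign not in ("positive", "absolute"):
        raise ValidationError(f"sign must be 'positive' or 'absolute', got {sign!r}")
    genes = cmap.genes
    mat = cmap.r.to_numpy()
    crit = np.abs(mat) if sign == "absolute" else mat
    iu, ju = np.triu_indices(len(genes), k=1)
    with np.errstate(invalid="ignore"):
        mask = crit[iu, ju] >= threshold
    rows = [
        (genes[i], genes[j], float(mat[i, j]))
        for i, j in zip(iu[mask], ju[mask])
    ]
    return pd.DataFrame(rows, columns=["gene_1", "gene_2", "r"])


def contrast_conditions(
    disease_edges: pd.DataFrame, control_map: CorrelationMap
) -> pd.DataFrame:
    """Attach the control-condition r to each disease co-expression edge.

    One row per disease edge: (gene_1, gene_2, r_disease, r_control). Pairs
    with no defined control correlation get NaN and a warning.
    """
    rows = []
    n_missing = 0
    for rec in disease_edges.itertuples(index=False):
        r_ctrl = control_map.lookup(rec.gene_1, rec.gene_2)
        if np.isnan(r_ctrl):
            n_missing += 1
        rows.append((rec.gene_1, rec.gene_2, float(rec.r), r_ctrl))
    if n_missing:
        logger.warning(
            "%d disease edge(s) missing from the control correlation map", n_missing
        )
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


def connectivity_counts(
    contrast: pd.DataFrame, candidates: Iterable[str]
) -> dict[str, int]:
    """Number of contrast rows incident to each candidate gene.

    This is the candidate's direct connectivity to its co-expression
    partners in the disease network; absent candidates count 0.
    """
    incident: dict[str, int] = {}
    for col in ("gene_1", "gene_2"):
        if len(contrast):
            for g, n in contrast[col].value_counts().items():
                incident[g] = incident.get(g, 0) + int(n)
    return {str(c).upper(): incident.get(str(c).upper(), 0) for c in candidates}


def classify_reported(
    ssg_coexpressed: Iterable[str], obesity_annotation: Iterable[str]
) -> dict[str, str]:
    """Label each co-expressed SSG 'reported' or 'unreported' for the disease.

    Reported means membership in the disease (obesity) annotation set.
    """
    annotation = {str(g).upper() for g in obesity_annotation}
    return {
        (g := str(gene).upper()): ("reported" if g in annotation else "unreported")
        for gene in ssg_coexpressed
    }


@dataclass
class PrioritizationResult:
    """Connectivity-ranked shortlist of unreported candidate genes."""

    table: pd.DataFrame = field(repr=False)  # gene, connectivity, reported, selected
    selected: list[str] = field(default_factory=list)
    min_connectivity: int = 3


def prioritize(
    connectivity: Mapping[str, int],
    reported: Mapping[str, str],
    min_connectivity: int = 3,
) -> PrioritizationResult:
    """Select unreported genes with connectivity >= ``min_connectivity``.

    Selection is restricted to genes not already reported for the disease;
    the shortlist is ranked by connectivity descending, ties alphabetical.
    """
    if min_connectivity < 0:
        raise ValidationError("min_connectivity must be non-negative")
    rows = []
    for gene in sorted(connectivity):
        is_reported = reported.get(gene, "unreported") == "reported"
        n = int(connectivity[gene])
        rows.append(
            {
                "gene": gene,
                "connectivity": n,
                "reported": is_reported,
                "selected": (not is_reported) and n >= min_connectivity,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "connectivity", "reported", "selected"])
    if len(table):
        table = table.sort_values(
            ["connectivity", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    selected = list(table.loc[table["selected"], "gene"]) if len(table) else []
    return PrioritizationResult(
        table=table, selected=selected, min_connectivity=min_connectivity
    )
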