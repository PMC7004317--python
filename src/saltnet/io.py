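"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and sample metadata travel as TSV; interaction
networks as two-column TSV, SIF ("nodeA relation nodeB") or GraphML; gene
sets as GMT or one-symbol-per-line lists; correlation/contrast tables as
TSV with r serialized to 4 decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .coexpression import CONTRAST_COLUMNS
from .errors import ValidationError
from .expression import ExpressionMatrix
from .sspin import GeneSetCollection


# -- expression ---------------------------------------------------------------

def read_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a (sample_id, condition) metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    expected = {"sample_id", "condition"}
    if not expected <= set(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(expected)}, got {list(meta.columns)}"
        )
    condition_of = pd.Series(
        meta["condition"].to_numpy(), index=meta["sample_id"].astype(str)
    )
    return ExpressionMatrix(values, condition_of)


def write_expression(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t", float_format="%.6f")
    meta = pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "condition": [matrix.condition_of[s] for s in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# -- networks -----------------------------------------------------------------

def read_edge_list(path) -> list[tuple[str, str]]:
    """Raw edge pairs from SIF (by .sif extension) or two-column TSV.

    SIF rows are ``source relation target [target2 ...]``; TSV rows are two
    tab-separated symbols, ``#`` comments and a ``gene_1``-style header line
    are skipped. The result is the *raw* list: cleaning (loop/duplicate
    removal) is a separate, explicit step.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    is_sif = path.suffix.lower() == ".sif"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if is_sif:
                if len(parts) < 3:
                    if len(parts) == 1:  # isolated node: legal SIF, no edge
                        continue
                    raise ValidationError(f"malformed SIF line: {line!r}")
                edges.extend((parts[0], t) for t in parts[2:])
            else:
                if parts[0].lower() in ("gene_1", "source", "node_1", "gene1"):
                    continue
                if len(parts) < 2:
                    raise ValidationError(f"malformed edge line: {line!r}")
                edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(network: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{b}\n")


def write_sif(network: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(nx.isolates(network)):
            fh.write(f"{node}\n")


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


# -- gene sets ----------------------------------------------------------------

def read_gene_list(path) -> set[str]:
    """One upper-cased symbol per line; blanks and # comments skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym.upper())
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted({str(g).upper() for g in genes}):
            fh.write(g + "\n")


def read_gmt(path) -> GeneSetCollection:
    """GMT: tab-separated set name, description, then member symbols."""
    sets = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                if not line.strip():
                    continue
                raise ValidationError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# -- correlation / contrast tables --------------------------------------------

def write_contrast(contrast: pd.DataFrame, path) -> None:
    """Contrast TSV (gene_1, gene_2, r_disease, r_control), r to 4 decimals."""
    contrast.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_contrast(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != CONTRAST_COLUMNS:
        raise ValidationError(
            f"contrast table must have columns {CONTRAST_COLUMNS}, "
            f"got {list(frame.columns)}"
        )
    return frame


def write_long_correlations(cmap_frame: pd.DataFrame, path) -> None:
    """Long-format (gene_1, gene_2, r) TSV of a symmetric correlation matrix."""
    genes = list(cmap_frame.index)
    with open(path, "w") as fh:
        fh.write("gene_1\tgene_2\tr\n")
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                fh.write(f"{a}\t{b}\t{cmap_frame.at[a, b]:.4f}\n")
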