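"""Bundled reference tables from the published visceral-adipose
salt-sensitivity study this pipeline re-implements.

These small TSVs are transcriptions of the study's printed result tables
and serve as fixtures for the fixtures-only analysis path and the test
suite:

* ``coexpression_pairs`` — the 56 disease co-expression partners of the
  unreported salt-sensitivity genes, with the Pearson r of each pair in the
  obese (disease) and lean (control) condition;
* ``ssg_obesity_status`` — the 23 co-expressed salt-sensitivity genes and
  whether each was already reported for obesity;
* ``ssg_bottleneck_overlap`` — the 15 salt-sensitivity genes that also act
  as bottlenecks in the interactome, with their centralities;
* ``obesity_gene_categories`` — the disease-annotated genes partitioned
  into salt-sensitivity, hub and bottleneck categories;
* ``top_degree_genes`` — the 10 highest-degree genes of the full
  interaction network, with degree and betweenness.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sspin import GeneSetCollection

_DATA = resources.files("saltnet") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t")


def load_coexpression_pairs() -> pd.DataFrame:
    """Disease co-expression contrast table (gene_1, gene_2, r_disease, r_control)."""
    frame = _read("coexpression_pairs.tsv")
    return frame.rename(columns={"r_obese": "r_disease", "r_normal": "r_control"})


def load_ssg_obesity_status() -> pd.DataFrame:
    """Co-expressed salt-sensitivity genes with their obesity status."""
    return _read("ssg_obesity_status.tsv")


def reported_ssgs() -> set[str]:
    frame = load_ssg_obesity_status()
    return set(frame.loc[frame["role_in_obesity"] == "Reported", "gene"])


def unreported_ssgs() -> set[str]:
    frame = load_ssg_obesity_status()
    return set(frame.loc[frame["role_in_obesity"] == "Unreported", "gene"])


def load_ssg_bottleneck_overlap() -> pd.DataFrame:
    """Salt-sensitivity genes that are also bottlenecks (gene, bc, dc)."""
    return _read("ssg_bottleneck_overlap.tsv")


def load_obesity_gene_categories() -> GeneSetCollection:
    """Disease-annotated genes keyed by category.

    Categories: ``salt_sensitivity``, ``hub``, ``bottleneck``. The union is
    the obesity annotation set used for reported/unreported classification.
    """
    frame = _read("obesity_gene_categories.tsv")
    return GeneSetCollection(
        {
            cat: set(sub["gene"])
            for cat, sub in frame.groupby("category")
        }
    )


def obesity_annotation() -> set[str]:
    """All disease-annotated genes (union over the three categories)."""
    sets = load_obesity_gene_categories()
    out: set[str] = set()
    for members in sets.values():
        out |= members
    return out


def load_top_degree_genes() -> pd.DataFrame:
    """Highest-degree genes of the full interaction network (gene, bc, dc)."""
    return _read("top_degree_genes.tsv")
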