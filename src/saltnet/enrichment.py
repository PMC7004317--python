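"""Gene-set over-representation testing (hypergeometric with BH control).

Over-representation of a query gene list in user-supplied gene-set
libraries (GMT collections) is scored by the one-sided (upper-tail)
hypergeometric test against a stated gene universe, with Benjamini-Hochberg
adjustment across the library. Membership partitions of a query against
labelled categories (e.g. disease-annotated hubs / bottlenecks / SSGs) are
reported by simple overlap tables.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .expression import bh_adjust
from .sspin import GeneSetCollection


def hypergeom_enrich(
    query: Iterable[str],
    library: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each library set.

    For each set, with population size ``|universe|``, ``K`` successes (the
    set intersected with the universe) and ``N`` draws (the query size), the
    p value is ``P(X >= overlap)``. Query genes outside the universe are
    dropped before testing. Results are sorted by p ascending; ``q`` is the
    BH-adjusted p across the library.
    """
    universe = {str(g).upper() for g in universe}
    query = {str(g).upper() for g in query}
    if not universe:
        raise ValidationError("empty gene universe")
    if not query:
        raise ValidationError("empty query gene set")
    query &= universe
    if not query:
        raise ValidationError("query has no genes inside the universe")

    rows = []
    for name in sorted(library):
        members = library[name] & universe
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p", "genes"])
    if len(result):
        result["q"] = bh_adjust(result["p"])
        result = result.sort_values(["p", "set"]).reset_index(drop=True)
        result = result[["set", "set_size", "overlap", "p", "q", "genes"]]
    return result


def overlap_table(query: Iterable[str], labels: GeneSetCollection) -> pd.DataFrame:
    """Membership counts of the query in each labelled gene set."""
    query = {str(g).upper() for g in query}
    rows = []
    for name in labels:
        members = sorted(query & labels[name])
        rows.append(
            {
                "label": name,
                "set_size": len(labels[name]),
                "count": len(members),
                "genes": ",".join(members),
            }
        )
    return pd.DataFrame(rows, columns=["label", "set_size", "count", "genes"])
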