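"""Hypergeometric over-representation analysis on GMT term maps.

Standing in for GO/KEGG enrichment of selected DEP sets: for a query set of
``n`` proteins drawn from a background of ``N``, a term annotating ``K``
background proteins and overlapping the query in ``k``, the enrichment
p-value is the upper tail of the hypergeometric distribution,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

adjusted across terms with Benjamini-Hochberg by default.  Terms are first
intersected with the background; the recommended background is the set of
quantitated proteins, not everything ever identified.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "write_gmt", "enrich", "top_terms"]

TermMap = dict[str, tuple[str, frozenset[str]]]


def read_gmt(path) -> TermMap:
    """Read a GMT file: per line, term id, description, then member ids."""
    terms: TermMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            terms[term] = (desc, frozenset(m for m in members if m))
    return terms


def write_gmt(terms: TermMap, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc, members = terms[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def enrich(
    query: set[str],
    background: set[str],
    terms: TermMap,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Test every term for over-representation in ``query``.

    Returns one row per term with K >= 1 after intersecting with the
    background: ``term_id, description, k, K, n, N, p, p_adj``, sorted by
    ascending p with lexicographic term-id tie-break.

    Raises
    ------
    ValueError
        If the query is not a subset of the background (offenders listed).
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"query proteins missing from background: {sorted(stray)[:10]}"
        )
    N, n = len(background), len(query)
    rows = []
    for term_id in sorted(terms):
        desc, members = terms[term_id]
        in_bg = members & background
        K = len(in_bg)
        if K < 1:
            continue
        k = len(in_bg & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "description": desc,
                     "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    result = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "K", "n", "N", "p"]
    )
    if result.empty:
        result["p_adj"] = pd.Series(dtype=float)
        return result
    if adjust == "none":
        result["p_adj"] = result["p"]
    else:
        result["p_adj"] = multipletests(result["p"], method=adjust)[1]
    return (
        result.sort_values(["p", "term_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def top_terms(
    results: pd.DataFrame,
    alpha: float = 0.05,
    top: int = 10,
    on: str = "p",
) -> pd.DataFrame:
    """At most ``top`` terms with ``on``-column value < alpha (smallest p).

    The conventional figure filter uses the raw p-value (``on="p"``); pass
    ``on="p_adj"`` to filter on the adjusted values instead.
    """
    if on not in ("p", "p_adj"):
        raise ValueError("filter column must be 'p' or 'p_adj'")
    kept = results[results[on] < alpha]
    return kept.nsmallest(top, "p", keep="first").reset_index(drop=True)
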