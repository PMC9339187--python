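"""Salinity-response classification of DEP call vectors.

Each protein carries four differential calls against the control, ordered by
ascending salinity with the control excluded: two hyposaline comparisons
(0 and 10 permille) and two hypersaline comparisons (35 and 50 permille).
The classifier maps that call vector to one of seven mutually exclusive
response classes:

========================  =================================================
osmoregulatory_positive   down in both hypo, up in both hyper comparisons —
                          abundance tracks salinity monotonically
osmoregulatory_negative   the mirror pattern (up under hypo, down under hyper)
non_directional_up        up in all four comparisons regardless of direction
                          of the salinity change
non_directional_down      down in all four comparisons
hypo_exclusive            significant, direction-consistent response in the
                          hyposaline arm with the hypersaline arm entirely ns
hyper_exclusive           the symmetric hypersaline-only pattern
unclassified              anything else (incl. all-ns and opposing arms)
========================  =================================================

``strictness="all"`` (default) requires significance in both comparisons of
each responding arm; ``strictness="any"`` relaxes a responding arm to "at
least one significant call in the class direction and none opposing".  The
non-responding arm of an exclusive class must be entirely ns under either
setting.  The definitions are disjoint for both settings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CONDITION_ARMS",
    "RESPONSE_CLASSES",
    "classify",
    "classify_all",
    "undirected_totals",
    "direction_matrix",
]

#: (hypo arm, hyper arm) condition labels, ascending salinity.
CONDITION_ARMS = (("0", "10"), ("35", "50"))

RESPONSE_CLASSES = (
    "osmoregulatory_positive",
    "osmoregulatory_negative",
    "non_directional_up",
    "non_directional_down",
    "hypo_exclusive",
    "hyper_exclusive",
    "unclassified",
)

_VALID = frozenset({"up", "down", "ns"})


def _arm_directed(arm: tuple[str, str], direction: str, strictness: str) -> bool:
    """Does the arm respond in ``direction`` under the given strictness?"""
    opposite = "down" if direction == "up" else "up"
    if strictness == "all":
        return all(c == direction for c in arm)
    return any(c == direction for c in arm) and not any(c == opposite for c in arm)


def _arm_ns(arm: tuple[str, str]) -> bool:
    return all(c == "ns" for c in arm)


def _arm_consistent(arm: tuple[str, str], strictness: str) -> bool:
    """Significant in one consistent direction (either up or down)."""
    return _arm_directed(arm, "up", strictness) or _arm_directed(arm, "down", strictness)


def classify(calls, strictness: str = "all") -> str:
    """Assign one response class to a 4-call vector (0, 10, 35, 50 order)."""
    calls = tuple(calls)
    if len(calls) != 4:
        raise ValueError(f"expected 4 calls, got {len(calls)}")
    unknown = set(calls) - _VALID
    if unknown:
        raise ValueError(f"unknown call symbol(s): {sorted(unknown)}")
    if strictness not in ("all", "any"):
        raise ValueError(f"strictness must be 'all' or 'any', got {strictness!r}")

    hypo, hyper = calls[:2], calls[2:]
    if _arm_directed(hypo, "down", strictness) and _arm_directed(hyper, "up", strictness):
        return "osmoregulatory_positive"
    if _arm_directed(hypo, "up", strictness) and _arm_directed(hyper, "down", strictness):
        return "osmoregulatory_negative"
    if _arm_directed(hypo, "up", strictness) and _arm_directed(hyper, "up", strictness):
        return "non_directional_up"
    if _arm_directed(hypo, "down", strictness) and _arm_directed(hyper, "down", strictness):
        return "non_directional_down"
    if _arm_consistent(hypo, strictness) and _arm_ns(hyper):
        return "hypo_exclusive"
    if _arm_consistent(hyper, strictness) and _arm_ns(hypo):
        return "hyper_exclusive"
    return "unclassified"


def classify_all(
    stats: pd.DataFrame, strictness: str = "all"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every protein in a comparison-stats table.

    ``stats`` needs columns ``protein_id, condition, call`` covering all four
    non-control conditions for every protein (a protein missing a condition
    raises, naming it).

    Returns
    -------
    assignments : DataFrame
        ``protein_id, response_class`` plus per-condition ``call_<cond>``
        columns, sorted by protein_id.
    counts : dict
        Count per response class, plus the undirected totals
        ``osmoregulatory`` and ``non_directional``.
    """
    order = [c for arm in CONDITION_ARMS for c in arm]
    wide = stats.pivot(index="protein_id", columns="condition", values="call")
    missing_cols = [c for c in order if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"conditions missing from stats: {missing_cols}")
    incomplete = wide[order].isna().any(axis=1)
    if incomplete.any():
        bad = wide.index[incomplete][:5].tolist()
        raise ValueError(f"protein(s) missing a condition call: {bad}")
    wide = wide[order].sort_index()

    assigned = [classify(row, strictness) for row in wide.itertuples(index=False)]
    assignments = pd.DataFrame({"protein_id": wide.index,
                                "response_class": assigned})
    for c in order:
        assignments[f"call_{c}"] = wide[c].to_numpy()
    counts = {cls: 0 for cls in RESPONSE_CLASSES}
    for cls in assigned:
        counts[cls] += 1
    counts.update(undirected_totals(counts))
    return assignments.reset_index(drop=True), counts


def undirected_totals(counts: dict[str, int]) -> dict[str, int]:
    """Direction-pooled class totals as reported in the study design."""
    return {
        "osmoregulatory": counts.get("osmoregulatory_positive", 0)
        + counts.get("osmoregulatory_negative", 0),
        "non_directional": counts.get("non_directional_up", 0)
        + counts.get("non_directional_down", 0),
    }


def direction_matrix(stats: pd.DataFrame) -> pd.DataFrame:
    """Proteins x conditions matrix with up=+1, down=-1, ns=0."""
    order = [c for arm in CONDITION_ARMS for c in arm]
    wide = stats.pivot(index="protein_id", columns="condition", values="call")
    wide = wide.reindex(columns=order)
    coded = {"up": 1, "down": -1, "ns": 0}
    return wide.apply(lambda col: col.map(coded)).fillna(0).astype(int)
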