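"""Differential protein expression calling for multiplexed label ratios.

The caller reproduces the standard isobaric-label workflow for a multi-
condition design with one control channel per run:

1. drop proteins quantified by fewer than two unique peptides,
2. form treatment/control channel ratios per run and normalise them to the
   per-(run, condition) median ratio (so each run-condition's median is 1),
3. test each protein x condition with a one-sample two-sided t-test of the
   per-run log2 normalised ratios against 0, correct for multiple testing,
   and call ``up`` when the across-run geometric-mean ratio exceeds 1.20
   with adjusted p < 0.05, ``down`` below 0.83, otherwise ``ns``,
4. aggregate calls into per-condition up/down counts, grand totals, the DEP
   union, and the Venn partition over the condition DEP sets.

The up and down cutoffs are independent settings: 0.83 is the conventional
rounded reciprocal of 1.20 and the asymmetry is preserved exactly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DataError",
    "filter_proteins",
    "normalize_ratios",
    "test_differential",
    "summarize_deps",
    "replicate_overlap",
    "dep_sets",
    "write_comparison_stats",
    "read_comparison_stats",
]

logger = logging.getLogger(__name__)

CALLS = ("up", "down", "ns")

#: Multiple-testing families: correct within each condition across proteins
#: (each condition is reported as its own comparison), across every
#: condition x protein test at once, or within each protein across its
#: conditions only.
FAMILIES = ("per_condition", "global", "per_protein")
CORRECTIONS = ("bonferroni", "fdr_bh", "none")


class DataError(ValueError):
    """Raised for invalid quantitation data (non-positive or non-finite)."""


def filter_proteins(table: pd.DataFrame, min_unique_peptides: int = 2) -> pd.DataFrame:
    """Keep proteins with >= ``min_unique_peptides`` in every run they appear.

    Row order is preserved; an empty result is allowed.
    """
    if min_unique_peptides <= 0:
        return table
    ok = table.groupby("protein_id")["unique_peptides"].transform("min")
    return table[ok >= min_unique_peptides].reset_index(drop=True)


def normalize_ratios(table: pd.DataFrame, control: str) -> pd.DataFrame:
    """Median-normalised treatment/control ratios, long format.

    Raw ratio = channel(condition) / channel(control) per protein and run;
    each (run, condition) ratio vector is divided by its median across
    proteins, so the post-normalisation median is exactly 1.

    Returns columns ``protein_id, run_id, condition, ratio``.

    Raises
    ------
    DataError
        If any channel value is non-positive, naming the protein and run.
    """
    meta = {"protein_id", "run_id", "unique_peptides"}
    conditions = [c for c in table.columns if c not in meta]
    if control not in conditions:
        raise DataError(f"control channel {control!r} missing from table")
    values = table[conditions].to_numpy(float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        bad = np.where(~(np.isfinite(values) & (values > 0)))[0][0]
        row = table.iloc[bad]
        raise DataError(
            f"non-positive channel value for protein {row['protein_id']} "
            f"in run {row['run_id']}"
        )
    out = []
    ctrl = table[control].to_numpy(float)
    for cond in conditions:
        if cond == control:
            continue
        raw = table[cond].to_numpy(float) / ctrl
        part = pd.DataFrame(
            {"protein_id": table["protein_id"], "run_id": table["run_id"],
             "condition": cond, "ratio": raw}
        )
        part["ratio"] /= part.groupby("run_id")["ratio"].transform("median")
        out.append(part)
    return pd.concat(out, ignore_index=True)


def test_differential(
    ratios: pd.DataFrame,
    alpha: float = 0.05,
    up_threshold: float = 1.20,
    down_threshold: float = 0.83,
    correction: str = "bonferroni",
    family: str = "per_condition",
) -> pd.DataFrame:
    """Per protein x condition fold-change + t-test differential calls.

    The p-value is a one-sample two-sided t-test of the per-run log2
    normalised ratios against 0; the reported ratio is the geometric mean
    across runs.  Degenerate cases follow fixed rules: fewer than two runs
    gives p = 1 and ``ns`` (logged); zero across-run variance gives p = 0
    when the mean log2 ratio is non-zero, else p = 1 (logged).

    Returns columns ``protein_id, condition, n_runs, ratio, p_raw, p_adj,
    call`` with ``call = up`` iff ratio > up_threshold and p_adj < alpha,
    ``down`` iff ratio < down_threshold and p_adj < alpha.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    log2r = np.log2(ratios["ratio"].to_numpy(float))
    if not np.all(np.isfinite(log2r)):
        raise DataError("non-finite log2 ratio in input")

    work = ratios.assign(log2_ratio=log2r)
    frames = []
    for cond, grp in work.groupby("condition", sort=True):
        wide = grp.pivot(index="protein_id", columns="run_id",
                         values="log2_ratio")
        arr = wide.to_numpy(float)
        n_runs = np.sum(np.isfinite(arr), axis=1)
        with warnings.catch_warnings():
            # single-run rows legitimately yield all-NaN/ddof slices here;
            # they are routed to the p=1/ns rule below
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(np.where(np.isfinite(arr), arr, np.nan), axis=1)
            sd = np.nanstd(np.where(np.isfinite(arr), arr, np.nan), axis=1,
                           ddof=1)

        p = np.ones(len(wide))
        testable = (n_runs >= 2) & (sd > 0)
        if testable.any():
            res = sps.ttest_1samp(arr[testable], 0.0, axis=1,
                                  nan_policy="omit")
            p[testable] = res.pvalue
        degenerate = (n_runs >= 2) & (sd == 0)
        if degenerate.any():
            logger.warning(
                "%d protein(s) in condition %s have zero across-run "
                "variance; p set to 0 (mean != 0) or 1 (mean == 0)",
                int(degenerate.sum()), cond,
            )
            p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
        few = n_runs < 2
        if few.any():
            logger.warning(
                "%d protein(s) in condition %s quantified in <2 runs; "
                "p set to 1 and call ns", int(few.sum()), cond,
            )
            p[few] = 1.0
        frames.append(
            pd.DataFrame(
                {"protein_id": wide.index, "condition": cond,
                 "n_runs": n_runs, "ratio": 2.0 ** mean, "p_raw": p}
            )
        )
    stats = pd.concat(frames, ignore_index=True)

    stats["p_adj"] = _adjust(stats, correction, family)
    up = (stats["ratio"] > up_threshold) & (stats["p_adj"] < alpha)
    down = (stats["ratio"] < down_threshold) & (stats["p_adj"] < alpha)
    stats["call"] = np.select([up, down], ["up", "down"], default="ns")
    stats.loc[stats["n_runs"] < 2, "call"] = "ns"
    return stats


def _adjust(stats: pd.DataFrame, correction: str, family: str) -> np.ndarray:
    if correction == "none":
        return stats["p_raw"].to_numpy(float)
    adj = np.empty(len(stats))
    if family == "global":
        groups = [np.arange(len(stats))]
    elif family == "per_condition":
        groups = [idx.to_numpy() for _, idx in
                  stats.groupby("condition").groups.items()]
    else:  # per_protein: across the conditions of each protein only
        groups = [idx.to_numpy() for _, idx in
                  stats.groupby("protein_id").groups.items()]
    for idx in groups:
        adj[idx] = multipletests(stats["p_raw"].to_numpy(float)[idx],
                                 method=correction)[1]
    return adj


def dep_sets(stats: pd.DataFrame) -> dict[str, set[str]]:
    """Per-condition sets of proteins called up or down."""
    sig = stats[stats["call"] != "ns"]
    conds = _ordered_conditions(stats)
    return {c: set(sig.loc[sig["condition"] == c, "protein_id"]) for c in conds}


def _ordered_conditions(stats: pd.DataFrame) -> list[str]:
    conds = stats["condition"].unique().tolist()
    try:
        return sorted(conds, key=float)
    except ValueError:
        return sorted(conds)


def summarize_deps(stats: pd.DataFrame) -> dict:
    """Aggregate calls into the study's summary-table quantities.

    Returns a dict with per-condition up/down/total counts, grand up and
    down totals, the DEP union size, and the Venn partition of the union
    over every non-empty subset of conditions (keys are "+"-joined
    condition labels).
    """
    conds = _ordered_conditions(stats)
    per_condition = {}
    for c in conds:
        sub = stats[stats["condition"] == c]
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        per_condition[c] = {"up": n_up, "down": n_down, "total": n_up + n_down}
    sets = dep_sets(stats)
    union = set().union(*sets.values()) if sets else set()

    venn: dict[str, int] = {}
    for r in range(1, len(conds) + 1):
        for subset in itertools.combinations(conds, r):
            inside = set.intersection(*(sets[c] for c in subset)) if subset else set()
            outside = set().union(*(sets[c] for c in conds if c not in subset),
                                  set())
            venn["+".join(subset)] = len(inside - outside)
    return {
        "per_condition": per_condition,
        "grand_up": sum(v["up"] for v in per_condition.values()),
        "grand_down": sum(v["down"] for v in per_condition.values()),
        "dep_union": len(union),
        "venn": venn,
    }


def replicate_overlap(identified: dict[str, set[str]] | list[set[str]]):
    """Cross-run identification overlap: (count, percentage of the union).

    ``count`` is the size of the intersection of all runs' identified-protein
    sets; the percentage is 100 * count / |union|, rounded half-up to one
    decimal place.
    """
    sets = list(identified.values()) if isinstance(identified, dict) else list(identified)
    if len(sets) < 2:
        raise ValueError("replicate overlap needs at least two runs")
    inter = set.intersection(*sets)
    union = set.union(*sets)
    count = len(inter)
    if not union:
        return 0, 0.0
    pct = float(
        Decimal(100 * count) / Decimal(len(union))
    )
    pct = float(Decimal(str(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return count, pct


def write_comparison_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_comparison_stats(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "condition": str, "call": str}
    )
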