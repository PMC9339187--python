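"""DEP caller: peptide filter, median normalisation, threshold + t-test
calls, summary arithmetic, and replicate overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltgill.deps import test_differential as call_differential
from saltgill import (
    DataError,
    filter_proteins,
    normalize_ratios,
    replicate_overlap,
    summarize_deps,
)
from conftest import make_quant_table, make_stats


# --- filter ---------------------------------------------------------------


def test_filter_removes_single_peptide_proteins():
    counts = (1, 2, 2, 3, 1)
    table = pd.DataFrame(
        {"protein_id": [f"P{i}" for i in range(5)], "run_id": "run1",
         "unique_peptides": counts, "25": 1.0, "0": 1.0}
    )
    kept = filter_proteins(table, 2)
    assert set(kept["protein_id"]) == {"P1", "P2", "P3"}
    assert list(kept["protein_id"]) == ["P1", "P2", "P3"]  # order preserved


def test_filter_requires_threshold_in_every_run():
    table = pd.DataFrame(
        {"protein_id": ["A", "A", "B", "B"],
         "run_id": ["run1", "run2"] * 2,
         "unique_peptides": [2, 1, 3, 3], "25": 1.0, "0": 1.0}
    )
    assert set(filter_proteins(table, 2)["protein_id"]) == {"B"}


def test_filter_zero_threshold_is_identity():
    table = make_quant_table({"A": {"0": 1, "10": 1, "35": 1, "50": 1}})
    pd.testing.assert_frame_equal(filter_proteins(table, 0), table)


# --- normalisation --------------------------------------------------------


def test_normalize_divides_by_per_run_condition_median():
    table = make_quant_table(
        {"A": {"0": 2.0, "10": 1, "35": 1, "50": 1},
         "B": {"0": 4.0, "10": 1, "35": 1, "50": 1},
         "C": {"0": 8.0, "10": 1, "35": 1, "50": 1}},
        n_runs=1,
    )
    ratios = normalize_ratios(table, "25")
    got = ratios[ratios["condition"] == "0"].set_index("protein_id")["ratio"]
    assert got["A"] == pytest.approx(0.5)
    assert got["B"] == pytest.approx(1.0)
    assert got["C"] == pytest.approx(2.0)


def test_post_normalization_median_is_one_everywhere():
    rng = np.random.default_rng(0)
    rows = {f"P{i}": {c: float(rng.lognormal(0, 1)) for c in ("0", "10", "35", "50")}
            for i in range(31)}
    ratios = normalize_ratios(make_quant_table(rows, n_runs=2), "25")
    med = ratios.groupby(["run_id", "condition"])["ratio"].median()
    assert np.allclose(med, 1.0)


def test_identical_channels_normalize_to_one():
    table = make_quant_table(
        {f"P{i}": {"0": 1, "10": 1, "35": 1, "50": 1} for i in range(5)}
    )
    assert np.allclose(normalize_ratios(table, "25")["ratio"], 1.0)


def test_nonpositive_channel_value_names_protein_and_run():
    table = make_quant_table({"BAD": {"0": 1, "10": 1, "35": 1, "50": 1}})
    table.loc[1, "10"] = 0.0
    with pytest.raises(DataError, match="BAD.*run2"):
        normalize_ratios(table, "25")


# --- differential test ----------------------------------------------------


def _stats_for(ratios_by_protein, **kwargs):
    """Ratios constant across runs: exercises the zero-variance rule."""
    rows = []
    for pid, by_cond in ratios_by_protein.items():
        for cond, vals in by_cond.items():
            for r, v in enumerate(vals, 1):
                rows.append({"protein_id": pid, "run_id": f"run{r}",
                             "condition": cond, "ratio": v})
    return call_differential(pd.DataFrame(rows), **kwargs)


def test_fold_and_significance_give_up_and_down_calls():
    stats = _stats_for(
        {"NKCC1": {"50": (2.0, 2.1, 2.05)},
         "TFAP2B": {"50": (0.74, 0.76, 0.75)},
         "FLAT": {"50": (1.0, 1.0, 1.0)}},
        correction="none",
    )
    call = stats.set_index("protein_id")["call"]
    assert call["NKCC1"] == "up"
    assert call["TFAP2B"] == "down"
    assert call["FLAT"] == "ns"


def test_ratio_exactly_one_is_ns_regardless_of_p():
    stats = _stats_for({"A": {"0": (1.0, 1.0, 1.0)}}, alpha=1.0,
                       correction="none")
    assert stats["call"].iloc[0] == "ns"
    assert stats["p_raw"].iloc[0] == 1.0  # zero variance, zero mean


def test_zero_variance_nonzero_mean_gives_p_zero():
    stats = _stats_for({"A": {"0": (2.0, 2.0, 2.0)}}, correction="none")
    assert stats["p_raw"].iloc[0] == 0.0
    assert stats["call"].iloc[0] == "up"


def test_fewer_than_two_runs_is_ns_with_p_one():
    rows = pd.DataFrame(
        [{"protein_id": "A", "run_id": "run1", "condition": "0", "ratio": 5.0}]
    )
    stats = call_differential(rows, correction="none")
    assert stats["p_raw"].iloc[0] == 1.0
    assert stats["call"].iloc[0] == "ns"


def test_geometric_mean_ratio_reported():
    stats = _stats_for({"A": {"0": (1.0, 4.0)}}, correction="none")
    assert stats["ratio"].iloc[0] == pytest.approx(2.0)


def test_no_correction_alpha_one_reduces_to_fold_thresholding():
    """Oracle: with correction none and alpha 1, the call is pure fold
    thresholding of the geometric-mean ratio."""
    rng = np.random.default_rng(5)
    ratios_by_protein = {
        f"P{i}": {"0": tuple(float(rng.lognormal(rng.normal(0, 0.5), 0.1))
                             for _ in range(3))}
        for i in range(60)
    }
    stats = _stats_for(ratios_by_protein, alpha=1.0, correction="none")
    gm = {pid: float(np.exp(np.mean(np.log(v["0"]))))
          for pid, v in ratios_by_protein.items()}
    for _, row in stats.iterrows():
        expected = ("up" if gm[row["protein_id"]] > 1.20
                    else "down" if gm[row["protein_id"]] < 0.83 else "ns")
        assert row["call"] == expected


def test_bonferroni_family_sizes():
    """Per-condition family multiplies by the protein count; per-protein
    family by the condition count."""
    ratios_by_protein = {
        f"P{i}": {c: (1.5, 1.6, 1.4) for c in ("0", "10")} for i in range(8)
    }
    per_cond = _stats_for(ratios_by_protein, correction="bonferroni",
                          family="per_condition")
    per_prot = _stats_for(ratios_by_protein, correction="bonferroni",
                          family="per_protein")
    glob = _stats_for(ratios_by_protein, correction="bonferroni",
                      family="global")
    praw = per_cond["p_raw"]
    assert np.allclose(per_cond["p_adj"], np.minimum(1, praw * 8))
    assert np.allclose(per_prot["p_adj"], np.minimum(1, praw * 2))
    assert np.allclose(glob["p_adj"], np.minimum(1, praw * 16))


def test_null_permutation_type_one_rate_bounded():
    """Condition-label shuffles of null-only data stay within the nominal
    false-positive rate (binomial tolerance)."""
    from saltgill import SimulationConfig, simulate_quant_table

    cfg = SimulationConfig(n_proteins=800, seed=23, class_proportions={},
                           noise_sd_log2=0.15)
    quant, _ = simulate_quant_table(cfg)
    # permute the treatment channel labels within each run
    perm = quant.rename(columns={"0": "35", "35": "0", "10": "50", "50": "10"})
    stats = call_differential(normalize_ratios(perm, "25"), alpha=0.05,
                              correction="none")
    rate = float((stats["call"] != "ns").mean())
    m = len(stats)
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / m)


# --- summaries ------------------------------------------------------------


def test_summary_venn_identical_sets_share_one_region():
    stats = make_stats(
        {f"P{i}": ("up", "up", "ns", "ns") for i in range(5)}
    )
    summary = summarize_deps(stats)
    assert summary["venn"]["0+10"] == 5
    assert summary["venn"]["0"] == 0
    assert summary["dep_union"] == 5


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(*[st.sampled_from(["up", "down", "ns"])] * 4),
        min_size=1, max_size=40,
    )
)
def test_summary_arithmetic_invariants(call_rows):
    """total = up + down per condition; grand totals are column sums; Venn
    regions partition the DEP union — for any call matrix."""
    stats = make_stats({f"P{i:03d}": calls for i, calls in enumerate(call_rows)})
    summary = summarize_deps(stats)
    for c, cell in summary["per_condition"].items():
        assert cell["total"] == cell["up"] + cell["down"]
    assert summary["grand_up"] == sum(
        v["up"] for v in summary["per_condition"].values())
    assert summary["grand_down"] == sum(
        v["down"] for v in summary["per_condition"].values())
    assert sum(summary["venn"].values()) == summary["dep_union"]


# --- replicate overlap ----------------------------------------------------


def test_replicate_overlap_printed_counts():
    # intersection 3,897 of a 6,272-protein union
    runs = [set(range(6272)), set(range(3897)), set(range(6272))]
    count, pct = replicate_overlap(runs)
    assert count == 3897
    assert pct == 62.1


def test_replicate_overlap_identical_and_disjoint():
    same = [set("abc")] * 3
    assert replicate_overlap(same) == (3, 100.0)
    disjoint = [{"a"}, {"b"}, {"c"}]
    assert replicate_overlap(disjoint) == (0, 0.0)


def test_replicate_overlap_rounds_half_up():
    # 1/16 = 6.25% rounds up to 6.3 (half-up, not banker's)
    sets = [set(range(16)), {0}]
    count, pct = replicate_overlap(sets)
    assert count == 1
    assert pct == 6.3
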