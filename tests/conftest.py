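import numpy as np
import pandas as pd
import pytest

from saltgill import SimulationConfig


CONDITIONS = ("0", "10", "25", "35", "50")


def make_quant_table(ratio_rows, n_runs=3, peptides=3, baseline=1000.0):
    """Hand-build a quantitation table from exact per-protein ratio vectors.

    ``ratio_rows`` maps protein_id -> {condition: treatment/control ratio};
    the control channel is set to ``baseline`` and treatment channels to
    baseline * ratio, identically in every run (noise-free).
    """
    rows = []
    for r in range(1, n_runs + 1):
        for pid, ratios in ratio_rows.items():
            row = {"protein_id": pid, "run_id": f"run{r}",
                   "unique_peptides": peptides, "25": baseline}
            for cond in ("0", "10", "35", "50"):
                row[cond] = baseline * ratios[cond]
            rows.append(row)
    return pd.DataFrame(rows)


def make_stats(call_rows):
    """Comparison-stats frame from protein_id -> (call0, call10, call35, call50)."""
    ratio_for = {"up": 1.5, "down": 0.6, "ns": 1.0}
    rows = []
    for pid, calls in call_rows.items():
        for cond, call in zip(("0", "10", "35", "50"), calls):
            rows.append({"protein_id": pid, "condition": cond, "n_runs": 3,
                         "ratio": ratio_for[call], "p_raw": 0.001,
                         "p_adj": 0.001 if call != "ns" else 1.0, "call": call})
    return pd.DataFrame(rows)


@pytest.fixture
def small_config():
    return SimulationConfig(n_proteins=200, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
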