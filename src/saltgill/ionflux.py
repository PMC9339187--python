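"""Net per-cell ion flux from diluted-medium ion chromatography.

Cultured branchial cells are challenged with media of different osmolality;
after the challenge the medium is diluted (1:100 ... 1:300), run on an ion
chromatograph, and the measured Na+/K+/Cl- concentrations are converted to a
net ion movement per million cells:

    net_flux = (measured_conc * dilution_factor - baseline_conc)
               * medium_volume / (cell_count / 1e6)

in mass per 1e6 cells.  ``baseline_conc`` is the medium concentration at
time 0 on the undiluted scale.  Sign convention: positive = efflux (ions
left the cells and accumulated in the medium), negative = influx.  "1:100
dilution" means the diluted sample is at 1/100 of the original
concentration, so the measurement is multiplied by 100.

Concentration units cancel against the baseline and scale the output
linearly, so any consistent mass/volume pair works (ug/mL with mL gives
ug per 1e6 cells).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = [
    "compute_flux",
    "compute_flux_table",
    "summarize_flux",
    "read_measurements",
    "write_flux_table",
]

logger = logging.getLogger(__name__)

IONS = ("Na", "K", "Cl")


def compute_flux(
    measured_conc: float,
    dilution_factor: float,
    baseline_conc: float,
    medium_volume: float,
    cell_count: float,
    dead_band: float = 0.0,
) -> tuple[float, str]:
    """Net flux (mass per 1e6 cells) and direction for one measurement.

    ``dead_band`` is an absolute threshold below which the direction is
    reported as "none" (default 0: only an exact balance is "none").
    """
    if dilution_factor < 1:
        raise ValueError(f"dilution_factor must be >= 1, got {dilution_factor}")
    if cell_count <= 0:
        raise ValueError(f"cell_count must be > 0, got {cell_count}")
    if medium_volume <= 0:
        raise ValueError(f"medium_volume must be > 0, got {medium_volume}")
    excess = measured_conc * dilution_factor - baseline_conc
    flux = excess * medium_volume / (cell_count / 1e6)
    if math.fabs(flux) <= dead_band:
        direction = "none"
    elif flux > 0:
        direction = "efflux"
    else:
        direction = "influx"
    return flux, direction


def compute_flux_table(measurements: pd.DataFrame, dead_band: float = 0.0) -> pd.DataFrame:
    """Vectorised :func:`compute_flux` over a measurements table.

    Expects columns ``ion, condition, measured_conc, dilution_factor,
    baseline_conc, medium_volume, cell_count`` (plus any extras such as
    ``replicate``, carried through).  Returns the table with ``net_flux``
    and ``direction`` columns appended.
    """
    m = measurements.copy()
    if (m["dilution_factor"] < 1).any():
        raise ValueError("dilution_factor must be >= 1")
    if (m["cell_count"] <= 0).any() or (m["medium_volume"] <= 0).any():
        raise ValueError("cell_count and medium_volume must be > 0")
    excess = m["measured_conc"] * m["dilution_factor"] - m["baseline_conc"]
    m["net_flux"] = excess * m["medium_volume"] / (m["cell_count"] / 1e6)
    m["direction"] = np.select(
        [m["net_flux"].abs() <= dead_band, m["net_flux"] > 0],
        ["none", "efflux"],
        default="influx",
    )
    return m


def summarize_flux(flux: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of net flux per ion x condition over replicates.

    SEM is the sample SD (ddof=1) over sqrt(n); with a single replicate the
    SEM is reported as 0 with a warning.
    """
    rows = []
    for (ion, cond), grp in flux.groupby(["ion", "condition"], sort=True):
        vals = grp["net_flux"].to_numpy(float)
        n = len(vals)
        mean = float(np.mean(vals))
        if n == 1:
            logger.warning(
                "single replicate for %s at %s; SEM reported as 0", ion, cond
            )
            sem = 0.0
        else:
            sem = float(np.std(vals, ddof=1) / np.sqrt(n))
        rows.append({"ion": ion, "condition": cond, "n": n,
                     "mean_flux": mean, "sem": sem})
    return pd.DataFrame(rows)


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"ion": str})


def write_flux_table(flux: pd.DataFrame, path) -> None:
    flux.to_csv(path, sep="\t", index=False)
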