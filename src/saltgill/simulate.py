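"""Synthetic data for the bidirectional-salinity gill proteome design.

The generator emulates a five-group salinity gradient (0 and 10 permille as
hyposaline stress, 25 permille as control, 35 and 50 permille as hypersaline
stress) quantified in three multiplexed isobaric-label runs, each run carrying
all five groups as reporter channels.  Every protein is planted with a known
salinity-response class (ground truth), so the downstream differential-
expression caller and response classifier can be validated for recovery
without access to real spectra-derived data.

Model: the channel value of protein *i* in condition *c*, run *r* is

    baseline_i * 2 ** (effect[class(i), c] + eps_{i,c,r})

with eps ~ Normal(0, noise_sd_log2) drawn independently per protein,
condition (including the control channel) and run, and the control-channel
effect identically zero.  A treatment/control ratio therefore has a log2
marginal of Normal(effect, noise_sd_log2 * sqrt(2)) for null normalisation.
Baselines are log-uniform over three decades — a realistic dynamic range
without modelling spectra.  Per-protein unique-peptide counts follow a
shifted geometric distribution (support >= 1) so the two-peptide
quantitation filter removes a tunable fraction of proteins.

Missing values, reporter-ion interference and ratio compression are
deliberately not simulated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "PLANTED_CLASSES",
    "DEFAULT_EFFECTS",
    "DEFAULT_CLASS_PROPORTIONS",
    "simulate_quant_table",
    "simulate_term_map",
    "simulate_ion_measurements",
    "write_quant_table",
    "read_quant_table",
    "write_ground_truth",
    "read_ground_truth",
]


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


#: Response classes that can be planted (``null`` marks non-responders).
PLANTED_CLASSES = (
    "osmoregulatory_positive",
    "osmoregulatory_negative",
    "non_directional_up",
    "non_directional_down",
    "hypo_exclusive",
    "hyper_exclusive",
    "null",
)

#: Default planted log2 effects per non-control condition (0, 10, 35, 50
#: permille, ascending).  Signs follow the class semantics: osmoregulatory-
#: positive proteins fall under hyposaline and rise under hypersaline stress;
#: exclusive classes respond in one arm only.
DEFAULT_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "osmoregulatory_positive": (-1.0, -1.0, 1.0, 1.0),
    "osmoregulatory_negative": (1.0, 1.0, -1.0, -1.0),
    "non_directional_up": (1.0, 1.0, 1.0, 1.0),
    "non_directional_down": (-1.0, -1.0, -1.0, -1.0),
    "hypo_exclusive": (1.0, 1.0, 0.0, 0.0),
    "hyper_exclusive": (0.0, 0.0, 1.0, 1.0),
    "null": (0.0, 0.0, 0.0, 0.0),
}

#: Default class mix, scaled to the selected-DEP proportions of the study
#: design (~22 osmoregulatory, 18 non-directional, 52 hypo- and 40
#: hyper-exclusive of ~1,600 quantifiable proteins); remainder is null.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "osmoregulatory_positive": 0.007,
    "osmoregulatory_negative": 0.007,
    "non_directional_up": 0.006,
    "non_directional_down": 0.005,
    "hypo_exclusive": 0.0325,
    "hyper_exclusive": 0.025,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic quantitation-table generator.

    Attributes
    ----------
    n_proteins : int
        Number of proteins per run (default 1600, the study's quantifiable
        scale).
    conditions : tuple of str
        Salinity labels in ascending order; must contain ``control``.
    control : str
        The control salinity label (default "25").
    n_runs : int
        Number of multiplexed runs, i.e. technological repeats (default 3).
    class_proportions : dict
        Response class -> fraction of proteins; non-negative, sum <= 1; the
        remainder is planted as null.
    effect_log2 : dict
        Response class -> per-condition log2 effect vector over the
        non-control conditions (ascending salinity).
    noise_sd_log2 : float
        Log2-scale channel noise SD (>= 0; 0 gives noise-free channels).
    peptide_geom_p : float
        Success probability of the shifted geometric unique-peptide-count
        distribution; P(count = 1) = p is the fraction removed by the
        default two-peptide filter.
    baseline_log10_range : (float, float)
        Decades spanned by the log-uniform baseline abundances.
    seed : int
        Seed for all randomness; identical seeds give identical tables.
    """

    n_proteins: int = 1600
    conditions: tuple[str, ...] = ("0", "10", "25", "35", "50")
    control: str = "25"
    n_runs: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_log2: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_sd_log2: float = 0.1
    peptide_geom_p: float = 0.35
    baseline_log10_range: tuple[float, float] = (4.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def treatment_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.control)

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.control not in self.conditions:
            raise ConfigError(
                f"control condition {self.control!r} not among conditions "
                f"{self.conditions}"
            )
        if sum(c == self.control for c in self.conditions) != 1:
            raise ConfigError("exactly one control condition required")
        salinities = [float(c) for c in self.conditions]
        if salinities != sorted(salinities):
            raise ConfigError("conditions must be sorted ascending by salinity")
        for cls, p in self.class_proportions.items():
            if cls not in PLANTED_CLASSES:
                raise ConfigError(f"unknown response class {cls!r}")
            if p < 0:
                raise ConfigError(f"class proportion for {cls!r} is negative")
        if sum(self.class_proportions.values()) > 1 + 1e-12:
            raise ConfigError("class proportions sum to more than 1")
        # noise_sd_log2 == 0 is the noise-free limit used for exact-recovery
        # checks; negative values are meaningless.
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if not 0 < self.peptide_geom_p <= 1:
            raise ConfigError("peptide_geom_p must be in (0, 1]")
        n_treat = len(self.treatment_conditions)
        for cls in self.class_proportions:
            eff = self.effect_log2.get(cls)
            if eff is None or len(eff) != n_treat:
                raise ConfigError(
                    f"effect_log2[{cls!r}] must give {n_treat} values"
                )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic class counts (rounded proportions), shuffled over ids."""
    n = config.n_proteins
    labels = []
    for cls in PLANTED_CLASSES[:-1]:
        k = int(round(config.class_proportions.get(cls, 0.0) * n))
        labels.extend([cls] * k)
    if len(labels) > n:
        labels = labels[:n]
    labels.extend(["null"] * (n - len(labels)))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return labels


def simulate_quant_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multiplexed quantitation table with planted ground truth.

    Returns
    -------
    quant : DataFrame
        One row per (protein, run): columns ``protein_id``, ``run_id``,
        ``unique_peptides`` and one positive channel column per salinity
        label.
    truth : DataFrame
        One row per protein: ``protein_id``, ``response_class`` and the
        planted ``effect_<condition>`` log2 columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    width = max(4, len(str(n)))
    protein_ids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    classes = _assign_classes(config, rng)
    lo, hi = config.baseline_log10_range
    baselines = 10.0 ** rng.uniform(lo, hi, size=n)
    peptides = rng.geometric(config.peptide_geom_p, size=n)

    treat = config.treatment_conditions
    effect_lookup = {
        cls: np.asarray(config.effect_log2.get(cls, (0.0,) * len(treat)), float)
        for cls in PLANTED_CLASSES
    }
    # effects matrix over all conditions; control column fixed at zero
    eff = np.zeros((n, len(config.conditions)))
    treat_idx = [config.conditions.index(c) for c in treat]
    for i, cls in enumerate(classes):
        eff[i, treat_idx] = effect_lookup[cls]

    frames = []
    for r in range(1, config.n_runs + 1):
        noise = rng.normal(0.0, config.noise_sd_log2,
                           size=(n, len(config.conditions)))
        values = baselines[:, None] * 2.0 ** (eff + noise)
        frame = pd.DataFrame(
            {"protein_id": protein_ids, "run_id": f"run{r}",
             "unique_peptides": peptides}
        )
        for j, cond in enumerate(config.conditions):
            frame[cond] = values[:, j]
        frames.append(frame)
    quant = pd.concat(frames, ignore_index=True)

    truth = pd.DataFrame({"protein_id": protein_ids, "response_class": classes})
    for j, cond in enumerate(treat):
        truth[f"effect_{cond}"] = [effect_lookup[c][j] for c in classes]
    return quant, truth


# ---------------------------------------------------------------------------
# Term-map (GMT) fixture generator


def simulate_term_map(
    ground_truth: pd.DataFrame,
    n_terms: int = 50,
    enriched_terms: int = 5,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 40),
    odds_ratio: float = 10.0,
    target_class: str | None = None,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Generate a GMT-style term map with planted enrichment.

    Enriched terms over-sample the ``target_class`` proteins at the given
    odds ratio: the overlap count between a term of size ``k`` and the class
    (size ``K`` of ``N`` proteins) is drawn from Fisher's noncentral
    hypergeometric distribution with odds ``odds_ratio``, then members are
    sampled uniformly within each stratum.  Non-enriched terms sample
    uniformly from all proteins (odds ratio 1).  ``odds_ratio=inf`` draws an
    enriched term entirely from the class.

    Returns a mapping term_id -> (description, member set).
    """
    if ground_truth.empty:
        raise ValueError("ground truth is empty")
    if enriched_terms > n_terms:
        raise ValueError("enriched_terms must be <= n_terms")
    rng = np.random.default_rng(seed)
    ids = ground_truth["protein_id"].to_numpy()
    N = len(ids)

    if enriched_terms > 0:
        if target_class is None:
            non_null = ground_truth[ground_truth["response_class"] != "null"]
            if non_null.empty:
                raise ValueError(
                    "no non-null planted class available for enriched terms"
                )
            target_class = non_null["response_class"].mode().iloc[0]
        in_class = ground_truth["response_class"].to_numpy() == target_class
        class_ids = ids[in_class]
        other_ids = ids[~in_class]
        if len(class_ids) == 0:
            raise ValueError(f"target class {target_class!r} has no members")

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = term_size_range
    for t in range(1, n_terms + 1):
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        k = min(k, N)
        if t <= enriched_terms:
            K = len(class_ids)
            if math.isinf(odds_ratio):
                x = min(k, K)
            else:
                x = int(
                    sps.nchypergeom_fisher.rvs(
                        N, K, k, odds_ratio, random_state=rng
                    )
                )
            x = min(x, K, k)
            members = np.concatenate(
                [
                    rng.choice(class_ids, size=x, replace=False),
                    rng.choice(other_ids, size=k - x, replace=False),
                ]
            )
            desc = f"enriched:{target_class}"
        else:
            members = rng.choice(ids, size=k, replace=False)
            desc = "background"
        terms[f"T{t:04d}"] = (desc, frozenset(members.tolist()))
    return terms


# ---------------------------------------------------------------------------
# Ion-chromatography fixture generator

#: Per-(ion, osmolality mOsmol/L) true mean net flux in ug per 1e6 cells
#: (positive = efflux) with replicate SDs, shaped on the cultured-cell
#: experiment: hypotonic media drive Na+/K+/Cl- efflux, hypertonic media
#: drive influx; the K+ isotonic mean is not reported and defaults to 0.
DEFAULT_FLUX_MEANS: dict[str, dict[int, tuple[float, float]]] = {
    "Na": {150: (223.71, 5.5), 250: (97.37, 71.7), 355: (-138.05, 47.0),
           500: (-358.85, 89.3), 600: (-175.68, 59.6)},
    "Cl": {150: (537.95, 120.6), 250: (207.81, 89.9), 355: (-77.40, 33.4),
           500: (-453.72, 163.5), 600: (-207.70, 33.6)},
    "K": {150: (41.75, 9.2), 250: (60.37, 14.0), 355: (0.0, 10.0),
          500: (-8.32, 10.4), 600: (-16.43, 11.0)},
}

#: 1:x dilution factors per osmolality, hypotonic -> hypertonic.
DEFAULT_DILUTIONS: dict[int, float] = {150: 100, 250: 150, 355: 200,
                                       500: 250, 600: 300}

#: Baseline (time-0, undiluted) medium concentrations in ug/mL,
#: approximating an L-15-based culture medium.
DEFAULT_BASELINES: dict[str, float] = {"Na": 3150.0, "K": 225.0, "Cl": 5100.0}


def simulate_ion_measurements(
    seed: int = 0,
    n_replicates: int = 3,
    flux_means: dict[str, dict[int, tuple[float, float]]] | None = None,
    dilutions: dict[int, float] | None = None,
    baselines: dict[str, float] | None = None,
    medium_volume: float = 8.0,
    cell_count: float = 1e6,
) -> pd.DataFrame:
    """Simulate diluted-medium ion-chromatography readings.

    Per replicate, a true net flux is drawn around the configured mean and
    inverted through the flux formula to a diluted measured concentration:
    ``measured = (flux * cells/1e6 / volume + baseline) / dilution``.
    Columns match the ion-flux reader: ion, condition, replicate,
    measured_conc (ug/mL, diluted scale), dilution_factor, baseline_conc,
    medium_volume (mL), cell_count.
    """
    rng = np.random.default_rng(seed)
    flux_means = flux_means or DEFAULT_FLUX_MEANS
    dilutions = dilutions or DEFAULT_DILUTIONS
    baselines = baselines or DEFAULT_BASELINES
    rows = []
    for ion, by_cond in flux_means.items():
        for cond, (mean, sd) in by_cond.items():
            dil = dilutions[cond]
            base = baselines[ion]
            for rep in range(1, n_replicates + 1):
                flux = rng.normal(mean, sd)
                measured = (flux * (cell_count / 1e6) / medium_volume + base) / dil
                rows.append(
                    {"ion": ion, "condition": cond, "replicate": rep,
                     "measured_conc": measured, "dilution_factor": dil,
                     "baseline_conc": base, "medium_volume": medium_volume,
                     "cell_count": cell_count}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV round-trips


def write_quant_table(quant: pd.DataFrame, path) -> None:
    quant.to_csv(path, sep="\t", index=False)


def read_quant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "run_id": str})


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str})
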