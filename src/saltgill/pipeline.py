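"""End-to-end run orchestration: simulate -> call DEPs -> classify -> enrich
-> ion flux, from a single JSON-able configuration, with a reproducibility
manifest.

The manifest records the configuration hash, the seed, per-stage row counts
and the SHA-256 of every output file; its own hash is computed over those
deterministic fields only, so an identical configuration and seed yields an
identical manifest hash (wall-clock timings go to the log, never into the
manifest).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

# the package __init__ re-exports functions named `classify` and `enrich`,
# shadowing those submodules in `from . import ...` — import their functions
from . import deps as _deps
from . import ionflux as _ionflux
from . import simulate as _simulate
from .classify import classify_all, direction_matrix
from .enrich import enrich as _enrich_test
from .enrich import write_gmt
from .simulate import ConfigError, SimulationConfig

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {},  # SimulationConfig overrides (n_proteins, noise_sd_log2, ...)
    "dep_calling": {
        "min_unique_peptides": 2,
        "alpha": 0.05,
        "up_threshold": 1.20,
        "down_threshold": 0.83,
        "correction": "bonferroni",
        "family": "per_condition",
    },
    "classification": {"strictness": "all"},
    "enrichment": {
        "n_terms": 50,
        "enriched_terms": 5,
        "odds_ratio": 10.0,
        "alpha": 0.05,
        "top": 10,
        "adjust": "fdr_bh",
    },
    "ion_flux": {"n_replicates": 3, "dead_band": 0.0},
}


def _merge_defaults(user: dict) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(copy.deepcopy(value))
        else:
            config[key] = copy.deepcopy(value)
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        return _merge_defaults(json.load(fh))


def validate_config(config: dict) -> None:
    dep = config["dep_calling"]
    if not dep["up_threshold"] > 1:
        raise ConfigError("up_threshold must be > 1")
    if not 0 < dep["down_threshold"] < 1:
        raise ConfigError("down_threshold must be in (0, 1)")
    if not 0 <= dep["alpha"] <= 1:
        raise ConfigError("alpha must be in [0, 1]")
    if not 0 <= config["enrichment"]["alpha"] <= 1:
        raise ConfigError("enrichment alpha must be in [0, 1]")
    if config["classification"]["strictness"] not in ("all", "any"):
        raise ConfigError("strictness must be 'all' or 'any'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage, write outputs under ``out_dir``, return the manifest.

    Stage failures propagate with the stage name prefixed.  An empty DEP set
    (e.g. alpha = 0) cascades gracefully: the classifier reports everything
    unclassified and enrichment is skipped with a notice.
    """
    config = _merge_defaults(config)
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, str(config.get("log_level", "INFO")).upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    seed = int(config["seed"])
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }

    def record(stage: str, rows: int, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "rows": rows,
            "outputs": {name: _sha256(p) for name, p in files.items()},
        }

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", stage)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is None:
                    logger.info("stage %s: done in %.2fs", stage, dt)
                else:
                    logger.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
                return False

        return _T()

    # --- simulate -----------------------------------------------------
    with timed("simulate"):
        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
        quant, truth = _simulate.simulate_quant_table(sim_cfg)
        terms = _simulate.simulate_term_map(
            truth,
            n_terms=config["enrichment"]["n_terms"],
            enriched_terms=config["enrichment"]["enriched_terms"],
            odds_ratio=config["enrichment"]["odds_ratio"],
            seed=seed + 1,
        )
        measurements = _simulate.simulate_ion_measurements(
            seed=seed + 2, n_replicates=config["ion_flux"]["n_replicates"]
        )
        quant_path = out / "quant.tsv"
        truth_path = out / "ground_truth.tsv"
        gmt_path = out / "terms.gmt"
        meas_path = out / "ion_measurements.tsv"
        _simulate.write_quant_table(quant, quant_path)
        _simulate.write_ground_truth(truth, truth_path)
        write_gmt(terms, gmt_path)
        measurements.to_csv(meas_path, sep="\t", index=False)
        record("simulate", len(quant),
               {p.name: p for p in (quant_path, truth_path, gmt_path, meas_path)})

    # --- DEP calling --------------------------------------------------
    with timed("dep_calling"):
        dep_cfg = config["dep_calling"]
        filtered = _deps.filter_proteins(quant, dep_cfg["min_unique_peptides"])
        ratios = _deps.normalize_ratios(filtered, sim_cfg.control)
        stats = _deps.test_differential(
            ratios,
            alpha=dep_cfg["alpha"],
            up_threshold=dep_cfg["up_threshold"],
            down_threshold=dep_cfg["down_threshold"],
            correction=dep_cfg["correction"],
            family=dep_cfg["family"],
        )
        summary = _deps.summarize_deps(stats)
        stats_path = out / "comparison_stats.tsv"
        summary_path = out / "dep_summary.json"
        _deps.write_comparison_stats(stats, stats_path)
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        record("dep_calling", len(stats),
               {stats_path.name: stats_path, summary_path.name: summary_path})

    # --- classification ----------------------------------------------
    with timed("classification"):
        assignments, counts = classify_all(
            stats, strictness=config["classification"]["strictness"]
        )
        assign_path = out / "assignments.tsv"
        counts_path = out / "class_counts.json"
        matrix_path = out / "direction_matrix.tsv"
        assignments.to_csv(assign_path, sep="\t", index=False)
        counts_path.write_text(json.dumps(counts, indent=2, sort_keys=True))
        direction_matrix(stats).to_csv(matrix_path, sep="\t")
        record("classification", len(assignments),
               {p.name: p for p in (assign_path, counts_path, matrix_path)})

    # --- enrichment ---------------------------------------------------
    with timed("enrichment"):
        background = set(stats["protein_id"])
        query = set().union(*_deps.dep_sets(stats).values()) if len(stats) else set()
        enr_path = out / "enrichment.tsv"
        if not query:
            logger.warning("no DEPs called; enrichment skipped")
            enr_path.write_text(
                "term_id\tdescription\tk\tK\tn\tN\tp\tp_adj\n"
            )
            n_rows = 0
        else:
            results = _enrich_test(
                query, background, terms, adjust=config["enrichment"]["adjust"]
            )
            results.to_csv(enr_path, sep="\t", index=False)
            n_rows = len(results)
        record("enrichment", n_rows, {enr_path.name: enr_path})

    # --- ion flux -----------------------------------------------------
    with timed("ion_flux"):
        flux = _ionflux.compute_flux_table(
            measurements, dead_band=config["ion_flux"]["dead_band"]
        )
        summary_flux = _ionflux.summarize_flux(flux)
        flux_path = out / "ion_flux.tsv"
        flux_summary_path = out / "ion_flux_summary.tsv"
        _ionflux.write_flux_table(flux, flux_path)
        summary_flux.to_csv(flux_summary_path, sep="\t", index=False)
        record("ion_flux", len(flux),
               {flux_path.name: flux_path, flux_summary_path.name: flux_summary_path})

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
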