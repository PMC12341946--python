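"""End-to-end orchestration: simulate/load -> filter -> normalize -> DE ->
regression -> classification -> overlaps (-> enrichment), with every table
written as TSV and a JSON run report echoing parameters and stage counts.

Re-running with an identical config and seed reproduces every table bitwise:
all randomness flows from the single seed in the simulation block, and every
downstream stage is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import de as _de
from . import enrichment as _enrichment
from . import preprocess as _pre
from . import regression as _reg
from . import simulate as _sim

logger = logging.getLogger("memorytc")

__all__ = ["RunConfig", "run_pipeline", "evaluate_recovery", "setup_logging"]


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Everything one run needs: input source, thresholds, seed, outputs."""

    outdir: str = "memorytc_run"
    counts_path: str | None = None
    design_path: str | None = None
    simulation: _sim.SimConfig | None = None
    gene_sets_path: str | None = None
    cpm_threshold: float = 1.0
    min_samples_fraction: float = 0.5
    fc_lo: float = 1.2
    fc_hi: float = 2.0
    prob_threshold: float = 0.8
    alpha: float = 0.05
    fdr: float = 0.05
    baseline_time: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.fc_hi > self.fc_lo > 1.0):
            raise ValueError("need fc_hi > fc_lo > 1")
        for name in ("alpha", "fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.simulation is None and (self.counts_path is None or self.design_path is None):
            raise ValueError("provide either a simulation block or counts+design paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = _sim.config_from_dict(sim)
        if "seed" in (sim or {}):
            cfg.seed = cfg.simulation.seed
        elif cfg.simulation is not None:
            cfg.simulation.seed = cfg.seed
        return cfg


def _echo_params(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = dataclasses.asdict(config.simulation)
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _echo_params(config), "stages": {}, "artifacts": {}}

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        report["artifacts"][name] = str(path)

    # --- input ---------------------------------------------------------
    truth = None
    if config.simulation is not None:
        stage = "simulate"
        logger.info("simulating %d genes", config.simulation.n_genes)
        counts, design, truth = _sim.simulate_counts(config.simulation)
        save("counts", counts)
        save("design", design)
        save("truth", truth)
    else:
        stage = "load"
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        design = pd.read_csv(config.design_path, sep="\t", index_col=0)
        missing = set(counts.columns) - set(design.index)
        if missing:
            raise RuntimeError(f"stage {stage}: samples without design rows: {sorted(missing)[:5]}")
    report["stages"]["input_genes"] = int(counts.shape[0])
    report["stages"]["samples"] = int(counts.shape[1])

    try:
        # --- preprocessing ---------------------------------------------
        stage = "filter"
        filtered = _pre.filter_low_counts(
            counts, config.cpm_threshold, config.min_samples_fraction
        )
        report["stages"]["filtered_genes"] = int(filtered.shape[0])

        stage = "normalize"
        factors = _pre.tmm_factors(filtered)
        norm = _pre.normalize(filtered, factors)
        save("normalized_log2cpm", norm.values)
        scores, var_frac = _pre.pca_qc(norm)
        save("pca_scores", scores)
        report["stages"]["pca_variance_fractions"] = [float(v) for v in var_frac[:3]]

        # --- differential expression -----------------------------------
        stage = "differential_expression"
        de_tables = _de.de_vs_baseline(
            norm, design, config.baseline_time,
            config.fc_lo, config.fc_hi, config.prob_threshold,
        )
        times = sorted(t for t in design["time"].unique() if t != config.baseline_time)
        n_de = {}
        for (strain, memory, t), table in de_tables.items():
            save(f"de_{strain}_{memory}_t{t:g}", table)
            n_de[f"{strain}_{memory}_t{t:g}"] = int(
                (table["fc_category"] != "unchanged").sum()
            )
        report["stages"]["n_differential"] = n_de
        if len(times) >= 2:
            for strain in design["strain"].unique():
                for memory in design["memory"].unique():
                    tab = _de.transition_table(
                        de_tables[(strain, memory, times[0])]["fc_category"],
                        de_tables[(strain, memory, times[-1])]["fc_category"],
                    )
                    save(f"transitions_{strain}_{memory}", tab)

        # --- regression -------------------------------------------------
        stage = "regression"
        X = _reg.build_design(design)
        fits = _reg.fit_all_genes(norm.values, X, alpha=config.alpha)
        fits = _reg.filter_time_significant(fits, fdr=config.fdr)
        save("gene_fits", fits)
        n_time = int(fits["time_significant"].sum())
        report["stages"]["time_significant_genes"] = n_time

        # --- classification ---------------------------------------------
        stage = "classify"
        kept = fits[fits["time_significant"]]
        classes = _classify.classify_genes(kept, design=design, alpha=config.alpha)
        save("memory_classes", classes)
        for factor in ("memory_effect", "strain_effect", "interaction_effect"):
            report["stages"][factor] = {
                k: int(v) for k, v in classes[factor].value_counts().items()
            }
        overlaps = _classify.overlap_summary(classes)
        save("overlap_summary", overlaps)

        # --- enrichment ---------------------------------------------------
        if config.gene_sets_path is not None:
            stage = "enrichment"
            path = Path(config.gene_sets_path)
            sets = (
                _enrichment.read_gmt(path)
                if path.suffix.lower() == ".gmt"
                else _enrichment.read_gene_sets_tsv(path)
            )
            universe = set(filtered.index)
            for label in ("dampened", "enhanced", "reversed"):
                ids = classes.index[classes["memory_effect"] == label]
                if len(ids) == 0:
                    continue
                res = _enrichment.fisher_enrich(ids, sets, universe, q_cutoff=None)
                save(f"enrichment_memory_{label}", res)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- recovery against simulated truth --------------------------------
    if truth is not None:
        report["recovery"] = evaluate_recovery(truth, classes)

    report_path = outdir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    report["artifacts"]["run_report"] = str(report_path)
    logger.info(
        "pipeline done: %d genes in, %d time-significant",
        report["stages"]["input_genes"], report["stages"].get("time_significant_genes", 0),
    )
    return report


def evaluate_recovery(truth: pd.DataFrame, classes: pd.DataFrame) -> dict:
    """Compare recovered labels with simulated truth on classified genes.

    not_applicable labels (quadratic-only profiles) are excluded from the
    accuracy denominators since the truth table has no counterpart for them.
    """
    common = classes.index.intersection(truth.index)
    t = truth.loc[common]
    c = classes.loc[common]
    out: dict = {"n_classified": int(len(common))}
    for factor, col in (
        ("memory", "memory_class"),
        ("strain", "strain_class"),
        ("interaction", "interaction_class"),
    ):
        pred = c[f"{factor}_effect"]
        usable = pred != "not_applicable"
        n = int(usable.sum())
        acc = float((pred[usable] == t.loc[usable.index[usable], col]).mean()) if n else np.nan
        out[f"{factor}_accuracy"] = acc
        out[f"{factor}_n"] = n
    dir_usable = (c["direction"] != "flat") & (t["direction"] != "flat")
    if dir_usable.any():
        out["direction_accuracy"] = float(
            (c.loc[dir_usable, "direction"] == t.loc[dir_usable, "direction"]).mean()
        )
    vc = c.loc[c["memory_effect"] != "not_applicable", "memory_effect"].value_counts()
    out["memory_label_counts"] = {k: int(v) for k, v in vc.items()}
    return out
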