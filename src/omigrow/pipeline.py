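"""End-to-end orchestration: simulate -> growth rates -> preprocess ->
benchmark -> importance -> combine -> retrain -> differential stats.

A run is fully determined by its :class:`RunConfig` (inputs or a
simulate spec, plus one master seed); rerunning the same config
reproduces every output table byte for byte. No timestamps are written
into any artifact for exactly that reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .diffstats import diff_abundance
from .errors import InputError
from .growth import curves_from_table, fit_all, fits_to_frame, growth_rate_table
from .importance import (
    CombinedImportance,
    ImportanceResult,
    combine_importance,
    permutation_importance,
    recovery_score,
    retrain_reduced,
)
from .models import benchmark, default_configs, fit_regressor
from .preprocess import build_locus_map, match_layers, standardize
from .synthetic import (
    SyntheticTruth,
    default_curve_params,
    generate_design,
    generate_growth_curves,
    generate_omics,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulateSpec:
    """Synthetic-scenario parameters for a pipeline run."""

    n_conditions: int = 14
    n_features: int = 1855
    n_planted: int = 8
    coupling: float = 0.8
    oxygen_shift: float = 0.0
    noise_sd: float = 0.05
    n_replicates: int = 3
    curve_noise_sd: float = 0.01


@dataclass
class InputPaths:
    """File inputs for a run on real (non-simulated) data."""

    transcriptomics: str
    proteomics: str
    growth: str  # rates table or tidy curve table
    growth_kind: str = "rates"  # "rates" | "curves"
    id_map: str | None = None
    design: str | None = None


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    outdir: str
    seed: int = 0
    simulate: SimulateSpec | None = None
    inputs: InputPaths | None = None
    k: int = 20
    n_repeats: int = 30
    alpha: float = 0.05
    panel: list[str] | None = None
    panel_size: int = 8

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise InputError("exactly one of simulate spec and input paths is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "simulate" in payload and payload["simulate"] is not None:
            payload["simulate"] = SimulateSpec(**payload["simulate"])
        if "inputs" in payload and payload["inputs"] is not None:
            payload["inputs"] = InputPaths(**payload["inputs"])
        return cls(**payload)


@dataclass
class RunReport:
    """In-memory record of one pipeline run; every table is also on disk."""

    config: RunConfig
    growth_rates: pd.Series
    benchmark: pd.DataFrame
    importance: dict[str, ImportanceResult]
    combined: CombinedImportance
    top_features: dict[str, list[str]]
    panel: list[str]
    reduced: pd.DataFrame
    diff_stats: pd.DataFrame
    recovery: float | None
    truth: SyntheticTruth | None
    provenance: dict


def _simulated_targets(spec: SimulateSpec, seed: int):
    design = generate_design(spec.n_conditions, seed=seed)
    trans, prot, rates_true, truth = generate_omics(
        design,
        n_features=spec.n_features,
        n_planted=spec.n_planted,
        coupling=spec.coupling,
        oxygen_shift=spec.oxygen_shift,
        noise_sd=spec.noise_sd,
        seed=seed,
    )
    params = default_curve_params(design, rates_true, seed=seed)
    curves = generate_growth_curves(
        design,
        params,
        noise_sd=spec.curve_noise_sd,
        n_replicates=spec.n_replicates,
        seed=seed,
    )
    return design, trans, prot, curves, truth


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; write all outputs under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: SyntheticTruth | None = None

    if config.simulate is not None:
        logger.info("stage simulate: %s (seed %d)", config.simulate, config.seed)
        design, trans, prot, curves, truth = _simulated_targets(config.simulate, config.seed)
        io.write_design(design, outdir / "design.tsv")
        io.write_matrix(trans, outdir / "transcriptomics.tsv")
        io.write_matrix(prot, outdir / "proteomics.tsv")
        io.write_growth_curves(curves, outdir / "growth_curves.tsv")
        io.write_truth(truth, outdir / "truth.yaml")
    else:
        inp = config.inputs
        trans = io.read_matrix(inp.transcriptomics, "transcriptomics")
        prot = io.read_matrix(inp.proteomics, "proteomics")
        design = io.read_design(inp.design) if inp.design else None
        curves = io.read_growth_curves(inp.growth) if inp.growth_kind == "curves" else None

    # Growth-rate targets: fit logistic curves when curves are the input.
    if curves is not None:
        fits = fit_all(curves_from_table(curves))
        fits_to_frame(fits).to_csv(outdir / "logistic_fits.tsv", sep=io.SEP)
        y = growth_rate_table(fits, design)
    else:
        y = io.read_rates(config.inputs.growth)
    y = y.loc[trans.condition_ids]
    io.write_rates(y, outdir / "growth_rates.tsv")

    # Preprocess: locus matching then per-feature standardization.
    if config.simulate is None and config.inputs.id_map:
        id_map = io.read_id_map(config.inputs.id_map)
    else:
        id_map = build_locus_map(trans.feature_ids, prot.feature_ids)
    trans_m, prot_m, id_map = match_layers(trans, prot, id_map)
    trans_s = standardize(trans_m)
    prot_s = standardize(prot_m)
    io.write_id_map(id_map, outdir / "id_map.tsv")

    # Benchmark the three families on both layers (in-sample protocol).
    configs = default_configs()
    logger.info(
        "stage fit: ANN %dx%d, %d iters, seed %d; RF %d trees; SVR %s C=%g eps=%g",
        configs[0].hidden_layers, configs[0].neurons_per_layer,
        configs[0].max_iterations, configs[0].seed,
        configs[1].n_estimators, configs[2].kernel, configs[2].C, configs[2].epsilon,
    )
    layers = {"transcriptomics": trans_s, "proteomics": prot_s}
    bench = benchmark(configs, layers, y)
    bench.to_csv(outdir / "benchmark.tsv", sep=io.SEP, index=False)

    # Permutation importance from the ANN (the best-performing family
    # in the protocol this package follows), per layer.
    ann = configs[0]
    importance: dict[str, ImportanceResult] = {}
    tops: dict[str, list[str]] = {}
    for layer, X in layers.items():
        model = fit_regressor(ann, X, y)
        imp = permutation_importance(
            model, X, y, n_repeats=config.n_repeats, seed=config.seed
        )
        importance[layer] = imp
        tops[layer] = imp.top(config.k)
        imp.table.to_csv(outdir / f"importance_{layer}.tsv", sep=io.SEP)
        io.write_panel(tops[layer], outdir / f"top{config.k}_{layer}.txt")

    combined = combine_importance(
        importance["transcriptomics"], importance["proteomics"], id_map
    )
    combined.table.to_csv(outdir / "combined_importance.tsv", sep=io.SEP)
    tops["combined"] = combined.top(config.k)
    io.write_panel(tops["combined"], outdir / f"top{config.k}_combined.txt")

    # Reduced panel: user-supplied, else the top of the combined ranking.
    panel = list(config.panel) if config.panel else combined.top(config.panel_size)
    io.write_panel(panel, outdir / "panel.txt")
    p2g = id_map.protein_to_gene()
    panel_genes = [p2g[p.casefold()] for p in panel]
    reduced_rows = []
    for layer, X, feats in (
        ("proteomics", prot_s, panel),
        ("transcriptomics", trans_s, panel_genes),
    ):
        full = bench.set_index(["layer", "family"]).loc[(layer, "ANN")]
        _, red = retrain_reduced(X, y, feats, ann)
        reduced_rows.append(
            {
                "layer": layer,
                "n_features_full": X.n_features,
                "panel_size": len(feats),
                "full_mae": float(full["mae"]),
                "reduced_mae": red.mae,
                "full_accuracy_pct": float(full["accuracy_pct"]),
                "reduced_accuracy_pct": red.accuracy_pct,
            }
        )
    reduced = pd.DataFrame(reduced_rows)
    reduced.to_csv(outdir / "reduced_comparison.tsv", sep=io.SEP, index=False)

    # Oxygen differential stats on raw matched proteomics, over the
    # top-k proteomics panel.
    diff = pd.DataFrame()
    if design is not None:
        diff = diff_abundance(
            prot_m, design, alpha=config.alpha, subset=tops["proteomics"]
        )
        diff.to_csv(outdir / "diff_stats.tsv", sep=io.SEP)

    recovery = None
    if truth is not None:
        recovery = recovery_score(truth, tops["combined"])
        logger.info("combined top-%d recovery of planted truth: %.3f", config.k, recovery)

    provenance = {
        "seed": config.seed,
        "k": config.k,
        "n_repeats": config.n_repeats,
        "alpha": config.alpha,
        "panel": panel,
        "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
        "inputs": dataclasses.asdict(config.inputs) if config.inputs else None,
        "model_configs": [dataclasses.asdict(c) for c in configs],
        "recovery_score": recovery,
        "n_conditions": len(y),
        "n_matched_features": trans_s.n_features,
    }
    (outdir / "report.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return RunReport(
        config=config,
        growth_rates=y,
        benchmark=bench,
        importance=importance,
        combined=combined,
        top_features=tops,
        panel=panel,
        reduced=reduced,
        diff_stats=diff,
        recovery=recovery,
        truth=truth,
        provenance=provenance,
    )
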