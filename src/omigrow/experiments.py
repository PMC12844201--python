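"""Self-contained validation studies for the pipeline's guarantees.

Because the methodology is exercised on synthetic data with planted
truth, its guarantees are checked by designed experiments rather than
by comparison to deposited measurements. Each function here runs one
such experiment end to end from a seed and returns plain numbers:

* Monte-Carlo vs exhaustive permutation-importance agreement on a toy
  where all n! permutations can be enumerated.
* Recovery of planted growth drivers by combined cross-layer top-k
  selection at the default study scale (14 conditions, 200 features
  per layer, 8 planted drivers, coupling 0.8, 5% growth noise).
* Logistic growth-rate recovery, noiseless and under OD noise.
* False-positive calibration of the oxygen differential test under a
  global null.
* In-sample accuracy of the planted reduced panel against random
  panels of the same size.

The problem sizes are deliberately moderate (hundreds of features, not
thousands) so that a full validation sweep runs on a laptop-class CPU
in minutes; the statistical structure, not the raw dimensionality, is
what the guarantees depend on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffstats import diff_abundance
from .growth import GrowthCurve, fit_logistic, logistic_od
from .importance import (
    combine_importance,
    exhaustive_importance,
    permutation_importance,
    recovery_score,
    retrain_reduced,
)
from .models import LinearPredictor, RegressorConfig, fit_regressor
from .preprocess import OmicsMatrix, build_locus_map, match_layers, standardize
from .synthetic import generate_design, generate_omics


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def importance_oracle_gap(seed: int = 0, n_repeats: int = 10_000) -> dict:
    """Monte-Carlo vs exhaustive importance on a 3-row, 2-feature toy.

    The predictor is the fixed linear map yhat = 2 * x1 (feature 2
    unused), so the exact importance of feature 1 is the average MSE
    increase over all 3! = 6 orderings of its column and feature 2's is
    exactly zero. Returns the Monte-Carlo estimate, the exact value and
    their relative gap.
    """
    X = pd.DataFrame({"x1": [0.0, 1.0, 2.0], "x2": [5.0, -3.0, 1.0]})
    y = np.array([0.0, 2.0, 4.0])  # y = 2*x1 exactly
    model = LinearPredictor([2.0, 0.0])
    exact = exhaustive_importance(model, X, y)
    mc = permutation_importance(model, X, y, n_repeats=n_repeats, seed=seed)
    e = float(exact.table.loc["x1", "mean_delta"])
    m = float(mc.table.loc["x1", "mean_delta"])
    return {
        "mc_mean_delta": m,
        "exact_mean_delta": e,
        "rel_err": abs(m - e) / e,
        "unused_feature_mc": float(mc.table.loc["x2", "mean_delta"]),
    }


def planted_recovery(
    n_replicates: int = 10,
    seed: int = 0,
    n_conditions: int = 14,
    n_features: int = 200,
    n_planted: int = 8,
    coupling: float = 0.8,
    noise_sd: float = 0.05,
    k: int = 20,
    n_repeats: int = 30,
) -> list[float]:
    """Recovery fraction of planted drivers per seeded replicate.

    Each replicate generates a fresh dual-layer dataset, trains the ANN
    on both standardized layers, computes permutation importance,
    combines across layers, and scores the combined top-k against the
    planted truth.
    """
    out = []
    for s in _child_seeds(seed, n_replicates):
        s = int(s)
        design = generate_design(n_conditions, seed=s)
        trans, prot, rates, truth = generate_omics(
            design,
            n_features=n_features,
            n_planted=n_planted,
            coupling=coupling,
            noise_sd=noise_sd,
            seed=s,
        )
        id_map = build_locus_map(trans.feature_ids, prot.feature_ids)
        trans_m, prot_m, id_map = match_layers(trans, prot, id_map)
        imps = {}
        for layer, m in (("t", trans_m), ("p", prot_m)):
            std = standardize(m)
            model = fit_regressor(RegressorConfig.ann(), std, rates)
            imps[layer] = permutation_importance(
                model, std, rates, n_repeats=n_repeats, seed=s
            )
        combined = combine_importance(imps["t"], imps["p"], id_map)
        out.append(recovery_score(truth, combined.top(k)))
    return out


def logistic_recovery_grid(
    K_values=(0.5, 1.0, 2.0),
    r_values=(0.1, 0.3, 0.6),
    od0_values=(0.01, 0.05, 0.1),
    timepoints=None,
) -> float:
    """Max relative parameter error over a noiseless (K, r, OD0) grid."""
    if timepoints is None:
        timepoints = np.linspace(0.0, 48.0, 17)
    worst = 0.0
    for K in K_values:
        for r in r_values:
            for od0 in od0_values:
                od = logistic_od(timepoints, K, r, od0)
                fit = fit_logistic(GrowthCurve("grid", timepoints, od))
                assert fit.converged
                worst = max(
                    worst,
                    abs(fit.K - K) / K,
                    abs(fit.r - r) / r,
                    abs(fit.od0 - od0) / od0,
                )
    return worst


def logistic_noise_study(
    n_seeds: int = 100,
    noise_sd: float = 0.01,
    K: float = 1.0,
    r: float = 0.5,
    od0: float = 0.1,
    seed: int = 0,
) -> dict:
    """Median fitted r under Gaussian OD noise, across seeded replicates."""
    t = np.linspace(0.0, 24.0, 13)
    clean = logistic_od(t, K, r, od0)
    estimates = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        noisy = np.maximum(clean + rng.normal(0.0, noise_sd, t.size), 1e-6)
        fit = fit_logistic(GrowthCurve("noisy", t, noisy))
        if fit.converged:
            estimates.append(fit.r)
    med = float(np.median(estimates))
    return {"median_r": med, "true_r": r, "rel_err": abs(med - r) / r}


def null_fdr_calibration(
    n_seeds: int = 20,
    n_features: int = 1000,
    group_size: int = 7,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean realized false-positive proportion under a global null.

    Both oxygen groups are drawn from one Gaussian, so every flagged
    feature is a false positive; BH at `alpha` should keep the flagged
    proportion near zero.
    """
    props = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        design = generate_design(2 * group_size, seed=int(s))
        values = rng.normal(100.0, 10.0, (2 * group_size, n_features))
        m = OmicsMatrix(
            "proteomics",
            pd.DataFrame(
                values,
                index=[c.condition_id for c in design],
                columns=[f"RPA{j:04d}" for j in range(n_features)],
            ),
        )
        res = diff_abundance(m, design, alpha=alpha)
        props.append(res["significant"].mean())
    return float(np.mean(props))


def reduced_vs_random_panels(
    seed: int = 0,
    n_random: int = 50,
    n_conditions: int = 14,
    n_features: int = 200,
    n_planted: int = 8,
    coupling: float = 0.8,
    noise_sd: float = 0.05,
) -> dict:
    """Planted-panel vs random-panel in-sample accuracy on one dataset.

    Retrains the ANN on the 8 planted proteins and on `n_random` random
    panels of the same size; returns both accuracies (the planted panel
    should not be beaten by the random-panel median).
    """
    design = generate_design(n_conditions, seed=seed)
    _, prot, rates, truth = generate_omics(
        design,
        n_features=n_features,
        n_planted=n_planted,
        coupling=coupling,
        noise_sd=noise_sd,
        seed=seed,
    )
    prot_s = standardize(prot)
    ann = RegressorConfig.ann()
    _, planted_metrics = retrain_reduced(prot_s, rates, truth.planted_features, ann)
    rng = np.random.default_rng(seed)
    rand_acc = []
    for _ in range(n_random):
        panel = list(rng.choice(prot_s.feature_ids, size=n_planted, replace=False))
        _, m = retrain_reduced(prot_s, rates, panel, ann)
        rand_acc.append(m.accuracy_pct)
    return {
        "planted_accuracy_pct": planted_metrics.accuracy_pct,
        "random_median_accuracy_pct": float(np.median(rand_acc)),
        "random_accuracies": rand_acc,
    }
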