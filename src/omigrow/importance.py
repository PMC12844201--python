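"""Permutation feature importance, cross-layer combination, panel retraining.

Permutation importance of feature j is the mean increase in prediction
loss when column j is randomly shuffled across samples while all other
columns stay fixed:

    delta_j = E_pi [ L(y, f(X with column j reordered by pi)) ] - L(y, f(X))

with the expectation over uniformly drawn permutations pi. The loss L
defaults to MSE (matching the benchmark metric family); MAE is
available. A feature the model ignores has importance exactly 0 in
expectation, and a constant column has importance exactly 0 always.

The estimator here is written from first principles rather than
delegated: permutations are sampled with replacement, one substream per
(feature, repeat) pair derived from the master seed, so results are
reproducible regardless of evaluation order or chunking. For small
sample counts :func:`exhaustive_importance` enumerates all n!
permutations and serves as the exact oracle the sampler must converge
to.

Cross-layer combination min-max normalizes each layer's mean deltas
over the matched loci to [0, 1] and sums them, yielding a combined
score in [0, 2] per gene/protein pair. A layer with all-equal scores
is mapped to 0.5 everywhere (preserving layer symmetry rather than
dividing by zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, MappingError
from .models import FitMetrics, RegressorConfig, as_feature_array, evaluate, fit_regressor
from .preprocess import IdMap, OmicsMatrix, resolve_features
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)


def _mse_rows(y: np.ndarray, preds: np.ndarray) -> np.ndarray:
    return ((preds - y) ** 2).mean(axis=-1)


def _mae_rows(y: np.ndarray, preds: np.ndarray) -> np.ndarray:
    return np.abs(preds - y).mean(axis=-1)


_LOSSES = {"mse": _mse_rows, "mae": _mae_rows}


@dataclass
class ImportanceResult:
    """Per-feature importance table, sorted by rank.

    ``table`` is indexed by feature ID with columns ``mean_delta``
    (mean loss increase), ``sd_delta`` and ``rank`` (1 = most
    important; ties broken by lexicographically smaller feature ID).
    """

    table: pd.DataFrame
    n_repeats: int
    scoring_loss: str
    baseline_loss: float

    def top(self, k: int) -> list[str]:
        return top_k(self, k)


def _feature_names(X) -> list[str]:
    if isinstance(X, OmicsMatrix):
        return X.feature_ids
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"f{j}" for j in range(np.asarray(X).shape[1])]


def _rank_table(df: pd.DataFrame, score_col: str) -> pd.DataFrame:
    # Descending score, ties resolved by ascending feature ID: sort by
    # ID first, then a stable sort on the score.
    out = df.sort_index().sort_values(score_col, ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def permutation_importance(
    model,
    X,
    y,
    n_repeats: int = 30,
    seed: int = 0,
    loss: str = "mse",
    max_block_rows: int = 200_000,
) -> ImportanceResult:
    """Monte-Carlo permutation importance for every feature of X.

    Parameters
    ----------
    model
        Anything with a ``predict`` method trained on X's feature space.
    n_repeats
        Shuffle repeats per feature (>= 1); the published protocol uses
        30.
    seed
        Master seed; the permutation for (feature j, repeat i) comes
        from the substream ``SeedSequence((seed, j, i))``, so any
        evaluation order gives identical results.
    loss
        ``"mse"`` (default) or ``"mae"``.
    max_block_rows
        Memory cap for the batched predict calls (rows per block).
    """
    if n_repeats < 1:
        raise InputError("n_repeats must be >= 1")
    if loss not in _LOSSES:
        raise InputError(f"loss must be one of {sorted(_LOSSES)}")
    if seed < 0:
        raise InputError("seed must be non-negative")
    loss_fn = _LOSSES[loss]
    V = as_feature_array(X)
    target = np.asarray(y, dtype=float).ravel()
    n, p = V.shape
    if target.size != n:
        raise InputError("X and y are misaligned")
    names = _feature_names(X)
    if len(names) != p:
        raise InputError("feature name count does not match matrix width")

    baseline = float(loss_fn(target, np.asarray(model.predict(V), float).ravel()))

    rows_per_feature = n_repeats * n
    chunk = max(1, max_block_rows // max(rows_per_feature, 1))
    deltas = np.empty((p, n_repeats))
    for start in range(0, p, chunk):
        stop = min(start + chunk, p)
        c = stop - start
        block = np.tile(V, (c * n_repeats, 1))
        for local_j, j in enumerate(range(start, stop)):
            for rep in range(n_repeats):
                rng = np.random.default_rng(np.random.SeedSequence((seed, j, rep)))
                perm = rng.permutation(n)
                r0 = (local_j * n_repeats + rep) * n
                block[r0 : r0 + n, j] = V[perm, j]
        preds = np.asarray(model.predict(block), float).reshape(c, n_repeats, n)
        deltas[start:stop] = loss_fn(target, preds) - baseline

    mean_delta = deltas.mean(axis=1)
    sd_delta = deltas.std(axis=1, ddof=1) if n_repeats > 1 else np.zeros(p)
    table = _rank_table(
        pd.DataFrame(
            {"mean_delta": mean_delta, "sd_delta": sd_delta},
            index=pd.Index(names, name="feature_id"),
        ),
        "mean_delta",
    )
    return ImportanceResult(table, n_repeats, loss, baseline)


def exhaustive_importance(model, X, y, loss: str = "mse") -> ImportanceResult:
    """Exact importance: average over ALL n! permutations per feature.

    The small-n oracle the Monte-Carlo sampler converges to. Guarded to
    n <= 8 rows (8! = 40320 predictions per feature).
    """
    if loss not in _LOSSES:
        raise InputError(f"loss must be one of {sorted(_LOSSES)}")
    loss_fn = _LOSSES[loss]
    V = as_feature_array(X)
    target = np.asarray(y, dtype=float).ravel()
    n, p = V.shape
    if n > 8:
        raise InputError("exhaustive enumeration is limited to n <= 8 rows")
    names = _feature_names(X)
    baseline = float(loss_fn(target, np.asarray(model.predict(V), float).ravel()))
    perms = np.array(list(_all_permutations(range(n))))
    mean_delta = np.empty(p)
    sd_delta = np.empty(p)
    for j in range(p):
        block = np.tile(V, (len(perms), 1))
        for b, perm in enumerate(perms):
            block[b * n : (b + 1) * n, j] = V[list(perm), j]
        preds = np.asarray(model.predict(block), float).reshape(len(perms), n)
        d = loss_fn(target, preds) - baseline
        mean_delta[j] = d.mean()
        sd_delta[j] = d.std(ddof=1)
    table = _rank_table(
        pd.DataFrame(
            {"mean_delta": mean_delta, "sd_delta": sd_delta},
            index=pd.Index(names, name="feature_id"),
        ),
        "mean_delta",
    )
    return ImportanceResult(table, len(perms), loss, baseline)


def top_k(imp: ImportanceResult, k: int) -> list[str]:
    """The k most important feature IDs (descending mean delta, ID tie-break)."""
    p = len(imp.table)
    if not 1 <= k <= p:
        raise InputError(f"k must lie in [1, {p}], got {k}")
    return list(imp.table.index[:k])


@dataclass
class CombinedImportance:
    """Cross-layer combined importance per matched gene/protein pair.

    ``table`` is indexed by protein ID with columns ``gene_id``,
    ``norm_trans_score``, ``norm_prot_score`` (each min-max normalized
    to [0, 1] over the matched set), ``combined_score`` (their sum, in
    [0, 2]) and ``rank``.
    """

    table: pd.DataFrame

    def top(self, k: int) -> list[str]:
        p = len(self.table)
        if not 1 <= k <= p:
            raise InputError(f"k must lie in [1, {p}], got {k}")
        return list(self.table.index[:k])


def _minmax(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def combine_importance(
    trans_imp: ImportanceResult, prot_imp: ImportanceResult, id_map: IdMap
) -> CombinedImportance:
    """Sum of per-layer min-max normalized importances per locus.

    Both results must cover exactly the loci of `id_map` (the matched
    feature sets); anything unmatched is reported.
    """
    g2p = id_map.gene_to_protein()
    trans_scores = {f.casefold(): v for f, v in trans_imp.table["mean_delta"].items()}
    prot_scores = {f.casefold(): v for f, v in prot_imp.table["mean_delta"].items()}

    missing = sorted(
        [g for g, _ in id_map.pairs if g.casefold() not in trans_scores]
        + [p for _, p in id_map.pairs if p.casefold() not in prot_scores]
    )
    extra = sorted(
        [f for f in trans_scores if f not in {g.casefold() for g, _ in id_map.pairs}]
        + [f for f in prot_scores if f not in {p.casefold() for _, p in id_map.pairs}]
    )
    if missing or extra:
        raise MappingError(
            f"importance results and map are misaligned; missing from results: "
            f"{missing[:5]}, unmapped features: {extra[:5]}"
        )

    genes = [g for g, _ in id_map.pairs]
    prots = [p for _, p in id_map.pairs]
    t = np.array([trans_scores[g.casefold()] for g in genes])
    q = np.array([prot_scores[p.casefold()] for p in prots])
    nt, nq = _minmax(t), _minmax(q)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "norm_trans_score": nt,
            "norm_prot_score": nq,
            "combined_score": nt + nq,
        },
        index=pd.Index(prots, name="protein_id"),
    )
    table = _rank_table(table, "combined_score")
    return CombinedImportance(table)


def retrain_reduced(
    X_full, y, panel: Sequence[str], config: RegressorConfig
) -> tuple[object, FitMetrics]:
    """Refit `config` on only the panel columns of X_full; return (model, metrics).

    `X_full` must be an OmicsMatrix or DataFrame so panel IDs can be
    resolved (case-insensitively). Metrics are in-sample, matching the
    full-model protocol, so the pair is directly comparable.
    """
    if len(panel) == 0:
        raise InputError("panel must contain at least one feature")
    if isinstance(X_full, OmicsMatrix):
        sub = X_full.subset(panel)
        arr = sub.values()
    elif isinstance(X_full, pd.DataFrame):
        cols = resolve_features([str(c) for c in X_full.columns], panel)
        arr = X_full.loc[:, cols].to_numpy(dtype=float)
    else:
        raise InputError("X_full must be an OmicsMatrix or DataFrame (named features)")
    model = fit_regressor(config, arr, y)
    metrics = evaluate(model, arr, y)
    logger.info(
        "reduced %s model on %d features: mae=%.4g accuracy=%.4g%%",
        config.family, len(panel), metrics.mae, metrics.accuracy_pct,
    )
    return model, metrics


def recovery_score(truth: SyntheticTruth, selected: Sequence[str]) -> float:
    """Fraction of planted features present in `selected` (case-insensitive).

    Only meaningful on synthetic runs where the truth is known; 1.0
    means every planted driver was recovered.
    """
    planted = {f.casefold() for f in truth.planted_features}
    if not planted:
        raise InputError("truth has no planted features")
    chosen = {f.casefold() for f in selected}
    return len(planted & chosen) / len(planted)
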