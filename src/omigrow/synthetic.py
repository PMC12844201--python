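"""Synthetic dual-layer omics data with planted growth drivers.

The study design this generator emulates: a phototrophic bacterium
grown on a panel of lignin breakdown products (three monolignols, two
acid derivatives, kraft lignin) plus an acetate control, under aerobic
and anaerobic regimes — fourteen condition combinations in the default
factorial. For each condition a transcript and a protein abundance
profile is drawn, and the growth rate is a known deterministic function
of a small set of planted protein abundances plus Gaussian noise, so
downstream feature-selection machinery can be scored against ground
truth.

Statistical structure:

* All features are log-normal (abundance data are right-skewed and
  strictly positive). Non-planted features are organized into
  co-expression modules — blocks sharing a latent expression program —
  because condition-series omics data are dominated by a handful of
  strong programs (the oxygen regime above all), not by independent
  genes.
* Planted features share a per-condition latent "growth potential"
  factor (cohesion 0.9 by default), emulating a tightly co-regulated
  driver cluster such as a transporter regulon.
* Transcript and protein values of one locus share their log-scale
  latent with mixing weight ``coupling``; the mixing is residualized so
  the *sample* log-scale correlation equals ``coupling`` exactly.
* Protein abundances are rescaled per feature to a mean of 100 across
  conditions, matching the conventional label-free normalization.
* An optional subset of non-planted features receives an additive
  between-oxygen-group mean shift of ``oxygen_shift`` (raw scale).

Randomness: separate named substreams for the design, the growth
curves and the omics matrices are derived from one master seed, so
changing one stage's parameters never perturbs another stage's draws.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InvalidDesignError, InvalidTruthError
from .growth import logistic_od
from .preprocess import OmicsMatrix

DEFAULT_SUBSTRATES = (
    "p-coumaryl alcohol",
    "coniferyl alcohol",
    "sinapyl alcohol",
    "p-coumarate",
    "sodium ferulate",
    "kraft lignin",
    "acetate",
)

#: Substrates catabolized without acetate co-feeding (acetate itself and
#: the one readily consumed acid derivative).
_NO_SUPPLEMENT = {"acetate", "p-coumarate"}

_STREAMS = {"design": 0, "curves": 1, "omics": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    if seed < 0:
        raise InputError("seeds must be non-negative integers")
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass(frozen=True)
class ConditionDesign:
    """One growth condition: substrate x oxygen regime."""

    condition_id: str
    substrate: str
    oxygen: str  # "aerobic" | "anaerobic"
    acetate_supplemented: bool


@dataclass
class SyntheticTruth:
    """Full record of the planted construction, for recovery scoring."""

    planted_features: list[str]
    layer_effects: dict[str, float]
    oxygen_shifted_features: list[str]
    growth_function: dict
    noise_sd: float
    seed: int
    gene_ids: dict[str, str] = field(default_factory=dict)  # protein -> gene tag


def generate_design(
    n_conditions: int = 14,
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    oxygen_split: float = 0.5,
    seed: int = 0,
) -> list[ConditionDesign]:
    """Enumerate a substrate x oxygen condition design.

    Substrates are cycled in order; the first ``round(n * oxygen_split)``
    conditions are aerobic (clamped so both oxygen levels appear
    whenever ``0 < oxygen_split < 1``). With 14 conditions and the 7
    default substrates this yields the full factorial. The layout is a
    deterministic function of its arguments; `seed` is accepted for
    interface symmetry with the other generators.
    """
    _rng(seed, "design")  # validates the seed
    if n_conditions < 2:
        raise InvalidDesignError(f"need at least 2 conditions, got {n_conditions}")
    if not substrates:
        raise InvalidDesignError("substrate list must be non-empty")
    if not 0.0 <= oxygen_split <= 1.0:
        raise InvalidDesignError("oxygen_split must lie in [0, 1]")
    n_aerobic = int(round(n_conditions * oxygen_split))
    if 0.0 < oxygen_split < 1.0:
        n_aerobic = min(max(n_aerobic, 1), n_conditions - 1)
    seen: Counter[str] = Counter()
    design = []
    for i in range(n_conditions):
        substrate = substrates[i % len(substrates)]
        oxygen = "aerobic" if i < n_aerobic else "anaerobic"
        base = f"{substrate.lower().replace(' ', '-')}_{oxygen}"
        seen[base] += 1
        cid = base if seen[base] == 1 else f"{base}_{seen[base]}"
        design.append(
            ConditionDesign(cid, substrate, oxygen, substrate not in _NO_SUPPLEMENT)
        )
    return design


def generate_growth_curves(
    design: Sequence[ConditionDesign],
    logistic_params: Mapping[str, tuple[float, float, float]],
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    timepoints: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate OD660 logistic growth curves.

    Parameters
    ----------
    logistic_params
        Per condition ID a ``(K, r, OD0)`` triple with K > OD0 > 0 and
        r > 0.
    noise_sd
        Gaussian measurement noise on OD readings (OD units); with
        ``noise_sd=0`` every replicate lies exactly on the logistic.
    timepoints
        Strictly increasing sampling times in hours; default 0..72 h
        every 3 h.

    Returns
    -------
    Tidy DataFrame with columns ``condition_id, replicate, time_h,
    od660`` (replicates numbered from 1).
    """
    rng = _rng(seed, "curves")
    if timepoints is None:
        timepoints = np.arange(0.0, 73.0, 3.0)
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise InputError("timepoints must be strictly increasing")
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    rows = []
    for cond in design:
        try:
            K, r, od0 = logistic_params[cond.condition_id]
        except KeyError:
            raise InputError(f"no logistic parameters for condition {cond.condition_id}")
        if not (K > od0 > 0) or not r > 0:
            raise InputError(
                f"{cond.condition_id}: logistic parameters must satisfy K > OD0 > 0, r > 0"
            )
        clean = logistic_od(t, K, r, od0)
        for rep in range(1, n_replicates + 1):
            noisy = clean + (rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0)
            noisy = np.maximum(noisy, 0.0)
            rows.append(
                pd.DataFrame(
                    {
                        "condition_id": cond.condition_id,
                        "replicate": rep,
                        "time_h": t,
                        "od660": noisy,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _locus_tags(n_features: int) -> tuple[list[str], list[str]]:
    width = max(4, len(str(n_features)))
    genes = [f"rpa{i:0{width}d}" for i in range(1, n_features + 1)]
    prots = [f"RPA{i:0{width}d}" for i in range(1, n_features + 1)]
    return genes, prots


def _exact_corr_mix(z: np.ndarray, eta: np.ndarray, coupling: float) -> np.ndarray:
    """Mix `eta` into standardized `z` so each column's sample corr with z equals `coupling`.

    Residualizes eta against z per column (Gram-Schmidt) before mixing;
    requires >= 3 rows for the residual to have positive variance.
    """
    zs = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    if coupling >= 1.0:
        return zs
    proj = (eta * zs).mean(axis=0)
    resid = eta - proj * zs
    sd = resid.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    rs = (resid - resid.mean(axis=0)) / sd
    return coupling * zs + np.sqrt(1.0 - coupling**2) * rs


def generate_omics(
    design: Sequence[ConditionDesign],
    n_features: int = 1855,
    n_planted: int = 8,
    effect_sizes: Sequence[float] | None = None,
    coupling: float = 0.8,
    oxygen_shift: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    n_oxygen_shifted: int = 10,
    growth_model: str = "saturating",
    baseline_rate: float = 0.05,
    planted_cohesion: float = 0.9,
    module_size: int = 25,
    module_cor: float = 0.7,
    log_sigma: float = 0.5,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.Series, SyntheticTruth]:
    """Generate paired transcript/protein matrices plus growth rates and truth.

    Parameters
    ----------
    design
        Condition list from :func:`generate_design` (>= 3 conditions).
    n_features, n_planted
        Features per layer and number of planted growth drivers
        (1 <= n_planted < n_features).
    effect_sizes
        Per-planted-feature weight on the growth rate (1/h units);
        default draws U(0.02, 0.06) per feature.
    coupling
        Log-scale sample correlation between a locus' transcript and
        protein values, in [0, 1].
    oxygen_shift
        Additive raw-scale abundance shift applied to aerobic conditions
        for `n_oxygen_shifted` non-planted features (0 disables).
    noise_sd
        Growth-rate noise, as a fraction of the spread (population SD
        across conditions) of the noiseless rates.
    growth_model
        ``"saturating"``: rate = baseline + sum_j w_j * a_j/(a_j + h_j)
        with h_j the feature's median abundance (Michaelis-type,
        bounded, monotone). ``"linear"``: rate = baseline +
        sum_j w_j * a_j/100 (kept for closed-form oracle work).
    planted_cohesion
        Correlation of each planted feature's log-latent with the
        shared growth-potential factor.
    module_size, module_cor
        Background co-expression structure: non-planted features form
        modules of `module_size` whose log-latents correlate
        `module_cor` with a module-specific expression program
        (`module_cor=0` gives an independent background).

    Returns
    -------
    (transcriptomics, proteomics, growth_rates, truth)
        Proteomics feature means are exactly 100; growth rates are
        keyed by condition ID; `truth` records the whole construction.
    """
    rng = _rng(seed, "omics")
    n_c = len(design)
    if n_c < 3:
        raise InvalidDesignError("omics generation needs at least 3 conditions")
    if not 1 <= n_planted < n_features:
        raise InvalidTruthError(
            f"need 1 <= n_planted < n_features, got {n_planted} of {n_features}"
        )
    if not 0.0 <= coupling <= 1.0:
        raise InputError("coupling must lie in [0, 1]")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if growth_model not in ("saturating", "linear"):
        raise InputError("growth_model must be 'saturating' or 'linear'")

    cids = [c.condition_id for c in design]
    if len(set(cids)) != n_c:
        raise InvalidDesignError("condition IDs must be unique")
    gene_ids, prot_ids = _locus_tags(n_features)

    if not 0.0 <= planted_cohesion <= 1.0 or not 0.0 <= module_cor < 1.0:
        raise InputError("planted_cohesion must lie in [0, 1], module_cor in [0, 1)")

    planted_idx = np.sort(rng.choice(n_features, size=n_planted, replace=False))
    # Latent structure: common growth-potential factor for planted loci,
    # module-specific expression programs for the background.
    g = rng.standard_normal(n_c)
    z = rng.standard_normal((n_c, n_features))
    rho = planted_cohesion
    z[:, planted_idx] = rho * g[:, None] + np.sqrt(1.0 - rho**2) * z[:, planted_idx]
    if module_cor > 0.0:
        non_planted_idx = np.setdiff1d(np.arange(n_features), planted_idx)
        for start in range(0, non_planted_idx.size, max(module_size, 1)):
            block = non_planted_idx[start : start + module_size]
            program = rng.standard_normal(n_c)
            z[:, block] = (
                module_cor * program[:, None]
                + np.sqrt(1.0 - module_cor**2) * z[:, block]
            )

    eta = rng.standard_normal((n_c, n_features))
    t_latent = _exact_corr_mix(z, eta, coupling)
    zs = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)

    # Log-normal abundances. Protein per-feature scale is irrelevant (the
    # mean-100 rescaling removes it); transcripts get a per-feature scale.
    prot_raw = np.exp(log_sigma * zs)
    trans_scale = np.exp(rng.normal(np.log(200.0), 0.7, n_features))
    trans = trans_scale * np.exp(log_sigma * t_latent)

    shifted_idx = np.array([], dtype=int)
    if oxygen_shift != 0.0:
        non_planted = np.setdiff1d(np.arange(n_features), planted_idx)
        k = min(n_oxygen_shifted, non_planted.size)
        shifted_idx = np.sort(rng.choice(non_planted, size=k, replace=False))
        aerobic = np.array([c.oxygen == "aerobic" for c in design])
        if aerobic.any() and (~aerobic).any():
            # Calibrated so the between-group mean difference equals
            # oxygen_shift exactly (the random baselines are netted out).
            for mat in (prot_raw, trans):
                d0 = mat[np.ix_(aerobic, shifted_idx)].mean(axis=0) - mat[
                    np.ix_(~aerobic, shifted_idx)
                ].mean(axis=0)
                mat[np.ix_(aerobic, shifted_idx)] += oxygen_shift - d0
            prot_raw = np.maximum(prot_raw, 0.0)
            trans = np.maximum(trans, 0.0)

    col_means = prot_raw.mean(axis=0)
    prot = prot_raw * (100.0 / col_means)

    if effect_sizes is None:
        weights = rng.uniform(0.02, 0.06, n_planted)
    else:
        weights = np.asarray(effect_sizes, dtype=float)
        if weights.shape != (n_planted,):
            raise InvalidTruthError(
                f"effect_sizes must have length n_planted={n_planted}"
            )

    planted_ab = prot[:, planted_idx]
    half_sat = np.median(planted_ab, axis=0)
    if growth_model == "saturating":
        s = planted_ab / (planted_ab + half_sat)
    else:
        s = planted_ab / 100.0
    growth_det = baseline_rate + s @ weights
    spread = float(growth_det.std(ddof=0))
    noise = rng.normal(0.0, noise_sd * spread, n_c) if noise_sd > 0 else 0.0
    rates = pd.Series(
        np.maximum(growth_det + noise, 0.0),
        index=pd.Index(cids, name="condition_id"),
        name="growth_rate",
    )

    trans_m = OmicsMatrix(
        "transcriptomics", pd.DataFrame(trans, index=cids, columns=gene_ids)
    )
    prot_m = OmicsMatrix("proteomics", pd.DataFrame(prot, index=cids, columns=prot_ids))

    planted_prots = [prot_ids[j] for j in planted_idx]
    truth = SyntheticTruth(
        planted_features=planted_prots,
        layer_effects={prot_ids[j]: float(w) for j, w in zip(planted_idx, weights)},
        oxygen_shifted_features=[prot_ids[j] for j in shifted_idx],
        growth_function={
            "type": growth_model,
            "baseline_rate": baseline_rate,
            "weights": {prot_ids[j]: float(w) for j, w in zip(planted_idx, weights)},
            "half_saturation": {
                prot_ids[j]: float(h) for j, h in zip(planted_idx, half_sat)
            },
            "planted_cohesion": planted_cohesion,
            "module_size": module_size,
            "module_cor": module_cor,
            "coupling": coupling,
        },
        noise_sd=noise_sd,
        seed=seed,
        gene_ids={prot_ids[j]: gene_ids[j] for j in planted_idx},
    )
    return trans_m, prot_m, rates, truth


def default_curve_params(
    design: Sequence[ConditionDesign],
    rates: pd.Series,
    seed: int = 0,
    od0: float = 0.05,
) -> dict[str, tuple[float, float, float]]:
    """Per-condition (K, r, OD0) with r taken from generated growth rates.

    Carrying capacities are drawn U(0.8, 1.2) OD units from the curve
    substream, so the same master seed reproduces the same curves.
    """
    rng = _rng(seed, "curves")
    params = {}
    for cond in design:
        K = float(rng.uniform(0.8, 1.2))
        params[cond.condition_id] = (K, float(rates[cond.condition_id]), od0)
    return params
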