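"""Logistic growth-curve fitting and per-condition growth-rate targets.

Optical-density time series are summarized by the three-parameter
logistic model

    OD(t) = K / (1 + ((K - OD0) / OD0) * exp(-r t))

with carrying capacity ``K`` (OD660 units), intrinsic growth rate ``r``
(1/h) and initial density ``OD0``. The fitted ``r`` per condition is
the regression target for the downstream models.

Replicates are averaged before fitting by default (growth curves in
batch-culture studies are conventionally reported as replicate means);
pooled per-point fitting is available via ``replicates="pooled"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateCurveError, IncompleteTargetsError, InputError

logger = logging.getLogger(__name__)


def logistic_od(t: np.ndarray, K: float, r: float, od0: float) -> np.ndarray:
    """Three-parameter logistic OD(t)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - od0) / od0) * np.exp(-r * t))


@dataclass
class GrowthCurve:
    """OD660 time series for one condition, replicate-resolved.

    ``od`` has shape (n_replicates, n_timepoints); readings are
    non-negative and every replicate is sampled at the shared ``times``.
    """

    condition_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise InputError(f"{self.condition_id}: timepoints must be strictly increasing")
        if self.od.shape[1] != self.times.size:
            raise InputError(
                f"{self.condition_id}: replicate arrays must match timepoint count"
            )
        if np.any(self.od < 0):
            raise InputError(f"{self.condition_id}: OD readings must be non-negative")

    @property
    def mean_od(self) -> np.ndarray:
        return self.od.mean(axis=0)


@dataclass
class LogisticFit:
    """Result of a least-squares logistic fit.

    When ``converged`` the parameters satisfy K > 0, r >= 0, OD0 > 0;
    otherwise they are NaN and ``message`` holds the diagnostic.
    """

    K: float
    r: float
    od0: float
    rss: float
    converged: bool
    message: str = ""


def curves_from_table(table: pd.DataFrame) -> list[GrowthCurve]:
    """Build :class:`GrowthCurve` objects from a tidy curve table.

    Expects columns ``condition_id``, ``replicate``, ``time_h``,
    ``od660`` (the on-disk format written by the synthetic generator).
    """
    required = {"condition_id", "replicate", "time_h", "od660"}
    if not required.issubset(table.columns):
        raise InputError(f"curve table must have columns {sorted(required)}")
    curves = []
    for cid, sub in table.groupby("condition_id", sort=True):
        wide = sub.pivot(index="replicate", columns="time_h", values="od660").sort_index()
        if wide.isna().any().any():
            raise InputError(f"{cid}: replicates do not share a common time grid")
        curves.append(GrowthCurve(str(cid), wide.columns.to_numpy(float), wide.to_numpy(float)))
    return curves


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # K slightly above the peak, OD0 from the first reading, r from a
    # log-linear fit to the sub-half-maximum (early exponential) phase.
    K0 = 1.05 * float(y.max())
    od00 = max(float(y[0]), 1e-6 * K0)
    early = (y > 0) & (y <= 0.5 * K0)
    if early.sum() >= 2:
        slope = np.polyfit(t[early], np.log(y[early]), 1)[0]
        r0 = float(max(slope, 1e-3))
    else:
        r0 = 0.1
    return K0, r0, od00


def fit_logistic(curve: GrowthCurve, replicates: str = "mean") -> LogisticFit:
    """Least-squares fit of the three-parameter logistic model.

    Parameters
    ----------
    curve
        Replicate-resolved OD trace; needs >= 4 distinct timepoints.
    replicates
        ``"mean"`` fits the replicate-mean trace (default); ``"pooled"``
        stacks all replicate points into one residual vector.

    Raises
    ------
    DegenerateCurveError
        For flat traces or too few timepoints. Optimizer failure does
        NOT raise: it returns ``converged=False`` with diagnostics.
    """
    if replicates not in ("mean", "pooled"):
        raise InputError("replicates must be 'mean' or 'pooled'")
    if np.unique(curve.times).size < 4:
        raise DegenerateCurveError(
            f"{curve.condition_id}: need >= 4 distinct timepoints, got {curve.times.size}"
        )
    if replicates == "mean":
        t, y = curve.times, curve.mean_od
    else:
        t = np.tile(curve.times, curve.od.shape[0])
        y = curve.od.ravel()
    if np.ptp(y) == 0.0:
        raise DegenerateCurveError(f"{curve.condition_id}: flat OD trace cannot be fitted")
    p0 = _initial_guess(curve.times, curve.mean_od)
    try:
        popt, _ = curve_fit(
            logistic_od,
            t,
            y,
            p0=p0,
            bounds=([1e-9, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=20000,
        )
    except RuntimeError as exc:  # scipy signals non-convergence this way
        logger.warning("logistic fit failed for %s: %s", curve.condition_id, exc)
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    K, r, od0 = (float(v) for v in popt)
    rss = float(np.sum((logistic_od(t, K, r, od0) - y) ** 2))
    return LogisticFit(K, r, od0, rss, True)


def fit_all(curves: Iterable[GrowthCurve], replicates: str = "mean") -> dict[str, LogisticFit]:
    """Fit every curve, keyed by condition ID."""
    out: dict[str, LogisticFit] = {}
    for c in curves:
        if c.condition_id in out:
            raise InputError(f"duplicate condition ID in curves: {c.condition_id}")
        out[c.condition_id] = fit_logistic(c, replicates=replicates)
    return out


def growth_rate_table(
    fits: Mapping[str, LogisticFit], design: Sequence | None = None
) -> pd.Series:
    """Per-condition growth-rate vector (1/h) from converged fits.

    `design` may be a list of condition IDs or of objects with a
    ``condition_id`` attribute; it fixes the output order and requires
    every listed condition to have a converged fit.

    Raises
    ------
    IncompleteTargetsError
        Listing the conditions that are missing or unconverged.
    """
    if design is None:
        wanted = list(fits)
    else:
        wanted = [getattr(c, "condition_id", c) for c in design]
    if len(set(wanted)) != len(wanted):
        raise InputError("duplicate condition IDs in design")
    if not wanted:
        raise IncompleteTargetsError("no conditions to tabulate")
    bad = [c for c in wanted if c not in fits or not fits[c].converged]
    if bad:
        raise IncompleteTargetsError(f"missing or unconverged fits for conditions: {bad}")
    rates = pd.Series(
        [fits[c].r for c in wanted], index=pd.Index(wanted, name="condition_id"),
        name="growth_rate", dtype=float,
    )
    if not np.isfinite(rates).all() or (rates < 0).any():
        raise IncompleteTargetsError("fitted rates must be finite and non-negative")
    return rates


def fits_to_frame(fits: Mapping[str, LogisticFit]) -> pd.DataFrame:
    """Tabular view of fits (condition_id, rate_per_h, K, od0, rss, converged)."""
    rows = [
        {
            "condition_id": cid,
            "rate_per_h": f.r,
            "K": f.K,
            "od0": f.od0,
            "rss": f.rss,
            "converged": f.converged,
        }
        for cid, f in fits.items()
    ]
    return pd.DataFrame(rows).set_index("condition_id")


def flag_above_control(curves: Iterable[GrowthCurve], control_id: str) -> pd.Series:
    """Flag conditions whose peak mean OD strictly exceeds the control's.

    Cultures of poorly bioavailable substrates are often supplemented
    with acetate; growth is attributed to the substrate only when the
    culture surpasses the acetate-only positive control. The control
    itself is flagged False. Comparison is strict (must exceed, not
    merely equal).
    """
    curves = list(curves)
    peaks = {c.condition_id: float(c.mean_od.max()) for c in curves}
    if control_id not in peaks:
        raise InputError(f"control condition {control_id!r} not among curves")
    control_peak = peaks[control_id]
    flags = {
        cid: (peak > control_peak) and cid != control_id for cid, peak in peaks.items()
    }
    return pd.Series(flags, name="above_control").sort_index()
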