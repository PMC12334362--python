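"""Empirical stability indicators and their regression diagnostics.

Theoretical indices (required diagonal strength S, maximum loop weight
MLW) need the full interaction-strength matrix.  For management use a
biomass-only proxy is attractive: the geometric-mean predator/prey biomass
ratio over a set of trophic pairs,

    BCBP_t = geomean(B_pred,1 … B_pred,k) / geomean(B_prey,1 … B_prey,k),

tracks S because heavier tops of the biomass pyramid strengthen the
destabilizing omnivorous feedbacks.  This module computes biomass ratios,
BCBP, simple-regression R², and multi-period trend reports (including a
regime-shift flag when the identity of the heaviest loop changes).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .webmodel import FoodWeb, WebValidationError

__all__ = [
    "biomass_ratio",
    "bcbp",
    "rsquared",
    "regression_report",
    "stability_trend_report",
    "grazing_detritus_deviation",
]


def biomass_ratio(web: FoodWeb, predator: str, prey: str) -> float:
    """B_predator / B_prey; the prey may be the detritus pool."""
    bp = web.group(prey).biomass
    if bp <= 0:
        raise WebValidationError(f"prey {prey!r} has non-positive biomass")
    return web.group(predator).biomass / bp


def bcbp(
    web: FoodWeb, pairs: Sequence[tuple[str, str]] | None = None
) -> float:
    """Geometric-mean predator/prey biomass ratio over a pair set.

    ``pairs`` is a list of ``(predator, prey)`` names; by default every
    direct trophic link of the web (detritus links included).  With a single
    pair this reduces exactly to :func:`biomass_ratio`.
    """
    if pairs is None:
        pairs = [
            (pred, prey)
            for (prey, pred), w in web.diet.entries.items()
            if w > 0
        ]
    if not pairs:
        raise WebValidationError("BCBP needs at least one predator-prey pair")
    preds = np.array([web.group(p).biomass for p, _ in pairs])
    preys = np.array([web.group(q).biomass for _, q in pairs])
    k = len(pairs)
    # per-pair ratio product keeps the single-pair case exactly equal to
    # biomass_ratio and avoids overflow for long pair lists
    return float(np.prod((preds / preys) ** (1.0 / k)))


def rsquared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of the simple linear regression of y on
    x (untransformed values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        return 0.0
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def regression_report(x: Sequence[float], y: Sequence[float]) -> dict:
    """Slope, intercept, R² and p-value of the linear fit of y on x."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }


def stability_trend_report(series: pd.DataFrame) -> dict:
    """Trend diagnostics for a multi-period indicator series.

    ``series`` has one row per period with at least ``required_s``; optional
    columns ``mlw``, ``mlw_loop``, ``bcbp`` and any ``pbr_*`` ratio columns
    are folded in.  Reports per-period deltas, each indicator's R² against
    required_s, a regime-shift flag at periods where the heaviest loop's
    identity changes, and concordance of each indicator's trend with the
    stability trend.
    """
    if len(series) < 2:
        raise ValueError("trend analysis needs at least two periods")
    s = series["required_s"].to_numpy(dtype=float)
    periods = [str(p) for p in (series.index if series.index.name or
               not isinstance(series.index, pd.RangeIndex)
               else range(len(series)))]
    report: dict = {
        "periods": periods,
        "deltas": {"required_s": np.diff(s).tolist()},
        "r_squared_vs_s": {},
        "regime_shift_periods": [],
        "concordant_trend": {},
    }
    indicator_cols = [
        c for c in series.columns
        if c not in ("required_s", "mlw_loop") and
        pd.api.types.is_numeric_dtype(series[c])
    ]
    for c in indicator_cols:
        v = series[c].to_numpy(dtype=float)
        report["deltas"][c] = np.diff(v).tolist()
        if len(series) >= 3 and np.ptp(v) > 0 and np.ptp(s) > 0:
            report["r_squared_vs_s"][c] = rsquared(v, s)
        report["concordant_trend"][c] = bool(
            np.all(np.sign(np.diff(v)) == np.sign(np.diff(s)))
        )
    if "mlw_loop" in series.columns:
        labels = series["mlw_loop"].astype(str).tolist()
        report["regime_shift_periods"] = [
            periods[i]
            for i in range(1, len(labels))
            if labels[i] != labels[i - 1]
        ]
    return report


def grazing_detritus_deviation(
    s_detritus: Sequence[float], s_grazing: Sequence[float]
) -> dict:
    """Per-period relative deviation |S_det − S_graz| / S_det between the
    two matrix variants, with the mean (as a percentage)."""
    sd = np.asarray(s_detritus, float)
    sg = np.asarray(s_grazing, float)
    if sd.shape != sg.shape:
        raise ValueError("series lengths differ")
    rel = np.abs(sd - sg) / sd
    return {
        "per_period_percent": (100 * rel).tolist(),
        "mean_percent": float(100 * rel.mean()),
    }
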