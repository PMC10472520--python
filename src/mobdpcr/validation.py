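"""Dilution-series quality metrics for digital-PCR validation.

Three metrics summarize a serial-dilution experiment: the per-level
coefficient of variation of replicate estimates (CV = sample SD /
mean, as a percentage), the linearity of estimated versus expected
copies (OLS slope, intercept, R^2 and a pointwise 95% confidence band
for the mean response), and the per-level accuracy ratio
log10(estimated) / log10(predicted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .quant import ChipCounts, estimate_copies

__all__ = ["cv", "linearity", "log_ratio", "LinearFit", "summarize_series"]


def cv(values) -> float:
    """Coefficient of variation in percent: sample SD (n-1) over mean x 100."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need at least 2 finite values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(x.std(ddof=1) / mean * 100.0)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    band_x: np.ndarray  # sorted expected values
    band_low: np.ndarray  # pointwise 95% band for the mean response
    band_high: np.ndarray


def linearity(expected, estimated) -> LinearFit:
    """OLS of estimated on expected copies with a 95% mean-response band."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct expected values")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    order = np.argsort(x)
    pred = fit.get_prediction(X[order]).conf_int(alpha=0.05)
    return LinearFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        band_x=x[order],
        band_low=pred[:, 0],
        band_high=pred[:, 1],
    )


def log_ratio(estimated: float, predicted: float) -> float:
    """Accuracy ratio log10(estimated) / log10(predicted)."""
    if estimated <= 0 or predicted <= 0:
        raise ValueError("copies must be positive")
    denom = np.log10(predicted)
    if denom == 0:
        raise ValueError("predicted = 1 gives a zero log denominator")
    return float(np.log10(estimated) / denom)


def summarize_series(
    series: pd.DataFrame,
    volume_cv: float = 0.0,
    *,
    log_scale: bool = False,
) -> tuple[pd.DataFrame, LinearFit]:
    """Quantify a tidy series table and compute per-level CV and accuracy.

    ``series`` needs columns concentration, replicate, expected_copies,
    n_total, n_positive (and optionally loaded_volume_ul) — the layout
    written by :func:`mobdpcr.simulate.simulate_series`. Returns one row
    per level (mean estimate, CV %, log-ratio) plus the linear fit of
    estimated vs expected copies (raw scale by default; ``log_scale``
    regresses log10 against log10).
    """
    est = []
    for _, row in series.iterrows():
        counts = ChipCounts(
            n_total=int(row["n_total"]),
            n_positive=int(row["n_positive"]),
            loaded_volume_ul=float(row.get("loaded_volume_ul", 14.5)),
        )
        est.append(estimate_copies(counts, volume_cv).copies_chip)
    df = series.copy()
    df["estimated_copies"] = est

    rows = []
    for (conc, expected), grp in df.groupby(["concentration", "expected_copies"]):
        vals = grp["estimated_copies"].to_numpy()
        rows.append(
            {
                "concentration": conc,
                "expected_copies": expected,
                "mean_estimated": vals.mean(),
                "cv_percent": cv(vals) if vals.size >= 2 else np.nan,
                "log_ratio": log_ratio(vals.mean(), expected),
            }
        )
    levels = pd.DataFrame(rows).sort_values("expected_copies", ignore_index=True)
    if log_scale:
        fit = linearity(
            np.log10(df["expected_copies"]), np.log10(df["estimated_copies"])
        )
    else:
        fit = linearity(df["expected_copies"], df["estimated_copies"])
    return levels, fit
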