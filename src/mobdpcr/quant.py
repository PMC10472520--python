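"""Absolute quantification from digital-PCR partition counts.

A chip partitions the reaction into N wells; after end-point PCR each
well is classified positive or negative from its fluorescence. With
molecules distributed independently at mean lambda copies per well, the
negative fraction is e^-lambda, so lambda_hat = -ln(1 - k/N) (plain
Poisson). Real chips have well-to-well volume variability; with volume
coefficient of variation eta the expected negative fraction becomes
E[exp(-lambda V/Vbar)], implemented here to second order in the volume
moments as exp(-lambda + lambda^2 eta^2 / 2) and inverted by bracketed
root finding (the volume-corrected, "Poisson-Plus"-style estimator). At
eta = 0 it reduces exactly to the plain Poisson estimator.

Confidence intervals are delta-method on the positive fraction:
SE(lambda_hat) = sqrt(p / (N (1 - p))), with an exact binomial
inversion available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assay import Assay

__all__ = [
    "ChipCounts",
    "QuantResult",
    "NoSeparationError",
    "classify_wells",
    "estimate_copies",
    "convert_units",
    "quantify_table",
]


class NoSeparationError(ValueError):
    """Fluorescence distribution shows no usable positive/negative split."""


@dataclass(frozen=True)
class ChipCounts:
    """Well summary of one chip."""

    n_total: int
    n_positive: int
    loaded_volume_ul: float = 14.5
    classification: str = "auto"  # "auto" or "manual"
    threshold: float | None = None
    quality_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if self.loaded_volume_ul <= 0:
            raise ValueError("loaded_volume_ul must be positive")
        object.__setattr__(self, "quality_flags", frozenset(self.quality_flags))


@dataclass(frozen=True)
class QuantResult:
    """Copy-number estimate for one chip."""

    lambda_hat: float  # mean copies per well; NaN when saturated
    copies_chip: float  # copies in the loaded volume
    conc_per_ul_mix: float  # copies per uL of reaction mix
    ci95: tuple[float, float]  # on copies_chip
    estimator: str  # "poisson" or "poisson_plus(cv=...)"
    flags: frozenset = frozenset()
    n_total: int = 0
    n_positive: int = 0
    loaded_volume_ul: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))


def _otsu_threshold(values: np.ndarray) -> float:
    """Exact between-class-variance-maximizing split of the intensities.

    Computed on the sorted values rather than a binned histogram so the
    threshold cannot land a bin-edge away from an isolated well; the
    returned threshold is the midpoint of the optimal split gap.
    """
    s = np.sort(values)
    n = s.size
    w = np.arange(1, n) / n
    csum = np.cumsum(s)[:-1]
    mu_lo = csum / np.arange(1, n)
    mu_hi = (s.sum() - csum) / (n - np.arange(1, n))
    between = w * (1.0 - w) * (mu_lo - mu_hi) ** 2
    i = int(np.argmax(between))
    return float((s[i] + s[i + 1]) / 2.0)


def _separation_score(values: np.ndarray, threshold: float) -> float:
    """Gap between class means over the pooled within-class SD."""
    lo = values[values <= threshold]
    hi = values[values > threshold]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    pooled = math.sqrt((lo.var(ddof=0) + hi.var(ddof=0)) / 2.0)
    if pooled == 0.0:
        return math.inf if hi.mean() > lo.mean() else 0.0
    return float((hi.mean() - lo.mean()) / pooled)


def classify_wells(
    intensities,
    method: str = "auto",
    threshold: float | None = None,
    *,
    loaded_volume_ul: float = 14.5,
    min_separation: float = 2.0,
) -> ChipCounts:
    """Split per-well fluorescence into positive/negative counts.

    ``auto`` picks the threshold maximizing between-class variance on the
    intensity histogram (Otsu); if the resulting separation score (gap
    between component means over pooled SD) falls below
    ``min_separation`` the automatic call is rejected: a supplied manual
    ``threshold`` is applied instead (flagged ``no_separation``), and
    without one a :class:`NoSeparationError` is raised. ``manual``
    applies ``threshold`` verbatim.
    """
    values = np.asarray(intensities, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise ValueError("need at least 100 wells with finite intensities")

    if method == "manual":
        if threshold is None:
            raise ValueError("manual classification requires a threshold")
        k = int((values > threshold).sum())
        return ChipCounts(values.size, k, loaded_volume_ul,
                          classification="manual", threshold=float(threshold))
    if method != "auto":
        raise ValueError("method must be 'auto' or 'manual'")

    if np.ptp(values) == 0.0:
        raise NoSeparationError("all intensities identical")
    thr = _otsu_threshold(values)
    score = _separation_score(values, thr)
    if score < min_separation:
        if threshold is not None:
            counts = classify_wells(values, "manual", threshold,
                                    loaded_volume_ul=loaded_volume_ul)
            return replace(counts, quality_flags=frozenset({"no_separation"}))
        raise NoSeparationError(
            f"separation score {score:.2f} below floor {min_separation}"
        )
    k = int((values > thr).sum())
    return ChipCounts(values.size, k, loaded_volume_ul,
                      classification="auto", threshold=thr)


def _lambda_from_negative_fraction(neg_frac: float, volume_cv: float) -> float:
    """Invert the occupancy model for lambda given the negative fraction."""
    if volume_cv == 0.0:
        return -math.log(neg_frac)
    eta2 = volume_cv * volume_cv
    # exp(-lam + lam^2 eta^2 / 2) is decreasing on (0, 1/eta^2]
    lam_max = 1.0 / eta2
    floor = math.exp(-lam_max / 2.0)
    if neg_frac <= floor:
        raise ValueError(
            "negative fraction below the invertible range of the "
            f"volume-corrected model (volume_cv={volume_cv})"
        )
    f = lambda lam: math.exp(-lam + lam * lam * eta2 / 2.0) - neg_frac
    return float(optimize.brentq(f, 0.0, lam_max, xtol=1e-12, rtol=1e-14))


def estimate_copies(
    counts: ChipCounts,
    volume_cv: float = 0.0,
    *,
    alpha: float = 0.05,
    ci_method: str = "delta",
) -> QuantResult:
    """Estimate mean copies per well and absolute copies on the chip.

    ``volume_cv = 0`` is the plain Poisson estimator; ``volume_cv > 0``
    applies the volume-variability correction (always >= the plain
    Poisson estimate). Empty chips (k = 0) return 0 with a one-sided
    upper bound; saturated chips (k = N) return no point estimate, only
    a lower bound computed at k = N - 0.5.
    """
    if volume_cv < 0:
        raise ValueError("volume_cv must be >= 0")
    N, k = counts.n_total, counts.n_positive
    estimator = "poisson" if volume_cv == 0 else f"poisson_plus(cv={volume_cv:g})"
    flags = set(counts.quality_flags)

    if k == N:
        flags.add("saturated")
        p_low = (N - 0.5) / N
        lam_low = _lambda_from_negative_fraction(1.0 - p_low, 0.0)
        return QuantResult(
            lambda_hat=float("nan"), copies_chip=float("nan"),
            conc_per_ul_mix=float("nan"),
            ci95=(lam_low * N, float("inf")), estimator=estimator,
            flags=flags, n_total=N, n_positive=k,
            loaded_volume_ul=counts.loaded_volume_ul,
        )

    if k == 0:
        flags.add("empty")
        # one-sided (1 - alpha) Clopper-Pearson upper bound at k = 0
        p_up = 1.0 - alpha ** (1.0 / N)
        lam_up = _lambda_from_negative_fraction(1.0 - p_up, volume_cv)
        return QuantResult(
            lambda_hat=0.0, copies_chip=0.0, conc_per_ul_mix=0.0,
            ci95=(0.0, lam_up * N), estimator=estimator, flags=flags,
            n_total=N, n_positive=k, loaded_volume_ul=counts.loaded_volume_ul,
        )

    p_hat = k / N
    lam = _lambda_from_negative_fraction(1.0 - p_hat, volume_cv)

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if ci_method == "delta":
        se = math.sqrt(p_hat / (N * (1.0 - p_hat)))
        lam_lo = max(lam - z * se, 0.0)
        lam_hi = lam + z * se
    elif ci_method == "binomial":
        p_lo, p_hi = stats.beta.ppf(
            [alpha / 2.0, 1.0 - alpha / 2.0], [k, k + 1], [N - k + 1, N - k]
        )
        lam_lo = _lambda_from_negative_fraction(1.0 - float(p_lo), volume_cv)
        lam_hi = _lambda_from_negative_fraction(1.0 - float(p_hi), volume_cv)
    else:
        raise ValueError("ci_method must be 'delta' or 'binomial'")

    if p_hat > 0.999:
        flags.add("low_precision")
    copies = lam * N
    return QuantResult(
        lambda_hat=lam, copies_chip=copies,
        conc_per_ul_mix=copies / counts.loaded_volume_ul,
        ci95=(lam_lo * N, lam_hi * N), estimator=estimator, flags=flags,
        n_total=N, n_positive=k, loaded_volume_ul=counts.loaded_volume_ul,
    )


def convert_units(
    quant: QuantResult,
    assay: Assay,
    *,
    elution_volume_ul: float | None = None,
    template_dilution: float = 1.0,
    soil_dry_mass_g: float | None = None,
) -> dict:
    """Propagate a chip concentration to template and per-gram units.

    copies/uL template = conc_mix * reaction_volume / template_volume;
    copies/g dry soil = copies/uL template * elution_volume * dilution
    / soil mass (``template_dilution`` undoes any pre-dilution of the
    extract before loading).
    """
    if template_dilution <= 0:
        raise ValueError("template_dilution must be positive")
    per_ul_template = (
        quant.conc_per_ul_mix
        * assay.reaction_volume_ul
        / assay.template_volume_ul
    )
    out = {
        "conc_per_ul_mix": quant.conc_per_ul_mix,
        "copies_per_ul_template": per_ul_template,
    }
    if elution_volume_ul is not None and soil_dry_mass_g is not None:
        if elution_volume_ul <= 0 or soil_dry_mass_g <= 0:
            raise ValueError("elution volume and soil mass must be positive")
        out["copies_per_g"] = (
            per_ul_template * elution_volume_ul * template_dilution / soil_dry_mass_g
        )
    return out


def quantify_table(
    summary: pd.DataFrame,
    volume_cv: float = 0.0,
    assay: Assay | None = None,
    extract: dict | None = None,
) -> pd.DataFrame:
    """Quantify a summary table (chip_id, n_total, n_positive[, loaded_volume_ul])."""
    rows = []
    for _, row in summary.iterrows():
        counts = ChipCounts(
            n_total=int(row["n_total"]),
            n_positive=int(row["n_positive"]),
            loaded_volume_ul=float(row.get("loaded_volume_ul", 14.5)),
        )
        q = estimate_copies(counts, volume_cv)
        rec = {
            "chip_id": row.get("chip_id", ""),
            "estimator": q.estimator,
            "lambda_hat": q.lambda_hat,
            "copies_chip": q.copies_chip,
            "ci_low": q.ci95[0],
            "ci_high": q.ci95[1],
            "conc_per_ul_mix": q.conc_per_ul_mix,
            "flags": ",".join(sorted(q.flags)),
        }
        if assay is not None and extract is not None:
            rec.update(convert_units(q, assay, **extract))
        rows.append(rec)
    return pd.DataFrame(rows)
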