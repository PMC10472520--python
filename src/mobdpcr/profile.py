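"""Depth-profile statistics for type-specific methanotroph abundances.

Copy numbers per gram dry soil are compared across soil layers on the
log10 scale with the Tukey-Kramer test (all pairwise comparisons of a
one-way layout against the studentized-range distribution, valid for
unequal group sizes), summarized as a compact letter display. Relative
abundance, percent change against the pre-flooding sample and a
cross-check of the three-type sum against an externally measured total
complete the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import studentized_range


@lru_cache(maxsize=256)
def _q_critical(alpha: float, k: int, df: int) -> float:
    """Cached studentized-range quantile q(alpha, k, df) (ppf is costly)."""
    return float(studentized_range.ppf(1.0 - alpha, k, df))

__all__ = [
    "ComparisonResult",
    "tukey_kramer",
    "compact_letter_display",
    "relative_abundance",
    "percent_change",
    "profile_report",
]


@dataclass(frozen=True)
class ComparisonResult:
    """All pairwise Tukey-Kramer comparisons plus the letter display."""

    pairwise: pd.DataFrame  # group_i, group_j, mean_diff_log10, q, q_crit, significant
    letters: dict  # group -> letter string
    alpha: float
    df_error: int
    mse: float
    group_means: dict  # group -> mean of log10 values


def tukey_kramer(
    groups: dict,
    alpha: float = 0.05,
    *,
    log10_transform: bool = True,
    p_values: bool = True,
) -> ComparisonResult:
    """Tukey-Kramer all-pairs comparison on log10-transformed values.

    ``groups`` maps group labels to replicate measurements (> 0 when the
    log transform is on; >= 2 values per group). The statistic for a
    pair (i, j) is q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),
    referred to the studentized-range distribution q(alpha, k, df_error).
    With equal group sizes this is exactly Tukey's HSD. ``p_values=False``
    skips the (slow) adjusted p-value computation, keeping only the
    reject/accept decision against the cached critical value.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    data = {}
    for name in names:
        vals = np.asarray(groups[name], dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
        if log10_transform:
            if (vals <= 0).any():
                raise ValueError(f"group {name!r} has non-positive values")
            vals = np.log10(vals)
        data[name] = vals

    k = len(names)
    ns = {g: v.size for g, v in data.items()}
    means = {g: float(v.mean()) for g, v in data.items()}
    df_error = sum(ns.values()) - k
    if df_error < 1:
        raise ValueError("no error degrees of freedom")
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    mse = sse / df_error
    q_crit = _q_critical(alpha, k, df_error)

    rows = []
    sig = {}
    for a in range(k):
        for b in range(a + 1, k):
            gi, gj = names[a], names[b]
            diff = means[gi] - means[gj]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            q = abs(diff) / se if se > 0 else (np.inf if diff != 0 else 0.0)
            if p_values:
                p = float(studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
            else:
                p = np.nan
            significant = bool(q > q_crit)
            sig[(gi, gj)] = sig[(gj, gi)] = significant
            rows.append(
                {
                    "group_i": gi,
                    "group_j": gj,
                    "mean_diff_log10": diff,
                    "q": q,
                    "q_crit": q_crit,
                    "p_value": p,
                    "significant": significant,
                }
            )
    letters = compact_letter_display(names, sig, order_by=means)
    return ComparisonResult(
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        df_error=df_error,
        mse=mse,
        group_means=means,
    )


def compact_letter_display(names, significant: dict, order_by: dict | None = None) -> dict:
    """Assign letters so two groups share a letter iff not significantly different.

    Letter classes are the maximal cliques of the non-significance graph
    (enumerated by Bron-Kerbosch with pivoting): every non-different pair
    sits inside some maximal clique and so shares a letter, while a
    significant pair can never co-occur in a clique. Classes are lettered
    in descending order of their largest group mean.
    """
    names = list(names)
    adj = {
        g: {h for h in names if h != g and not significant.get((g, h), False)}
        for g in names
    }

    cliques: list[set] = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in list(p - adj[pivot]):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p.discard(v)
            x.add(v)

    bron_kerbosch(set(), set(names), set())
    rank = order_by or {}
    cliques.sort(key=lambda cls: -max(rank.get(g, 0.0) for g in cls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, cls in zip(alphabet, cliques):
        for g in sorted(cls):
            letters[g] += letter
    return letters


def relative_abundance(copies_by_type: dict) -> dict:
    """Each type's share of the summed copies; shares sum to 1."""
    vals = {k: float(v) for k, v in copies_by_type.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("copies must be >= 0")
    total = sum(vals.values())
    if total == 0:
        raise ValueError("all copies zero; relative abundance undefined")
    return {k: v / total for k, v in vals.items()}


def percent_change(before: float, after: float) -> float:
    """(after - before) / before x 100."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return (after - before) / before * 100.0


def profile_report(
    profile: pd.DataFrame,
    alpha: float = 0.05,
    baseline: str = "before",
) -> dict:
    """Full depth-profile analysis of a tidy per-replicate table.

    ``profile`` needs columns sample, mob_type, replicate, copies_per_g
    and optionally total_pmoa_per_g (an externally measured total used
    only for a sum/total ratio cross-check). Comparisons across samples
    run per type (matching how layer differences are reported per
    methanotroph group). Percent change uses arithmetic replicate means
    on the raw copy scale.
    """
    required = {"sample", "mob_type", "replicate", "copies_per_g"}
    if not required <= set(profile.columns):
        raise ValueError(f"profile table needs columns {sorted(required)}")

    comparisons = {}
    for mob_type, grp in profile.groupby("mob_type"):
        groups = {
            s: sub["copies_per_g"].to_numpy() for s, sub in grp.groupby("sample")
        }
        comparisons[mob_type] = tukey_kramer(groups, alpha)

    means = (
        profile.groupby(["sample", "mob_type"])["copies_per_g"].mean().unstack()
    )
    rel = means.div(means.sum(axis=1), axis=0)

    change_rows = []
    if baseline in means.index:
        for sample in means.index:
            if sample == baseline:
                continue
            for mob_type in means.columns:
                change_rows.append(
                    {
                        "sample": sample,
                        "mob_type": mob_type,
                        "percent_change_vs_baseline": percent_change(
                            means.loc[baseline, mob_type], means.loc[sample, mob_type]
                        ),
                    }
                )
    changes = pd.DataFrame(change_rows)

    totals = None
    if "total_pmoa_per_g" in profile.columns:
        tot = profile.groupby("sample")["total_pmoa_per_g"].mean()
        totals = pd.DataFrame(
            {
                "sum_of_types": means.sum(axis=1),
                "total_pmoa": tot,
                "sum_over_total": means.sum(axis=1) / tot,
            }
        )
    return {
        "comparisons": comparisons,
        "means": means,
        "relative_abundance": rel,
        "percent_change": changes,
        "totals": totals,
    }
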