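"""Rank-based two-group comparisons with effect sizes.

The workhorse pair is the two-sided Wilcoxon-Mann-Whitney test and Cliff's
delta.  The WMW p-value is exact (network/shift algorithm) for small tie-free
inputs and switches to the tie- and continuity-corrected normal approximation
otherwise; Cliff's delta comes with a 95% CI from the consistent (unpooled)
variance estimator.  Fisher's exact test covers 2x2 prevalence contrasts, and
a competitive rank test provides taxon-set enrichment over per-taxon effect
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_N_MAX = 30  # exact WMW branch: combined n at or below this, tie-free


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wmw_test(x, y) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration (scipy's shift algorithm) when the combined sample size
    is <= 30 and there are no ties; otherwise the normal approximation with
    tie correction and continuity correction, clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0  # constant feature: no evidence either way
    exact = (x.size + y.size) <= EXACT_N_MAX and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def cliffs_delta(x, y) -> tuple[float, float, float]:
    """Cliff's delta with a 95% CI.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y), in [-1, 1].  The CI
    uses Cliff's consistent variance estimate with normal quantiles, clamped
    to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    # dominance matrix: sign(x_i - y_j)
    d = np.sign(x[:, None] - y[None, :])
    delta = float(d.mean())
    if nx * ny == 1:
        return delta, -1.0, 1.0
    # consistent variance estimator (Cliff 1993)
    di_ = d.mean(axis=1)   # row means
    d_j = d.mean(axis=0)   # column means
    s_di = ((di_ - delta) ** 2).sum() / max(nx - 1, 1)
    s_dj = ((d_j - delta) ** 2).sum() / max(ny - 1, 1)
    s_dij = ((d - delta) ** 2).sum() / max(nx * ny - 1, 1)
    var = (s_di / nx) + (s_dj / ny) + (s_dij / (nx * ny))
    z = sps.norm.ppf(0.975)
    half = z * np.sqrt(max(var, 0.0))
    lo = max(delta - half, -1.0)
    hi = min(delta + half, 1.0)
    return delta, float(lo), float(hi)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (margins fixed)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EffectResult:
    feature_id: str
    n_x: int
    n_y: int
    p_value: float
    delta: float
    delta_ci_low: float
    delta_ci_high: float
    fdr_q: float | None = None


def compare_features(matrix: pd.DataFrame, groups: pd.Series,
                     adjust: bool = False) -> pd.DataFrame:
    """Per-feature WMW test + Cliff's delta between two groups.

    ``matrix`` is samples x features; ``groups`` maps sample -> label with
    exactly two levels.  Output is one row per feature, sorted by descending
    Cliff's delta.  Constant features get p = 1, delta = 0.
    """
    groups = groups.loc[matrix.index]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    gx, gy = levels
    mx = matrix.loc[groups == gx]
    my = matrix.loc[groups == gy]
    rows = []
    for feat in matrix.columns:
        x = mx[feat].dropna().to_numpy(dtype=float)
        y = my[feat].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            warnings.warn(f"feature {feat!r} missing in one group; skipped")
            continue
        constant = np.all(np.concatenate([x, y]) == x[0])
        if constant:
            p, (d, lo, hi) = 1.0, (0.0, 0.0, 0.0)
        else:
            p = wmw_test(x, y)
            d, lo, hi = cliffs_delta(x, y)
        rows.append(EffectResult(feat, x.size, y.size, p, d, lo, hi))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if adjust and len(out):
        out["fdr_q"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("delta", ascending=False).reset_index(drop=True)


def taxon_set_enrichment(results: pd.DataFrame, sets: dict[str, list[str]],
                         adjust: bool = True) -> pd.DataFrame:
    """Competitive taxon-set enrichment over per-taxon Cliff's deltas.

    For each named set, a two-sided WMW test compares the Cliff's-delta ranks
    of member vs. non-member taxa; p-values are BH-adjusted across sets.
    Sets with fewer than 2 present members, or with no complement, are
    skipped with a warning.
    """
    deltas = results.set_index("feature_id")["delta"]
    rows = []
    for name, members in sets.items():
        inside = deltas.loc[deltas.index.intersection(members)]
        outside = deltas.loc[deltas.index.difference(members)]
        if len(inside) < 2:
            warnings.warn(f"set {name!r} has <2 present members; skipped")
            continue
        if len(outside) == 0:
            warnings.warn(f"set {name!r} covers all features; skipped")
            continue
        p = wmw_test(inside.to_numpy(), outside.to_numpy())
        rows.append({"set": name, "n_members": len(inside),
                     "median_delta": float(inside.median()), "p_value": p})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["fdr_q"] = bh_adjust(out["p_value"].to_numpy())
    return out
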