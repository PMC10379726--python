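"""Interdomain KO-metabolite association analysis.

Pairwise Kendall tau-b correlations between KO relative abundances and
metabolite concentrations, with Benjamini-Hochberg FDR control applied once
across the entire correlation matrix (significance at FDR 10%).  Features
detected (value > 0) in fewer than a minimum number of samples are filtered
out before testing.  Sidebar associations — treatment contrasts by
MWU/Cliff's delta and ordinal-FCT correlations (FCT1 = 1, FCT2 = 2, ...)
— are computed per visit with BH control within each visit.  Heatmap
row/column ordering uses Ward clustering on Euclidean distances between tau
vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage

from .stats import bh_adjust, compare_features

KENDALL_EXACT_N_MAX = 8


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with a two-sided p-value.

    Exact enumeration for n <= 8 without ties, the tie-corrected normal
    approximation otherwise.  A constant vector makes tau undefined; it is
    reported as (0, 1) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: tau undefined, reported as 0 with p = 1")
        return 0.0, 1.0
    ties = (len(np.unique(x)) < x.size) or (len(np.unique(y)) < y.size)
    method = "exact" if (x.size <= KENDALL_EXACT_N_MAX and not ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMatrix:
    """All-pairs Kendall correlations with matrix-wide BH control."""

    tau: pd.DataFrame          # rows: KOs, columns: metabolites
    p: pd.DataFrame
    q: pd.DataFrame            # BH over every cell at once
    significant: pd.DataFrame  # q < fdr_threshold
    nominal: pd.DataFrame      # p < 0.05 (display tier below the FDR tier)
    fdr_threshold: float = 0.10


def _detection_filter(df: pd.DataFrame, min_detect: int, label: str) -> pd.DataFrame:
    detected = (df > 0).sum(axis=0)
    keep = detected[detected >= min_detect].index
    dropped = sorted(set(df.columns) - set(keep))
    if dropped:
        warnings.warn(f"{label}: filtered {len(dropped)} features detected in "
                      f"< {min_detect} samples: {dropped[:5]}")
    return df[keep]


def interdomain_matrix(ko: pd.DataFrame, mtb: pd.DataFrame,
                       min_detect: int = 3,
                       fdr_threshold: float = 0.10) -> CorrelationMatrix:
    """Pairwise KO x metabolite Kendall correlation matrix.

    Samples are intersected by ID; features detected in fewer than
    ``min_detect`` of the shared samples are removed before testing; BH is
    applied once across all remaining cells.
    """
    shared = ko.index.intersection(mtb.index)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between KO and metabolite tables")
    ko = _detection_filter(ko.loc[shared], min_detect, "KO")
    mtb = _detection_filter(mtb.loc[shared], min_detect, "metabolites")

    tau = pd.DataFrame(index=ko.columns, columns=mtb.columns, dtype=float)
    p = tau.copy()
    for k in ko.columns:
        xk = ko[k]
        for m in mtb.columns:
            pair = pd.concat([xk, mtb[m]], axis=1).dropna()
            t_, p_ = kendall_tau(pair.iloc[:, 0].to_numpy(),
                                 pair.iloc[:, 1].to_numpy())
            tau.loc[k, m] = t_
            p.loc[k, m] = p_
    q_flat = bh_adjust(p.to_numpy().ravel())
    q = pd.DataFrame(q_flat.reshape(p.shape), index=p.index, columns=p.columns)
    return CorrelationMatrix(tau=tau, p=p, q=q,
                             significant=q < fdr_threshold,
                             nominal=p < 0.05,
                             fdr_threshold=fdr_threshold)


def treatment_association(features: pd.DataFrame, arms: pd.Series,
                          visits: pd.Series, visit: str,
                          fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Per-feature arm contrast (MWU + Cliff's delta) at one visit.

    Reuses the group-comparison engines; BH is applied across features
    within the visit, flagging q < ``fdr_threshold``.
    """
    at = visits[visits == visit].index.intersection(features.index)
    if at.empty:
        raise ValueError(f"no samples at visit {visit!r}")
    sub = features.loc[at]
    sub_arms = arms.loc[at]
    if sub_arms.nunique() != 2:
        raise ValueError(f"need both arms at visit {visit!r}")
    out = compare_features(sub, sub_arms, adjust=True)
    out["significant"] = out["fdr_q"] < fdr_threshold
    out["visit"] = visit
    return out


def fct_ordinal_association(feature: pd.Series, fct_labels: pd.Series
                            ) -> tuple[float, float]:
    """Kendall correlation of a feature with ordinally encoded FCTs.

    FCT labels are used as ordered integers (FCT1 = 1, FCT2 = 2, ...).  A
    single observed FCT level makes tau undefined -> (0, 1) with a warning.
    """
    shared = feature.dropna().index.intersection(fct_labels.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >= 3 samples with both feature and FCT label")
    x = feature.loc[shared].to_numpy(dtype=float)
    f = fct_labels.loc[shared].to_numpy(dtype=float)
    if len(np.unique(f)) < 2:
        warnings.warn("single FCT level present: tau undefined, 0 with p = 1")
        return 0.0, 1.0
    return kendall_tau(x, f)


def fct_association_table(features: pd.DataFrame, fct_labels: pd.Series,
                          visits: pd.Series, visit: str,
                          fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Ordinal-FCT Kendall association for every feature at one visit."""
    at = visits[visits == visit].index.intersection(features.index)
    rows = []
    for feat in features.columns:
        tau, p = fct_ordinal_association(features.loc[at, feat], fct_labels.loc[at])
        rows.append({"feature_id": feat, "tau": tau, "p_value": p, "visit": visit})
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr_q"] < fdr_threshold
    return out


def cluster_heatmap_order(matrix: CorrelationMatrix | pd.DataFrame
                          ) -> tuple[list, list]:
    """Ward/Euclidean leaf orders for heatmap rows and columns.

    Agglomerative Ward linkage (Ward.D2 convention, squared distances inside
    the criterion) on Euclidean distances between tau row-vectors and between
    tau column-vectors.  Single rows or columns yield identity order.
    """
    tau = matrix.tau if isinstance(matrix, CorrelationMatrix) else matrix

    def order(frame: pd.DataFrame) -> list:
        if frame.shape[0] < 2:
            return list(frame.index)
        Z = linkage(frame.to_numpy(dtype=float), method="ward",
                    metric="euclidean")
        return [frame.index[i] for i in leaves_list(Z)]

    return order(tau), order(tau.T)
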