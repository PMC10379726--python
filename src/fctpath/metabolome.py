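"""PLS/PLS-DA metabolome modelling, discriminant-metabolite selection,
bile-acid conjugation ratios, and within-arm baseline-shift tests.

The regression engine is NIPALS PLS2 on mean-centered, unit-variance-scaled
data (Pareto or no scaling available by flag).  Y may mix a continuous age
column with a coded treatment column (control=0, test=1), mirroring the
combined age+treatment model.  Model quality is judged by cross-validated
Q2Y (venetian-blind folds) and Y-permutation tests; per-variable importance
combines the VIP score, the correlation of each scaled variable with a
chosen component's scores (p(corr)), and a univariate rank test, with the
selection rule VIP > 1 and |p(corr)| > 0.2 and WMW p < 0.05.

Bile-acid conjugation ratios quantify bacterial bile salt hydrolase
activity: total unconjugated (CA + CDCA + LCA + DCA) over total conjugated
(TCA + TCDCA + TDCA + GCA + TLCA + GCDCA + GDCA), plus the per-acid pairs
CA/(GCA+TCA), CDCA/(GCDCA+TCDCA) and LCA/(GLCA+TLCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import wmw_test
from .tables import MetaboliteMatrix, SampleTable


@dataclass
class PLSModel:
    """A fitted NIPALS PLS2 model (scores, weights, loadings per component)."""

    n_components: int
    x_scores: np.ndarray      # T, (n, a)
    x_weights: np.ndarray     # W, (p, a)
    x_loadings: np.ndarray    # P, (p, a)
    y_loadings: np.ndarray    # Q, (m, a)
    explained_y_variance: np.ndarray  # per component, fractions of total SSY
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    scaling: str
    feature_ids: list[str]
    kept_columns: np.ndarray  # indices of X columns retained after variance filter

    @property
    def r2y(self) -> float:
        return float(self.explained_y_variance.sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float)[:, self.kept_columns] - self.x_mean) / self.x_scale
        B = self.x_weights @ np.linalg.pinv(self.x_loadings.T @ self.x_weights) @ self.y_loadings.T
        return Xs @ B * self.y_scale + self.y_mean


def _scale_factors(X: np.ndarray, scaling: str) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if scaling == "unit_variance":
        return sd
    if scaling == "pareto":
        return np.sqrt(sd)
    if scaling == "none":
        return np.ones(X.shape[1])
    raise ValueError(f"unknown scaling {scaling!r}")


def fit_pls(X, Y, n_components: int = 2, scaling: str = "unit_variance",
            feature_ids: list[str] | None = None, max_iter: int = 500,
            tol: float = 1e-10) -> PLSModel:
    """NIPALS PLS2 with mean centering and column scaling.

    Constant X columns are dropped (with a warning) under unit-variance
    scaling rather than dividing by zero.  Y is centered and unit-variance
    scaled so that a days-scale age column and a 0/1 treatment column carry
    comparable weight.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]

    sd = X.std(axis=0, ddof=1)
    kept = np.where(sd > 0)[0]
    if len(kept) < X.shape[1]:
        dropped = [feature_ids[j] for j in np.where(sd == 0)[0]]
        warnings.warn(f"dropping constant X columns: {dropped[:5]}")
    Xk = X[:, kept]
    x_mean = Xk.mean(axis=0)
    x_scale = _scale_factors(Xk, scaling)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0, ddof=1)
    y_scale = np.where(y_sd == 0, 1.0, y_sd)

    E = (Xk - x_mean) / x_scale
    F = (Y - y_mean) / y_scale
    ssy_total = float((F**2).sum())
    if ssy_total == 0:
        raise ValueError("Y has zero variance")

    n, p = E.shape
    m = F.shape[1]
    a_max = min(n_components, n - 1, p)
    Ts, Ws, Ps, Qs, ssy_frac = [], [], [], [], []
    for _ in range(a_max):
        # start u from the Y column with the largest remaining variance
        u = F[:, int(np.argmax((F**2).sum(axis=0)))].copy()
        if not np.any(u):
            break
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            q = F.T @ t / (t @ t)
            u = F @ q / (q @ q) if (q @ q) > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        if t_old is None and nw == 0:
            break
        pvec = E.T @ t / (t @ t)
        ssy_before = (F**2).sum()
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        ssy_after = (F**2).sum()
        Ts.append(t); Ws.append(w); Ps.append(pvec); Qs.append(q)
        ssy_frac.append((ssy_before - ssy_after) / ssy_total)

    if not Ts:
        raise ValueError("no PLS components could be extracted")
    return PLSModel(
        n_components=len(Ts),
        x_scores=np.column_stack(Ts), x_weights=np.column_stack(Ws),
        x_loadings=np.column_stack(Ps), y_loadings=np.column_stack(Qs),
        explained_y_variance=np.asarray(ssy_frac),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        scaling=scaling, feature_ids=[feature_ids[j] for j in kept],
        kept_columns=kept,
    )


def vip(model: PLSModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the Y-variance explained by component a.  The identity
    sum_j VIP_j^2 = p holds for every fitted model.
    """
    ssy = model.explained_y_variance
    if ssy.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    W = model.x_weights
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    contrib = (W**2 / wnorm2) @ ssy
    scores = np.sqrt(p * contrib / ssy.sum())
    return pd.Series(scores, index=model.feature_ids, name="vip")


def p_corr(model: PLSModel, X, component: int = 2) -> pd.Series:
    """Pearson correlation of each scaled X column with a component's scores.

    ``component`` is 1-based.  Constant columns get correlation 0 with a
    warning.
    """
    if not 1 <= component <= model.n_components:
        raise ValueError(f"component must be in 1..{model.n_components}")
    X = np.asarray(X, dtype=float)[:, model.kept_columns]
    Xs = (X - model.x_mean) / model.x_scale
    t = model.x_scores[:, component - 1]
    tc = t - t.mean()
    denom_t = np.sqrt((tc**2).sum())
    out = np.zeros(Xs.shape[1])
    for j in range(Xs.shape[1]):
        xc = Xs[:, j] - Xs[:, j].mean()
        denom = np.sqrt((xc**2).sum()) * denom_t
        if denom == 0:
            warnings.warn(f"constant column {model.feature_ids[j]!r}: p(corr) = 0")
            out[j] = 0.0
        else:
            out[j] = float((xc @ tc) / denom)
    return pd.Series(out, index=model.feature_ids, name="p_corr")


def validate_pls(X, Y, n_components: int = 2, folds: int = 7,
                 n_permutations: int = 200, seed: int = 0,
                 scaling: str = "unit_variance") -> tuple[float, float | None]:
    """Cross-validated Q2Y and a Y-permutation p-value.

    Q2Y = 1 - PRESS/SS over venetian-blind folds assigned by sample order
    after a seeded shuffle.  The permutation p-value is the fraction of
    Y-permuted refits achieving Q2 >= the observed Q2, with the +1
    correction, so it lies in [1/(n_permutations+1), 1].  With
    ``n_permutations`` = 0 only Q2Y is returned (p is None).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    def q2(Yin: np.ndarray) -> float:
        press = 0.0
        ss = 0.0
        for f in range(folds):
            test = fold_of == f
            train = ~test
            model = fit_pls(X[train], Yin[train], n_components, scaling=scaling)
            pred = model.predict(X[test])
            press += float(((Yin[test] - pred) ** 2).sum())
            ss += float(((Yin[test] - Yin[train].mean(axis=0)) ** 2).sum())
        return 1.0 - press / ss

    q2_obs = q2(Y)
    if n_permutations == 0:
        return q2_obs, None
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if q2(Y[perm]) >= q2_obs:
            hits += 1
    return q2_obs, (hits + 1) / (n_permutations + 1)


def select_discriminant(vips: pd.Series, p_corrs: pd.Series,
                        wmw_ps: pd.Series) -> pd.DataFrame:
    """Apply the discriminant-metabolite rule.

    A metabolite is selected iff VIP > 1 and |p(corr)| > 0.2 and
    WMW p < 0.05.  Metabolites missing any statistic are excluded with a
    warning; the table is sorted by descending VIP.
    """
    common = vips.index.intersection(p_corrs.index).intersection(wmw_ps.index)
    dropped = sorted((set(vips.index) | set(p_corrs.index) | set(wmw_ps.index))
                     - set(common))
    if dropped:
        warnings.warn(f"metabolites missing a statistic excluded: {dropped[:5]}")
    out = pd.DataFrame({
        "vip": vips.loc[common],
        "p_corr": p_corrs.loc[common],
        "wmw_p": wmw_ps.loc[common],
    })
    out["selected"] = (out["vip"] > 1) & (out["p_corr"].abs() > 0.2) & (out["wmw_p"] < 0.05)
    return out.sort_values("vip", ascending=False).rename_axis("metabolite_id")


# -- bile-acid conjugation ratios --------------------------------------------

UNCONJUGATED_TOTAL = ("CA", "CDCA", "LCA", "DCA")
CONJUGATED_TOTAL = ("TCA", "TCDCA", "TDCA", "GCA", "TLCA", "GCDCA", "GDCA")
RATIO_PAIRS = {
    "ba_cba": (UNCONJUGATED_TOTAL, CONJUGATED_TOTAL),
    "ca_cca": (("CA",), ("GCA", "TCA")),
    "cdca_ccdca": (("CDCA",), ("GCDCA", "TCDCA")),
    "lca_clca": (("LCA",), ("GLCA", "TLCA")),
}


def bile_acid_ratios(panel: pd.DataFrame) -> pd.DataFrame:
    """Unconjugated/conjugated bile-acid ratios per sample.

    ba_cba = (CA+CDCA+LCA+DCA) / (TCA+TCDCA+TDCA+GCA+TLCA+GCDCA+GDCA), plus
    the cholic, chenodeoxycholic and lithocholic pairs.  A ratio is NaN
    (undefined, never infinity) when a required analyte is missing or the
    conjugated denominator is zero.
    """
    out = {}
    for name, (num_cols, den_cols) in RATIO_PAIRS.items():
        missing = [c for c in (*num_cols, *den_cols) if c not in panel.columns]
        if missing:
            warnings.warn(f"ratio {name}: missing analytes {missing}; undefined")
            out[name] = pd.Series(np.nan, index=panel.index)
            continue
        num = panel[list(num_cols)].sum(axis=1, skipna=False)
        den = panel[list(den_cols)].sum(axis=1, skipna=False)
        ratio = num / den
        ratio[den == 0] = np.nan
        out[name] = ratio
    return pd.DataFrame(out, index=panel.index)


def baseline_shift_tests(values: pd.Series, metadata: SampleTable,
                         arm: str) -> pd.Series:
    """Within-arm WMW tests of each follow-up visit against baseline (V0).

    ``values`` is a per-sample metabolite level or ratio; the test is the
    unpaired two-sided WMW of the visit's values against the same arm's V0
    values, one p-value per visit in {V1, V3, V6}.  Visits without samples
    are skipped with a warning.
    """
    meta = metadata.frame.set_index("sample_id")
    vals = values.dropna()
    meta = meta.loc[meta.index.intersection(vals.index)]
    meta = meta[meta["arm"] == arm]
    baseline = vals.loc[meta.index[meta["visit"] == "V0"]]
    if baseline.empty:
        raise ValueError(f"no V0 samples in arm {arm!r}")
    out = {}
    for visit in ("V1", "V3", "V6"):
        at_visit = vals.loc[meta.index[meta["visit"] == visit]]
        if at_visit.empty:
            warnings.warn(f"no {visit} samples in arm {arm!r}; skipped")
            continue
        out[visit] = wmw_test(at_visit.to_numpy(), baseline.to_numpy())
    return pd.Series(out, name=f"p_vs_V0_{arm}")
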