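"""Dirichlet-multinomial mixture (DMM) community typing.

Samples are clustered on non-rarefied genus-level counts: each mixture
component is a Dirichlet-multinomial (DM) with its own parameter vector
``alpha``, fitted by EM with a responsibility-weighted fixed-point M-step
(Minka's MM update, which never decreases the weighted DM likelihood).  The
number of components is selected by the minimal Laplace-approximated negative
log model evidence over K = 2..10 with repeated fits, after which components
are renamed fecal community types (FCT1..FCTK) by ascending mean age of their
member samples.

A weak exponential prior (rate ``eta``) on each alpha keeps the posterior
mode away from the boundary; the Laplace Hessian is computed analytically in
log-alpha space, block-diagonal per component.  When a block fails to be
positive definite the evidence falls back to a BIC-style penalty with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, polygamma
from sklearn.cluster import KMeans

from .tables import SampleTable, TaxaCountMatrix

ALPHA_FLOOR = 1e-8
PRIOR_RATE = 0.1  # exponential prior rate on alpha (mean 10)
#: Minimum mixture weight a component must retain during EM.  A DM component
#: carries one parameter per taxon; a component holding only a handful of
#: samples is unidentifiable and games the Laplace evidence through its
#: near-flat Hessian block (the classic mixture micro-cluster degeneracy).
#: Community types are population-level states, so components below 3% of
#: samples are pruned as degenerate.
MIN_WEIGHT = 0.03


def dm_log_pmf(counts, alpha) -> float:
    """Log pmf of the Dirichlet-multinomial.

    log[n!/prod(x_j!)] + logG(A) - logG(n+A) + sum_j [logG(x_j+a_j) - logG(a_j)]
    with A = sum(alpha).
    """
    x = np.asarray(counts, dtype=np.int64)
    a = np.asarray(alpha, dtype=float)
    if x.shape != a.shape:
        raise ValueError("counts and alpha must have equal length")
    if (x < 0).any():
        raise ValueError("negative counts")
    if (a <= 0).any():
        raise ValueError("alpha must be strictly positive")
    n = x.sum()
    A = a.sum()
    coef = gammaln(n + 1) - gammaln(x + 1).sum()
    return float(coef + gammaln(A) - gammaln(n + A)
                 + (gammaln(x + a) - gammaln(a)).sum())


@dataclass
class DMMModel:
    """A fitted Dirichlet-multinomial mixture."""

    K: int
    alpha: np.ndarray                 # (K, T) positive Dirichlet parameters
    weights: np.ndarray               # (K,) mixture proportions
    responsibilities: np.ndarray      # (N, K) posterior memberships
    log_likelihood: float             # observed-data mixture log-likelihood
    neg_log_evidence: float           # Laplace -log evidence
    sample_ids: list[str]
    taxon_ids: list[str]
    fit_meta: dict = field(default_factory=dict)
    selection_table: pd.DataFrame | None = None

    @property
    def hard_labels(self) -> pd.Series:
        """Hard assignment: argmax responsibility (ties -> lowest index)."""
        lab = np.argmax(self.responsibilities, axis=1)
        return pd.Series(lab, index=self.sample_ids, name="component")

    def component_means(self) -> np.ndarray:
        """Per-component expected proportions alpha_k / A_k, shape (K, T)."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)


def _component_log_dm(X: np.ndarray, n: np.ndarray, logcoef: np.ndarray,
                      alpha: np.ndarray) -> np.ndarray:
    """(N, K) matrix of per-component DM log densities."""
    A = alpha.sum(axis=1)                                     # (K,)
    # (K, N, T) broadcast; modest sizes (K<=10, T~30) keep this cheap
    term = gammaln(X[None, :, :] + alpha[:, None, :]) - gammaln(alpha)[:, None, :]
    ll = term.sum(axis=2) + gammaln(A)[:, None] - gammaln(n[None, :] + A[:, None])
    return ll.T + logcoef[:, None]


def _objective(loglik: float, alpha: np.ndarray, eta: float) -> float:
    """Penalized objective: log-likelihood plus exponential log prior."""
    return loglik + float(np.sum(np.log(eta) - eta * alpha))


def _m_step_alpha(X, n, resp, alpha, eta, inner_iters=10, inner_tol=1e-3):
    """MAP fixed-point update of all component alphas (Minka MM update)."""
    for _ in range(inner_iters):
        A = alpha.sum(axis=1)                                  # (K,)
        Rk = resp.sum(axis=0)                                  # (K,)
        # numerator: sum_i r_ik [psi(x_ij + a_kj) - psi(a_kj)]
        num = np.einsum("ik,kij->kj", resp,
                        digamma(X[None, :, :] + alpha[:, None, :]))
        num -= Rk[:, None] * digamma(alpha)
        # denominator: sum_i r_ik [psi(n_i + A_k) - psi(A_k)] + prior rate
        den = (resp * digamma(n[:, None] + A[None, :])).sum(axis=0)
        den -= Rk * digamma(A)
        new = alpha * num / (den[:, None] + eta)
        new = np.maximum(new, ALPHA_FLOOR)
        rel = np.max(np.abs(new - alpha) / (alpha + 1e-12))
        alpha = new
        if rel < inner_tol:
            break
    return alpha


def _init_responsibilities(X: np.ndarray, K: int, rng: np.random.Generator):
    """k-means++ seeding on centered log-ratio proportions (pseudocount 0.5)."""
    P = (X + 0.5) / (X + 0.5).sum(axis=1, keepdims=True)
    L = np.log(P)
    L -= L.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=K, init="k-means++", n_init=1,
                random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(L)
    resp = np.full((X.shape[0], K), 0.05 / max(K - 1, 1) if K > 1 else 0.0)
    resp[np.arange(X.shape[0]), labels] = 0.95 if K > 1 else 1.0
    resp /= resp.sum(axis=1, keepdims=True)
    return resp, P


def _em_fit(X, n, logcoef, K, tol, max_iter, seed, eta, min_weight=MIN_WEIGHT,
            track=None):
    rng = np.random.default_rng(seed)
    resp, P = _init_responsibilities(X, K, rng)
    # moment-style init: weighted mean proportions at moderate concentration
    w = resp / resp.sum(axis=0, keepdims=True)
    alpha = np.maximum((w.T @ P) * 10.0, ALPHA_FLOOR)
    weights = resp.mean(axis=0)

    prev_obj = -np.inf
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logdm = _component_log_dm(X, n, logcoef, alpha)          # (N, K)
        joint = logdm + np.log(weights)[None, :]
        norm = logsumexp(joint, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(joint - norm[:, None])

        if track is not None:
            track.append(loglik)

        # prune degenerate components (insufficient effective occupancy);
        # a short grace period lets the initialization settle first
        weights_new = resp.mean(axis=0)
        floor = min_weight if it >= 3 else 1e-8
        live = weights_new >= floor
        if not live.any():
            live = weights_new == weights_new.max()
        if not live.all():
            warnings.warn(
                f"pruning {int((~live).sum())} degenerate component(s); "
                f"effective K = {int(live.sum())}"
            )
            alpha = alpha[live]
            resp = resp[:, live]
            resp /= resp.sum(axis=1, keepdims=True)
            weights_new = resp.mean(axis=0)
        weights = weights_new / weights_new.sum()

        # M-step
        alpha = _m_step_alpha(X, n, resp, alpha, eta)

        obj = _objective(loglik, alpha, eta)
        if np.abs(obj - prev_obj) < tol * (np.abs(obj) + 1.0):
            converged = True
            break
        prev_obj = obj

    # final E-step so responsibilities/log-likelihood match returned alpha
    logdm = _component_log_dm(X, n, logcoef, alpha)
    joint = logdm + np.log(weights)[None, :]
    norm = logsumexp(joint, axis=1)
    loglik = float(norm.sum())
    resp = np.exp(joint - norm[:, None])
    return alpha, weights, resp, loglik, converged, it


def _as_matrix(counts) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(counts, TaxaCountMatrix):
        return counts.values.astype(np.int64), counts.sample_ids, counts.taxon_ids
    X = np.asarray(counts, dtype=np.int64)
    return X, [f"S{i}" for i in range(X.shape[0])], [f"T{j}" for j in range(X.shape[1])]


def fit_dmm(counts, K: int, restarts: int = 1, tol: float = 1e-6,
            seed: int = 0, max_iter: int = 200, eta: float = PRIOR_RATE,
            min_weight: float = MIN_WEIGHT,
            track_loglik: list | None = None) -> DMMModel:
    """Fit a K-component DMM by EM, best of ``restarts`` runs.

    Restarts use distinct seeds derived from ``seed``; the winner is the run
    with the highest penalized likelihood.  ``track_loglik``, when given,
    collects the observed-data log-likelihood at every EM iteration of the
    winning run's trajectory (used by monotonicity tests).
    """
    X, sample_ids, taxon_ids = _as_matrix(counts)
    if K < 1:
        raise ValueError("K must be >= 1")
    if X.shape[0] < K:
        raise ValueError(f"need at least K={K} samples, got {X.shape[0]}")
    n = X.sum(axis=1)
    logcoef = gammaln(n + 1) - gammaln(X + 1).sum(axis=1)

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(restarts):
        run_seed = child.generate_state(1)[0] % (2**31 - 1)
        track = [] if track_loglik is not None else None
        alpha, weights, resp, loglik, converged, iters = _em_fit(
            X, n, logcoef, K, tol, max_iter, run_seed, eta,
            min_weight=min_weight, track=track)
        obj = _objective(loglik, alpha, eta)
        if best is None or obj > best[0]:
            best = (obj, alpha, weights, resp, loglik, converged, iters, run_seed, track)

    _, alpha, weights, resp, loglik, converged, iters, run_seed, track = best
    if track_loglik is not None:
        track_loglik.extend(track)
    model = DMMModel(
        K=alpha.shape[0], alpha=alpha, weights=weights, responsibilities=resp,
        log_likelihood=loglik, neg_log_evidence=np.nan,
        sample_ids=sample_ids, taxon_ids=taxon_ids,
        fit_meta={"seed": int(seed), "run_seed": int(run_seed),
                  "restarts": restarts, "iterations": iters,
                  "converged": bool(converged), "tol": tol, "eta": eta},
    )
    model.neg_log_evidence = laplace_neg_log_evidence(model, X, eta=eta)
    return model


def laplace_neg_log_evidence(model: DMMModel, counts, eta: float = PRIOR_RATE) -> float:
    """Laplace-approximated negative log model evidence.

    -log Z ~= -log posterior at the mode - (d/2) log 2pi + (1/2) log|H|,
    with d = K*T free parameters (the alphas in log space) and H the
    block-diagonal Hessian of the negative log posterior, computed
    analytically in log-alpha space using the responsibility-weighted
    complete-data likelihood.  Falls back to a BIC-style penalty when a
    block is not positive definite.
    """
    X, _, _ = _as_matrix(counts)
    n = X.sum(axis=1)
    alpha = model.alpha
    resp = model.responsibilities
    K, T = alpha.shape
    N = X.shape[0]
    d = K * T

    # negative log posterior at the mode (observed-data likelihood + prior)
    f_mode = -_objective(model.log_likelihood, alpha, eta)

    half_logdet = 0.0
    for k in range(K):
        a = alpha[k]
        A = a.sum()
        r = resp[:, k]
        Rk = r.sum()
        # alpha-space Hessian of -sum_i r_ik log DM(x_i; a) - log prior
        c = -float((r * (polygamma(1, A) - polygamma(1, n + A))).sum())
        diag_ll = -(r[:, None] * (polygamma(1, X + a[None, :])
                                  - polygamma(1, a)[None, :])).sum(axis=0)
        # gradient in alpha space (likelihood + prior incl. log-alpha Jacobian)
        g = -(r[:, None] * (digamma(X + a[None, :]) - digamma(a)[None, :])).sum(axis=0)
        g += -Rk * digamma(A) + float((r * digamma(n + A)).sum())
        g += eta - 1.0 / a
        H_aa = c * np.ones((T, T)) + np.diag(diag_ll + 1.0 / a**2)
        # transform to log-alpha: H_ll = D H_aa D + diag(a * g)
        H = (a[:, None] * H_aa * a[None, :]) + np.diag(a * g)
        try:
            L = np.linalg.cholesky(H)
            half_logdet += float(np.log(np.diag(L)).sum())
        except np.linalg.LinAlgError:
            warnings.warn(
                f"non-positive-definite Hessian block (component {k}); "
                "falling back to BIC-style penalty"
            )
            d_total = K * T + (K - 1)
            return float(-model.log_likelihood + 0.5 * d_total * np.log(N))

    return float(f_mode - 0.5 * d * np.log(2 * np.pi) + half_logdet)


def select_dmm(counts, k_range=range(2, 11), repeats: int = 10,
               seed: int = 0, tol: float = 1e-6, max_iter: int = 200,
               min_weight: float = MIN_WEIGHT) -> DMMModel:
    """Fit DMMs across ``k_range`` with ``repeats`` fits each and return the
    model minimizing the Laplace negative log evidence.

    The full evidence-vs-K table is attached as ``selection_table``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    ss = np.random.SeedSequence(seed)
    rows = []
    best_model = None
    failures = []
    for K in k_range:
        for rep, child in enumerate(ss.spawn(repeats)):
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            try:
                m = fit_dmm(counts, K, restarts=1, tol=tol, seed=rep_seed,
                            max_iter=max_iter, min_weight=min_weight)
            except Exception as exc:  # pragma: no cover - diagnostics path
                failures.append((K, rep, str(exc)))
                continue
            rows.append({"K": K, "repeat": rep,
                         "neg_log_evidence": m.neg_log_evidence,
                         "log_likelihood": m.log_likelihood,
                         "effective_K": m.K,
                         "converged": m.fit_meta["converged"]})
            if best_model is None or m.neg_log_evidence < best_model.neg_log_evidence:
                best_model = m
    if best_model is None:
        raise RuntimeError(f"all DMM fits failed: {failures}")
    best_model.selection_table = pd.DataFrame(rows)
    return best_model


@dataclass
class FCTAssignment:
    """Hard sample-to-FCT assignment with the component renumbering map."""

    labels: pd.Series                 # sample_id -> FCT number (1..K)
    renumbering: dict[int, int]       # raw component index -> FCT number

    @property
    def n_fct(self) -> int:
        return int(self.labels.max())

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("fct").rename_axis("sample_id").reset_index()


def order_fcts(model_or_labels, metadata: SampleTable) -> FCTAssignment:
    """Renumber mixture components as FCT1..FCTK by ascending mean member age.

    Ties are broken by ascending median age, then by raw component index
    (logged).  Accepts a fitted :class:`DMMModel` or a raw-label Series.
    """
    if isinstance(model_or_labels, DMMModel):
        raw = model_or_labels.hard_labels
    else:
        raw = model_or_labels
    ages = metadata.frame.set_index("sample_id")["age"]
    missing = set(raw.index) - set(ages.index)
    if missing:
        raise ValueError(f"samples without metadata age: {sorted(missing)[:5]}")
    ages = ages.loc[raw.index]
    stats = pd.DataFrame({"component": raw.to_numpy(), "age": ages.to_numpy()})
    agg = stats.groupby("component")["age"].agg(["mean", "median"])
    agg["raw"] = agg.index
    agg = agg.sort_values(["mean", "median", "raw"])
    if agg["mean"].duplicated().any():
        warnings.warn("mean-age tie between components; broke by median age, then index")
    renumber = {int(raw_idx): fct for fct, raw_idx in enumerate(agg.index, start=1)}
    labels = raw.map(renumber).rename("fct")
    return FCTAssignment(labels=labels, renumbering=renumber)
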