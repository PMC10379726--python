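"""FCT transition networks and time-to-transition survival analysis.

The transition model bins samples into age groups (nearest month, month =
30.4375 days, half-up rounding) and records, for every infant, an edge
between each pair of consecutive samples — including self-loops when both
fall in the same age bin and skip edges when bins are jumped.  Edges are
categorized as no-change, progression, or regression; edges at or below a
display threshold (default 4%) are retained in the data but flagged hidden.

Time-to-event analysis treats "reaching a target FCT or any later FCT" as
the event; the event time is the age at the earliest such visit, with
right-censoring at the last observed visit otherwise.  Arm contrasts use a
single-binary-covariate Cox proportional hazards model (Newton-Raphson,
Breslow ties) whose score test is reported as the log-rank result, exactly
as survival packages report it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dmm import FCTAssignment
from .tables import SampleTable

DAYS_PER_MONTH = 30.4375  # mean Gregorian month


def assign_age_group(age: float) -> int:
    """Age in days -> month index, half-up rounding at the .5 boundary."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    return int(np.floor(age / DAYS_PER_MONTH + 0.5))


@dataclass
class TransitionGraph:
    """Age-binned FCT transition network.

    ``nodes``: one row per (age_month, fct) with the occupancy fraction of
    that FCT within its age column.  ``edges``: one row per observed
    (from, to) transition with its fraction of all transitions leaving the
    source age column, its category, and a ``hidden`` flag for rendering.
    """

    nodes: pd.DataFrame   # age_month, fct, n, occupancy
    edges: pd.DataFrame   # from_month, from_fct, to_month, to_fct, n, fraction, category, hidden
    display_threshold: float = 0.04

    def to_dot(self) -> str:
        """Graphviz DOT export of the visible part of the network."""
        lines = ["digraph fct_transitions {", "  rankdir=LR;"]
        for _, r in self.nodes.iterrows():
            lines.append(
                f'  "m{int(r.age_month)}_FCT{int(r.fct)}" '
                f'[label="FCT{int(r.fct)}\\n{r.occupancy:.0%}"];'
            )
        for _, r in self.edges.iterrows():
            if r.hidden:
                continue
            color = {"no_change": "grey", "progression": "blue",
                     "regression": "red"}[r.category]
            lines.append(
                f'  "m{int(r.from_month)}_FCT{int(r.from_fct)}" -> '
                f'"m{int(r.to_month)}_FCT{int(r.to_fct)}" '
                f'[color={color}, penwidth={max(0.5, 6 * r.fraction):.2f}];'
            )
        lines.append("}")
        return "\n".join(lines)


def _categorize(from_fct: int, to_fct: int) -> str:
    if to_fct > from_fct:
        return "progression"
    if to_fct < from_fct:
        return "regression"
    return "no_change"


def build_transition_graph(assignment: FCTAssignment, metadata: SampleTable,
                           display_threshold: float = 0.04) -> TransitionGraph:
    """Build the age-binned transition network from hard FCT assignments.

    Every consecutive sample pair within an infant contributes one edge from
    its source to its destination age group; same-bin pairs yield self-loops
    and skipped bins are allowed.  Node occupancy is the fraction of the age
    column's samples in each FCT; edge fractions are relative to all
    transitions leaving the source age column.
    """
    df = metadata.frame.merge(
        assignment.labels.rename("fct").rename_axis("sample_id").reset_index(),
        on="sample_id", how="inner",
    )
    df["age_month"] = df["age"].map(assign_age_group)

    node_counts = (df.groupby(["age_month", "fct"]).size()
                   .rename("n").reset_index())
    col_totals = node_counts.groupby("age_month")["n"].transform("sum")
    node_counts["occupancy"] = node_counts["n"] / col_totals

    edge_rows = []
    for _, g in df.sort_values(["age", "sample_id"]).groupby("infant_id"):
        recs = g[["age_month", "fct"]].to_numpy()
        for (m0, f0), (m1, f1) in zip(recs[:-1], recs[1:]):
            edge_rows.append({"from_month": m0, "from_fct": f0,
                              "to_month": m1, "to_fct": f1})
    if edge_rows:
        edges = (pd.DataFrame(edge_rows)
                 .groupby(["from_month", "from_fct", "to_month", "to_fct"])
                 .size().rename("n").reset_index())
        leaving = edges.groupby("from_month")["n"].transform("sum")
        edges["fraction"] = edges["n"] / leaving
        edges["category"] = [
            _categorize(a, b) for a, b in zip(edges["from_fct"], edges["to_fct"])
        ]
        edges["hidden"] = edges["fraction"] <= display_threshold
    else:
        edges = pd.DataFrame(columns=["from_month", "from_fct", "to_month",
                                      "to_fct", "n", "fraction", "category",
                                      "hidden"])
    return TransitionGraph(nodes=node_counts, edges=edges,
                           display_threshold=display_threshold)


# -- survival ---------------------------------------------------------------

def fct_event_table(assignment: FCTAssignment, metadata: SampleTable,
                    target_fct: int, min_samples: int = 2) -> pd.DataFrame:
    """Per-infant time-to-event records for reaching ``target_fct`` or later.

    Event time = age at the earliest visit with FCT >= target; infants never
    observed there are right-censored at their last visit age.  Infants with
    fewer than ``min_samples`` samples are excluded with a warning.
    """
    if target_fct < 1:
        raise ValueError("target_fct must be >= 1")
    df = metadata.frame.merge(
        assignment.labels.rename("fct").rename_axis("sample_id").reset_index(),
        on="sample_id", how="inner",
    ).sort_values(["infant_id", "age"])
    rows, excluded = [], 0
    for iid, g in df.groupby("infant_id"):
        if len(g) < min_samples:
            excluded += 1
            continue
        hits = g[g["fct"] >= target_fct]
        if len(hits):
            rows.append({"infant_id": iid, "time": float(hits["age"].iloc[0]),
                         "event": True, "arm": g["arm"].iloc[0]})
        else:
            rows.append({"infant_id": iid, "time": float(g["age"].iloc[-1]),
                         "event": False, "arm": g["arm"].iloc[0]})
    if excluded:
        warnings.warn(f"excluded {excluded} infant(s) with < {min_samples} samples")
    return pd.DataFrame(rows)


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate from (time, event) records.

    Returns a step table with columns time, at_risk, events, censored,
    survival; S(0) = 1 and S is non-increasing.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [{"time": 0.0, "at_risk": len(t), "events": 0, "censored": 0,
             "survival": 1.0}]
    s = 1.0
    for u in np.unique(t):
        at_risk = int((t >= u).sum())
        d = int(((t == u) & e).sum())
        c = int(((t == u) & ~e).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": float(u), "at_risk": at_risk, "events": d,
                     "censored": c, "survival": s})
    return pd.DataFrame(rows)


@dataclass
class CoxResult:
    """Binary-covariate Cox PH fit with the score (log-rank) test."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    score_chi2: float
    score_p: float
    beta: float
    se: float
    n: int
    n_events: int
    meta: dict = field(default_factory=dict)


BETA_CAP = 15.0  # |beta| bound reported under complete separation


def _cox_quantities(t, e, z, beta):
    """Breslow partial log-likelihood, score, and information at beta."""
    order = np.argsort(-t, kind="stable")  # descending time
    t, e, z = t[order], e[order], z[order]
    w = np.exp(beta * z)
    loglik = score = info = 0.0
    i = 0
    s0 = s1 = 0.0  # running risk-set sums (z binary: s2 == s1)
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        s0 += w[i:j].sum()
        s1 += (w[i:j] * z[i:j]).sum()
        d_idx = np.arange(i, j)[e[i:j]]
        d = len(d_idx)
        if d:
            zsum = z[d_idx].sum()
            loglik += beta * zsum - d * np.log(s0)
            score += zsum - d * s1 / s0
            info += d * (s1 / s0 - (s1 / s0) ** 2)
        i = j
    return loglik, score, info


def cox_binary(records: pd.DataFrame, group_col: str = "arm",
               ref_level: str | None = None) -> CoxResult:
    """Cox PH with one binary covariate; score test reported as log-rank.

    The covariate is 1 for the non-reference group level (reference defaults
    to the alphabetically first level, e.g. control=0 / test=1).  Fitting is
    Newton-Raphson on the Breslow partial likelihood; the 95% CI is Wald.
    Complete separation is reported at a bounded |beta| with a warning.
    """
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    levels = sorted(pd.unique(records[group_col]))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    ref = ref_level if ref_level is not None else levels[0]
    z = (records[group_col] != ref).to_numpy(dtype=float)
    if (t <= 0).any():
        raise ValueError("event/censoring times must be > 0")
    if not e.any():
        raise ValueError("no events observed")

    _, u0, i0 = _cox_quantities(t, e, z, 0.0)
    score_chi2 = u0**2 / i0 if i0 > 0 else 0.0
    score_p = float(sps.chi2.sf(score_chi2, df=1)) if i0 > 0 else 1.0

    beta, capped = 0.0, False
    for _ in range(60):
        _, u, info = _cox_quantities(t, e, z, beta)
        if info <= 1e-12:
            break
        step = u / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) > BETA_CAP:
            beta = float(np.sign(beta) * BETA_CAP)
            capped = True
            warnings.warn("complete separation: beta capped")
            break
        if abs(step) < 1e-10:
            break
    _, _, info = _cox_quantities(t, e, z, beta)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    zq = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # capped beta under separation
        hr = float(np.exp(beta))
        lo = float(np.exp(beta - zq * se))
        hi = float(np.exp(beta + zq * se))
    return CoxResult(
        hazard_ratio=hr,
        ci_low=lo,
        ci_high=hi,
        score_chi2=float(score_chi2), score_p=score_p,
        beta=float(beta), se=float(se), n=len(t), n_events=int(e.sum()),
        meta={"reference": ref, "capped": capped},
    )
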