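"""Per-subject threshold discrimination and epileptogenic-network extraction.

First level (within subject): compare ictal vs interictal perfusion indexes
(pooled-variance Student t) and derive a perfusion-index cut-off, either by
a single-split classification tree (Gini impurity over all candidate
midpoints) or by the "traditional" mean +/- k*sd convention.  A structure
belongs to the subject's network when its PI is *equal to or greater* than
the cut-off (ictal state) or *equal to or less* (interictal state) —
comparisons are inclusive.

Second level (across subjects): location/dispersion summaries of the
thresholds, group consensus networks, and per-subject PI extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "first_level_compare",
    "tree_threshold",
    "traditional_threshold",
    "subject_thresholds",
    "extract_network",
    "consensus_network",
    "ThresholdSummary",
    "summarize_thresholds",
    "per_patient_extremes",
    "recovery_scores",
]


def first_level_compare(pi_ictal, pi_interictal) -> tuple[float, float]:
    """Two-sample pooled-variance Student t between the two states.

    Positive t means the ictal mean exceeds the interictal mean; the
    two-sided p comes from the t distribution with n1 + n2 - 2 df.  Two
    identical zero-variance samples give (0, 1).
    """
    a = np.asarray(pi_ictal, dtype=float)
    b = np.asarray(pi_interictal, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each state needs at least 2 values")
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # zero-variance case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    return t, p


def _gini_split_cost(values: np.ndarray, is_ictal: np.ndarray, cut: float) -> float:
    left = values <= cut
    cost = 0.0
    for mask in (left, ~left):
        n = mask.sum()
        if n == 0:
            continue
        p = is_ictal[mask].mean()
        cost += n * 2.0 * p * (1.0 - p)
    return cost / len(values)


def tree_threshold(pi_ictal, pi_interictal) -> float:
    """Single-split classification-tree cut-off between the two states.

    Candidates are the midpoints between adjacent distinct pooled sorted
    values; the one minimizing total Gini impurity of the two children wins,
    ties broken toward the midpoint closest to the pooled median (then the
    smaller midpoint).  All pooled values identical is degenerate.
    """
    a = np.asarray(pi_ictal, dtype=float)
    b = np.asarray(pi_interictal, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    values = np.concatenate([a, b])
    is_ictal = np.concatenate([np.ones(len(a), bool), np.zeros(len(b), bool)])
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise ValueError("degenerate: all pooled values identical")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    costs = np.array([_gini_split_cost(values, is_ictal, c) for c in mids])
    best = costs.min()
    optimal = mids[np.isclose(costs, best, rtol=0, atol=1e-12)]
    med = np.median(values)
    dist = np.abs(optimal - med)
    nearest = optimal[np.isclose(dist, dist.min(), rtol=0, atol=1e-12)]
    return float(nearest.min())


def traditional_threshold(pi_values, state: str, k: float = 1.0) -> float:
    """Mean +/- k*sd cut-off from one state's own PI distribution.

    Minus for the interictal gate (hypoperfusion), plus for the ictal gate
    (hyperperfusion).  Sample sd uses the n-1 denominator.
    """
    v = np.asarray(pi_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if state not in ("ictal", "interictal"):
        raise ValueError(f"unknown state {state!r}")
    sign = -1.0 if state == "interictal" else 1.0
    return float(v.mean() + sign * k * v.std(ddof=1))


def subject_thresholds(
    table: pd.DataFrame, method: str = "tree", k: float = 1.0
) -> pd.DataFrame:
    """Per-subject, per-state cut-offs with first-level comparison statistics.

    ``table`` is a perfusion table possibly spanning subjects and states.
    With ``method='tree'`` both states of a subject share the single split
    point of the ictal-vs-interictal comparison; with ``'traditional'`` each
    state gets mean -/+ k*sd of its own distribution.  The t statistic is
    reported whenever the subject has both states.
    """
    if method not in ("tree", "traditional"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for sid, sub in table.groupby("subject_id", sort=True):
        by_state = {s: g["pi"].to_numpy() for s, g in sub.groupby("state")}
        t_stat = p_val = np.nan
        if len(by_state) == 2 and all(len(v) >= 2 for v in by_state.values()):
            t_stat, p_val = first_level_compare(
                by_state["ictal"], by_state["interictal"]
            )
        if method == "tree":
            if len(by_state) < 2:
                continue  # the split needs both states
            thr = tree_threshold(by_state["ictal"], by_state["interictal"])
            thresholds = {s: thr for s in by_state}
        else:
            thresholds = {
                s: traditional_threshold(v, s, k=k)
                for s, v in by_state.items() if len(v) >= 2
            }
        for state, thr in thresholds.items():
            rows.append({
                "subject_id": sid, "state": state, "threshold": thr,
                "method": method, "t_statistic": t_stat, "p_value": p_val,
                "n_ictal": len(by_state.get("ictal", ())),
                "n_interictal": len(by_state.get("interictal", ())),
            })
    return pd.DataFrame(
        rows, columns=["subject_id", "state", "threshold", "method",
                       "t_statistic", "p_value", "n_ictal", "n_interictal"]
    )


def extract_network(table: pd.DataFrame, threshold: float, state: str) -> set:
    """Structures passing a subject's cut-off in one state.

    Interictal members have ``pi <= threshold``; ictal members have
    ``pi >= threshold``; both comparisons inclusive.  ``table`` must contain
    rows of that state only (for one subject).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if state not in ("ictal", "interictal"):
        raise ValueError(f"unknown state {state!r}")
    if len(table) and set(table["state"]) != {state}:
        raise ValueError(
            f"table states {sorted(set(table['state']))} do not match rule "
            f"for {state!r}"
        )
    if not len(table):
        return set()
    if state == "interictal":
        hit = table["pi"] <= threshold
    else:
        hit = table["pi"] >= threshold
    return set(zip(table.loc[hit, "name"], table.loc[hit, "side"]))


def consensus_network(networks: list, min_subjects: int) -> pd.DataFrame:
    """Structures present in at least ``min_subjects`` member sets.

    ``networks`` is a list of ``(state, member_set)`` pairs or plain member
    sets; mixed states are an error.  Returns a frame with per-structure
    subject counts, restricted to the consensus.
    """
    states = set()
    sets = []
    for nw in networks:
        if isinstance(nw, tuple):
            states.add(nw[0])
            sets.append(nw[1])
        else:
            sets.append(nw)
    if len(states) > 1:
        raise ValueError(f"mixed states in consensus: {sorted(states)}")
    counts: dict = {}
    for members in sets:
        for key in members:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"name": k[0], "side": k[1], "n_subjects": c}
        for k, c in sorted(counts.items()) if c >= min_subjects
    ]
    return pd.DataFrame(rows, columns=["name", "side", "n_subjects"])


@dataclass
class ThresholdSummary:
    """Location and dispersion of a threshold collection."""

    n: int
    mean: float
    median: float
    min: float
    max: float
    sd: float
    p5: float
    p95: float
    max_quartile: float
    sd_degenerate: bool = False  # n == 1: sd reported as 0 with this flag


def summarize_thresholds(values) -> ThresholdSummary:
    """Mean/median/min/max, sample sd (n-1), linear-interpolated percentiles.

    ``max_quartile`` is the 75th percentile.  A single value yields sd 0
    with the degenerate flag set.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("need at least one value")
    degenerate = len(v) == 1
    sd = 0.0 if degenerate else float(v.std(ddof=1))
    return ThresholdSummary(
        n=len(v),
        mean=float(v.mean()),
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
        sd=sd,
        p5=float(np.percentile(v, 5)),
        p95=float(np.percentile(v, 95)),
        max_quartile=float(np.percentile(v, 75)),
        sd_degenerate=degenerate,
    )


def per_patient_extremes(table: pd.DataFrame, state: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject min/max PI in one state, plus cross-subject summaries.

    Returns ``(per_subject, summary)``: the first frame has one row per
    subject with its minimum and maximum PI over all regions present; the
    second summarizes the minima and the maxima across subjects (mean,
    sample sd, min, max).
    """
    sub = table[table["state"] == state]
    if not len(sub):
        raise ValueError(f"no rows in state {state!r}")
    per = (
        sub.groupby("subject_id")["pi"]
        .agg(min_pi="min", max_pi="max", n_regions="size")
        .reset_index()
    )
    rows = []
    for col in ("min_pi", "max_pi"):
        v = per[col].to_numpy()
        rows.append({
            "statistic": col, "mean": v.mean(),
            "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
            "min": v.min(), "max": v.max(), "n_subjects": len(v),
        })
    return per, pd.DataFrame(rows)


def recovery_scores(
    perfusion: pd.DataFrame,
    roster: pd.DataFrame,
    truth: pd.DataFrame,
    method: str = "traditional",
    k: float = 1.0,
    min_subjects: int | None = None,
) -> dict:
    """Sensitivity/specificity of consensus networks against known truth.

    The pipeline's own machinery runs end to end on a simulated cohort:
    per-subject per-state thresholds, inclusive network extraction, then
    per-group consensus (default ``min_subjects = ceil(n_group / 2)``).  A
    region counts as recovered when it enters the consensus of its group in
    either state; truth is the designated epileptogenic-zone membership.
    """
    thr = subject_thresholds(perfusion, method=method, k=k)
    tp = fp = fn = tn = 0
    for group, subjects in roster.groupby("epilepsy_group"):
        sids = list(subjects["subject_id"])
        n_min = min_subjects or int(np.ceil(len(sids) / 2))
        flagged: set = set()
        for state in ("interictal", "ictal"):
            nets = []
            for sid in sids:
                row = thr[(thr["subject_id"] == sid) & (thr["state"] == state)]
                if not len(row):
                    continue
                sub = perfusion[
                    (perfusion["subject_id"] == sid)
                    & (perfusion["state"] == state)
                ]
                nets.append((state, extract_network(
                    sub, float(row["threshold"].iloc[0]), state)))
            cons = consensus_network(nets, n_min)
            flagged |= set(zip(cons["name"], cons["side"]))
        # ground truth membership is identical across a group's subjects
        group_truth = truth[truth["subject_id"].isin(sids)]
        per_region = group_truth.groupby(["name", "side"])["is_ez"].any()
        for (name, side), is_ez in per_region.items():
            hit = (name, side) in flagged
            if is_ez and hit:
                tp += 1
            elif is_ez:
                fn += 1
            elif hit:
                fp += 1
            else:
                tn += 1
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
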