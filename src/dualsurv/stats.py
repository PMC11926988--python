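"""Survival evaluation statistics.

Interval discretization of follow-up time, the 8-stratum class-balance
scheme, Harrell's concordance index, Kaplan–Meier curves, the two-group
log-rank test, and median-risk grouping.  Censoring convention matches
the rest of the package: censor = 0 is an observed death, censor = 1 a
censored follow-up.

KM estimation and the log-rank test are computed with lifelines (which
expects the opposite flag, ``event_observed = 1 - censor``; the
conversion happens only here).  The C-index is implemented directly
because comparability and tie conventions matter: a pair (i, j) is
comparable iff t_i < t_j and patient i's death was observed; it is
concordant when risk_i > risk_j, and risk ties receive half credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


def discretize_times(times, censor, n_bins: int = 4):
    """Quartile-based interval labels from the uncensored time distribution.

    Edges are the {25, 50, 75}-th percentiles (linear interpolation) of
    uncensored times only; every patient (censored or not) is labeled by
    the same edges, with label j iff time ∈ [edge_{j−1}, edge_j), open
    ends at ±∞.  Returns (edges, labels) with labels in 1..n_bins.
    """
    times = np.asarray(times, dtype=float)
    censor = np.asarray(censor, dtype=int)
    uncensored = times[censor == 0]
    if uncensored.size < n_bins:
        raise ValueError(
            f"need at least {n_bins} uncensored patients, got {uncensored.size}")
    qs = np.linspace(0, 100, n_bins + 1)[1:-1]
    edges = np.percentile(uncensored, qs, method="linear")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("degenerate interval edges (ties in uncensored times)")
    labels = np.searchsorted(edges, times, side="right") + 1
    return edges, labels


def assign_bins(edges, times) -> np.ndarray:
    """Label times by precomputed edges (same rule as discretize_times)."""
    edges = np.asarray(edges, dtype=float)
    return np.searchsorted(edges, np.asarray(times, dtype=float),
                           side="right") + 1


def stratify_8(labels, censor) -> np.ndarray:
    """Map (interval label 1..4, censor flag) to strata 1..8 (bijective)."""
    labels = np.asarray(labels, dtype=int)
    censor = np.asarray(censor, dtype=int)
    if np.any((labels < 1) | (labels > 4)):
        raise ValueError("labels must lie in 1..4")
    return 2 * (labels - 1) + censor + 1


def stratum_weights(labels, censor) -> np.ndarray:
    """Inverse-frequency sampling weights per patient, normalized to mean 1."""
    strata = stratify_8(labels, censor)
    _, inv, counts = np.unique(strata, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inv]
    return w / w.mean()


def concordance_index(times, censor, risks) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly.

    Comparable pairs: t_i < t_j with death observed for i.  Concordant if
    risk_i > risk_j; risk ties get 0.5 credit.
    """
    times = np.asarray(times, dtype=float)
    censor = np.asarray(censor, dtype=int)
    risks = np.asarray(risks, dtype=float)
    lt = times[:, None] < times[None, :]            # t_i < t_j
    comparable = lt & (censor[:, None] == 0)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    gt = risks[:, None] > risks[None, :]
    eq = risks[:, None] == risks[None, :]
    concordant = (comparable & gt).sum() + 0.5 * (comparable & eq).sum()
    return float(concordant / n_comp)


@dataclass
class KMCurve:
    """Right-continuous Kaplan–Meier step function at the event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time": self.event_times,
                             "survival": self.survival_probs,
                             "at_risk": self.at_risk,
                             "events": self.events})


def km_curve(times, censor) -> KMCurve:
    """Kaplan–Meier estimate; S drops by (1 − d/n) at each event time."""
    times = np.asarray(times, dtype=float)
    censor = np.asarray(censor, dtype=int)
    if times.size < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=(1 - censor))
    tab = kmf.event_table
    mask = tab["observed"].to_numpy() > 0
    event_times = tab.index.to_numpy()[mask]
    at_risk = tab["at_risk"].to_numpy()[mask]
    events = tab["observed"].to_numpy()[mask]
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return KMCurve(event_times=event_times, survival_probs=surv,
                   at_risk=at_risk.astype(int), events=events.astype(int))


def logrank_test(times_a, censor_a, times_b, censor_b):
    """Two-group log-rank test; returns (chi2 statistic, p-value)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    censor_a = np.asarray(censor_a, dtype=int)
    censor_b = np.asarray(censor_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (censor_a == 1).all() and (censor_b == 1).all():
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(times_a, times_b,
                      event_observed_A=(1 - censor_a),
                      event_observed_B=(1 - censor_b))
    return float(res.test_statistic), float(res.p_value)


def median_risk_split(risks) -> np.ndarray:
    """Split at the median risk: > median → 'high', ≤ median → 'low'."""
    risks = np.asarray(risks, dtype=float)
    if risks.size < 2:
        raise ValueError("need at least two patients to split")
    med = np.median(risks)
    groups = np.where(risks > med, "high", "low")
    if (groups == "low").all():
        warnings.warn("degenerate risk split: all risks at or below the median")
    return groups
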