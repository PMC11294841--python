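"""Survival metrics, risk stratification and group comparison.

Harrell's concordance, the Kaplan-Meier estimator and the two-group
log-rank test are implemented directly (and cross-checked against
lifelines in the test suite); the IPCW concordance and cumulative
dynamic AUC are computed with scikit-survival behind this surface.

Conventions (fixed here, checked by tests):

* comparable pairs for Harrell's C are (i, j) with t_i < t_j and
  delta_i = 1; tied event times are not comparable; tied scores earn
  0.5 credit;
* a higher prognostic index means higher risk, i.e. shorter survival;
* median stratification is strict: high risk iff PI > median.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sksurv.metrics import concordance_index_ipcw as _sksurv_ipcw
from sksurv.metrics import cumulative_dynamic_auc as _sksurv_cd_auc
from sksurv.util import Surv

from .datatypes import SurvivalLabels


def _surv_array(labels: SurvivalLabels):
    return Surv.from_arrays(event=labels.event.astype(bool), time=labels.time)


def concordance_index(pi, labels: SurvivalLabels) -> float:
    """Harrell's C over comparable pairs; ties in score count 0.5."""
    pi = np.asarray(pi, dtype=float)
    t, d = labels.time, labels.event
    if pi.shape != t.shape:
        raise ValueError("pi and labels must have equal length")
    # pair (i, j) comparable iff t_i < t_j and event observed at t_i
    comp = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    greater = pi[:, None] > pi[None, :]
    tied = pi[:, None] == pi[None, :]
    concordant = (comp & greater).sum() + 0.5 * (comp & tied).sum()
    return float(concordant / n_comp)


def ipcw_concordance(pi, labels: SurvivalLabels,
                     tau: float | None = None) -> float:
    """Uno's IPCW concordance with weights 1/G(t_i)^2, pairs t_i < tau.

    ``tau`` defaults to the 90th percentile of observed times, which
    keeps the Kaplan-Meier censoring estimate G away from zero.
    """
    pi = np.asarray(pi, dtype=float)
    if tau is None:
        tau = float(np.percentile(labels.time, 90))
    y = _surv_array(labels)
    with np.errstate(divide="raise"):
        try:
            cindex, *_ = _sksurv_ipcw(y, y, pi, tau=tau)
        except (FloatingPointError, ZeroDivisionError) as exc:
            raise ValueError(
                "censoring survival estimate reaches 0 before an event "
                "time; use a smaller tau") from exc
    return float(cindex)


def cumulative_dynamic_auc(pi, labels: SurvivalLabels, eval_times):
    """IPCW-weighted cumulative/dynamic AUC at each time plus the mean.

    Times with no cases (events by t) or no controls (times beyond t)
    are dropped with a warning. Returns ``(times, aucs, mean_auc)``.
    """
    pi = np.asarray(pi, dtype=float)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    t, d = labels.time, labels.event
    valid = []
    for tt in eval_times:
        has_case = np.any((t <= tt) & (d == 1))
        has_control = np.any(t > tt)
        if has_case and has_control:
            valid.append(tt)
        else:
            warnings.warn(f"evaluation time {tt} has no cases or no "
                          "controls; dropped", stacklevel=2)
    if not valid:
        raise ValueError("no valid evaluation times")
    valid = np.asarray(valid)
    y = _surv_array(labels)
    aucs, mean_auc = _sksurv_cd_auc(y, y, pi, valid)
    return valid, np.asarray(aucs, dtype=float), float(mean_auc)


def km_curve(labels: SurvivalLabels):
    """Kaplan-Meier product-limit estimate.

    Returns ``(times, survival)`` where times are the distinct event
    times in increasing order and survival the estimate just after each;
    the curve starts at S(0) = 1 (prepended). Censored observations
    shrink the risk set without a step.
    """
    t, d = labels.time, labels.event
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    event_times = np.unique(t[d == 1])
    surv = 1.0
    times, values = [0.0], [1.0]
    for et in event_times:
        at_risk = np.sum(t >= et)
        deaths = np.sum((t == et) & (d == 1))
        surv *= 1.0 - deaths / at_risk
        times.append(float(et))
        values.append(float(surv))
    return np.asarray(times), np.asarray(values)


def log_rank_test(groups, labels: SurvivalLabels):
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    ``groups`` is a binary/boolean label per sample (e.g. from
    :func:`stratify_by_median`).
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("log-rank test requires exactly 2 non-empty groups")
    g1 = groups == uniq[1]
    t, d = labels.time, labels.event
    event_times = np.unique(t[d == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        deaths = ((t == et) & (d == 1)).sum()
        d1 = ((t == et) & (d == 1) & g1).sum()
        o_minus_e += d1 - deaths * n1 / n
        if n > 1:
            var += deaths * (n1 / n) * (1 - n1 / n) * (n - deaths) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def stratify_by_median(pi) -> np.ndarray:
    """Median prognostic-index split: high risk (1) iff PI > median."""
    pi = np.asarray(pi, dtype=float)
    if pi.size < 2:
        raise ValueError("need >= 2 samples to stratify")
    return (pi > np.median(pi)).astype(int)
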