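"""Semi-parametric multi-state model: stratified Cox regression.

One proportional-hazards partial likelihood is maximised with each
transition type as a separate stratum, so every transition keeps its own
non-parametric baseline hazard (Breslow estimator) while covariate
effects may be transition-specific (the default: one term per covariate
per transition) or tied across transitions by listing several
transitions in one :class:`~exacmsm.parametric.CovariateTerm`.

Delayed entry is respected throughout: a subject is in the risk set of a
stratum from its entry time to its exit time.  Ties on the integer-day
scale use the Breslow approximation, consistent with the Breslow
baseline.  Optimisation is Newton-Raphson with step-halving, converging
on a relative partial-likelihood change below 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import PERMITTED_TRANSITIONS
from .nonparam import StepFunction
from .parametric import Z975, ConvergenceError, CovariateTerm

__all__ = ["CoxMsmFit", "fit_stratified_cox"]


@dataclass
class _Stratum:
    transition: tuple
    entry: np.ndarray
    exit: np.ndarray
    d: np.ndarray
    X: np.ndarray
    event_times: np.ndarray
    d_count: np.ndarray          # deaths per tied event time
    xsum_events: np.ndarray      # sum of covariates over events per time
    risk_masks: list             # boolean mask of the risk set per time


@dataclass
class CoxMsmFit:
    """Stratified Cox fit: coefficients, vcov and Breslow baselines."""

    coefficients: pd.Series
    vcov: np.ndarray
    loglik: float
    baselines: dict              # transition -> StepFunction (cumulative)
    loglik_by_stratum: dict
    n_events: dict
    terms: tuple
    n_iter: int

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.vcov), 0, None)),
                         index=self.coefficients.index)

    def summary(self) -> pd.DataFrame:
        se = self.se()
        b = self.coefficients
        return pd.DataFrame({
            "coef": b,
            "se": se,
            "hr": np.exp(b),
            "hr_ci_low": np.exp(b - Z975 * se),
            "hr_ci_high": np.exp(b + Z975 * se),
        })

    def to_json_dict(self) -> dict:
        s = self.summary()
        return {
            "loglik": float(self.loglik),
            "coefficients": {
                name: {k: float(s.loc[name, k]) for k in s.columns}
                for name in s.index
            },
            "n_events": {f"{r}->{s_}": int(n)
                         for (r, s_), n in self.n_events.items()},
        }


def _build_strata(
    dataset: pd.DataFrame, terms: Sequence[CovariateTerm]
) -> list[_Stratum]:
    strata = []
    for rs in PERMITTED_TRANSITIONS:
        sub = dataset[(dataset["from_state"] == rs[0])
                      & (dataset["to_state"] == rs[1])]
        if not len(sub):
            continue
        entry = sub["entry_time"].to_numpy(dtype=float)
        exit_ = sub["exit_time"].to_numpy(dtype=float)
        d = (sub["status"].to_numpy() == "event")
        p = len(terms)
        X = np.zeros((len(sub), p))
        for j, term in enumerate(terms):
            if rs in term.transitions:
                X[:, j] = term.values(sub)
        ev_times = np.unique(exit_[d])
        d_count = np.zeros(len(ev_times))
        xsum = np.zeros((len(ev_times), p))
        masks = []
        for i, t in enumerate(ev_times):
            at_event = d & (exit_ == t)
            d_count[i] = at_event.sum()
            xsum[i] = X[at_event].sum(axis=0)
            masks.append((entry < t) & (exit_ >= t))
        strata.append(_Stratum(rs, entry, exit_, d, X, ev_times,
                               d_count, xsum, masks))
    return strata


def _stratum_loglik(st: _Stratum, beta: np.ndarray, want_derivs: bool):
    p = st.X.shape[1]
    eta = st.X @ beta if p else np.zeros(len(st.X))
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for i in range(len(st.event_times)):
        mask = st.risk_masks[i]
        wr = w[mask]
        s0 = wr.sum()
        ll += float(st.xsum_events[i] @ beta) if p else 0.0
        ll -= st.d_count[i] * np.log(s0)
        if want_derivs and p:
            Xr = st.X[mask]
            s1 = Xr.T @ wr
            mean = s1 / s0
            grad += st.xsum_events[i] - st.d_count[i] * mean
            s2 = (Xr * wr[:, None]).T @ Xr
            hess -= st.d_count[i] * (s2 / s0 - np.outer(mean, mean))
    if want_derivs:
        return ll, grad, hess
    return ll


def _breslow_baseline(st: _Stratum, beta: np.ndarray) -> StepFunction:
    p = st.X.shape[1]
    w = np.exp(st.X @ beta) if p else np.ones(len(st.X))
    inc = np.empty(len(st.event_times))
    for i in range(len(st.event_times)):
        inc[i] = st.d_count[i] / w[st.risk_masks[i]].sum()
    return StepFunction(st.event_times, np.cumsum(inc),
                        label="breslow_{}->{}".format(*st.transition))


def fit_stratified_cox(
    dataset: pd.DataFrame,
    terms: Sequence[CovariateTerm] = (),
    *,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxMsmFit:
    """Maximise the stratified partial likelihood over all transitions.

    With no terms this is the null model, whose Breslow baseline
    increments equal the Nelson-Aalen increments d/n per stratum.  With
    transition-specific terms the joint fit decomposes into independent
    per-stratum fits (shared terms couple the strata).
    """
    terms = tuple(terms)
    if not len(dataset):
        raise ValueError("dataset has no rows")
    strata = _build_strata(dataset, terms)
    if not strata:
        raise ValueError("dataset has no rows in any permitted stratum")
    p = len(terms)
    beta = np.zeros(p)

    def total(beta, derivs):
        if not derivs:
            return sum(_stratum_loglik(st, beta, False) for st in strata)
        ll, g, h = 0.0, np.zeros(p), np.zeros((p, p))
        for st in strata:
            l_, g_, h_ = _stratum_loglik(st, beta, True)
            ll += l_
            g += g_
            h += h_
        return ll, g, h

    n_iter = 0
    if p:
        ll, g, h = total(beta, True)
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-h, g)
            except np.linalg.LinAlgError:
                raise ConvergenceError(
                    "singular information in stratified Cox fit"
                ) from None
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                ll_new = total(cand, False)
                if ll_new >= ll - 1e-12:
                    break
                factor *= 0.5
            else:
                raise ConvergenceError("step-halving failed to improve "
                                       "the partial likelihood")
            beta_new = cand
            improved = ll_new - ll
            beta = beta_new
            ll, g, h = total(beta, True)
            if abs(improved) < tol * (1.0 + abs(ll)):
                break
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} Newton iterations"
            )
        if np.max(np.abs(beta)) > 10:  # log-HR beyond any plausible effect
            j = int(np.argmax(np.abs(beta)))
            raise ConvergenceError(
                f"monotone likelihood: coefficient {terms[j].name!r} "
                "diverges"
            )
        vcov = np.linalg.inv(-h)
    else:
        ll = total(beta, False)
        vcov = np.zeros((0, 0))

    baselines = {st.transition: _breslow_baseline(st, beta) for st in strata}
    ll_by = {st.transition: float(_stratum_loglik(st, beta, False))
             for st in strata}
    n_events = {st.transition: int(st.d.sum()) for st in strata}
    return CoxMsmFit(
        coefficients=pd.Series(beta, index=[t.name for t in terms]),
        vcov=vcov, loglik=float(ll), baselines=baselines,
        loglik_by_stratum=ll_by, n_events=n_events, terms=terms,
        n_iter=n_iter,
    )
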