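"""Fully parametric multi-state Markov models by maximum likelihood.

The likelihood is the standard one for a progressive Markov process
observed as left-truncated, right-censored sojourns on the study clock.
A sojourn in state ``r`` over ``[t0, t1)`` contributes

    sum_s [ H_rs(t1) - H_rs(t0) ]  -  log h_rs*(t1) * 1{transition to s*}

summed over the permitted exits ``r -> s``; this is exactly the row-wise
sum over the long-format transition dataset, so the code works directly
on those rows.  Each transition has its own rate parameter; ancillary
shape parameters are shared across transitions by default (configurable
per transition), and covariate effects can be tied across transitions
through :class:`CovariateTerm` (one coefficient per term, applied to all
transitions the term lists).

Times are converted from days to years internally so that rate
parameters are per-year quantities of interpretable magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .events import (
    DEATH_TRANSITIONS,
    EXACERBATION_TRANSITIONS,
    PERMITTED_TRANSITIONS,
)
from .families import Family, get_family

__all__ = [
    "DAYS_PER_YEAR",
    "CovariateTerm",
    "ParametricFit",
    "ConvergenceError",
    "neg_log_likelihood",
    "fit",
    "aic_table",
    "HazardRatioEstimate",
    "transition_hazard_ratios",
    "relative_hazard_ratio",
    "likelihood_ratio_test",
    "markov_diagnostic",
    "add_treatment_dummies",
    "default_covariate_spec",
]

DAYS_PER_YEAR = 365.25

Z975 = 1.959963984540054


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class CovariateTerm:
    """One regression coefficient and the transitions it applies to.

    The covariate value entering the linear predictor is
    ``(f(x) - center) / scale`` with ``f`` the optional transform
    (``"log"``), multiplied by ``interaction_column`` if set.  Tying a
    term to several transitions (e.g. all transitions to death) imposes a
    common effect; transition-specific effects are separate terms.
    """

    name: str
    column: str
    transitions: tuple
    center: float = 0.0
    scale: float = 1.0
    transform: str | None = None
    interaction_column: str | None = None

    def _base(self, x):
        x = np.asarray(x, dtype=float)
        if self.transform == "log":
            x = np.log(x)
        elif self.transform is not None:
            raise ValueError(f"unknown transform {self.transform!r}")
        return (x - self.center) / self.scale

    def values(self, df: pd.DataFrame) -> np.ndarray:
        v = self._base(df[self.column].to_numpy())
        if self.interaction_column is not None:
            v = v * df[self.interaction_column].to_numpy(dtype=float)
        return v

    def profile_value(self, profile: Mapping) -> float:
        if self.column in profile:
            v = float(self._base(profile[self.column]))
        else:
            v = 0.0  # covariate held at its centring value
        if self.interaction_column is not None:
            v *= float(profile.get(self.interaction_column, 0.0))
        return v


def add_treatment_dummies(
    baseline: pd.DataFrame, reference_arm: str = "BFF"
) -> pd.DataFrame:
    """Expand the 4-level treatment column into indicator columns."""
    df = baseline.copy()
    arms = sorted(df["treatment"].unique())
    if reference_arm not in arms:
        raise ValueError(f"reference arm {reference_arm!r} not in {arms}")
    for arm in arms:
        if arm != reference_arm:
            df[f"trt_{arm}"] = (df["treatment"] == arm).astype(float)
    df.attrs["treatment_reference"] = reference_arm
    df.attrs["treatment_dummies"] = [f"trt_{a}" for a in arms if a != reference_arm]
    return df


def default_covariate_spec(
    treatment_dummies: Sequence[str],
    *,
    include_interaction: bool = False,
) -> tuple[CovariateTerm, ...]:
    """The pre-specified covariate structure of the adjusted model.

    Transition-specific effects on every exacerbation transition for
    treatment, prior-year exacerbations, log eosinophils (centred at
    log 200), ICS use, FEV1 %-predicted (centred at 45), sex and age
    (centred at 65).  Transitions to death share one common effect per
    covariate across states 2-4, have separate effects from state 1, and
    are independent of treatment and sex.  Optionally adds the
    eosinophil x treatment interaction (on exacerbation transitions,
    common across them).
    """
    base = [
        ("prior", "prior_exacs", dict(center=1.0)),
        ("logeos", "eos", dict(transform="log", center=float(np.log(200.0)))),
        ("ics", "ics", {}),
        ("fev1", "fev1pp", dict(center=45.0, scale=10.0)),
        ("age", "age", dict(center=65.0, scale=10.0)),
    ]
    terms: list[CovariateTerm] = []
    for r, s in EXACERBATION_TRANSITIONS:
        tag = f"{r}{s}"
        for trt in treatment_dummies:
            terms.append(CovariateTerm(f"{trt}_{tag}", trt, ((r, s),)))
        terms.append(CovariateTerm(f"male_{tag}", "male", ((r, s),)))
        for nm, col, kw in base:
            terms.append(CovariateTerm(f"{nm}_{tag}", col, ((r, s),), **kw))
    # deaths: no treatment or sex; separate from state 1, common from 2-4
    shared = tuple(t for t in DEATH_TRANSITIONS if t != (1, 5))
    for nm, col, kw in base:
        terms.append(CovariateTerm(f"{nm}_15", col, ((1, 5),), **kw))
        terms.append(CovariateTerm(f"{nm}_death", col, shared, **kw))
    if include_interaction:
        for trt in treatment_dummies:
            terms.append(CovariateTerm(
                f"logeos_x_{trt}", "eos", EXACERBATION_TRANSITIONS,
                transform="log", center=float(np.log(200.0)),
                interaction_column=trt,
            ))
    return tuple(terms)


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _Prepared:
    family: Family
    t0: np.ndarray
    t1: np.ndarray
    d: np.ndarray
    tr: np.ndarray                     # index into free_transitions
    X: np.ndarray                      # (n, p)
    free_transitions: tuple
    dropped_transitions: tuple
    group_of: np.ndarray               # shape group per free transition
    n_groups: int
    spec: tuple
    shape_sharing: str
    time_scale: float
    n_events: dict
    exposure: dict
    signature: tuple

    @property
    def m(self) -> int:
        return len(self.free_transitions)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return self.m + self.n_groups * self.family.n_anc + self.p


def _prepare(
    dataset: pd.DataFrame,
    family: Family,
    spec: Sequence[CovariateTerm],
    shape_sharing: str,
    time_scale: float,
    drop_no_event: bool = True,
) -> _Prepared:
    if shape_sharing not in ("shared", "per_transition"):
        raise ValueError("shape_sharing must be 'shared' or 'per_transition'")
    df = dataset
    codes = (df["from_state"].to_numpy(dtype=int) * 10
             + df["to_state"].to_numpy(dtype=int))
    permitted_codes = {10 * r + s for (r, s) in PERMITTED_TRANSITIONS}
    bad = sorted(set(codes.tolist()) - permitted_codes)
    if bad:
        raise ValueError(
            "dataset contains forbidden transitions: "
            + str([(c // 10, c % 10) for c in bad])
        )
    d = (df["status"].to_numpy() == "event")
    n_events, exposure = {}, {}
    t0_days = df["entry_time"].to_numpy(dtype=float)
    t1_days = df["exit_time"].to_numpy(dtype=float)
    if np.any(t1_days <= t0_days):
        raise ValueError("rows with exit_time <= entry_time are not allowed")
    for (r, s) in PERMITTED_TRANSITIONS:
        mask = codes == 10 * r + s
        n_events[(r, s)] = int(d[mask].sum())
        exposure[(r, s)] = float(
            (t1_days[mask] - t0_days[mask]).sum() / time_scale
        )
    free = tuple(rs for rs in PERMITTED_TRANSITIONS
                 if exposure[rs] > 0
                 and (n_events[rs] > 0 or not drop_no_event))
    dropped = tuple(rs for rs in PERMITTED_TRANSITIONS
                    if exposure[rs] > 0 and rs not in free)
    idx_of = {rs: i for i, rs in enumerate(free)}
    code_map = np.full(60, -1, dtype=int)
    for rs, i in idx_of.items():
        code_map[10 * rs[0] + rs[1]] = i
    tr_all = code_map[codes]
    keep = tr_all >= 0
    tr = tr_all[keep]
    t0 = t0_days[keep] / time_scale
    t1 = t1_days[keep] / time_scale
    d = d[keep]
    sub = df.loc[keep]
    if spec:
        cols = np.zeros((keep.sum(), len(spec)))
        for j, term in enumerate(spec):
            vals = term.values(sub)
            on = np.isin(tr, [idx_of[rs] for rs in term.transitions
                              if rs in idx_of])
            cols[:, j] = np.where(on, vals, 0.0)
        X = cols
    else:
        X = np.zeros((keep.sum(), 0))
    if shape_sharing == "shared":
        group_of = np.zeros(len(free), dtype=int)
        n_groups = 1
    else:
        group_of = np.arange(len(free), dtype=int)
        n_groups = len(free)
    sig = (len(df), float(t0_days.sum()), float(t1_days.sum()),
           int((df["status"] == "event").sum()))
    return _Prepared(family, t0, t1, d, tr, X, free, dropped, group_of,
                     n_groups, tuple(spec), shape_sharing, time_scale,
                     n_events, exposure, sig)


def _unpack(theta: np.ndarray, prep: _Prepared):
    m, A, G = prep.m, prep.family.n_anc, prep.n_groups
    v = theta[:m]
    anc = theta[m:m + G * A].reshape(G, A)
    beta = theta[m + G * A:]
    return v, anc, beta


def _nll_core(theta: np.ndarray, prep: _Prepared, want_grad: bool):
    fam = prep.family
    v, anc, beta = _unpack(theta, prep)
    eta = v[prep.tr] + (prep.X @ beta if prep.p else 0.0)
    row_group = prep.group_of[prep.tr]
    n = len(eta)
    H = np.empty(n)
    logh = np.zeros(n)
    danc_H = np.zeros((n, fam.n_anc)) if (want_grad and fam.n_anc) else None
    danc_lh = np.zeros((n, fam.n_anc)) if (want_grad and fam.n_anc) else None
    ev = prep.d
    for g in range(prep.n_groups):
        rows = row_group == g if prep.n_groups > 1 else slice(None)
        a = anc[g]
        t0g, t1g, etag = prep.t0[rows], prep.t1[rows], eta[rows]
        if fam.kind == "ph":
            dG = fam.cumhaz(t1g, a) - fam.cumhaz(t0g, a)
            H[rows] = np.exp(etag) * dG
            logh[rows] = etag + fam.loghaz(t1g, a)
            if want_grad and fam.n_anc:
                dG1 = fam.cumhaz_danc(t1g, a)
                dG0 = fam.cumhaz_danc(t0g, a)
                dlh = fam.loghaz_danc(t1g, a)
                for j in range(fam.n_anc):
                    danc_H[rows, j] = np.exp(etag) * (dG1[j] - dG0[j])
                    danc_lh[rows, j] = dlh[j]
        else:
            u0 = t0g * np.exp(etag)
            u1 = t1g * np.exp(etag)
            H[rows] = fam.cumhaz(u1, a) - fam.cumhaz(u0, a)
            logh[rows] = etag + fam.loghaz(u1, a)
    nll = H.sum() - logh[ev].sum()
    if not np.isfinite(nll):
        nll = np.inf
    if not want_grad:
        return nll
    # analytic gradient (PH families only)
    w = H - ev  # dNLL/d eta per row
    grad_v = np.bincount(prep.tr, weights=w, minlength=prep.m)
    grad_beta = prep.X.T @ w if prep.p else np.zeros(0)
    grad_anc = np.zeros((prep.n_groups, fam.n_anc))
    if fam.n_anc:
        for g in range(prep.n_groups):
            rows = row_group == g if prep.n_groups > 1 else slice(None)
            for j in range(fam.n_anc):
                dH = danc_H[rows, j]
                dlh = np.where(ev[rows], danc_lh[rows, j], 0.0)
                grad_anc[g, j] = dH.sum() - dlh.sum()
    grad = np.concatenate([grad_v, grad_anc.ravel(), grad_beta])
    return nll, np.nan_to_num(grad, nan=0.0, posinf=1e12, neginf=-1e12)


def neg_log_likelihood(
    theta: np.ndarray,
    dataset: pd.DataFrame,
    family: str | Family = "weibull",
    spec: Sequence[CovariateTerm] = (),
    *,
    shape_sharing: str = "shared",
    time_scale: float = DAYS_PER_YEAR,
) -> float:
    """Multi-state negative log-likelihood at an unconstrained parameter
    vector (log rates per free transition, ancillaries, coefficients)."""
    fam = family if isinstance(family, Family) else get_family(family)
    prep = _prepare(dataset, fam, spec, shape_sharing, time_scale,
                    drop_no_event=False)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (prep.k,):
        raise ValueError(f"theta must have length {prep.k}, got {theta.shape}")
    return float(_nll_core(theta, prep, want_grad=False))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ParametricFit:
    """A fitted parametric multi-state model and everything prediction needs."""

    family: str
    kind: str
    transitions: tuple
    dropped_transitions: tuple
    spec: tuple
    shape_sharing: str
    theta: np.ndarray
    param_names: tuple
    loglik: float
    aic: float
    k: int
    vcov: np.ndarray
    n_events: dict
    exposure: dict
    time_scale: float
    n_rows: int
    data_signature: tuple
    score_norm: float
    group_of: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    n_anc: int = 0
    n_groups: int = 1

    # -- parameter access ---------------------------------------------------

    def _fam(self) -> Family:
        return get_family(self.family)

    def _index(self, transition) -> int:
        try:
            return self.transitions.index(tuple(transition))
        except ValueError:
            raise KeyError(f"transition {transition} not in fit") from None

    def rate(self, transition) -> float:
        """exp of the transition's log-rate parameter (per year)."""
        return float(np.exp(self.theta[self._index(transition)]))

    def anc_values(self, transition=None) -> np.ndarray:
        m = len(self.transitions)
        anc = self.theta[m:m + self.n_groups * self.n_anc]
        anc = anc.reshape(self.n_groups, self.n_anc)
        if transition is None:
            g = 0
        else:
            g = int(self.group_of[self._index(transition)])
        return anc[g]

    def coefficients(self) -> pd.Series:
        off = len(self.transitions) + self.n_groups * self.n_anc
        return pd.Series(self.theta[off:],
                         index=[t.name for t in self.spec])

    def linear_predictor(self, transition, profile: Mapping | None = None) -> float:
        eta = self.theta[self._index(transition)]
        if profile and self.spec:
            beta = self.coefficients()
            for term in self.spec:
                if tuple(transition) in term.transitions:
                    eta += beta[term.name] * term.profile_value(profile)
        return float(eta)

    def cumulative_hazard(self, transition, t_years, profile=None) -> np.ndarray:
        """H_rs(t | profile) with t in years since study start."""
        fam = self._fam()
        t = np.asarray(t_years, dtype=float)
        if tuple(transition) in self.dropped_transitions:
            return np.zeros_like(t)
        eta = self.linear_predictor(transition, profile)
        anc = self.anc_values(transition)
        if fam.kind == "ph":
            return np.exp(eta) * fam.cumhaz(t, anc)
        return fam.cumhaz(t * np.exp(eta), anc)

    def hazard(self, transition, t_years, profile=None) -> np.ndarray:
        fam = self._fam()
        t = np.asarray(t_years, dtype=float)
        if tuple(transition) in self.dropped_transitions:
            return np.zeros_like(t)
        eta = self.linear_predictor(transition, profile)
        anc = self.anc_values(transition)
        if fam.kind == "ph":
            return np.exp(eta + fam.loghaz(t, anc))
        return np.exp(eta + fam.loghaz(t * np.exp(eta), anc))

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def summary(self) -> pd.DataFrame:
        se = self.se()
        est = self.theta
        return pd.DataFrame({
            "estimate": est,
            "se": se,
            "ci_low": est - Z975 * se,
            "ci_high": est + Z975 * se,
        }, index=list(self.param_names))

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "shape_sharing": self.shape_sharing,
            "transitions": [list(t) for t in self.transitions],
            "dropped_transitions": [list(t) for t in self.dropped_transitions],
            "param_names": list(self.param_names),
            "theta": [float(x) for x in self.theta],
            "vcov": [[float(x) for x in row] for row in self.vcov],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "k": int(self.k),
            "n_events": {f"{r}->{s}": int(n)
                         for (r, s), n in self.n_events.items()},
            "terms": [
                {"name": t.name, "column": t.column,
                 "transitions": [list(x) for x in t.transitions],
                 "center": t.center, "scale": t.scale,
                 "transform": t.transform,
                 "interaction_column": t.interaction_column}
                for t in self.spec
            ],
            "time_scale_days_per_unit": self.time_scale,
        }


def _param_names(prep: _Prepared) -> tuple:
    names = [f"lograte_{r}->{s}" for (r, s) in prep.free_transitions]
    for g in range(prep.n_groups):
        suffix = "" if prep.n_groups == 1 else \
            "_{}->{}".format(*prep.free_transitions[g])
        names += [f"{a}{suffix}" for a in prep.family.anc_names]
    names += [t.name for t in prep.spec]
    return tuple(names)


def _initial_theta(prep: _Prepared) -> np.ndarray:
    v0 = np.array([
        np.log(max(prep.n_events[rs], 0.5) / prep.exposure[rs])
        for rs in prep.free_transitions
    ])
    anc0 = np.zeros((prep.n_groups, prep.family.n_anc))
    if prep.family.name == "gengamma":
        anc0[:, 1] = 0.5  # start between log-normal (0) and Weibull (1)
    return np.concatenate([v0, anc0.ravel(), np.zeros(prep.p)])


def _hessian(fun_grad, theta: np.ndarray, analytic: bool, fun=None) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    if analytic:
        for i in range(k):
            h = 1e-6 * (1.0 + abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            _, gp = fun_grad(tp)
            _, gm = fun_grad(tm)
            H[i] = (gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)
    h = 1e-4 * (1.0 + np.abs(theta))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            H[i, j] = H[j, i] = (
                fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)
            ) / (4.0 * h[i] * h[j])
    return H


def fit(
    dataset: pd.DataFrame,
    family: str | Family = "weibull",
    spec: Sequence[CovariateTerm] = (),
    *,
    shape_sharing: str = "shared",
    time_scale: float = DAYS_PER_YEAR,
    compute_vcov: bool = True,
    maxiter: int = 1000,
) -> ParametricFit:
    """Maximise the multi-state likelihood for one parametric family.

    Three deterministic starts are used (occurrence/exposure rates, then
    the same perturbed +-0.5 on the log-rate scale); BFGS with analytic
    gradients for the proportional-hazards families.  Transitions with
    exposure but no events are flagged non-identifiable and their hazard
    fixed at zero.  The variance-covariance matrix is the inverse
    observed information at the optimum (pseudo-inverse with a warning
    when the information is singular).
    """
    fam = family if isinstance(family, Family) else get_family(family)
    prep = _prepare(dataset, fam, spec, shape_sharing, time_scale)
    if prep.p:
        idx_of = {rs: i for i, rs in enumerate(prep.free_transitions)}
        for j, term in enumerate(prep.spec):
            on = np.isin(prep.tr, [idx_of[rs] for rs in term.transitions
                                   if rs in idx_of])
            col = prep.X[on, j]
            if col.size and np.ptp(col) == 0.0:
                raise ValueError(
                    f"covariate degenerate: term {term.name!r} has zero "
                    "variance on its transitions"
                )

    theta0 = _initial_theta(prep)
    starts = [theta0]
    for delta in (0.5, -0.5):
        t = theta0.copy()
        t[:prep.m] += delta
        starts.append(t)

    if fam.has_grad:
        def fg(th):
            return _nll_core(th, prep, want_grad=True)
        jac = True
    else:
        def fg(th):
            return _nll_core(th, prep, want_grad=False)
        jac = None

    best = None
    for start in starts:
        res = optimize.minimize(fg, start, jac=jac, method="BFGS",
                                options={"gtol": 1e-9, "maxiter": maxiter})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.success and best is res:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            f"{fam.name}: optimisation failed after {len(starts)} starts"
        )
    theta = best.x
    grad_norm = float(np.linalg.norm(np.atleast_1d(best.jac))) \
        if best.jac is not None else np.nan
    if fam.has_grad and grad_norm > 1e-4 * (1.0 + abs(best.fun)):
        raise ConvergenceError(
            f"{fam.name}: score norm {grad_norm:.2e} too large at optimum; "
            f"message: {best.message}"
        )

    loglik = -float(best.fun)
    k = prep.k
    if compute_vcov:
        if fam.has_grad:
            Hmat = _hessian(lambda th: _nll_core(th, prep, True), theta, True)
        else:
            Hmat = _hessian(None, theta, False,
                            fun=lambda th: _nll_core(th, prep, False))
        try:
            vcov = np.linalg.inv(Hmat)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(f"{fam.name}: singular observed information; "
                          "using pseudo-inverse", RuntimeWarning)
            vcov = np.linalg.pinv(Hmat)
        vcov = 0.5 * (vcov + vcov.T)
    else:
        vcov = np.full((k, k), np.nan)

    return ParametricFit(
        family=fam.name, kind=fam.kind,
        transitions=prep.free_transitions,
        dropped_transitions=prep.dropped_transitions,
        spec=prep.spec, shape_sharing=prep.shape_sharing,
        theta=theta, param_names=_param_names(prep),
        loglik=loglik, aic=2.0 * k - 2.0 * loglik, k=k, vcov=vcov,
        n_events=prep.n_events, exposure=prep.exposure,
        time_scale=prep.time_scale, n_rows=len(prep.t0),
        data_signature=prep.signature, score_norm=grad_norm,
        group_of=prep.group_of, n_anc=fam.n_anc, n_groups=prep.n_groups,
    )


def aic_table(fits: Iterable[ParametricFit]) -> pd.DataFrame:
    """Rank fitted families by AIC (same dataset required)."""
    fits = list(fits)
    sigs = {f.data_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("aic_table requires fits on the same dataset")
    df = pd.DataFrame({
        "family": [f.family for f in fits],
        "k": [f.k for f in fits],
        "loglik": [f.loglik for f in fits],
        "aic": [f.aic for f in fits],
    }).sort_values("aic", kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# hazard ratios and tests


@dataclass(frozen=True)
class HazardRatioEstimate:
    numerator: tuple
    denominator: tuple
    hr: float
    se_log_hr: float
    ci_low: float
    ci_high: float


def _log_hr_closed_form(fit_: ParametricFit, a, b):
    ia, ib = fit_._index(a), fit_._index(b)
    log_hr = fit_.theta[ia] - fit_.theta[ib]
    var = (fit_.vcov[ia, ia] + fit_.vcov[ib, ib] - 2.0 * fit_.vcov[ia, ib])
    return log_hr, float(np.sqrt(max(var, 0.0)))


def _log_hr_at_time(fit_: ParametricFit, a, b, t_years: float):
    def f(theta):
        alt = _clone_with_theta(fit_, theta)
        return (np.log(alt.hazard(a, t_years))
                - np.log(alt.hazard(b, t_years)))
    theta = fit_.theta
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2.0 * h)
    var = float(g @ fit_.vcov @ g)
    return float(f(theta)), float(np.sqrt(max(var, 0.0)))


def _clone_with_theta(fit_: ParametricFit, theta) -> ParametricFit:
    import copy
    alt = copy.copy(fit_)
    alt.theta = np.asarray(theta, dtype=float)
    return alt


def transition_hazard_ratios(
    fit_: ParametricFit,
    pairs: Sequence[tuple],
    *,
    t_ref_years: float | None = None,
) -> list[HazardRatioEstimate]:
    """Hazard ratios between transitions with delta-method 95% CIs.

    Constant ratios exist only for proportional-hazards families whose
    ancillary parameters are shared between the two transitions; for any
    other configuration a reference time must be supplied and the ratio
    is reported at that time.
    """
    out = []
    fam = get_family(fit_.family)
    for a, b in pairs:
        a, b = tuple(a), tuple(b)
        same_group = (fit_.group_of[fit_._index(a)]
                      == fit_.group_of[fit_._index(b)])
        constant = fam.kind == "ph" and (fam.n_anc == 0 or same_group)
        if constant:
            log_hr, se = _log_hr_closed_form(fit_, a, b)
        elif t_ref_years is None:
            raise ValueError(
                f"hazard ratio {a} vs {b} is time-varying for family "
                f"{fit_.family!r}; supply t_ref_years"
            )
        else:
            log_hr, se = _log_hr_at_time(fit_, a, b, t_ref_years)
        out.append(HazardRatioEstimate(
            a, b, float(np.exp(log_hr)), se,
            float(np.exp(log_hr - Z975 * se)),
            float(np.exp(log_hr + Z975 * se)),
        ))
    return out


def relative_hazard_ratio(hr_a_vs_ref: float, hr_b_vs_ref: float) -> float:
    """HR(A vs B) implied by two HRs against a common reference state.

    Exact under shared-shape proportional hazards, where every pairwise
    hazard ratio is a ratio of rate parameters.
    """
    if hr_a_vs_ref <= 0 or hr_b_vs_ref <= 0:
        raise ValueError("hazard ratios must be positive")
    return hr_a_vs_ref / hr_b_vs_ref


def likelihood_ratio_test(
    nested: ParametricFit, full: ParametricFit
) -> dict:
    """2*(loglik_full - loglik_nested) against chi-square(delta k)."""
    if nested.data_signature != full.data_signature:
        raise ValueError("LRT requires fits on the same dataset")
    df = full.k - nested.k
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6 * (1.0 + abs(full.loglik)):
        raise ConvergenceError(
            f"full-model log-likelihood {full.loglik:.6f} below nested "
            f"{nested.loglik:.6f}: optimisation failure"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return {"statistic": float(stat), "df": int(df), "p_value": p}


# ---------------------------------------------------------------------------
# Markov diagnostic


def add_time_in_state1(dataset: pd.DataFrame) -> pd.DataFrame:
    """Attach each patient's State-1 exit time as a covariate column."""
    df = dataset.copy()
    s1 = df[df["from_state"] == 1].groupby("patient_id")["exit_time"].max()
    df["time_in_state1"] = df["patient_id"].map(s1)
    return df


def markov_diagnostic(
    dataset: pd.DataFrame,
    family: str | Family = "weibull",
    spec: Sequence[CovariateTerm] = (),
    *,
    shape_sharing: str = "shared",
    time_scale: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Clock-forward Markov check: time spent in State 1 as a covariate.

    Refits the model with the patient's State-1 sojourn time (centred,
    in years) added to every transition out of states 2-4 and returns
    the per-transition hazard ratios with 95% CIs.  Under the Markov
    assumption all ratios should be near 1.
    """
    df = add_time_in_state1(dataset)
    later = df["from_state"] >= 2
    tis = df.loc[later, "time_in_state1"]
    if tis.isna().any():
        raise ValueError("State-1 exit time missing for some patients")
    if float(tis.std()) == 0.0:
        raise ValueError("covariate degenerate: all State-1 times equal")
    center = float(tis.mean())
    targets = [rs for rs in PERMITTED_TRANSITIONS if rs[0] >= 2]
    extra = tuple(
        CovariateTerm(f"tis1_{r}->{s}", "time_in_state1", ((r, s),),
                      center=center, scale=time_scale)
        for (r, s) in targets
    )
    fit_ = fit(df, family, tuple(spec) + extra,
               shape_sharing=shape_sharing, time_scale=time_scale)
    rows = []
    beta = fit_.coefficients()
    se = pd.Series(fit_.se(), index=list(fit_.param_names))
    for (r, s) in targets:
        name = f"tis1_{r}->{s}"
        if name not in beta.index:
            continue
        b, s_ = float(beta[name]), float(se[name])
        rows.append({
            "transition": f"{r}->{s}",
            "hr_per_year_in_state1": float(np.exp(b)),
            "ci_low": float(np.exp(b - Z975 * s_)),
            "ci_high": float(np.exp(b + Z975 * s_)),
        })
    return pd.DataFrame(rows)
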