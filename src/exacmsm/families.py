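"""Hazard families for the parametric transition models.

Every transition ``r -> s`` carries a log-rate-like linear predictor

    eta = v_rs + x' beta

and a family-specific baseline.  Proportional-hazards families
(exponential, Weibull, Gompertz) use

    H(t | x) = exp(eta) * G(t; anc),      h = exp(eta) * g(t; anc),

so ``exp(eta_a - eta_b)`` is a constant hazard ratio whenever the
ancillary parameters are shared.  The remaining families (log-logistic,
log-normal, gamma, generalised gamma) are accelerated-failure-time style:
time is rescaled, ``u = t * exp(eta)`` and

    H(t | x) = G(u; anc),                 h = exp(eta) * g(u; anc),

which does not give a constant hazard ratio between transitions.

Ancillary parameters live on an unconstrained scale (log for positive
shapes, identity for the Gompertz slope and the generalised-gamma Q).
The generalised gamma uses the (mu, sigma, Q) parameterisation, which
contains the log-normal at Q=0, the Weibull at Q=1 and the gamma at
Q=sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["Family", "FAMILIES", "get_family", "FAMILY_NAMES"]

_LOG_EPS = 1e-300


def _safe_log(x):
    return np.log(np.clip(x, _LOG_EPS, None))


@dataclass(frozen=True)
class Family:
    """A parametric baseline hazard with unconstrained ancillary scale."""

    name: str
    kind: str                  # "ph" or "aft"
    anc_names: tuple = ()
    has_grad: bool = False     # analytic gradient available in the fitter

    @property
    def n_anc(self) -> int:
        return len(self.anc_names)

    # subclasses implement on the natural time scale (rate already applied
    # for AFT via u = t * exp(eta); for PH these are rate-1 baselines).
    def cumhaz(self, t, anc):            # G
        raise NotImplementedError

    def loghaz(self, t, anc):            # log g
        raise NotImplementedError

    def cumhaz_danc(self, t, anc):       # dG/d(unconstrained anc), list
        raise NotImplementedError

    def loghaz_danc(self, t, anc):       # dlog g/d(unconstrained anc), list
        raise NotImplementedError

    def describe_anc(self, anc) -> dict:
        return dict(zip(self.anc_names, np.atleast_1d(np.asarray(anc, float))))


class _Exponential(Family):
    def cumhaz(self, t, anc):
        return np.asarray(t, float)

    def loghaz(self, t, anc):
        return np.zeros_like(np.asarray(t, float))

    def cumhaz_danc(self, t, anc):
        return []

    def loghaz_danc(self, t, anc):
        return []


class _Weibull(Family):
    """PH Weibull: G(t) = t^a, g(t) = a t^(a-1), a = exp(u)."""

    def cumhaz(self, t, anc):
        a = np.exp(anc[0])
        return np.power(t, a)

    def loghaz(self, t, anc):
        a = np.exp(anc[0])
        return anc[0] + (a - 1.0) * _safe_log(t)

    def cumhaz_danc(self, t, anc):
        a = np.exp(anc[0])
        t = np.asarray(t, float)
        out = np.where(t > 0, np.power(t, a) * _safe_log(t) * a, 0.0)
        return [out]

    def loghaz_danc(self, t, anc):
        a = np.exp(anc[0])
        return [1.0 + a * _safe_log(t)]


class _Gompertz(Family):
    """PH Gompertz: g(t) = exp(gamma t), G(t) = expm1(gamma t)/gamma."""

    def cumhaz(self, t, anc):
        g = anc[0]
        t = np.asarray(t, float)
        if abs(g) < 1e-8:
            return t * (1.0 + 0.5 * g * t)
        return np.expm1(g * t) / g

    def loghaz(self, t, anc):
        return anc[0] * np.asarray(t, float)

    def cumhaz_danc(self, t, anc):
        g = anc[0]
        t = np.asarray(t, float)
        if abs(g) < 1e-8:
            return [0.5 * t * t]
        return [(t * np.exp(g * t) * g - np.expm1(g * t)) / (g * g)]

    def loghaz_danc(self, t, anc):
        return [np.asarray(t, float)]


class _LogLogistic(Family):
    """AFT log-logistic: S(u) = 1/(1 + u^b), b = exp(anc)."""

    def cumhaz(self, t, anc):
        b = np.exp(anc[0])
        return np.log1p(np.power(t, b))

    def loghaz(self, t, anc):
        b = np.exp(anc[0])
        logu = _safe_log(t)
        return anc[0] + (b - 1.0) * logu - np.log1p(np.power(t, b))


class _LogNormal(Family):
    """AFT log-normal with unit median: z = log(u)/sigma, sigma = exp(anc)."""

    def cumhaz(self, t, anc):
        s = np.exp(anc[0])
        z = _safe_log(t) / s
        return -special.log_ndtr(-z)

    def loghaz(self, t, anc):
        s = np.exp(anc[0])
        logu = _safe_log(t)
        z = logu / s
        logf = -0.5 * z * z - logu - anc[0] - 0.5 * np.log(2.0 * np.pi)
        return logf - special.log_ndtr(-z)


class _Gamma(Family):
    """AFT gamma with unit rate and shape k = exp(anc)."""

    def cumhaz(self, t, anc):
        k = np.exp(anc[0])
        return -stats.gamma.logsf(t, k)

    def loghaz(self, t, anc):
        k = np.exp(anc[0])
        return stats.gamma.logpdf(t, k) - stats.gamma.logsf(t, k)


class _GenGamma(Family):
    """Generalised gamma, (sigma, Q) ancillaries: sigma = exp(u1), Q = u2.

    With w = log(u)/sigma and a = Q^-2:
        S(u) = Gammaincc(a, a e^{Qw})  for Q > 0   (Gammainc for Q < 0)
        log f = log|Q| + a log a - lgamma(a) - log(sigma u) + a (Qw - e^{Qw})
    and the Q -> 0 limit is the log-normal.
    """

    _Q_TOL = 1e-6

    def _lognormal(self):
        return _LogNormal("lognormal", "aft", ("log_sigma",))

    def cumhaz(self, t, anc):
        sigma, q = np.exp(anc[0]), anc[1]
        if abs(q) < self._Q_TOL:
            return self._lognormal().cumhaz(t, anc[:1])
        a = q ** -2
        w = _safe_log(t) / sigma
        x = a * np.exp(np.clip(q * w, -700, 700))
        sf = special.gammaincc(a, x) if q > 0 else special.gammainc(a, x)
        return -_safe_log(sf)

    def loghaz(self, t, anc):
        sigma, q = np.exp(anc[0]), anc[1]
        if abs(q) < self._Q_TOL:
            return self._lognormal().loghaz(t, anc[:1])
        a = q ** -2
        logu = _safe_log(t)
        w = logu / sigma
        qw = np.clip(q * w, -700, 700)
        logf = (np.log(abs(q)) + a * np.log(a) - special.gammaln(a)
                - anc[0] - logu + a * (qw - np.exp(qw)))
        return logf + self.cumhaz(t, anc)


FAMILIES: dict[str, Family] = {
    "exponential": _Exponential("exponential", "ph", (), True),
    "weibull": _Weibull("weibull", "ph", ("log_shape",), True),
    "gompertz": _Gompertz("gompertz", "ph", ("gamma",), True),
    "loglogistic": _LogLogistic("loglogistic", "aft", ("log_shape",)),
    "lognormal": _LogNormal("lognormal", "aft", ("log_sigma",)),
    "gamma": _Gamma("gamma", "aft", ("log_shape",)),
    "gengamma": _GenGamma("gengamma", "aft", ("log_sigma", "Q")),
}

FAMILY_NAMES = tuple(FAMILIES)

_ALIASES = {
    "exp": "exponential",
    "log-logistic": "loglogistic",
    "log-normal": "lognormal",
    "generalised gamma": "gengamma",
    "generalized gamma": "gengamma",
}


def get_family(name: str) -> Family:
    key = name.lower().strip()
    key = _ALIASES.get(key, key)
    if key not in FAMILIES:
        raise KeyError(f"unknown family {name!r}; choose from {FAMILY_NAMES}")
    return FAMILIES[key]
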