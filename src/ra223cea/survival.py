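"""Parametric time-to-event laws and right-censored maximum-likelihood fitting.

Four families are supported, all with time measured in weeks:

========== =============================== ==========================
family     survival function               parameters
========== =============================== ==========================
exponential ``S(t) = exp(-t/scale)``       scale = mean survival
weibull     ``S(t) = exp(-(t/scale)^k)``   shape ``k``
loglogistic ``S(t) = 1/(1+(t/scale)^k)``   shape ``k``
lognormal   ``S(t) = 1-Phi((ln t-mu)/sig)``scale = ``mu``, shape = ``ln sigma``
========== =============================== ==========================

The lognormal convention deserves emphasis: the ``shape`` field stores the
*logarithm* of the log-time standard deviation, so negative shapes are legal
and ``sigma = exp(shape)`` is always positive.  This is the convention in
which published scale/shape pairs for this model are quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal")

__all__ = [
    "FAMILIES",
    "SurvivalCurve",
    "IPDRecord",
    "FitResult",
    "survival_at",
    "cycle_event_prob",
    "restricted_mean",
    "fit_mle",
    "select_by_aic",
    "read_ipd",
    "write_ipd",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A parametric time-to-event law (time in weeks)."""

    family: str
    scale: float
    shape: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown survival family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "lognormal":
            # shape is log(sigma): any real value is legal
            pass
        elif self.family == "exponential":
            if self.scale <= 0:
                raise ValueError("exponential scale (mean) must be positive")
        else:
            if self.scale <= 0 or self.shape <= 0:
                raise ValueError(f"{self.family} requires positive scale and shape")

    @property
    def sigma(self) -> float:
        """Dispersion on the natural scale (lognormal only)."""
        if self.family != "lognormal":
            raise AttributeError("sigma is defined for the lognormal family only")
        return math.exp(self.shape)


@dataclass(frozen=True)
class IPDRecord:
    """One individual's observed time (weeks), event flag and arm label."""

    time: float
    event: bool
    arm: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError(f"time must be finite and positive, got {self.time}")


def survival_at(curve: SurvivalCurve, t):
    """S(t) for scalar or array ``t`` (weeks)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    s = np.ones_like(t)
    pos = t > 0
    tp = t[pos]
    if curve.family == "exponential":
        s[pos] = np.exp(-tp / curve.scale)
    elif curve.family == "weibull":
        s[pos] = np.exp(-((tp / curve.scale) ** curve.shape))
    elif curve.family == "loglogistic":
        s[pos] = 1.0 / (1.0 + (tp / curve.scale) ** curve.shape)
    else:  # lognormal
        s[pos] = norm.sf((np.log(tp) - curve.scale) / math.exp(curve.shape))
    return float(s[0]) if scalar else s


def cycle_event_prob(curve: SurvivalCurve, k: int, cycle_weeks: float = 1.0) -> float:
    """Conditional probability of the event during cycle ``k``.

    ``1 - S(k*d)/S((k-1)*d)`` — the probability that a subject still
    event-free when cycle ``k`` starts experiences the event before it ends.
    When the curve has already underflowed to zero the event is certain by
    convention and 1.0 is returned.
    """
    if k < 1:
        raise ValueError("cycle index k must be >= 1")
    s0 = survival_at(curve, (k - 1) * cycle_weeks)
    if s0 <= 0.0:
        return 1.0
    s1 = survival_at(curve, k * cycle_weeks)
    return min(max(1.0 - s1 / s0, 0.0), 1.0)


def restricted_mean(
    curve: SurvivalCurve, horizon_weeks: float, annual_rate: float = 0.0
) -> float:
    """Discounted restricted mean survival in years.

    Integrates ``S(t) * (1+r)^(-t/52)`` over ``[0, horizon]`` (weeks) by
    adaptive quadrature and divides by 52.  With ``annual_rate=0`` this is
    the truncated mean survival time.
    """
    if horizon_weeks < 0:
        raise ValueError("horizon must be non-negative")
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    if horizon_weeks == 0:
        return 0.0
    log1p_r = math.log1p(annual_rate)

    def integrand(t):
        return survival_at(curve, t) * math.exp(-log1p_r * t / 52.0)

    value, _ = integrate.quad(
        integrand, 0.0, horizon_weeks, epsabs=1e-8 * 52.0, limit=200
    )
    return value / 52.0


# ---------------------------------------------------------------------------
# Fitting (right-censored MLE via lifelines) and AIC model selection
# ---------------------------------------------------------------------------

_N_PARAMS = {"exponential": 1, "weibull": 2, "loglogistic": 2, "lognormal": 2}


@dataclass(frozen=True)
class FitResult:
    curve: SurvivalCurve
    log_likelihood: float
    aic: float
    n_params: int
    family: str
    converged: bool = True


def _to_curve(family: str, fitter) -> SurvivalCurve:
    if family == "exponential":
        return SurvivalCurve("exponential", float(fitter.lambda_))
    if family == "weibull":
        return SurvivalCurve("weibull", float(fitter.lambda_), float(fitter.rho_))
    if family == "loglogistic":
        return SurvivalCurve("loglogistic", float(fitter.alpha_), float(fitter.beta_))
    return SurvivalCurve(
        "lognormal", float(fitter.mu_), math.log(float(fitter.sigma_))
    )


def fit_mle(records: Sequence[IPDRecord], family: str) -> FitResult:
    """Maximum-likelihood fit of one family to right-censored records.

    The censored log-likelihood ``sum_events log f(t) + sum_censored log S(t)``
    is maximised; ``AIC = 2k - 2 loglik`` with ``k = 1`` for the exponential
    family and 2 otherwise.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(records) < 10:
        raise ValueError("need at least 10 records to fit")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if events.sum() < 5:
        raise ValueError(
            f"need at least 5 observed events to fit, got {int(events.sum())}"
        )

    from lifelines import (
        ExponentialFitter,
        LogLogisticFitter,
        LogNormalFitter,
        WeibullFitter,
    )
    from lifelines.exceptions import ConvergenceError

    fitter_cls = {
        "exponential": ExponentialFitter,
        "weibull": WeibullFitter,
        "loglogistic": LogLogisticFitter,
        "lognormal": LogNormalFitter,
    }[family]
    fitter = fitter_cls()
    try:
        fitter.fit(times, event_observed=events)
    except ConvergenceError as err:  # pragma: no cover - rare pathological data
        raise RuntimeError(f"MLE for {family} did not converge: {err}") from err
    k = _N_PARAMS[family]
    loglik = float(fitter.log_likelihood_)
    return FitResult(
        curve=_to_curve(family, fitter),
        log_likelihood=loglik,
        aic=2.0 * k - 2.0 * loglik,
        n_params=k,
        family=family,
    )


def select_by_aic(fits: Iterable[FitResult]) -> tuple[FitResult, pd.DataFrame]:
    """Pick the minimum-AIC fit; ties go to the fewer-parameter family.

    Returns the winning fit and the full AIC table sorted by (AIC, n_params).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    order = sorted(fits, key=lambda f: (round(f.aic, 10), f.n_params))
    table = pd.DataFrame(
        {
            "family": [f.family for f in order],
            "n_params": [f.n_params for f in order],
            "log_likelihood": [f.log_likelihood for f in order],
            "aic": [f.aic for f in order],
        }
    )
    return order[0], table


# ---------------------------------------------------------------------------
# IPD delimited-text interchange
# ---------------------------------------------------------------------------


def write_ipd(records: Sequence[IPDRecord], path) -> None:
    """Write records as tab-separated text: time_weeks, event, arm."""
    df = pd.DataFrame(
        {
            "time_weeks": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "arm": [r.arm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ipd(path) -> list[IPDRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"time_weeks", "event", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"IPD file missing columns: {sorted(missing)}")
    return [
        IPDRecord(time=float(t), event=bool(int(e)), arm=str(a))
        for t, e, a in zip(df["time_weeks"], df["event"], df["arm"])
    ]
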