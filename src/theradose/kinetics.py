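"""Time-activity curve fitting and time-integrated activity.

Organ kinetics are fitted on decay-corrected %ID/g means, i.e. on the
biological retention curve.  Physical decay is re-applied analytically
inside the dosimetry integral.  Three model forms are supported:

* ``mono``            A(t) = a1 * exp(-lambda1 * t)
* ``bi``              A(t) = a1 * exp(-lambda1 * t) + a2 * exp(-lambda2 * t)
* ``plateau_uptake``  A(t) = a1 * (1 - exp(-lambda1 * t))

The plateau model is the rising-organ (tumour) reparameterization of a
bi-exponential with one negative amplitude.  The time-integrated activity
coefficient (cumulated activity per injected MBq) is the closed-form
integral of A(t) * exp(-lambda_phys * t) over [0, inf).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .biodistribution import OrganTimeSeries
from .nuclide import RadionuclideData

__all__ = [
    "TimeActivityCurve",
    "CumulatedActivity",
    "fit_tac",
    "select_model",
    "aicc",
    "cumulated_activity",
]

_MODELS = ("mono", "bi", "plateau_uptake")


@dataclass
class TimeActivityCurve:
    """Fitted kinetic model for one organ, in decay-corrected %ID/g."""

    organ: str
    model: str
    a1: float
    lambda1: float
    a2: float = 0.0
    lambda2: float = 0.0
    rss: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        # lambda = 0 encodes permanent biological retention; the dosimetry
        # integral stays finite because physical decay always applies
        if self.a1 != 0 and self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative when a1 != 0")
        if self.a2 != 0 and self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative when a2 != 0")

    @property
    def n_parameters(self) -> int:
        return 4 if self.model == "bi" else 2

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.model == "mono":
            out = self.a1 * np.exp(-self.lambda1 * t)
        elif self.model == "bi":
            out = self.a1 * np.exp(-self.lambda1 * t) + self.a2 * np.exp(-self.lambda2 * t)
        else:  # plateau_uptake
            out = self.a1 * (1.0 - np.exp(-self.lambda1 * t))
        return out if out.ndim else float(out)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class CumulatedActivity:
    """Time-integrated activity coefficient for one organ.

    ``a_tilde_mbq_s_per_g`` is per gram of tissue and per injected MBq
    (concentration form); multiply by the organ mass for the whole-organ
    value, see ``per_organ``.
    """

    organ: str
    a_tilde_mbq_s_per_g: float
    includes_physical_decay: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.a_tilde_mbq_s_per_g) or self.a_tilde_mbq_s_per_g < 0:
            raise ValueError("cumulated activity must be finite and nonnegative")

    def per_organ(self, mass_g: float) -> float:
        """Whole-organ cumulated activity, MBq*s per injected MBq."""
        if mass_g <= 0:
            raise ValueError("mass must be positive")
        return self.a_tilde_mbq_s_per_g * mass_g


def _coerce_series(series: OrganTimeSeries | tuple[Sequence[float], Sequence[float]]
                   ) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(series, OrganTimeSeries):
        return (np.asarray(series.timepoints_h, float),
                np.asarray(series.mean_pid_g, float), series.organ)
    t, y = series
    return np.asarray(t, float), np.asarray(y, float), ""


def fit_tac(series: OrganTimeSeries | tuple[Sequence[float], Sequence[float]],
            model: str, seed: int = 0) -> TimeActivityCurve:
    """Least-squares fit of one model form to decay-corrected %ID/g means.

    Multi-start optimisation: rate constants start on a log-spaced grid
    {0.01, 0.1, 1} h^-1 with small seeded jitter; the best converged
    candidate by residual sum of squares wins.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    t, y, organ = _coerce_series(series)
    if t.size != y.size or t.size == 0:
        raise ValueError("times and values must be equal-length and nonempty")
    n_par = 4 if model == "bi" else 2
    if t.size < n_par:
        raise ValueError(f"{model} needs at least {n_par} points, got {t.size}")

    ymax = max(float(np.max(np.abs(y))), 1e-12)
    rng = np.random.default_rng(seed)

    def residual(p: np.ndarray) -> np.ndarray:
        if model == "mono":
            pred = p[0] * np.exp(-p[1] * t)
        elif model == "bi":
            pred = p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t)
        else:
            pred = p[0] * (1.0 - np.exp(-p[1] * t))
        return pred - y

    starts = []
    for lam in (0.01, 0.1, 1.0):
        jitter = float(np.exp(rng.normal(0.0, 0.05)))
        if model == "bi":
            starts.append([0.7 * ymax, lam * jitter, 0.3 * ymax, 10 * lam * jitter])
        else:
            starts.append([ymax, lam * jitter])

    lo = [0.0, 1e-9] * (2 if model == "bi" else 1)
    hi = [np.inf, 1e3] * (2 if model == "bi" else 1)

    best = None
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(f"TAC fit did not converge for model {model!r}")

    p = best.x
    rss = float(2.0 * best.cost)
    if model == "bi":
        # order components by rate so lambda1 is the slow one
        (a1, l1), (a2, l2) = sorted([(p[0], p[1]), (p[2], p[3])], key=lambda c: c[1])
        return TimeActivityCurve(organ, "bi", a1, l1, a2, l2, rss, int(t.size))
    return TimeActivityCurve(organ, model, p[0], p[1], 0.0, 0.0, rss, int(t.size))


def aicc(tac: TimeActivityCurve) -> float:
    """Small-sample-corrected Akaike criterion from the Gaussian RSS form.

    Returns +inf when n <= k + 1 (correction undefined); such candidates
    lose model selection unless every candidate is in that regime.
    """
    n, k = tac.n_points, tac.n_parameters
    if n <= k + 1:
        return float("inf")
    rss = max(tac.rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def select_model(candidates: Sequence[TimeActivityCurve]) -> TimeActivityCurve:
    """Pick the candidate with minimum AICc; ties go to fewer parameters."""
    if not candidates:
        raise ValueError("no candidate fits supplied")
    return min(candidates, key=lambda c: (aicc(c), c.n_parameters, c.rss))


def _term_integral(amplitude: float, rate: float, lambda_phys: float,
                   t_last: float | None) -> float:
    """Integral of amplitude*exp(-rate*t)*exp(-lambda_phys*t) dt in hours."""
    k = rate + lambda_phys
    if amplitude != 0 and k <= 0:
        raise ValueError("divergent integral: biological + physical rate <= 0")
    if amplitude == 0:
        return 0.0
    if t_last is None:
        return amplitude / k
    return amplitude * (1.0 - math.exp(-k * t_last)) / k


def cumulated_activity(tac: TimeActivityCurve, nuclide: RadionuclideData,
                       extrapolation: str = "model",
                       t_last_h: float | None = None) -> CumulatedActivity:
    """Closed-form integral of the fitted curve times physical decay, 0 to inf.

    The fitted curve is in decay-corrected %ID/g, so the physical decay
    factor exp(-lambda_phys * t) is re-applied here.  Units: %ID/g -> /100
    gives MBq/g per injected MBq; hours -> seconds gives MBq*s/g per MBq.

    extrapolation="model" integrates the fitted biological model as-is to
    infinity; "physical_after_t_last" freezes biology at ``t_last_h`` (the
    last measured timepoint) and lets only physical decay act beyond it,
    a conservative choice for rising organs.
    """
    lam_p = nuclide.lambda_phys_per_h
    if extrapolation not in ("model", "physical_after_t_last"):
        raise ValueError(f"unknown extrapolation mode {extrapolation!r}")
    t_last = None
    if extrapolation == "physical_after_t_last":
        if t_last_h is None or t_last_h <= 0:
            raise ValueError("physical_after_t_last requires a positive t_last_h")
        t_last = t_last_h

    if tac.model == "mono":
        integral_h = _term_integral(tac.a1, tac.lambda1, lam_p, t_last)
        tail_level = tac.a1 * math.exp(-tac.lambda1 * t_last) if t_last else 0.0
    elif tac.model == "bi":
        integral_h = (_term_integral(tac.a1, tac.lambda1, lam_p, t_last)
                      + _term_integral(tac.a2, tac.lambda2, lam_p, t_last))
        tail_level = float(tac.predict(t_last)) if t_last else 0.0
    else:  # plateau_uptake: P/ (lam_p) - P/(lam_p + lambda_u)
        integral_h = (_term_integral(tac.a1, 0.0, lam_p, t_last)
                      - _term_integral(tac.a1, tac.lambda1, lam_p, t_last))
        tail_level = float(tac.predict(t_last)) if t_last else 0.0

    if t_last is not None:
        # frozen biology: remaining decays = A(t_last)*exp(-lam_p*t_last)/lam_p
        integral_h += tail_level * math.exp(-lam_p * t_last) / lam_p

    a_tilde = integral_h / 100.0 * 3600.0
    return CumulatedActivity(tac.organ, a_tilde, includes_physical_decay=True)
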