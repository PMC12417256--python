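"""Optimal treatment thresholds under discrete clinical monitoring.

With appointments every ``tau`` days, a treatment holiday that starts with
the tumor at size ``N*`` cannot be interrupted before the next appointment.
The *optimal threshold* ``N*(tau)`` is the largest threshold such that the
worst-case drug-free regrowth from ``N*`` cannot reach the progression limit
``1.2 * N0`` within one appointment interval; equivalently, the *optimal
interval* ``tau*(N*)`` is the drug-free travel time from ``N*`` to the
limit,

    tau*(N*) = integral from N* to 1.2 N0 of dN / g(N),

where ``g`` is the model's worst-case drug-free growth law
(:func:`atopt.models.drug_free_total_growth`).  For the Lotka-Volterra and
waning-competition models the integral has a closed form and an explicit
inverse; for the stem-cell model the threshold satisfies an implicit
equation in ``N*`` that depends on the current stem population, so the
optimal threshold is time-varying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .models import SCParams, drug_free_total_growth

__all__ = [
    "ThresholdCurve",
    "lv_tau_star",
    "lv_optimal_threshold",
    "wc_optimal_threshold",
    "sc_optimal_threshold",
    "numeric_tau_star",
    "threshold_curve",
]

#: relative tolerance of the implicit stem-cell root solve
_SC_ROOT_RTOL = 1e-12


def _lv_check(N_star, r_S, d_S, K, N0, limit):
    if r_S <= d_S:
        raise ValueError("require r_S > d_S (positive net growth)")
    if limit >= K * (r_S - d_S) / r_S:
        raise ValueError(
            "require 1.2*N0 < K*(r_S - d_S)/r_S (growth positive below the limit)"
        )
    if N_star is not None and not 0.0 < N_star <= limit:
        raise ValueError("require 0 < N_star <= 1.2*N0")


def lv_tau_star(N_star: float, r_S: float, d_S: float, K: float, N0: float) -> float:
    """Maximal safe appointment interval (days) for the Lotka-Volterra model.

    Closed form of the drug-free travel time from ``N_star`` to ``1.2*N0``
    under ``dN/dt = r_S N (1 - N/K) - d_S N``:

        tau* = ln[ (1.2 N0 / N*) (K(r_S-d_S) - r_S N*)
                   / (K(r_S-d_S) - 1.2 r_S N0) ] / (r_S - d_S)
    """
    limit = 1.2 * N0
    _lv_check(N_star, r_S, d_S, K, N0, limit)
    a = K * (r_S - d_S)
    return math.log((limit / N_star) * (a - r_S * N_star) / (a - r_S * limit)) / (r_S - d_S)


def lv_optimal_threshold(tau: float, r_S: float, d_S: float, K: float, N0: float) -> float:
    """Optimal threshold N*(tau) for the Lotka-Volterra model (exact inverse
    of :func:`lv_tau_star`):

        N* = K(r_S - d_S) / [ (K(r_S - d_S)/(1.2 N0) - r_S) e^{(r_S-d_S) tau}
                              + r_S ]

    At ``tau = 0`` (continuous monitoring) this returns exactly ``1.2 * N0``,
    the clinical progression limit.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    limit = 1.2 * N0
    _lv_check(None, r_S, d_S, K, N0, limit)
    if tau == 0.0:
        return limit
    a = K * (r_S - d_S)
    # clamp one-ulp roundoff so N* never exceeds the progression limit
    return min(a / ((a / limit - r_S) * math.exp((r_S - d_S) * tau) + r_S), limit)


def wc_optimal_threshold(tau: float, r_S: float, K_S: float, alpha: float, N0: float) -> float:
    """Optimal threshold N*(tau) for the waning-competition model.

    Uses the deliberately conservative worst case of a wholly sensitive
    tumor with no inter-species competition (gamma = 0), whose regrowth is
    generalized-logistic:

        N* = K_S [ ((K_S / 1.2 N0)^alpha - 1) e^{alpha r_S tau} + 1 ]^{-1/alpha}

    ``alpha = 1`` recovers the Lotka-Volterra expression with ``d_S = 0``
    and ``K = K_S``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    limit = 1.2 * N0
    if limit >= K_S:
        raise ValueError("require 1.2*N0 < K_S")
    if tau == 0.0:
        return limit
    bracket = ((K_S / limit) ** alpha - 1.0) * math.exp(alpha * r_S * tau) + 1.0
    return min(K_S * bracket ** (-1.0 / alpha), limit)


def sc_optimal_threshold(
    tau: float, S_now: float, N_init: float, params: SCParams
) -> Optional[float]:
    """Time-varying optimal threshold N*(t) for the stem-cell model.

    Given the current stem population ``S_now = S(t)``, the threshold is the
    (larger) root in ``(0, 1.2*N_init]`` of

        g(x) = x^{1-p_S} + lambda (1-p_S) S_now tau x^{-p_S}
               - (1.2 N_init)^{1-p_S},

    obtained by integrating the exact drug-free growth law from ``N*`` to
    the progression limit over one interval ``tau``.  ``g`` has at most two
    roots (the holiday travel time tau(N*) vanishes at both ends of the
    bracket); the larger root is the meaningful threshold — above it a
    holiday of length ``tau`` overshoots the limit.  Returns ``None`` when
    no root exists, i.e. the stem population has grown so large that *any*
    holiday of length ``tau`` overshoots.

    Degenerate cases: ``tau = 0`` or ``S_now = 0`` return ``1.2 * N_init``
    exactly (no drug-free growth is possible).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if S_now < 0:
        raise ValueError("S_now must be >= 0")
    p = params.p_S  # validated in (0,1) by SCParams
    limit = 1.2 * N_init
    if tau == 0.0 or S_now == 0.0:
        return limit
    c = params.lambda_ * (1.0 - p) * S_now * tau

    def g(x):
        return x ** (1.0 - p) + c * x ** (-p) - limit ** (1.0 - p)

    # g -> +inf as x -> 0+, g(limit) > 0; unique interior minimum at
    # x_min = p * lambda * S_now * tau.
    x_min = p * params.lambda_ * S_now * tau
    if x_min >= limit or g(x_min) > 0.0:
        return None
    if g(x_min) == 0.0:
        return x_min
    return brentq(g, x_min, limit, rtol=_SC_ROOT_RTOL)


def numeric_tau_star(model_id: str, params, N_star: float, N0: float, aux=None) -> float:
    """Model-agnostic optimal interval by quadrature of the regrowth law.

    Integrates ``1 / g(N)`` from ``N_star`` to ``1.2 * N0`` where ``g`` is
    :func:`atopt.models.drug_free_total_growth`; serves as the numerical
    oracle against which the closed forms are checked.  Returns ``math.inf``
    when the growth rate is nonpositive anywhere on the interval (the tumor
    stalls before the limit, so no finite interval is unsafe).
    """
    limit = 1.2 * N0
    if N_star > limit:
        raise ValueError("require N_star <= 1.2*N0")
    if N_star == limit:
        return 0.0
    probe = np.linspace(N_star, limit, 101)
    if any(drug_free_total_growth(model_id, x, aux, params) <= 0 for x in probe):
        return math.inf
    val, _ = quad(
        lambda x: 1.0 / drug_free_total_growth(model_id, x, aux, params),
        N_star,
        limit,
        epsabs=1e-12,
        epsrel=1e-12,
        limit=200,
    )
    return val


@dataclass(frozen=True)
class ThresholdCurve:
    """Tabulated optimal threshold N*(tau) for one model/parameter set.

    ``n_star`` is strictly decreasing in ``tau`` and bounded by the
    progression limit ``1.2 * N0``.
    """

    tau_grid: np.ndarray
    n_star: np.ndarray
    model_id: str
    params: object

    def __post_init__(self):
        if self.tau_grid.shape != self.n_star.shape:
            raise ValueError("tau_grid and n_star must have equal shapes")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"tau": self.tau_grid, "n_star": self.n_star})


def threshold_curve(
    model_id: str,
    params,
    tau_grid: Sequence[float],
    N0: float,
    sc_S: Optional[float] = None,
) -> ThresholdCurve:
    """Tabulate N*(tau) over a sorted nonnegative ``tau_grid``.

    For the stem-cell model the curve is conditional on a stem population
    ``sc_S`` (the threshold is time-varying); entries where no threshold
    exists are NaN.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(tau_grid < 0) or np.any(np.diff(tau_grid) < 0):
        raise ValueError("tau_grid must be nonnegative and sorted")
    if model_id == "lv":
        vals = [lv_optimal_threshold(t, params.r_S, params.d, params.K, N0) for t in tau_grid]
    elif model_id == "wc":
        vals = [wc_optimal_threshold(t, params.r_S, params.K_S, params.alpha, N0) for t in tau_grid]
    elif model_id == "sc":
        if sc_S is None:
            raise ValueError("stem-cell curve needs sc_S (current stem population)")
        vals = [sc_optimal_threshold(t, sc_S, N0, params) for t in tau_grid]
        vals = [math.nan if v is None else v for v in vals]
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return ThresholdCurve(tau_grid, np.asarray(vals, dtype=float), model_id, params)
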