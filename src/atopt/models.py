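"""Tumor growth models for adaptive-therapy scheduling.

Three two-compartment ODE models of a heterogeneous tumor under a binary
(on/off) drug schedule, each previously proposed for intermittent hormone
therapy of metastatic prostate cancer:

``lv``
    Lotka-Volterra competition between drug-sensitive cells ``S`` and fully
    resistant cells ``R`` sharing a single carrying capacity ``K``
    (Strobl et al., 2021).  Drug kill follows the Norton-Simon hypothesis:
    death proportional to the sensitive population's growth rate times dose.
``wc``
    "Waning competition": a generalized (exponent ``alpha``) logistic
    competition model in which the inter-species resource overlap decays
    exponentially in time at rate ``gamma`` (Lu et al.).  With ``gamma = 0``
    and no drug it reduces to the generalized logistic model.
``sc``
    Stem-cell driven growth (Brady-Nicholls & Enderling): drug-immune
    stem-like cells ``S`` divide at rate ``lambda_`` and either self-renew
    (probability ``p_S``, under negative feedback ``S/(S+D)``) or produce
    drug-sensitive differentiated cells ``D``, which die under treatment at
    rate ``d_D``.

Throughout, ``N`` denotes total tumor burden: ``N = S + R`` (lv, wc) or
``N = S + D`` (sc).  Populations are dimensionless fractions of a reference
carrying capacity; rates are per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "LVParams",
    "WCParams",
    "SCParams",
    "TumorState",
    "MODEL_IDS",
    "lv_derivatives",
    "wc_derivatives",
    "sc_derivatives",
    "drug_free_total_growth",
    "sc_trajectory_constant",
]

MODEL_IDS = ("lv", "wc", "sc")


def _check_positive(obj, allow_zero=()):
    for f in fields(obj):
        v = getattr(obj, f.name)
        if f.name in allow_zero:
            if v < 0:
                raise ValueError(f"{type(obj).__name__}.{f.name} must be >= 0, got {v}")
        elif v <= 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class LVParams:
    """Lotka-Volterra model parameters.

    Attributes
    ----------
    r_S, r_R : float
        Sensitive / resistant growth rates (1/day).  ``r_S >= r_R`` in the
        default parameterization (cost of resistance).
    K : float
        Shared carrying capacity (population units).
    d : float
        Natural death (turnover) rate of both species (1/day).  May be zero;
        the drug-free regrowth law uses it as the sensitive death rate
        ``d_S``, so ``r_S > d`` is required for the thresholds to exist.
    d_D : float
        Norton-Simon drug-kill proportionality factor (dimensionless,
        multiplies the dose).
    """

    r_S: float
    r_R: float
    K: float
    d: float
    d_D: float

    def __post_init__(self):
        _check_positive(self, allow_zero=("d",))
        if self.r_S <= self.d:
            raise ValueError("require r_S > d (net drug-free growth)")


@dataclass(frozen=True)
class WCParams:
    """Waning-competition model parameters.

    ``alpha`` is the generalized-logistic growth exponent (> 0); ``gamma``
    (1/day, >= 0) sets how fast the inter-species competition weight
    ``1/(1 + exp(gamma * t))`` decays.  ``d_S``/``d_R`` are dimensionless
    drug-induced death coefficients entering the bracket of each growth term.
    """

    r_S: float
    r_R: float
    K_S: float
    K_R: float
    d_S: float
    d_R: float
    alpha: float
    gamma: float

    def __post_init__(self):
        _check_positive(self, allow_zero=("gamma",))


@dataclass(frozen=True)
class SCParams:
    """Stem-cell model parameters: division rate ``lambda_`` (1/day),
    symmetric self-renewal probability ``p_S`` in (0, 1), and drug-induced
    death rate ``d_D`` (1/day) of differentiated cells."""

    lambda_: float
    p_S: float
    d_D: float

    def __post_init__(self):
        if not 0.0 < self.p_S < 1.0:
            raise ValueError(f"p_S must lie in (0, 1), got {self.p_S}")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if self.d_D <= 0:
            raise ValueError("d_D must be > 0")


@dataclass
class TumorState:
    """Two-compartment population state at time ``t`` (days).

    ``pop1`` is the sensitive population ``S`` in every model; ``pop2`` is
    the resistant population ``R`` (lv, wc) or the differentiated
    population ``D`` (sc).
    """

    pop1: float
    pop2: float
    t: float = 0.0

    def __post_init__(self):
        if self.pop1 < 0 or self.pop2 < 0:
            raise ValueError("populations must be nonnegative")

    @property
    def total(self) -> float:
        """Total tumor burden N."""
        return self.pop1 + self.pop2


# ---------------------------------------------------------------------------
# Right-hand sides.  The *_rates functions operate on raw floats (hot path
# for the integrator); the *_derivatives wrappers add domain validation and
# take a TumorState.
# ---------------------------------------------------------------------------


def _lv_rates(S, R, p: LVParams, dose):
    crowd = 1.0 - (S + R) / p.K
    dS = p.r_S * S * crowd * (1.0 - p.d_D * dose) - p.d * S
    dR = p.r_R * R * crowd - p.d * R
    return dS, dR


def _wc_rates(S, R, t, p: WCParams, dose):
    # competition weight 1/(1 + e^{gamma t}); equals 1/2 at t = 0
    gt = p.gamma * t
    w = 0.5 if gt == 0.0 else 1.0 / (1.0 + math.exp(min(gt, 700.0)))
    dS = p.r_S * S * (1.0 - ((S + w * R) / p.K_S) ** p.alpha - p.d_S * dose)
    dR = p.r_R * R * (1.0 - ((R + w * S) / p.K_R) ** p.alpha - p.d_R * dose)
    return dS, dR


def _sc_rates(S, D, p: SCParams, dose):
    frac = 0.0 if S + D == 0.0 else S / (S + D)
    dS = frac * p.p_S * p.lambda_ * S
    dD = (1.0 - frac * p.p_S) * p.lambda_ * S - p.d_D * dose * D
    return dS, dD


def _validate(state: TumorState, dose):
    if state.pop1 < 0 or state.pop2 < 0:
        raise ValueError("populations must be nonnegative")
    if dose not in (0, 1, 0.0, 1.0):
        raise ValueError(f"dose must be binary, got {dose}")


def lv_derivatives(state: TumorState, params: LVParams, dose: float) -> tuple[float, float]:
    """(dS/dt, dR/dt) for the Lotka-Volterra model under binary ``dose``.

    dS/dt = r_S S (1 - (S+R)/K)(1 - d_D * dose) - d S
    dR/dt = r_R R (1 - (S+R)/K) - d R
    """
    _validate(state, dose)
    return _lv_rates(state.pop1, state.pop2, params, dose)


def wc_derivatives(state: TumorState, t: float, params: WCParams, dose: float) -> tuple[float, float]:
    """(dS/dt, dR/dt) for the waning-competition model at time ``t`` (days).

    The model is explicitly time-dependent: the competing species enters
    each logistic bracket with weight ``1/(1 + exp(gamma t))``.
    """
    _validate(state, dose)
    if t < 0:
        raise ValueError("t must be >= 0")
    return _wc_rates(state.pop1, state.pop2, t, params, dose)


def sc_derivatives(state: TumorState, params: SCParams, dose_flag: float) -> tuple[float, float]:
    """(dS/dt, dD/dt) for the stem-cell model; ``dose_flag`` is T_x in {0, 1}.

    The stem fraction ``S/(S+D)`` is defined as 0 at the null state so that
    the all-zero equilibrium is preserved.  The identity
    ``dS/dt + dD/dt = lambda_ * S - d_D * T_x * D`` holds exactly.
    """
    _validate(state, dose_flag)
    return _sc_rates(state.pop1, state.pop2, params, dose_flag)


def sc_trajectory_constant(S: float, N: float, p_S: float) -> float:
    """Drug-free invariant C = N * S**(-1/p_S) of the stem-cell model.

    Along any treatment-free trajectory N and S satisfy dN/dS = N/(p_S S),
    whose exact solution keeps C constant.  Can be large for small p_S; the
    growth law below also accepts the (S, N) pair directly to avoid it.
    """
    if S <= 0:
        raise ValueError("S must be > 0")
    return N * S ** (-1.0 / p_S)


def drug_free_total_growth(model_id: str, N: float, aux, params) -> float:
    """Worst-case drug-free growth rate dN/dt of the total burden (pop/day).

    This is the one-dimensional regrowth law each threshold derivation is
    built on:

    - ``lv``: wholly sensitive tumor, ``dN/dt = r_S N (1 - N/K) - d N``
      (``aux`` unused);
    - ``wc``: wholly sensitive, minimal competition (gamma = 0),
      ``dN/dt = r_S N (1 - (N/K_S)**alpha)`` (``aux`` unused);
    - ``sc``: exact holiday growth ``dN/dt = lambda_ * (N/C)**p_S`` where
      ``aux`` is either the trajectory constant ``C`` or an ``(S_ref,
      N_ref)`` pair fixing it.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    if model_id == "lv":
        return params.r_S * N * (1.0 - N / params.K) - params.d * N
    if model_id == "wc":
        return params.r_S * N * (1.0 - (N / params.K_S) ** params.alpha)
    if model_id == "sc":
        if aux is None:
            raise ValueError("sc growth law needs aux = C or (S_ref, N_ref)")
        p = params.p_S
        if isinstance(aux, tuple):
            S_ref, N_ref = aux
            return params.lambda_ * S_ref * (N / N_ref) ** p
        # scalar trajectory constant C: lambda * (N/C)**p_S, kept in logs
        return params.lambda_ * math.exp(p * (math.log(N) - math.log(aux)))
    raise ValueError(f"unknown model_id {model_id!r}")
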