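"""Dosing protocols evaluated at discrete clinical appointments.

All protocols are binary: at each appointment the measured tumor burden is
mapped to a dose in {0, 1} (maximum tolerated dose or holiday) that is then
held fixed until the next appointment.

- ``CT``: continuous therapy, dose 1 always.
- ``AT50``: window-based adaptive therapy with hysteresis — treat until the
  burden falls below ``window_lower_frac * N0`` (default 0.5), then hold
  until it regains ``window_upper_frac * N0`` (default 1.0).  Raising the
  upper fraction above 1 gives range-bounded variants.
- ``ATN_fixed``: threshold-based adaptive therapy — treat iff the measured
  burden is at or above a fixed threshold ``N_star``.  No phase memory.
- ``ATN_timevarying``: same threshold rule, but the threshold is recomputed
  at each appointment from the measured stem population via
  :func:`atopt.thresholds.sc_optimal_threshold` (stem-cell model only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .models import SCParams
from .thresholds import sc_optimal_threshold

__all__ = [
    "PROTOCOL_KINDS",
    "ProtocolSpec",
    "ProtocolState",
    "appointment_times",
    "decide_dose",
]

PROTOCOL_KINDS = ("CT", "AT50", "ATN_fixed", "ATN_timevarying")


@dataclass(frozen=True)
class ProtocolSpec:
    """Dosing rule plus its monitoring schedule.

    ``tau`` is the appointment interval (days); ``offset`` the duration of
    an initial treatment period before the first decision (0 <= offset <
    tau), used by the worst-case variable-offset evaluation.  ``N_star`` is
    required for ``ATN_fixed`` and ignored otherwise.
    """

    kind: str
    tau: float
    N_star: Optional[float] = None
    offset: float = 0.0
    window_lower_frac: float = 0.5
    window_upper_frac: float = 1.0

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.offset < self.tau:
            raise ValueError("offset must satisfy 0 <= offset < tau")
        if self.kind == "ATN_fixed":
            if self.N_star is None or self.N_star <= 0:
                raise ValueError("ATN_fixed requires N_star > 0")
        if self.kind == "AT50" and not 0 < self.window_lower_frac < self.window_upper_frac:
            raise ValueError("require 0 < window_lower_frac < window_upper_frac")


@dataclass(frozen=True)
class ProtocolState:
    """Decision memory carried between appointments.

    ``at50_phase`` ('on_until_lower' / 'off_until_upper') exists only for
    AT50; ``last_threshold`` records the most recent threshold used by the
    time-varying protocol (NaN if none could be found).
    """

    current_dose: int = 1
    at50_phase: Optional[str] = None
    last_threshold: Optional[float] = None

    @classmethod
    def initial(cls, spec: ProtocolSpec) -> "ProtocolState":
        # AT50 starts treating (phase on_until_lower); threshold rules carry
        # no memory and decide the first dose like any other.
        return cls(current_dose=1, at50_phase="on_until_lower" if spec.kind == "AT50" else None)


def appointment_times(tau: float, offset: float, horizon: float) -> np.ndarray:
    """Decision times ``offset, offset + tau, ...`` within ``[0, horizon]``.

    With ``offset = 0`` the first decision is at t = 0; otherwise the period
    ``[0, offset)`` is an initial treatment segment with no decision.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if not 0.0 <= offset < tau:
        raise ValueError("offset must satisfy 0 <= offset < tau")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if offset > horizon:
        return np.empty(0)
    n = int(math.floor((horizon - offset) / tau + 1e-9))
    return offset + tau * np.arange(n + 1, dtype=float)


def decide_dose(
    spec: ProtocolSpec,
    state: ProtocolState,
    measured_N: float,
    measured_S: Optional[float],
    t: float,
    N0: float,
    sc_params: Optional[SCParams] = None,
) -> tuple[int, ProtocolState]:
    """Evaluate the protocol at one appointment.

    Returns the binary dose to hold until the next appointment and the
    updated protocol state.  Ties at a threshold treat (the rule is
    ``N >= N_star``), and the AT50 upper bound is likewise inclusive.
    ``measured_S`` and ``sc_params`` are required for ``ATN_timevarying``.
    """
    if spec.kind == "CT":
        return 1, replace(state, current_dose=1)

    if spec.kind == "AT50":
        lower = spec.window_lower_frac * N0
        upper = spec.window_upper_frac * N0
        phase = state.at50_phase
        if phase == "on_until_lower":
            if measured_N < lower:
                phase, dose = "off_until_upper", 0
            else:
                dose = 1
        elif phase == "off_until_upper":
            if measured_N >= upper:
                phase, dose = "on_until_lower", 1
            else:
                dose = 0
        else:
            raise ValueError("AT50 state missing phase")
        return dose, replace(state, current_dose=dose, at50_phase=phase)

    if spec.kind == "ATN_fixed":
        dose = 1 if measured_N >= spec.N_star else 0
        return dose, replace(state, current_dose=dose)

    if spec.kind == "ATN_timevarying":
        if measured_S is None or sc_params is None:
            raise ValueError("ATN_timevarying requires measured_S and sc_params")
        nstar = sc_optimal_threshold(spec.tau, measured_S, N0, sc_params)
        if nstar is None:
            # no safe holiday of length tau exists any more: always treat
            dose = 1
            nstar = math.nan
        else:
            dose = 1 if measured_N >= nstar else 0
        return dose, replace(state, current_dose=dose, last_threshold=nstar)

    raise ValueError(f"unknown protocol kind {spec.kind!r}")
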