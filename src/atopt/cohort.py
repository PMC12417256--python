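"""Virtual-patient cohorts.

Optimal thresholds are patient-specific: they depend on the tumor's growth
parameters.  To exercise that personalization without clinical records, a
:class:`PatientSampler` draws parameter sets uniformly and independently
within per-field ranges around a base parameterization.  Uniform sampling is
a deliberate stand-in for an unknown population distribution — it probes the
parameter box, it does not emulate any fitted cohort.

All randomness in the package flows through the sampler's seed; the
simulation and threshold code is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, Sequence, Tuple

import numpy as np

from .models import LVParams, SCParams, WCParams

__all__ = ["PatientSampler", "sample_virtual_patients"]

_PARAM_TYPES = {"lv": LVParams, "wc": WCParams, "sc": SCParams}
_MAX_TRIES = 1000


@dataclass(frozen=True)
class PatientSampler:
    """Uniform per-field sampler around a base parameter set.

    ``ranges`` maps field names of the model's parameter type to (low, high)
    bounds; unlisted fields keep the base value.  Draws violating the
    parameter type's invariants (e.g. r_S <= d) are rejected and resampled.
    """

    model_id: str
    base: object
    ranges: Mapping[str, Tuple[float, float]]
    seed: int = 0

    def __post_init__(self):
        ptype = _PARAM_TYPES.get(self.model_id)
        if ptype is None:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not isinstance(self.base, ptype):
            raise TypeError(f"base must be {ptype.__name__}")
        valid = {f.name for f in fields(ptype)}
        for name, (low, high) in self.ranges.items():
            if name not in valid:
                raise ValueError(f"unknown parameter field {name!r} for model {self.model_id!r}")
            if low > high:
                raise ValueError(f"range for {name!r} has low > high")


def sample_virtual_patients(sampler: PatientSampler, n: int) -> list:
    """Draw ``n`` parameter sets, reproducibly under the sampler's seed.

    Raises if the ranges are infeasible (no valid draw found within the
    rejection budget — e.g. bounds that force r_S <= d).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(sampler.seed)
    patients = []
    for _ in range(n):
        for _try in range(_MAX_TRIES):
            draw = {
                name: float(rng.uniform(low, high))
                for name, (low, high) in sampler.ranges.items()
            }
            try:
                patients.append(replace(sampler.base, **draw))
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                f"infeasible parameter ranges for model {sampler.model_id!r}: "
                f"no valid draw in {_MAX_TRIES} attempts"
            )
    return patients
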