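"""Synthetic stand-ins for the external life table and utility norms.

The cost-utility model needs a period life table (all-cause annual death
probabilities by age) and age-specific population utility norms.  The
generators here produce deterministic, demographically plausible versions
of both: a Gompertz-Makeham mortality law with an infant-mortality bump
calibrated to a life expectancy near 81 years, and a smoothly declining
utility-norm curve from ~0.93 in childhood to ~0.70 at the terminal age.
Real tables in the same two-column format can be dropped in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifecourse import LifeTable, UtilityNorms


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Gompertz-Makeham parameters: q(age) = makeham + b * exp(g * age)."""

    makeham: float = 2e-4          # age-independent background hazard
    gompertz_b: float = 1.5e-5     # senescent baseline
    gompertz_g: float = 0.10       # senescent log-slope per year
    infant_q: float = 0.005        # q(0) bump
    max_age: int = 110

    def validate(self) -> None:
        if min(self.makeham, self.gompertz_b, self.infant_q) < 0 or self.gompertz_g < 0:
            raise ValueError("all mortality parameters must be >= 0")
        if not 0 <= self.infant_q <= 1:
            raise ValueError("infant_q must lie in [0, 1]")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")


def synth_life_table(spec: SyntheticLifeTableSpec | None = None) -> LifeTable:
    """Deterministic synthetic period life table.

    q rises exponentially beyond young adulthood and is forced to 1 at the
    terminal age (closed table).  Parameters that push q above 1 before
    the terminal age are rejected rather than silently clipped.
    """
    spec = spec or SyntheticLifeTableSpec()
    spec.validate()
    ages = np.arange(spec.max_age + 1)
    q = spec.makeham + spec.gompertz_b * np.exp(spec.gompertz_g * ages)
    q[0] = max(q[0], spec.infant_q)
    if np.any(q[:-1] > 1.0):
        first = int(np.argmax(q > 1.0))
        raise ValueError(
            f"mortality exceeds 1 at age {first}, before max_age {spec.max_age}"
        )
    q[-1] = 1.0
    return LifeTable(q)


def synth_utility_norms(max_age: int = 110) -> UtilityNorms:
    """Deterministic age-declining utility norms on (0.38, 1].

    u(age) = 0.93 - 0.23 * (age / max_age)^1.5: about 0.93 through
    childhood, ~0.80 in the mid-70s, 0.70 at the terminal age.  The floor
    of 0.70 keeps every value above the MMR disutility of 0.38, so the
    MMR utility u - 0.38 never truncates at zero.
    """
    if max_age <= 0:
        raise ValueError("max_age must be > 0")
    ages = np.arange(max_age + 1)
    u = 0.93 - 0.23 * (ages / max_age) ** 1.5
    return UtilityNorms(u)
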