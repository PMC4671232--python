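"""Alive/dead Markov accounting: survival, discounting, QALYs and costs.

The cohort enters at birth (age 0) and transitions alive -> dead with the
annual death probabilities of a period life table.  Rewards accrue at the
start of each annual cycle and are discounted to age 0; no half-cycle
correction is applied.  Remedial-education costs follow the Ontario SEPPA
tiers over the school ages (junior kindergarten at age 4 through grade 12
at age 17).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet, Strategy


class TableError(ValueError):
    """A life table or utility-norm table violates its invariants."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) for ages 0..max_age."""

    qx: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", q)
        if q.ndim != 1 or q.size < 2:
            raise TableError("life table needs q(age) for at least two ages")
        if np.any((q < 0) | (q > 1)) or not np.all(np.isfinite(q)):
            raise TableError("death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise TableError("q(max_age) must equal 1 (closed table)")

    @property
    def max_age(self) -> int:
        return self.qx.size - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.qx.size)

    def to_file(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    @classmethod
    def from_file(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise TableError(f"{path}: expected columns 'age' and 'qx'")
        df = df.sort_values("age")
        if not np.array_equal(df["age"].to_numpy(), np.arange(len(df))):
            raise TableError(f"{path}: ages must run 0..max_age without gaps")
        return cls(df["qx"].to_numpy(dtype=float))


@dataclass(frozen=True)
class UtilityNorms:
    """Baseline (population-norm) utility u(age) in [0, 1] per year of age."""

    utility: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.utility, dtype=float)
        object.__setattr__(self, "utility", u)
        if np.any((u < 0) | (u > 1)) or not np.all(np.isfinite(u)):
            raise TableError("utilities must lie in [0, 1]")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.utility.size)

    def to_file(self, path) -> None:
        pd.DataFrame({"age": self.ages, "utility": self.utility}).to_csv(path, index=False)

    @classmethod
    def from_file(cls, path) -> "UtilityNorms":
        df = pd.read_csv(path)
        if not {"age", "utility"} <= set(df.columns):
            raise TableError(f"{path}: expected columns 'age' and 'utility'")
        df = df.sort_values("age")
        return cls(df["utility"].to_numpy(dtype=float))


@dataclass(frozen=True)
class DiscountSchedule:
    """Constant or piecewise-constant annual discount rates.

    ``segments`` is a sequence of (n_years, rate) pairs; the final segment
    extends indefinitely.  The base analysis uses a constant 5%; the
    variable scenario is 5% for 10 years, then 3% for 5, then 1%.
    """

    segments: tuple[tuple[float, float], ...]

    @staticmethod
    def constant(rate: float) -> "DiscountSchedule":
        return DiscountSchedule(((np.inf, float(rate)),))

    @staticmethod
    def variable() -> "DiscountSchedule":
        return DiscountSchedule(((10, 0.05), (5, 0.03), (np.inf, 0.01)))

    def validate(self) -> None:
        if not self.segments:
            raise TableError("discount schedule needs at least one segment")
        for n, r in self.segments:
            if n <= 0 or r < 0:
                raise TableError(f"invalid discount segment ({n}, {r})")

    @property
    def is_constant(self) -> bool:
        return len(self.segments) == 1

    @property
    def rate(self) -> float:
        if not self.is_constant:
            raise ValueError("schedule is not constant")
        return self.segments[0][1]

    def annual_rates(self, n_years: int) -> np.ndarray:
        """Rate applying in years 1..n_years."""
        rates = np.empty(n_years)
        pos = 0
        for n, r in self.segments:
            take = n_years - pos if not np.isfinite(n) else min(int(n), n_years - pos)
            rates[pos:pos + take] = r
            pos += take
            if pos >= n_years:
                break
        rates[pos:] = self.segments[-1][1]
        return rates

    def factors(self, n_years: int) -> np.ndarray:
        """Discount factors for years 0..n_years-1; factor(0) = 1."""
        if n_years < 1:
            return np.empty(0)
        rates = self.annual_rates(n_years - 1)
        return np.concatenate(([1.0], np.cumprod(1.0 / (1.0 + rates))))

    def to_dict(self) -> dict:
        if self.is_constant:
            return {"rate": self.rate, "segments": None}
        return {
            "rate": None,
            "segments": [[None if not np.isfinite(n) else n, r]
                         for n, r in self.segments],
        }

    @classmethod
    def from_dict(cls, d) -> "DiscountSchedule":
        if d.get("segments"):
            return cls(tuple(
                (np.inf if n is None else float(n), float(r))
                for n, r in d["segments"]
            ))
        return cls.constant(float(d["rate"]))


def discount_factor(ds: DiscountSchedule, year: int) -> float:
    """Present-value factor for a reward accruing at the start of ``year``."""
    if year < 0:
        raise ValueError("year must be >= 0")
    return float(ds.factors(year + 1)[-1])


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs (CAD) and the SEPPA remedial-education tier structure."""

    lab_test: float = 23.27
    physician_visit: float = 33.70
    seppa_tiers: tuple[float, ...] = (931.29, 715.34, 472.92)
    # school ages covered by each tier: JK-grade 3, grades 4-8, grades 9-12
    tier_age_ranges: tuple[tuple[int, int], ...] = ((4, 8), (9, 13), (14, 17))

    def validate(self) -> None:
        if min(self.lab_test, self.physician_visit, *self.seppa_tiers) < 0:
            raise TableError("all costs must be >= 0")
        if len(self.seppa_tiers) != len(self.tier_age_ranges):
            raise TableError("one age range per SEPPA tier required")
        for lo, hi in self.tier_age_ranges:
            if hi < lo or lo < 0:
                raise TableError(f"invalid tier age range ({lo}, {hi})")

    def cost_by_age(self, max_age: int) -> np.ndarray:
        """Annual education cost at each age 0..max_age."""
        out = np.zeros(max_age + 1)
        for cost, (lo, hi) in zip(self.seppa_tiers, self.tier_age_ranges):
            out[lo:min(hi, max_age) + 1] = cost
        return out


# ---------------------------------------------------------------------------
# Markov accounting
# ---------------------------------------------------------------------------

def survival_curve(lt: LifeTable) -> np.ndarray:
    """S(t), probability of being alive at the start of age t, t = 0..max_age."""
    return np.concatenate(([1.0], np.cumprod(1.0 - lt.qx[:-1])))


def discounted_life_years(lt: LifeTable, ds: DiscountSchedule) -> float:
    """Sum over ages of S(t) x discount factor(t)."""
    S = survival_curve(lt)
    return float(S @ ds.factors(S.size))


def lifetime_qalys(
    lt: LifeTable,
    un: UtilityNorms,
    ds: DiscountSchedule,
    disutility: float = 0.0,
    has_mmr: bool = False,
) -> float:
    """Expected discounted lifetime QALYs for one person.

    With MMR the annual utility is reduced by the disutility, floored at 0
    (a health state cannot be valued below death here).
    """
    S = survival_curve(lt)
    u = un.utility
    if u.size < S.size:
        raise TableError("utility norms must cover every life-table age")
    u = u[:S.size]
    if has_mmr:
        u = np.maximum(u - disutility, 0.0)
    return float((S * u) @ ds.factors(S.size))


def education_cost_pv(cs: CostSchedule, lt: LifeTable, ds: DiscountSchedule) -> float:
    """Present value of SEPPA remedial-education costs for one MMR case.

    Costs at each school age are weighted by the probability of being alive
    at that age and discounted to birth.
    """
    S = survival_curve(lt)
    costs = cs.cost_by_age(lt.max_age)
    return float((costs * S) @ ds.factors(S.size))


def screening_cost_per_birth(
    ps: "ParameterSet",
    strategy: "Strategy",
    visit_per_screening: bool = False,
) -> float:
    """Screening + dietary-advice cost per planned live birth (CAD).

    The reference strategy incurs nothing.  Under screening every planned
    pregnancy pays the laboratory test; orphan patients (no family doctor)
    additionally pay an intermediate visit, as do women whose blood Hg
    exceeds the adverse-effect threshold (they receive the fish-consumption
    advice).  Dividing by the probability that a planned pregnancy yields a
    live birth converts cost per screened pregnancy into cost per planned
    live birth.  ``visit_per_screening`` switches to the scenario where
    every screening requires a family-doctor appointment.
    """
    if strategy.kind == "reference":
        return 0.0
    from .exposure import weighted_tail_probability

    p_advice = weighted_tail_probability(ps, ps.adverse_effect_threshold_maternal)
    cs, bm = ps.costs, ps.births
    per_screen = cs.lab_test + p_advice * cs.physician_visit
    if visit_per_screening:
        per_screen += cs.physician_visit
    else:
        per_screen += bm.orphan_patient_fraction * cs.physician_visit
    return per_screen / bm.live_birth_given_planned
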