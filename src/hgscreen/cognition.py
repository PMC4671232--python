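"""Dose-response: exposure category -> IQ loss -> probability of MMR shift.

A doubling of prenatal mercury exposure costs a fixed fraction of an IQ
standard deviation; the four above-threshold exposure categories scale
that unit effect by fixed multipliers.  Children shifted into mild mental
retardation (MMR) are those whose pre-exposure IQ lies between the MMR
cut-off and cut-off + loss under the population normal IQ distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .exposure import CategoryMass


@dataclass(frozen=True)
class DoseResponse:
    """Unit cognitive effect and category multipliers."""

    effect_per_doubling: float = 0.094        # fraction of an IQ SD
    iq_sd: float = 15.0
    category_multipliers: tuple[float, ...] = (0.125, 0.5, 1.0, 1.25)

    def __post_init__(self) -> None:
        if self.effect_per_doubling < 0:
            raise ValueError("effect_per_doubling must be >= 0")
        if np.any(np.diff(self.category_multipliers) <= 0):
            raise ValueError("category multipliers must be strictly increasing")


def iq_loss_by_category(dr: DoseResponse) -> np.ndarray:
    """IQ-point losses for the four above-threshold exposure categories.

    loss_k = multiplier_k x effect_per_doubling x iq_sd; the base case
    gives (0.176, 0.705, 1.41, 1.7625) IQ points.  The below-threshold
    category loses nothing.
    """
    mult = np.asarray(dr.category_multipliers, dtype=float)
    return mult * dr.effect_per_doubling * dr.iq_sd


def mmr_shift_probability(
    loss, iq_mean: float = 100.0, iq_sd: float = 15.0, mmr_upper: float = 70.0
):
    """Probability that an IQ loss shifts a child below the MMR cut-off.

    Under IQ ~ N(iq_mean, iq_sd), the shifted children are those with
    pre-exposure IQ in (mmr_upper, mmr_upper + loss]:

        Phi((mmr_upper + loss - iq_mean)/iq_sd) - Phi((mmr_upper - iq_mean)/iq_sd)

    Accepts scalar or array losses; a negative loss is a domain error.
    """
    loss = np.asarray(loss, dtype=float)
    if np.any(loss < 0):
        raise ValueError("IQ loss must be >= 0")
    z0 = (mmr_upper - iq_mean) / iq_sd
    out = ndtr(z0 + loss / iq_sd) - ndtr(z0)
    return float(out) if out.ndim == 0 else out


def expected_mmr_per_birth(
    cm: CategoryMass,
    losses: Sequence[float],
    iq_mean: float = 100.0,
    iq_sd: float = 15.0,
    mmr_upper: float = 70.0,
) -> float:
    """Expected probability a live birth is shifted into MMR.

    The mass of each exposure category is multiplied by the shift
    probability of its IQ loss and summed; the below-threshold category
    contributes zero.  ``losses`` holds the four above-threshold losses.
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size != cm.masses.size - 1:
        raise ValueError("need one IQ loss per above-threshold category")
    all_losses = np.concatenate(([0.0], losses))
    shifts = mmr_shift_probability(all_losses, iq_mean, iq_sd, mmr_upper)
    return float(cm.masses @ shifts)
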