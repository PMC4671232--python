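"""Maternal blood-mercury distributions, exposure categories and intervention.

Blood Hg in each maternal age group is lognormal; the geometric mean fixes
the log-scale location and the log-scale spread is fitted to the printed
upper percentiles (weighted least squares through the origin when more
than one anchor is available).  Cord-blood category boundaries divided by
the cord/maternal ratio give maternal-blood category boundaries.  The
dietary intervention multiplies an individual's blood Hg by
(1 - effectiveness) with the success probability; because a scaled
lognormal is again lognormal, the re-categorized masses are exact
differences of normal CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .parameters import BirthModel, ParameterSet

_DEGENERATE_SIGMA = 1e-9


class InfeasibleFitError(ValueError):
    """Anchor percentiles are inconsistent with a lognormal above its median."""


@dataclass(frozen=True)
class LognormalParams:
    """Log-scale location and spread of a blood-Hg distribution (log ug/L)."""

    log_mu: float
    log_sigma: float
    degenerate: bool = False


@dataclass(frozen=True)
class CategoryMass:
    """Probability masses of the five exposure categories.

    Category 0 is below the adverse-effect threshold; categories 1-4 are
    the low / intermediate / high / very-high ranges above it.
    """

    bounds: tuple[float, ...]     # 4 maternal-blood cut points, ug/L
    masses: np.ndarray            # 5 probabilities summing to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        b = np.asarray(self.bounds, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("category bounds must be strictly increasing")
        if np.any(m < -1e-12) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("masses must be a probability vector")


def fit_lognormal(
    gm: float, anchors: Sequence[tuple[float, float]]
) -> LognormalParams:
    """Fit (log_mu, log_sigma) from a geometric mean and percentile anchors.

    The geometric mean is the lognormal median, so log_mu = ln(gm).  Each
    anchor (rank, value) contributes ln(value) - ln(gm) = z_rank * sigma;
    with several anchors sigma is the least-squares slope through the
    origin.  A median anchor arbitrarily close to the GM flags a
    degenerate (point-mass) fit.
    """
    if gm <= 0:
        raise ValueError("geometric mean must be > 0")
    if not anchors:
        raise ValueError("at least one percentile anchor is required")
    z, d = [], []
    for rank, value in anchors:
        if not 0 < rank < 100:
            raise ValueError(f"percentile rank {rank} not in (0, 100)")
        if value <= 0:
            raise ValueError("anchor values must be > 0")
        if rank > 50 and value <= gm:
            raise InfeasibleFitError(
                f"P{rank:g} = {value} does not exceed the geometric mean {gm}"
            )
        z.append(norm.ppf(rank / 100.0))
        d.append(np.log(value) - np.log(gm))
    z, d = np.asarray(z), np.asarray(d)
    if z @ z == 0:  # only median anchors: no spread information
        return LognormalParams(float(np.log(gm)), _DEGENERATE_SIGMA, degenerate=True)
    sigma = float(z @ d / (z @ z))
    if sigma <= _DEGENERATE_SIGMA:
        return LognormalParams(float(np.log(gm)), _DEGENERATE_SIGMA, degenerate=True)
    return LognormalParams(float(np.log(gm)), sigma)


def maternal_bounds(cord_bounds: Sequence[float], ratio: float) -> np.ndarray:
    """Cord-blood category boundaries expressed on the maternal-blood scale."""
    if ratio <= 0:
        raise ValueError("cord/maternal ratio must be > 0")
    return np.asarray(cord_bounds, dtype=float) / ratio


# -- vectorized kernels ------------------------------------------------------
# mu, sigma may be scalars or (n,) arrays; bounds (4,) or (n, 4).  These are
# shared by the deterministic path and the PSA batch evaluator.

def _tail(mu, sigma, x):
    """P(X > x) for lognormal(mu, sigma)."""
    return 1.0 - ndtr((np.log(x) - mu) / sigma)


def _cdf_at(mu, sigma, x):
    x = np.asarray(x, dtype=float)
    out = np.ones(np.broadcast(x, mu, sigma).shape)
    finite = np.isfinite(x)
    safe = np.where(finite & (x > 0), x, 1.0)
    vals = ndtr((np.log(safe) - mu) / sigma)
    vals = np.where(np.asarray(x > 0), vals, 0.0)
    return np.where(finite, vals, out)


def _category_masses(mu, sigma, bounds):
    """Masses of the 5 categories; supports batched mu/sigma/bounds."""
    mu = np.asarray(mu, dtype=float)[..., None]
    sigma = np.asarray(sigma, dtype=float)[..., None]
    cdf = ndtr((np.log(bounds) - mu) / sigma)
    shape = cdf.shape[:-1]
    zeros = np.zeros(shape + (1,))
    ones = np.ones(shape + (1,))
    return np.diff(np.concatenate([zeros, cdf, ones], axis=-1), axis=-1)


def _post_intervention_masses(mu, sigma, bounds, threshold, p_success, effectiveness):
    """Category masses after the dietary intervention (closed form).

    Women at or below the threshold are untouched.  A treated woman's blood
    Hg X > threshold becomes X * (1 - e) with probability p; the treated
    sub-population is a truncated lognormal whose scaled version is again
    lognormal, so the mass landing in category (lo, hi] is
    P(max(lo, t(1-e)) < X(1-e) <= hi) = F(hi/(1-e)) - F(max(lo/(1-e), t)).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    p_success = np.asarray(p_success, dtype=float)
    scale = 1.0 - np.asarray(effectiveness, dtype=float)
    if np.any(scale <= 0) or np.any(scale > 1):
        raise ValueError("effectiveness must lie in [0, 1)")
    base = _category_masses(mu, sigma, bounds)
    shape = base.shape[:-1]
    lo = np.broadcast_to(
        np.concatenate([np.zeros(shape + (1,)),
                        np.broadcast_to(bounds, shape + (4,))], axis=-1),
        shape + (5,))
    hi = np.concatenate([np.broadcast_to(bounds, shape + (4,)),
                         np.full(shape + (1,), np.inf)], axis=-1)
    mu_ = mu[..., None]
    sig_ = sigma[..., None]
    p_ = p_success[..., None] if p_success.ndim else p_success
    sc_ = scale[..., None] if scale.ndim else scale
    # treated mass leaving each category
    removed = np.clip(
        _cdf_at(mu_, sig_, hi) - _cdf_at(mu_, sig_, np.maximum(lo, threshold)),
        0.0, None)
    # treated mass arriving in each category after scaling
    arrived = np.clip(
        _cdf_at(mu_, sig_, hi / sc_)
        - _cdf_at(mu_, sig_, np.maximum(lo / sc_, threshold)),
        0.0, None)
    return base + p_ * (arrived - removed)


# -- public operations -------------------------------------------------------

def category_masses(ln: LognormalParams, bounds: Sequence[float]) -> CategoryMass:
    """Five-category probability masses under a fitted lognormal."""
    b = np.asarray(bounds, dtype=float)
    m = _category_masses(ln.log_mu, ln.log_sigma, b)
    return CategoryMass(tuple(b), np.asarray(m, dtype=float).ravel())


def apply_intervention(
    ln: LognormalParams,
    bounds: Sequence[float],
    threshold: float,
    p_success: float,
    effectiveness: float,
) -> CategoryMass:
    """Exposure-category masses after screening plus dietary advice.

    Total mass is conserved; with zero effectiveness or zero success
    probability the result equals :func:`category_masses`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not 0 <= p_success <= 1:
        raise ValueError("p_success must lie in [0, 1]")
    b = np.asarray(bounds, dtype=float)
    m = _post_intervention_masses(
        ln.log_mu, ln.log_sigma, b, threshold, p_success, effectiveness
    )
    return CategoryMass(tuple(b), np.asarray(m, dtype=float).ravel())


@dataclass(frozen=True)
class BirthWeights:
    """Planned live births per maternal age band with exposure-group links."""

    band_labels: tuple[str, ...]
    live_births: np.ndarray             # per band
    planned_live_births: np.ndarray     # x planned fraction
    screened_pregnancies: np.ndarray    # planned live births / P(live birth)
    attempting_couples: np.ndarray      # screened / (1 - infertility)
    exposure_group: np.ndarray          # group index per band


def birth_weights(bm: BirthModel) -> BirthWeights:
    """Distribute total live births over age bands and exposure groups."""
    rates = np.asarray(bm.birth_rate_by_band, dtype=float)
    live = bm.total_live_births * rates
    planned = live * bm.planned_fraction
    if bm.live_birth_given_planned > 0:
        screened = planned / bm.live_birth_given_planned
    else:
        screened = np.zeros_like(planned)
    infert = np.asarray(bm.infertility_by_band, dtype=float)
    return BirthWeights(
        band_labels=bm.band_labels,
        live_births=live,
        planned_live_births=planned,
        screened_pregnancies=screened,
        attempting_couples=screened / (1.0 - infert),
        exposure_group=np.asarray(bm.exposure_group_by_band, dtype=int),
    )


def group_weights(bm: BirthModel) -> np.ndarray:
    """Live-birth share of each exposure group, normalized over the bands."""
    bw = birth_weights(bm)
    w = np.zeros(int(bw.exposure_group.max()) + 1)
    np.add.at(w, bw.exposure_group, bw.live_births)
    return w / w.sum()


def fitted_groups(ps: ParameterSet) -> list[LognormalParams]:
    """Point lognormal fits for every exposure group of a parameter set."""
    return [
        fit_lognormal(g.geometric_mean, [(a.rank, a.value) for a in g.anchors])
        for g in ps.exposure_groups
    ]


def weighted_tail_probability(ps: ParameterSet, threshold: float) -> float:
    """P(maternal blood Hg > threshold) averaged over exposure groups,
    weighted by each group's share of live births."""
    fits = fitted_groups(ps)
    w = group_weights(ps.births)
    return float(sum(
        wg * _tail(fit.log_mu, fit.log_sigma, threshold)
        for wg, fit in zip(w, fits)
    ))


def count_above_threshold(ps: ParameterSet) -> tuple[float, float]:
    """Live births and planned pregnancies above the intervention threshold.

    Returns ``(live_births_above, planned_pregnancies_above)``: the number
    of live births to mothers whose blood Hg exceeds the maternal
    intervention threshold, and the corresponding planned pregnancies
    (planned fraction of those births divided by the probability that a
    planned pregnancy results in a live birth).
    """
    fits = fitted_groups(ps)
    bw = birth_weights(ps.births)
    thr = ps.intervention_threshold_maternal
    tails = np.array([_tail(f.log_mu, f.log_sigma, thr) for f in fits])
    above = float(np.sum(bw.live_births * tails[bw.exposure_group]))
    bm = ps.births
    planned = above * bm.planned_fraction / bm.live_birth_given_planned
    return above, planned
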