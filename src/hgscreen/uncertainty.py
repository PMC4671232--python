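"""Probabilistic sensitivity analysis, CEAC, EVPI and quadrature EVPPI.

Monte Carlo replications draw the nine uncertain parameters jointly
(independent marginals) and evaluate both comparators deterministically;
decision uncertainty is then summarized as the cost-effectiveness
acceptability curve, the expected value of perfect information and the
per-parameter partial EVPIs estimated by the quadrature (outer quantile
node / inner expectation) scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import _batch_outcomes
from .lifecourse import LifeTable, UtilityNorms
from .parameters import (
    PARAMETER_LABELS,
    UNCERTAIN_PARAMETERS,
    ParameterSet,
    draw_parameter_batch,
    psa_distributions,
)


@dataclass(frozen=True)
class PSAResults:
    """Per-replication strategy outcomes from the PSA."""

    cost_reference: np.ndarray
    qaly_reference: np.ndarray
    cost_screening: np.ndarray
    qaly_screening: np.ndarray
    seed: int
    threshold: float

    @property
    def n_replications(self) -> int:
        return self.cost_reference.size

    @property
    def incr_cost(self) -> np.ndarray:
        return self.cost_screening - self.cost_reference

    @property
    def incr_qaly(self) -> np.ndarray:
        return self.qaly_screening - self.qaly_reference

    def inb(self, wtp: float) -> np.ndarray:
        """Per-replication incremental net benefit at a willingness to pay."""
        return wtp * self.incr_qaly - self.incr_cost

    def net_benefit(self, wtp: float) -> np.ndarray:
        """(n, 2) net benefit of [reference, screening] at ``wtp``."""
        return np.column_stack([
            wtp * self.qaly_reference - self.cost_reference,
            wtp * self.qaly_screening - self.cost_screening,
        ])


@dataclass(frozen=True)
class VOIResult:
    """EVPI and per-parameter EVPPI over a willingness-to-pay grid."""

    wtp_grid: tuple[float, ...]
    evpi: np.ndarray                       # per wtp
    evppi: pd.DataFrame                    # parameters x wtp

    def __post_init__(self) -> None:
        if np.any(self.evpi < 0):
            raise ValueError("EVPI must be >= 0")


def run_psa(
    ps: ParameterSet,
    lt: LifeTable,
    un: UtilityNorms,
    seed: int,
    n_replications: int | None = None,
    threshold: float | None = None,
    visit_per_screening: bool = False,
) -> PSAResults:
    """Monte Carlo propagation of the nine parameter distributions.

    Each replication draws one joint parameter sample and evaluates both
    comparators; results are reproducible given the master seed.
    """
    n = ps.psa_replications if n_replications is None else int(n_replications)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = draw_parameter_batch(ps, n, rng)
    out = _batch_outcomes(
        ps, lt, un, draws, threshold=threshold,
        visit_per_screening=visit_per_screening,
    )
    thr = ps.intervention_threshold_maternal if threshold is None else threshold
    return PSAResults(
        cost_reference=out["cost_reference"],
        qaly_reference=out["qaly_reference"],
        cost_screening=out["cost_screening"],
        qaly_screening=out["qaly_screening"],
        seed=seed,
        threshold=thr,
    )


def psa_summary(psa: PSAResults, wtp_values: tuple[float, ...] = (20_000.0, 50_000.0)) -> dict:
    """Headline PSA statistics.

    The average ICUR is the ratio of the expected increments
    E[dCost]/E[dQALY] (the stable aggregation for ratio statistics); the
    90% interval comes from the 5th/95th empirical percentiles of the
    per-replication ratios, and INB intervals likewise.
    """
    d_cost, d_qaly = psa.incr_cost, psa.incr_qaly
    ratios = d_cost / d_qaly
    out = {
        "mean_icur": float(d_cost.mean() / d_qaly.mean()),
        "icur_p5": float(np.percentile(ratios, 5)),
        "icur_p95": float(np.percentile(ratios, 95)),
        "mean_incr_cost": float(d_cost.mean()),
        "mean_incr_qaly": float(d_qaly.mean()),
    }
    for wtp in wtp_values:
        inb = psa.inb(wtp)
        key = f"{int(wtp)}"
        out[f"inb_mean_{key}"] = float(inb.mean())
        out[f"inb_p5_{key}"] = float(np.percentile(inb, 5))
        out[f"inb_p95_{key}"] = float(np.percentile(inb, 95))
    return out


def ceac(psa: PSAResults, wtp_grid) -> np.ndarray:
    """Probability the screening strategy is optimal at each willingness to pay."""
    wtp = np.asarray(wtp_grid, dtype=float)
    inb = wtp[:, None] * psa.incr_qaly[None, :] - psa.incr_cost[None, :]
    return (inb > 0).mean(axis=1)


def evpi(psa: PSAResults, wtp: float) -> float:
    """Expected value of perfect information at one willingness to pay.

    Mean over replications of the best achievable net benefit minus the
    net benefit of the strategy that is best on average; non-negative by
    construction up to floating point.
    """
    nb = psa.net_benefit(wtp)
    value = float(nb.max(axis=1).mean() - nb.mean(axis=0).max())
    return max(value, 0.0)


def evpi_curve(psa: PSAResults, wtp_grid) -> np.ndarray:
    return np.array([evpi(psa, w) for w in np.asarray(wtp_grid, dtype=float)])


def evppi_quadrature(
    ps: ParameterSet,
    lt: LifeTable,
    un: UtilityNorms,
    parameter_id: str,
    wtp: float,
    nodes: int = 20,
    inner_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Partial EVPI of one parameter by the quadrature method.

    The outer loop fixes the parameter of interest at equal-probability
    quantile nodes of its marginal; an inner Monte Carlo expectation over
    the remaining parameters (common random numbers across nodes) gives
    the conditional mean net benefit of each strategy.  EVPPI is the
    node-average of the conditional maxima minus the maximum of the
    overall means, clipped at zero.
    """
    if parameter_id not in UNCERTAIN_PARAMETERS:
        raise KeyError(
            f"unknown parameter {parameter_id!r}; valid ids: "
            + ", ".join(UNCERTAIN_PARAMETERS)
        )
    if nodes < 2:
        raise ValueError("at least 2 quadrature nodes are required")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    inner = draw_parameter_batch(ps, inner_reps, rng)
    dist = psa_distributions(ps)[parameter_id]
    node_values = dist.ppf((np.arange(nodes) + 0.5) / nodes)

    # one big batch: nodes x inner_reps, parameter of interest tiled per node
    batch = {
        k: np.tile(v, nodes) for k, v in inner.items()
    }
    batch[parameter_id] = np.repeat(node_values, inner_reps)
    out = _batch_outcomes(ps, lt, un, batch)
    nb = np.stack([
        wtp * out["qaly_reference"] - out["cost_reference"],
        wtp * out["qaly_screening"] - out["cost_screening"],
    ], axis=1).reshape(nodes, inner_reps, 2)
    cond_means = nb.mean(axis=1)                 # (nodes, 2)
    value = cond_means.max(axis=1).mean() - cond_means.mean(axis=0).max()
    return max(float(value), 0.0)


def voi_table(
    ps: ParameterSet,
    lt: LifeTable,
    un: UtilityNorms,
    seed: int,
    wtp_grid=None,
    n_replications: int | None = None,
    nodes: int = 20,
    inner_reps: int = 1000,
) -> VOIResult:
    """EVPI plus the nine EVPPIs over the willingness-to-pay grid."""
    wtps = tuple(float(w) for w in (wtp_grid if wtp_grid is not None else ps.wtp_grid))
    psa = run_psa(ps, lt, un, seed, n_replications)
    evpi_vals = np.array([evpi(psa, w) for w in wtps])
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(UNCERTAIN_PARAMETERS)) % (2**31)
    rows = {}
    for name, sub in zip(UNCERTAIN_PARAMETERS, sub_seeds):
        rows[PARAMETER_LABELS[name]] = [
            evppi_quadrature(ps, lt, un, name, w, nodes, inner_reps, int(sub))
            for w in wtps
        ]
    evppi_df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"{w:g}" for w in wtps])
    return VOIResult(wtp_grid=wtps, evpi=evpi_vals, evppi=evppi_df)
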