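"""Model parameterization: base-case constants, configuration I/O and PSA draws.

Every constant of the economic model lives in :class:`ParameterSet`.  The
base case is returned by :func:`default_parameters`; a YAML configuration
file can override any subset of keys (:func:`load_config`).  Nine
parameters carry uncertainty distributions for the probabilistic
sensitivity analysis; :func:`draw_parameters` produces one joint draw.

Units: blood mercury in ug/L, costs in 2012-2013 Canadian dollars,
utilities on the 0 (death) to 1 (perfect health) scale, IQ in points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .lifecourse import CostSchedule, DiscountSchedule

Z_95 = float(stats.norm.ppf(0.975))  # half-width of a 95% normal CI in SDs

#: Identifiers of the nine PSA-uncertain parameters, in reporting order.
UNCERTAIN_PARAMETERS = (
    "mu_hg_20_39",
    "sigma_hg_20_39",
    "mu_hg_40_59",
    "sigma_hg_40_59",
    "cord_maternal_ratio",
    "effect_per_doubling",
    "p_intervention_success",
    "intervention_effectiveness",
    "mmr_disutility",
)

#: Human-readable labels used in value-of-information reports.
PARAMETER_LABELS = {
    "mu_hg_20_39": "Mean Hg(B) of women 20-39 years",
    "sigma_hg_20_39": "Standard deviation Hg(B) of women 20-39 years",
    "mu_hg_40_59": "Mean Hg(B) of women 40-59 years",
    "sigma_hg_40_59": "Standard deviation Hg(B) of women 40-59 years",
    "cord_maternal_ratio": "Ratio of cord/maternal Hg(B)",
    "effect_per_doubling": "Percent of a standard deviation in cognitive deficits",
    "p_intervention_success": "Probability of a successful intervention",
    "intervention_effectiveness": "Effectiveness of a successful intervention",
    "mmr_disutility": "Disutility for MMR",
}


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


class ConfigError(ValueError):
    """A configuration file is malformed or names an unknown key."""


@dataclass(frozen=True)
class PercentileAnchor:
    """A survey percentile of the blood-Hg distribution with its 95% CI."""

    rank: float          # percentile rank in (0, 100)
    value: float         # ug/L
    ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class AgeGroupExposure:
    """Blood-mercury summary statistics for one maternal age group."""

    label: str
    geometric_mean: float                       # ug/L
    gm_ci: tuple[float, float]                  # 95% CI of the GM
    anchors: tuple[PercentileAnchor, ...]       # upper percentiles

    def validate(self) -> None:
        if self.geometric_mean <= 0:
            raise ValidationError(f"{self.label}: geometric_mean must be > 0")
        for a in self.anchors:
            if not 0 < a.rank < 100:
                raise ValidationError(f"{self.label}: anchor rank {a.rank} not in (0, 100)")
            if a.value <= 0:
                raise ValidationError(f"{self.label}: anchor value must be > 0")
            if a.rank > 50 and a.value <= self.geometric_mean:
                raise ValidationError(
                    f"{self.label}: percentile {a.rank} value {a.value} must exceed "
                    f"the geometric mean {self.geometric_mean}"
                )


@dataclass(frozen=True)
class BirthModel:
    """Ontario 2011 live births and the planning/fertility fractions.

    The age bands cover mothers 20-49; the printed band shares sum to 0.970
    because ~3% of live births fall outside the screened age range.  Bands
    20-39 draw exposure from group 0, bands 40-49 from group 1.
    """

    total_live_births: float = 140_135.0
    band_labels: tuple[str, ...] = ("20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
    birth_rate_by_band: tuple[float, ...] = (0.122, 0.280, 0.345, 0.181, 0.039, 0.003)
    infertility_by_band: tuple[float, ...] = (0.070, 0.085, 0.108, 0.130, 0.143, 0.143)
    exposure_group_by_band: tuple[int, ...] = (0, 0, 0, 0, 1, 1)
    planned_fraction: float = 0.5
    live_birth_given_planned: float = 0.9
    orphan_patient_fraction: float = 0.08

    def validate(self) -> None:
        n = len(self.band_labels)
        for name in ("birth_rate_by_band", "infertility_by_band", "exposure_group_by_band"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"births.{name}: expected {n} entries")
        if self.total_live_births <= 0:
            raise ValidationError("births.total_live_births must be > 0")
        total = float(np.sum(self.birth_rate_by_band))
        if not (0 < total <= 1 + 1e-9):
            raise ValidationError(f"births.birth_rate_by_band sums to {total}, not in (0, 1]")
        for name in ("planned_fraction", "live_birth_given_planned", "orphan_patient_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"births.{name}={v} not in [0, 1]")
        for r in self.birth_rate_by_band + self.infertility_by_band:
            if not 0 <= r <= 1:
                raise ValidationError(f"births: rate {r} not in [0, 1]")


@dataclass(frozen=True)
class Strategy:
    """A treatment comparator: standard care or screening at a threshold."""

    kind: str                    # "reference" or "screening"
    threshold: float | None = None   # maternal intervention threshold, ug/L
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("reference", "screening"):
            raise ValidationError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "screening" and (self.threshold is None or self.threshold <= 0):
            raise ValidationError("screening strategy requires a positive threshold")
        if not self.label:
            object.__setattr__(
                self, "label",
                "reference" if self.kind == "reference"
                else f"screening@{self.threshold:g}",
            )

    @staticmethod
    def reference() -> "Strategy":
        return Strategy("reference")

    @staticmethod
    def screening(threshold: float) -> "Strategy":
        return Strategy("screening", threshold)


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterization of the economic model (base case defaults)."""

    exposure_groups: tuple[AgeGroupExposure, ...] = (
        AgeGroupExposure(
            label="20-39",
            geometric_mean=0.66,
            gm_ci=(0.47, 0.92),
            anchors=(PercentileAnchor(75, 1.6, (1.1, 2.1)),),
        ),
        AgeGroupExposure(
            label="40-59",
            geometric_mean=0.82,
            gm_ci=(0.65, 1.0),
            anchors=(
                PercentileAnchor(75, 1.7, (1.1, 2.2)),
                PercentileAnchor(90, 2.9, (1.9, 3.9)),
            ),
        ),
    )
    cord_maternal_ratio: float = 1.7
    ratio_ci: tuple[float, float] = (1.0, 3.4)
    effect_per_doubling: float = 0.094      # fraction of an IQ SD per exposure doubling
    effect_se: float = 0.0093
    effect_gamma_shape: float = 101.0
    effect_gamma_scale: float = 0.000926
    iq_mean: float = 100.0
    iq_sd: float = 15.0
    mmr_upper: float = 70.0
    cord_category_bounds: tuple[float, ...] = (5.8, 7.3, 10.2, 13.0)
    category_multipliers: tuple[float, ...] = (0.125, 0.5, 1.0, 1.25)
    adverse_effect_threshold_cord: float = 5.8
    adverse_effect_threshold_maternal: float = 3.4
    intervention_threshold_maternal: float = 3.4
    p_success_beta: tuple[float, float] = (6.0, 1.0)
    effectiveness_beta: tuple[float, float] = (11.6, 9.2)
    mmr_disutility: float = 0.38
    mmr_disutility_sd: float = 0.021
    discount: DiscountSchedule = field(default_factory=lambda: DiscountSchedule.constant(0.05))
    costs: CostSchedule = field(default_factory=CostSchedule)
    births: BirthModel = field(default_factory=BirthModel)
    psa_replications: int = 5000
    wtp_grid: tuple[float, ...] = (20_000.0, 30_000.0, 50_000.0)

    @property
    def p_intervention_success(self) -> float:
        a, b = self.p_success_beta
        return a / (a + b)

    @property
    def intervention_effectiveness(self) -> float:
        a, b = self.effectiveness_beta
        return a / (a + b)

    def validate(self) -> None:
        errors: list[str] = []
        try:
            for g in self.exposure_groups:
                g.validate()
            self.births.validate()
            self.costs.validate()
            self.discount.validate()
        except ValueError as exc:  # includes lifecourse TableError
            errors.append(str(exc))
        bounds = np.asarray(self.cord_category_bounds, dtype=float)
        if bounds.size != 4 or np.any(np.diff(bounds) <= 0):
            errors.append("cord_category_bounds must be 4 strictly increasing values")
        mult = np.asarray(self.category_multipliers, dtype=float)
        if mult.size != 4 or np.any(np.diff(mult) <= 0):
            errors.append("category_multipliers must be 4 strictly increasing values")
        if self.cord_maternal_ratio <= 0:
            errors.append("cord_maternal_ratio must be > 0")
        if self.effect_per_doubling <= 0:
            errors.append("effect_per_doubling must be > 0")
        for name in ("p_intervention_success", "intervention_effectiveness"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errors.append(f"{name}={v} not in [0, 1]")
        if not 0 <= self.mmr_disutility <= 1:
            errors.append(f"mmr_disutility={self.mmr_disutility} not in [0, 1]")
        for name in ("intervention_threshold_maternal", "adverse_effect_threshold_maternal"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        if self.psa_replications < 1:
            errors.append("psa_replications must be >= 1")
        if len(UNCERTAIN_PARAMETERS) != 9:
            errors.append("exactly nine parameters must be PSA-uncertain")
        if errors:
            raise ValidationError("; ".join(errors))


@dataclass(frozen=True)
class ParameterSample:
    """One concrete joint draw of the nine uncertain parameters."""

    mu_hg_20_39: float
    sigma_hg_20_39: float
    mu_hg_40_59: float
    sigma_hg_40_59: float
    cord_maternal_ratio: float
    effect_per_doubling: float
    p_intervention_success: float
    intervention_effectiveness: float
    mmr_disutility: float
    replication: int = 0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in UNCERTAIN_PARAMETERS}


def default_parameters() -> ParameterSet:
    """Return the base-case configuration; all invariants hold."""
    ps = ParameterSet()
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

def _fitted_log_params(ps: ParameterSet):
    """Point fits (log_mu, log_sigma) for both exposure groups."""
    from .exposure import fit_lognormal  # local import avoids a module cycle

    return [
        fit_lognormal(g.geometric_mean, [(a.rank, a.value) for a in g.anchors])
        for g in ps.exposure_groups
    ]


def _log_scale_ses(group: AgeGroupExposure) -> tuple[float, float]:
    """Standard errors of (log_mu, log_sigma) back-solved from printed CIs.

    log_mu uncertainty comes from the geometric-mean CI (symmetric on the
    log scale).  log_sigma is a weighted least-squares slope through the
    anchor log-quantiles, so its SE propagates the anchor-CI variances
    through the same weights.
    """
    lo, hi = group.gm_ci
    se_mu = (np.log(hi) - np.log(lo)) / (2 * Z_95)
    z = np.array([stats.norm.ppf(a.rank / 100) for a in group.anchors])
    se_d = np.array(
        [(np.log(a.ci[1]) - np.log(a.ci[0])) / (2 * Z_95) for a in group.anchors]
    )
    se_sigma = float(np.sqrt(np.sum(z**2 * se_d**2)) / np.sum(z**2))
    return float(se_mu), se_sigma


def psa_distributions(ps: ParameterSet) -> dict[str, stats.rv_continuous]:
    """Frozen scipy marginals for the nine uncertain parameters.

    The cord/maternal ratio is lognormal with its 95% CI matched
    symmetrically on the log scale; log-sigma draws are truncated to stay
    positive and the MMR disutility to [0, 1].
    """
    fits = _fitted_log_params(ps)
    out: dict[str, stats.rv_continuous] = {}
    for g, fit, (mu_key, sd_key) in zip(
        ps.exposure_groups,
        fits,
        (("mu_hg_20_39", "sigma_hg_20_39"), ("mu_hg_40_59", "sigma_hg_40_59")),
    ):
        se_mu, se_sigma = _log_scale_ses(g)
        out[mu_key] = stats.norm(loc=fit.log_mu, scale=se_mu)
        a = (0.0 - fit.log_sigma) / se_sigma
        out[sd_key] = stats.truncnorm(a, np.inf, loc=fit.log_sigma, scale=se_sigma)
    r_lo, r_hi = ps.ratio_ci
    log_mid = 0.5 * (np.log(r_lo) + np.log(r_hi))
    log_sd = (np.log(r_hi) - np.log(r_lo)) / (2 * Z_95)
    out["cord_maternal_ratio"] = stats.lognorm(s=log_sd, scale=np.exp(log_mid))
    out["effect_per_doubling"] = stats.gamma(
        a=ps.effect_gamma_shape, scale=ps.effect_gamma_scale
    )
    out["p_intervention_success"] = stats.beta(*ps.p_success_beta)
    out["intervention_effectiveness"] = stats.beta(*ps.effectiveness_beta)
    a = (0.0 - ps.mmr_disutility) / ps.mmr_disutility_sd
    b = (1.0 - ps.mmr_disutility) / ps.mmr_disutility_sd
    out["mmr_disutility"] = stats.truncnorm(
        a, b, loc=ps.mmr_disutility, scale=ps.mmr_disutility_sd
    )
    return out


def draw_parameter_batch(
    ps: ParameterSet, n: int, seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` joint samples of the nine uncertain parameters.

    Deterministic given the seed; parameters are drawn independently, each
    from its marginal, in the fixed order of ``UNCERTAIN_PARAMETERS``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dists = psa_distributions(ps)
    return {
        name: np.asarray(dists[name].rvs(size=n, random_state=rng), dtype=float)
        for name in UNCERTAIN_PARAMETERS
    }


def draw_parameters(ps: ParameterSet, seed: int) -> ParameterSample:
    """Draw one :class:`ParameterSample` (deterministic given ``seed``)."""
    if seed < 0:
        raise ValueError("seed must be >= 0")
    batch = draw_parameter_batch(ps, 1, seed)
    return ParameterSample(
        **{name: float(batch[name][0]) for name in UNCERTAIN_PARAMETERS},
        replication=0,
    )


def point_sample(ps: ParameterSet) -> ParameterSample:
    """The deterministic (base-case) parameter values as a sample object."""
    fits = _fitted_log_params(ps)
    return ParameterSample(
        mu_hg_20_39=fits[0].log_mu,
        sigma_hg_20_39=fits[0].log_sigma,
        mu_hg_40_59=fits[1].log_mu,
        sigma_hg_40_59=fits[1].log_sigma,
        cord_maternal_ratio=ps.cord_maternal_ratio,
        effect_per_doubling=ps.effect_per_doubling,
        p_intervention_success=ps.p_intervention_success,
        intervention_effectiveness=ps.intervention_effectiveness,
        mmr_disutility=ps.mmr_disutility,
    )


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

def serialize(ps: ParameterSet) -> dict:
    """Nested plain-python dict mirroring the configuration schema."""
    return {
        "exposure_groups": [
            {
                "label": g.label,
                "geometric_mean": g.geometric_mean,
                "gm_ci": list(g.gm_ci),
                "anchors": [
                    {"rank": a.rank, "value": a.value,
                     "ci": list(a.ci) if a.ci else None}
                    for a in g.anchors
                ],
            }
            for g in ps.exposure_groups
        ],
        "cord_maternal_ratio": ps.cord_maternal_ratio,
        "ratio_ci": list(ps.ratio_ci),
        "effect_per_doubling": ps.effect_per_doubling,
        "effect_se": ps.effect_se,
        "effect_gamma_shape": ps.effect_gamma_shape,
        "effect_gamma_scale": ps.effect_gamma_scale,
        "iq_mean": ps.iq_mean,
        "iq_sd": ps.iq_sd,
        "mmr_upper": ps.mmr_upper,
        "cord_category_bounds": list(ps.cord_category_bounds),
        "category_multipliers": list(ps.category_multipliers),
        "adverse_effect_threshold_cord": ps.adverse_effect_threshold_cord,
        "adverse_effect_threshold_maternal": ps.adverse_effect_threshold_maternal,
        "intervention_threshold_maternal": ps.intervention_threshold_maternal,
        "p_success_beta": list(ps.p_success_beta),
        "effectiveness_beta": list(ps.effectiveness_beta),
        "mmr_disutility": ps.mmr_disutility,
        "mmr_disutility_sd": ps.mmr_disutility_sd,
        "discount": ps.discount.to_dict(),
        "costs": dataclasses.asdict(ps.costs),
        "births": dataclasses.asdict(ps.births),
        "psa_replications": ps.psa_replications,
        "wtp_grid": list(ps.wtp_grid),
    }


def _build(cfg: Mapping) -> ParameterSet:
    def _tup(x):
        return tuple(x) if isinstance(x, (list, tuple)) else x

    groups = tuple(
        AgeGroupExposure(
            label=g["label"],
            geometric_mean=g["geometric_mean"],
            gm_ci=tuple(g["gm_ci"]),
            anchors=tuple(
                PercentileAnchor(a["rank"], a["value"],
                                 tuple(a["ci"]) if a.get("ci") else None)
                for a in g["anchors"]
            ),
        )
        for g in cfg["exposure_groups"]
    )
    births_cfg = dict(cfg["births"])
    births = BirthModel(**{k: _tup(v) for k, v in births_cfg.items()})
    costs_cfg = {k: _tup(v) for k, v in dict(cfg["costs"]).items()}
    costs_cfg["tier_age_ranges"] = tuple(
        tuple(r) for r in costs_cfg["tier_age_ranges"]
    )
    costs = CostSchedule(**costs_cfg)
    discount = DiscountSchedule.from_dict(cfg["discount"])
    scalar_keys = [
        "cord_maternal_ratio", "ratio_ci", "effect_per_doubling", "effect_se",
        "effect_gamma_shape", "effect_gamma_scale", "iq_mean", "iq_sd",
        "mmr_upper", "cord_category_bounds", "category_multipliers",
        "adverse_effect_threshold_cord", "adverse_effect_threshold_maternal",
        "intervention_threshold_maternal", "p_success_beta",
        "effectiveness_beta", "mmr_disutility", "mmr_disutility_sd",
        "psa_replications", "wtp_grid",
    ]
    kwargs = {k: _tup(cfg[k]) for k in scalar_keys}
    return ParameterSet(
        exposure_groups=groups, discount=discount, costs=costs, births=births,
        **kwargs,
    )


def _deep_merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(value, Mapping) and isinstance(base[key], Mapping):
            out[key] = _deep_merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path) -> ParameterSet:
    """Load a YAML configuration; missing keys fall back to the defaults.

    Raises :class:`ConfigError` for unparseable files or unknown keys and
    :class:`ValidationError` when the merged configuration violates a
    model invariant.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    merged = _deep_merge(serialize(default_parameters()), raw)
    ps = _build(merged)
    ps.validate()
    return ps


def save_config(ps: ParameterSet, path) -> None:
    """Write the configuration as YAML; ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(serialize(ps), fh, sort_keys=False)
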