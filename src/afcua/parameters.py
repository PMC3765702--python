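"""Model parameter registry: baselines, sensitivity ranges and PSA distributions.

Every scalar input of the decision model lives in a :class:`ParameterSet`.
Parameters that carry an uncertainty range are additionally described in
:data:`PSA_REGISTRY`, which records the distribution family used by the
probabilistic sensitivity analysis (beta for probabilities and utilities,
gamma for costs, log-normal for relative risks). Ranges are interpreted as
central 95% intervals when fitting those distributions.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Any, NamedTuple

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "ParameterError",
    "ParameterValue",
    "ParameterSet",
    "PSA_REGISTRY",
    "default_parameter_set",
    "load_parameter_set",
    "save_parameter_set",
    "apply_overrides",
    "sample_psa_draw",
    "fit_beta_from_ci",
    "fit_gamma_from_ci",
    "fit_lognormal_from_ci",
    "validate_parameter_set",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ParameterError(ValueError):
    """Raised when a parameter value or override is invalid."""


@dataclass(frozen=True)
class ParameterValue:
    """Metadata for one uncertain scalar: baseline, range and PSA family."""

    name: str
    baseline: float
    low: float | None = None
    high: float | None = None
    family: str = "fixed"  # beta | gamma | lognormal | fixed
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in {"beta", "gamma", "lognormal", "fixed"}:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.baseline <= self.high):
                raise ParameterError(
                    f"{self.name}: baseline {self.baseline} outside "
                    f"[{self.low}, {self.high}]"
                )
            if self.family == "beta" and not (
                0.0 <= self.low <= 1.0 and 0.0 <= self.high <= 1.0
            ):
                raise ParameterError(f"{self.name}: beta range must lie in [0, 1]")


@dataclass
class ParameterSet:
    """Complete set of model inputs plus global run settings.

    All monetary amounts are CAD$; probabilities are annual unless the
    field name says otherwise; splits are conditional probabilities.
    """

    # --- INR control -------------------------------------------------------
    ttr_sdw: float = 0.64
    frac_below_of_out_of_range: float = 0.54
    gtw_ttr_uplift: float = 0.073

    # --- bleeding ----------------------------------------------------------
    p_bleed_annual_inrange: float = 0.014
    rr_bleed_out_of_range: float = 4.7
    rr_bleed_dab: float = 0.93
    bleed_split_warfarin: dict = field(
        default_factory=lambda: {"intracranial": 0.42, "extracranial": 0.58}
    )
    # raw values sum to 1.03; normalized at use sites
    bleed_split_dab_raw: dict = field(
        default_factory=lambda: {"intracranial": 0.126, "extracranial": 0.904}
    )

    # --- thromboembolism ---------------------------------------------------
    p_te_annual_inrange: float = 0.024
    rr_te_subtherapeutic: float = 3.5
    rr_te_other_out_of_range: float = 0.9
    rr_te_dab: dict = field(
        default_factory=lambda: {"stroke": 0.66, "mi": 1.38, "pe": 1.61, "dvt": 1.0}
    )
    te_split_warfarin: dict = field(
        default_factory=lambda: {"stroke": 0.525, "mi": 0.125, "pe": 0.30, "dvt": 0.05}
    )

    # --- event outcome trees ----------------------------------------------
    ich_outcomes: dict = field(
        default_factory=lambda: {
            "no_deficit": 0.08,
            "mild": 0.16,
            "severe": 0.34,
            "death_first_month": 0.42,
        }
    )
    p_death_extracranial: float = 0.02
    stroke_outcomes: dict = field(
        default_factory=lambda: {
            "death_m1": 0.083,
            "death_m2": 0.056,
            "death_m3": 0.056,
            "severe": 0.402,
            "mild": 0.425,
            "none": 0.091,
        }
    )
    p_death_pe: float = 0.12
    p_death_dvt: float = 0.06
    p_death_mi: float = 0.07

    # --- discontinuation ---------------------------------------------------
    stop_after_gi_bleed_days: int = 30  # intracranial bleeds stop therapy for good

    # --- costs -------------------------------------------------------------
    cost_dab_daily: float = 3.20
    cost_warfarin_daily: float = 0.074
    cost_lmwh_course: float = 27.90
    cost_inr_month_sdw_y1: float = 8.06
    cost_inr_month_gtw_y1: float = 5.00
    cost_inr_month_later: float = 4.03
    cost_genotyping: float = 615.0
    event_costs: dict = field(
        default_factory=lambda: {
            "stroke_none": 845.0,
            "stroke_mild": 23772.0,
            "stroke_severe": 42620.0,
            "ich_none": 1067.0,
            "ich_mild": 21218.0,
            "ich_severe": 36451.0,
            "subdural": 31942.0,
            "extracranial_bleed": 8146.0,
            "dvt": 2576.0,
            "pe": 8799.0,
            "mi": 7177.0,
        }
    )
    post_event_monthly: dict = field(
        default_factory=lambda: {"severe": 6259.0, "mild": 1855.0}
    )

    # --- utilities ---------------------------------------------------------
    # ich_* stores the corrected ordering (no-deficit best); the literal
    # printed ordering is available through flags.literal_ich_utilities.
    utilities: dict = field(
        default_factory=lambda: {
            "no_event_warfarin": 0.95,
            "no_event_dab": 0.95,
            "ich_none": 0.95,
            "ich_mild": 0.75,
            "ich_severe": 0.51,
            "extracranial": 0.80,
            "stroke_none": 0.95,
            "stroke_mild": 0.75,
            "stroke_severe": 0.39,
            "mi": 0.84,
            "pe": 0.76,
            "dvt": 0.84,
        }
    )

    # --- global run settings ----------------------------------------------
    horizon_days: int = 1825
    discount_annual: float = 0.03
    cohort_size: int = 10000
    n_replicates: int = 1000
    psa_cohort_size: int = 5000
    psa_iterations: int = 1000
    wtp_threshold: float = 50000.0
    age_mean: float = 64.0
    age_sd: float = 8.0

    # --- structural switches ------------------------------------------------
    flags: dict = field(
        default_factory=lambda: {
            "literal_rr_labels": False,
            "literal_ich_utilities": False,
            "additive_ttr_uplift": False,
        }
    )

    def to_dict(self) -> dict:
        return copy.deepcopy(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = set(cls.__dataclass_fields__)
        extra = set(data) - known
        if extra:
            raise ParameterError(f"unknown parameter field(s): {sorted(extra)}")
        missing = known - set(data)
        if missing:
            raise ParameterError(f"missing parameter field(s): {sorted(missing)}")
        pset = cls(**copy.deepcopy(data))
        validate_parameter_set(pset)
        return pset

    def copy(self) -> "ParameterSet":
        return ParameterSet(**self.to_dict())

    def get_path(self, path: str) -> Any:
        obj: Any = self
        for i, part in enumerate(path.split(".")):
            if isinstance(obj, dict):
                if part not in obj:
                    raise ParameterError(f"unknown parameter path {path!r}")
                obj = obj[part]
            else:
                if part not in type(obj).__dataclass_fields__:
                    raise ParameterError(f"unknown parameter path {path!r}")
                obj = getattr(obj, part)
        return obj

    def set_path(self, path: str, value: Any) -> None:
        parts = path.split(".")
        if parts[0] not in type(self).__dataclass_fields__:
            raise ParameterError(f"unknown parameter path {path!r}")
        if len(parts) == 1:
            setattr(self, parts[0], value)
            return
        obj = getattr(self, parts[0])
        for part in parts[1:-1]:
            if not isinstance(obj, dict) or part not in obj:
                raise ParameterError(f"unknown parameter path {path!r}")
            obj = obj[part]
        if not isinstance(obj, dict) or parts[-1] not in obj:
            raise ParameterError(f"unknown parameter path {path!r}")
        obj[parts[-1]] = value


# ---------------------------------------------------------------------------
# PSA registry: every scalar with a stated range and distribution family.
# Event-type splits and outcome trees are fixed in the PSA.
# ---------------------------------------------------------------------------
PSA_REGISTRY: tuple[ParameterValue, ...] = (
    ParameterValue("ttr_sdw", 0.64, 0.55, 0.69, "beta", "fraction"),
    ParameterValue("frac_below_of_out_of_range", 0.54, 0.45, 0.60, "beta", "fraction"),
    ParameterValue("gtw_ttr_uplift", 0.073, 0.0, 0.30, "beta", "fraction"),
    ParameterValue("p_bleed_annual_inrange", 0.014, 0.009, 0.023, "beta", "1/yr"),
    ParameterValue("rr_bleed_out_of_range", 4.7, 3.57, 10.0, "lognormal", "RR"),
    ParameterValue("rr_bleed_dab", 0.93, 0.81, 1.07, "lognormal", "RR"),
    ParameterValue("p_te_annual_inrange", 0.024, 0.012, 0.049, "beta", "1/yr"),
    ParameterValue("rr_te_subtherapeutic", 3.5, 2.8, 4.4, "lognormal", "RR"),
    ParameterValue("rr_te_other_out_of_range", 0.9, 0.6, 1.3, "lognormal", "RR"),
    ParameterValue("rr_te_dab.stroke", 0.66, 0.53, 0.82, "lognormal", "RR"),
    ParameterValue("rr_te_dab.mi", 1.38, 1.0, 1.91, "lognormal", "RR"),
    ParameterValue("rr_te_dab.pe", 1.61, 0.76, 3.42, "lognormal", "RR"),
    ParameterValue("cost_dab_daily", 3.20, 1.0, 5.0, "gamma", "CAD$/day"),
    ParameterValue("cost_warfarin_daily", 0.074, 0.03, 0.10, "gamma", "CAD$/day"),
    ParameterValue("cost_inr_month_sdw_y1", 8.06, 5.0, 12.0, "gamma", "CAD$/month"),
    ParameterValue("cost_inr_month_gtw_y1", 5.00, 2.0, 8.0, "gamma", "CAD$/month"),
    ParameterValue("cost_inr_month_later", 4.03, 2.0, 6.0, "gamma", "CAD$/month"),
    ParameterValue("cost_genotyping", 615.0, 100.0, 1000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.stroke_none", 845.0, 500.0, 1000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.stroke_mild", 23772.0, 15000.0, 40000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.stroke_severe", 42620.0, 30000.0, 60000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.ich_mild", 21218.0, 15000.0, 25000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.ich_severe", 36451.0, 25000.0, 50000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.subdural", 31942.0, 20000.0, 45000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.extracranial_bleed", 8146.0, 5000.0, 12000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.dvt", 2576.0, 1500.0, 4000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.pe", 8799.0, 5000.0, 9000.0, "gamma", "CAD$"),
    ParameterValue("event_costs.mi", 7177.0, 5000.0, 15000.0, "gamma", "CAD$"),
    ParameterValue("post_event_monthly.severe", 6259.0, 3000.0, 10000.0, "gamma", "CAD$/month"),
    ParameterValue("post_event_monthly.mild", 1855.0, 1000.0, 3000.0, "gamma", "CAD$/month"),
    ParameterValue("utilities.no_event_warfarin", 0.95, 0.95, 0.98, "beta", "utility"),
    ParameterValue("utilities.no_event_dab", 0.95, 0.95, 0.98, "beta", "utility"),
    ParameterValue("utilities.ich_none", 0.95, 0.90, 0.95, "beta", "utility"),
    ParameterValue("utilities.ich_mild", 0.75, 0.70, 0.90, "beta", "utility"),
    ParameterValue("utilities.ich_severe", 0.51, 0.15, 0.60, "beta", "utility"),
    ParameterValue("utilities.extracranial", 0.80, 0.75, 0.85, "beta", "utility"),
    ParameterValue("utilities.stroke_none", 0.95, 0.90, 0.95, "beta", "utility"),
    ParameterValue("utilities.stroke_mild", 0.75, 0.70, 0.90, "beta", "utility"),
    ParameterValue("utilities.stroke_severe", 0.39, 0.15, 0.50, "beta", "utility"),
    ParameterValue("utilities.mi", 0.84, 0.80, 0.90, "beta", "utility"),
    ParameterValue("utilities.pe", 0.76, 0.70, 0.90, "beta", "utility"),
    ParameterValue("utilities.dvt", 0.84, 0.80, 0.90, "beta", "utility"),
)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_PROBABILITY_FIELDS = (
    "ttr_sdw",
    "frac_below_of_out_of_range",
    "p_bleed_annual_inrange",
    "p_te_annual_inrange",
    "p_death_extracranial",
    "p_death_pe",
    "p_death_dvt",
    "p_death_mi",
)

_COST_FIELDS = (
    "cost_dab_daily",
    "cost_warfarin_daily",
    "cost_lmwh_course",
    "cost_inr_month_sdw_y1",
    "cost_inr_month_gtw_y1",
    "cost_inr_month_later",
    "cost_genotyping",
)


def validate_parameter_set(pset: ParameterSet) -> None:
    """Raise :class:`ParameterError` naming the first offending field."""
    for name in _PROBABILITY_FIELDS:
        v = getattr(pset, name)
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}: probability {v} outside [0, 1]")
    for name in _COST_FIELDS:
        v = getattr(pset, name)
        if v < 0:
            raise ParameterError(f"{name}: cost {v} is negative")
    for key, v in {**pset.event_costs, **pset.post_event_monthly}.items():
        if v < 0:
            raise ParameterError(f"event cost {key}: {v} is negative")
    for key, v in pset.utilities.items():
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"utilities.{key}: {v} outside [0, 1]")
    for key, v in {**pset.ich_outcomes, **pset.stroke_outcomes}.items():
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"outcome probability {key}: {v} outside [0, 1]")
    if abs(sum(pset.te_split_warfarin.values()) - 1.0) > 1e-9:
        raise ParameterError("te_split_warfarin does not sum to 1")
    if abs(sum(pset.ich_outcomes.values()) - 1.0) > 1e-9:
        raise ParameterError("ich_outcomes does not sum to 1")
    raw = pset.bleed_split_dab_raw
    total = sum(raw.values())
    if total <= 0:
        raise ParameterError("bleed_split_dab_raw sums to zero")
    if abs(sum(v / total for v in raw.values()) - 1.0) > 1e-9:
        raise ParameterError("normalized dabigatran bleed split does not sum to 1")
    if abs(sum(pset.bleed_split_warfarin.values()) - 1.0) > 1e-9:
        raise ParameterError("bleed_split_warfarin does not sum to 1")
    for rr_name in ("rr_bleed_out_of_range", "rr_bleed_dab",
                    "rr_te_subtherapeutic", "rr_te_other_out_of_range"):
        if getattr(pset, rr_name) < 0:
            raise ParameterError(f"{rr_name}: relative risk is negative")
    if pset.horizon_days < 1:
        raise ParameterError("horizon_days must be >= 1")
    if pset.discount_annual < 0:
        raise ParameterError("discount_annual must be >= 0")
    if not 0.0 <= pset.gtw_ttr_uplift:
        raise ParameterError("gtw_ttr_uplift must be >= 0")


def default_parameter_set() -> ParameterSet:
    """Return the full baseline input set."""
    pset = ParameterSet()
    validate_parameter_set(pset)
    return pset


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_parameter_set(pset: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(pset.to_dict(), fh, sort_keys=True)


def load_parameter_set(path) -> ParameterSet:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: not a parameter mapping")
    return ParameterSet.from_dict(data)


def apply_overrides(pset: ParameterSet, overrides: dict[str, Any]) -> ParameterSet:
    """Return a copy of *pset* with dotted-path overrides applied and revalidated."""
    out = pset.copy()
    for path, value in overrides.items():
        out.get_path(path)  # raises on unknown key before mutating
        out.set_path(path, value)
    validate_parameter_set(out)
    return out


# ---------------------------------------------------------------------------
# Distribution fitting (ranges read as central 95% intervals)
# ---------------------------------------------------------------------------

class BetaFit(NamedTuple):
    alpha: float
    beta: float


class GammaFit(NamedTuple):
    shape: float
    scale: float


class LognormalFit(NamedTuple):
    mu: float
    sigma: float
    mean_constrained: bool


def _check_range(mean: float, low: float, high: float) -> None:
    if not (low <= mean <= high):
        raise ParameterError(f"mean {mean} outside range [{low}, {high}]")


@lru_cache(maxsize=None)
def fit_beta_from_ci(mean: float, low: float, high: float) -> BetaFit | None:
    """Fit a beta distribution with the given mean whose 2.5/97.5% quantiles
    best match (low, high) in least squares. Returns ``None`` for a
    degenerate range (treated as fixed)."""
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean {mean} outside (0, 1)")
    _check_range(mean, low, high)
    if high - low <= 0:
        return None

    def objective(log_k: float) -> float:
        k = math.exp(log_k)
        a, b = mean * k, (1.0 - mean) * k
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return (q[0] - low) ** 2 + (q[1] - high) ** 2

    res = optimize.minimize_scalar(objective, bounds=(-3.0, 15.0), method="bounded")
    k = math.exp(res.x)
    return BetaFit(mean * k, (1.0 - mean) * k)


@lru_cache(maxsize=None)
def fit_gamma_from_ci(mean: float, low: float, high: float) -> GammaFit | None:
    """Fit a gamma distribution with the given mean; quantile match as for beta."""
    if mean <= 0 or low <= 0 or high <= 0:
        raise ParameterError("gamma fit requires positive mean, low, high")
    _check_range(mean, low, high)
    if high - low <= 0:
        return None

    def objective(log_shape: float) -> float:
        a = math.exp(log_shape)
        q = stats.gamma.ppf([0.025, 0.975], a, scale=mean / a)
        return (q[0] - low) ** 2 + (q[1] - high) ** 2

    res = optimize.minimize_scalar(objective, bounds=(-5.0, 15.0), method="bounded")
    a = math.exp(res.x)
    return GammaFit(a, mean / a)


@lru_cache(maxsize=None)
def fit_lognormal_from_ci(mean: float, low: float, high: float) -> LognormalFit | None:
    """Fit a log-normal distribution using the symmetric-CI rule for sigma.

    sigma = (ln high - ln low) / (2 * z_0.975); mu is then chosen so the
    distribution mean equals *mean*. If *mean* falls outside [low, high] the
    mean constraint is dropped, the log-scale midpoint is used as the median
    and ``mean_constrained`` is False.
    """
    if mean <= 0 or low <= 0 or high <= 0:
        raise ParameterError("lognormal fit requires positive mean, low, high")
    if high - low <= 0:
        if abs(mean - low) > 1e-12:
            raise ParameterError(f"mean {mean} outside range [{low}, {high}]")
        return None
    sigma = (math.log(high) - math.log(low)) / (2.0 * _Z95)
    if low <= mean <= high:
        mu = math.log(mean) - 0.5 * sigma * sigma
        return LognormalFit(mu, sigma, True)
    mu = 0.5 * (math.log(low) + math.log(high))
    return LognormalFit(mu, sigma, False)


def fitted_mean(fit) -> float:
    """Analytic mean of a fitted distribution (for validation)."""
    if isinstance(fit, BetaFit):
        return fit.alpha / (fit.alpha + fit.beta)
    if isinstance(fit, GammaFit):
        return fit.shape * fit.scale
    if isinstance(fit, LognormalFit):
        return math.exp(fit.mu + 0.5 * fit.sigma**2)
    raise TypeError(f"not a fit result: {fit!r}")


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def _fit_entry(entry: ParameterValue, mean: float):
    if entry.family == "fixed" or entry.low is None or entry.high is None:
        return None
    if entry.low >= entry.high:
        return None
    if entry.family == "beta":
        return fit_beta_from_ci(mean, entry.low, entry.high)
    if entry.family == "gamma":
        return fit_gamma_from_ci(mean, entry.low, entry.high)
    return fit_lognormal_from_ci(mean, entry.low, entry.high)


def sample_psa_draw(pset: ParameterSet, seed: int) -> ParameterSet:
    """Independently redraw every non-fixed registry parameter.

    The distribution of each parameter is fitted around the *current* value
    in *pset* with the registry's range and family, so that overridden sets
    sample around their override. Fixed parameters, splits and outcome trees
    are left untouched. Deterministic in *seed*.
    """
    rng = np.random.default_rng(seed)
    out = pset.copy()
    for entry in PSA_REGISTRY:
        mean = float(pset.get_path(entry.name))
        try:
            fit = _fit_entry(entry, mean)
        except ParameterError:
            fit = None  # current value incompatible with range: keep fixed
        if fit is None:
            rng.random()  # keep the stream aligned across parameterizations
            continue
        if isinstance(fit, BetaFit):
            value = rng.beta(fit.alpha, fit.beta)
        elif isinstance(fit, GammaFit):
            value = rng.gamma(fit.shape, fit.scale)
        else:
            value = rng.lognormal(fit.mu, fit.sigma)
        out.set_path(entry.name, float(value))
    validate_parameter_set(out)
    return out
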