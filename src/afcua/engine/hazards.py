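"""Daily transition probabilities by INR category, arm and treatment status.

Annual probabilities are converted to daily ones on the hazard scale
(constant hazard within a year), and relative risks are applied on the same
scale so probabilities can never leave [0, 1].

Relative-risk assignment: by default the elevated bleeding risk (4.7)
attaches to the above-range INR state and the elevated thromboembolic risk
(3.5) to the below-range state, which is the clinically coherent reading;
``flags.literal_rr_labels`` swaps both assignments to the printed ones.

The dabigatran arm is not INR-monitored. Its hazards are referenced to the
standard-dosing warfarin arm: each day a latent INR category is drawn from
the standard-arm occupancy probabilities and the subtype-specific relative
risk is applied to the corresponding warfarin hazard. Marginally this equals
the relative risk times the time-weighted average warfarin hazard, while
keeping event days identical across arms under unit relative risks when
streams are shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..parameters import ParameterSet

ARMS = ("sdw", "gtw", "dab150")
WARFARIN_ARMS = ("sdw", "gtw")
TE_SUBTYPES = ("stroke", "mi", "pe", "dvt")
INR_STATES = ("below", "in_range", "above")

DAYS_PER_YEAR = 365


def annual_prob_to_daily(p_annual: float) -> float:
    """Constant-hazard conversion: 1 - (1 - p)^(1/365)."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (1.0 / DAYS_PER_YEAR)


def rr_adjusted_daily_prob(p_annual: float, rr: float) -> float:
    """Daily probability after scaling the annual hazard by a relative risk.

    The degenerate case p_annual == 1 maps to 1 for any positive relative
    risk (infinite hazard), which keeps forced-event parameterizations
    usable in tests.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    if rr < 0:
        raise ValueError(f"relative risk {rr} is negative")
    if p_annual == 1.0:
        return 1.0 if rr > 0 else 0.0
    return 1.0 - math.exp(-rr * (-math.log(1.0 - p_annual)) / DAYS_PER_YEAR)


def inr_state_probs(arm: str, year_index: int, params: ParameterSet):
    """Occupancy probabilities (below, in-range, above) for a warfarin arm.

    Year 1 of the genotype-guided arm applies the TTR uplift (relative by
    default, additive with ``flags.additive_ttr_uplift``); from year 2 both
    warfarin arms share the standard-arm year-1 proportions (stable dose).
    """
    if arm not in WARFARIN_ARMS:
        raise ValueError(f"arm {arm!r} is not INR-monitored")
    if year_index < 1:
        raise ValueError("year_index must be >= 1")
    ttr = params.ttr_sdw
    if arm == "gtw" and year_index == 1:
        if params.flags.get("additive_ttr_uplift", False):
            ttr = params.ttr_sdw + params.gtw_ttr_uplift
        else:
            ttr = params.ttr_sdw * (1.0 + params.gtw_ttr_uplift)
        ttr = min(ttr, 1.0)
    out = 1.0 - ttr
    below = out * params.frac_below_of_out_of_range
    above = out - below
    return (below, ttr, above)


def _rr_by_state(params: ParameterSet):
    """(bleed_rr, te_rr) indexed by INR state (below, in, above)."""
    literal = params.flags.get("literal_rr_labels", False)
    rr_b = params.rr_bleed_out_of_range
    rr_t_hi, rr_t_lo = params.rr_te_subtherapeutic, params.rr_te_other_out_of_range
    if literal:
        bleed = (rr_b, 1.0, 1.0)
        te = (rr_t_lo, 1.0, rr_t_hi)
    else:
        bleed = (1.0, 1.0, rr_b)
        te = (rr_t_hi, 1.0, rr_t_lo)
    return bleed, te


@dataclass(frozen=True)
class ArmYearTable:
    """Per-(arm, year-block) daily hazards and state occupancy."""

    state_probs: np.ndarray        # (3,) occupancy of (below, in, above)
    p_bleed_by_state: np.ndarray   # (3,)
    p_te_by_state_sub: np.ndarray  # (3, 4) ordered as TE_SUBTYPES

    @property
    def p_te_total_by_state(self) -> np.ndarray:
        return self.p_te_by_state_sub.sum(axis=1)

    @property
    def mean_bleed(self) -> float:
        return float(self.state_probs @ self.p_bleed_by_state)

    @property
    def mean_te_sub(self) -> np.ndarray:
        return self.state_probs @ self.p_te_by_state_sub


@dataclass(frozen=True)
class ModelTables:
    """All derived hazard quantities for one parameter set."""

    by_arm_year: dict            # (arm, year_block) -> ArmYearTable, year_block 1|2
    off_te_sub: np.ndarray       # (4,) off-treatment daily TE probability
    te_split: np.ndarray         # (4,)
    p_ic: dict                   # arm -> P(intracranial | bleed)

    def table(self, arm: str, day: int) -> ArmYearTable:
        return self.by_arm_year[(arm, 1 if day < DAYS_PER_YEAR else 2)]


def build_tables(params: ParameterSet) -> ModelTables:
    bleed_rr, te_rr = _rr_by_state(params)
    split = np.array([params.te_split_warfarin[s] for s in TE_SUBTYPES])
    p_b = np.array(
        [rr_adjusted_daily_prob(params.p_bleed_annual_inrange, r) for r in bleed_rr]
    )
    p_t = np.array(
        [rr_adjusted_daily_prob(params.p_te_annual_inrange, r) for r in te_rr]
    )
    p_te_sub = p_t[:, None] * split[None, :]
    rr_dab = np.array([params.rr_te_dab[s] for s in TE_SUBTYPES])

    by_arm_year = {}
    for year in (1, 2):
        sdw_probs = np.array(inr_state_probs("sdw", year, params))
        gtw_probs = np.array(inr_state_probs("gtw", year, params))
        by_arm_year[("sdw", year)] = ArmYearTable(sdw_probs, p_b, p_te_sub)
        by_arm_year[("gtw", year)] = ArmYearTable(gtw_probs, p_b, p_te_sub)
        by_arm_year[("dab150", year)] = ArmYearTable(
            sdw_probs,
            params.rr_bleed_dab * p_b,
            rr_dab[None, :] * p_te_sub,
        )

    off_te_sub = rr_adjusted_daily_prob(
        params.p_te_annual_inrange, te_rr[0]
    ) * split

    raw = params.bleed_split_dab_raw
    total = raw["intracranial"] + raw["extracranial"]
    p_ic = {
        "sdw": params.bleed_split_warfarin["intracranial"],
        "gtw": params.bleed_split_warfarin["intracranial"],
        "dab150": raw["intracranial"] / total,
    }
    return ModelTables(by_arm_year, off_te_sub, split, p_ic)


def daily_hazards(
    inr_state: str,
    arm: str,
    treatment_status: str,
    params: ParameterSet,
    year_index: int = 1,
):
    """Daily bleed probability and per-subtype TE probabilities.

    ``inr_state`` is one of below/in_range/above for warfarin arms and
    ``not_monitored`` for dabigatran (where the time-weighted average over
    the latent standard-arm states is returned). ``treatment_status`` is
    on_treatment/off_temporary/off_permanent; off treatment the drug-related
    bleed hazard is zero and the TE hazard equals the warfarin
    subtherapeutic hazard.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    tables = build_tables(params)
    if treatment_status != "on_treatment":
        return 0.0, dict(zip(TE_SUBTYPES, tables.off_te_sub))
    tab = tables.by_arm_year[(arm, 1 if year_index == 1 else 2)]
    if arm == "dab150":
        if inr_state != "not_monitored":
            raise ValueError("dabigatran arm is not INR-monitored")
        return tab.mean_bleed, dict(zip(TE_SUBTYPES, tab.mean_te_sub))
    if inr_state not in INR_STATES:
        raise ValueError(f"invalid INR state {inr_state!r} for warfarin arm")
    s = INR_STATES.index(inr_state)
    return float(tab.p_bleed_by_state[s]), dict(
        zip(TE_SUBTYPES, tab.p_te_by_state_sub[s])
    )
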