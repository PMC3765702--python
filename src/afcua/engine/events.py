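"""Resolution of major events: subtype, outcome, fatality and sequelae.

Resolution consumes raw uniforms so it can be driven either by a scalar
random stream (one event) or vectorized over a batch of events; both paths
share the same code.

Conventions adopted where the source material gives only point values:

* All intracranial bleeds are resolved on the intracerebral outcome tree
  (no separate subdural branch is parameterized).
* Fatal events die on a uniformly drawn day within the stated window
  (first 30 days; days 31-90 for stroke deaths in months 2-3).
* Stroke outcome percentages overshoot 100%; total stroke death keeps its
  printed 19.5% and the survivor sequela probabilities are renormalized.
* Fatal intracranial bleeds and strokes are costed as severe events and
  carry the severe-state utility until death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..parameters import ParameterSet
from .hazards import TE_SUBTYPES, build_tables

DEATH_WINDOW_DAYS = 30

SEQ_NONE, SEQ_MILD, SEQ_SEVERE = 0, 1, 2
SEQ_NAMES = {SEQ_NONE: "none", SEQ_MILD: "mild", SEQ_SEVERE: "severe"}


@dataclass(frozen=True)
class EventRecord:
    day: int
    category: str               # "bleed" | "thromboembolic"
    subtype: str                # ich/subdural/extracranial_gi | stroke/mi/pe/dvt
    fatal: bool
    death_day: int | None
    sequela: str                # none | mild | severe | not_applicable


@dataclass(frozen=True)
class TreatmentStatus:
    """on_treatment, off_temporary(days_remaining) or off_permanent."""

    kind: str
    days_remaining: int = 0

    def __post_init__(self):
        if self.kind not in {"on_treatment", "off_temporary", "off_permanent"}:
            raise ValueError(f"invalid treatment status {self.kind!r}")
        if self.kind == "off_temporary" and self.days_remaining <= 0:
            raise ValueError("off_temporary requires days_remaining > 0")

    def tick(self) -> "TreatmentStatus":
        """Advance one day: temporary cessation counts down to resumption."""
        if self.kind != "off_temporary":
            return self
        if self.days_remaining <= 1:
            return TreatmentStatus("on_treatment")
        return TreatmentStatus("off_temporary", self.days_remaining - 1)


ON_TREATMENT = TreatmentStatus("on_treatment")
OFF_PERMANENT = TreatmentStatus("off_permanent")


def update_treatment_status(
    status: TreatmentStatus, event: EventRecord | None, params: ParameterSet
) -> TreatmentStatus:
    """Apply the discontinuation rules for a just-resolved event."""
    if status.kind == "off_permanent":
        return status
    if event is None or event.category != "bleed":
        return status
    if event.subtype in ("ich", "subdural"):
        return OFF_PERMANENT
    return TreatmentStatus("off_temporary", int(params.stop_after_gi_bleed_days))


# ---------------------------------------------------------------------------
# Outcome lookup tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeTables:
    """Per-outcome probabilities, one-time costs, and utilities."""

    # ICH: cumulative (none, mild, severe) thresholds; remainder is fatal
    ich_cum: np.ndarray
    p_death_ec: float
    # stroke
    p_stroke_death: float
    stroke_death_month_cum: np.ndarray   # cumulative over months 1..3 (abs probs)
    stroke_seq_cum: np.ndarray           # cumulative survivor (severe, mild) probs
    p_death_te: np.ndarray               # by TE subtype (stroke slot unused)
    # costs/utilities, indexed [none, mild, severe, fatal]
    ich_costs: np.ndarray
    ich_utils: np.ndarray
    stroke_costs: np.ndarray
    stroke_utils: np.ndarray
    ec_cost: float
    ec_util: float
    te_costs: np.ndarray                 # by subtype (stroke slot unused)
    te_utils: np.ndarray
    seq_utils_ich: np.ndarray            # [_, mild, severe]
    seq_utils_stroke: np.ndarray
    monthly_cost: np.ndarray             # [0, mild, severe]


def build_outcome_tables(params: ParameterSet) -> OutcomeTables:
    ich = params.ich_outcomes
    ich_cum = np.cumsum([ich["no_deficit"], ich["mild"], ich["severe"]])

    so = params.stroke_outcomes
    p_death = so["death_m1"] + so["death_m2"] + so["death_m3"]
    month_cum = np.cumsum([so["death_m1"], so["death_m2"], so["death_m3"]])
    surv = np.array([so["severe"], so["mild"], so["none"]])
    seq_cum = np.cumsum(surv / surv.sum())[:2]

    u = dict(params.utilities)
    if params.flags.get("literal_ich_utilities", False):
        u["ich_none"], u["ich_severe"] = u["ich_severe"], u["ich_none"]
    c = params.event_costs

    ich_costs = np.array([c["ich_none"], c["ich_mild"], c["ich_severe"], c["ich_severe"]])
    ich_utils = np.array([u["ich_none"], u["ich_mild"], u["ich_severe"], u["ich_severe"]])
    stroke_costs = np.array(
        [c["stroke_none"], c["stroke_mild"], c["stroke_severe"], c["stroke_severe"]]
    )
    stroke_utils = np.array(
        [u["stroke_none"], u["stroke_mild"], u["stroke_severe"], u["stroke_severe"]]
    )
    te_costs = np.array([0.0, c["mi"], c["pe"], c["dvt"]])
    te_utils = np.array([0.0, u["mi"], u["pe"], u["dvt"]])
    # order matches TE_SUBTYPES = (stroke, mi, pe, dvt)
    p_death_te = np.array(
        [p_death, params.p_death_mi, params.p_death_pe, params.p_death_dvt]
    )
    return OutcomeTables(
        ich_cum=ich_cum,
        p_death_ec=params.p_death_extracranial,
        p_stroke_death=p_death,
        stroke_death_month_cum=month_cum,
        stroke_seq_cum=seq_cum,
        p_death_te=p_death_te,
        ich_costs=ich_costs,
        ich_utils=ich_utils,
        stroke_costs=stroke_costs,
        stroke_utils=stroke_utils,
        ec_cost=c["extracranial_bleed"],
        ec_util=u["extracranial"],
        te_costs=te_costs,
        te_utils=te_utils,
        seq_utils_ich=np.array([1.0, u["ich_mild"], u["ich_severe"]]),
        seq_utils_stroke=np.array([1.0, u["stroke_mild"], u["stroke_severe"]]),
        monthly_cost=np.array(
            [0.0, params.post_event_monthly["mild"], params.post_event_monthly["severe"]]
        ),
    )


@dataclass
class ResolvedBatch:
    """Vectorized event-resolution result (parallel arrays)."""

    subtype_idx: np.ndarray   # bleeds: 0 ich, 1 extracranial; TE: TE_SUBTYPES index
    fatal: np.ndarray
    death_day: np.ndarray     # -1 when non-fatal
    seq_level: np.ndarray     # 0/1/2
    event_cost: np.ndarray
    trans_util: np.ndarray    # utility carried for the 30-day event window
    seq_util: np.ndarray      # permanent utility once the sequela activates


def resolve_bleed_batch(
    arm: str, u: np.ndarray, params: ParameterSet, days: np.ndarray | int = 0
) -> ResolvedBatch:
    """Resolve bleeds from uniforms ``u`` of shape (k, 3).

    Column 0 selects intracranial vs extracranial, column 1 the outcome,
    column 2 the death day within the 30-day window for fatal bleeds.
    """
    u = np.atleast_2d(u)
    days = np.broadcast_to(np.asarray(days), u.shape[:1])
    tables = build_tables(params)
    out = build_outcome_tables(params)
    k = u.shape[0]
    ic = u[:, 0] < tables.p_ic[arm]

    outcome = np.searchsorted(out.ich_cum, u[:, 1], side="right")  # 0..3
    fatal = np.where(ic, outcome == 3, u[:, 1] < out.p_death_ec)
    seq_level = np.where(ic & (outcome == 1), SEQ_MILD, SEQ_NONE)
    seq_level = np.where(ic & (outcome == 2), SEQ_SEVERE, seq_level)

    death_day = np.where(
        fatal, days + 1 + (u[:, 2] * DEATH_WINDOW_DAYS).astype(np.int64), -1
    )
    event_cost = np.where(ic, out.ich_costs[outcome], out.ec_cost)
    trans_util = np.where(ic, out.ich_utils[outcome], out.ec_util)
    seq_util = out.seq_utils_ich[seq_level]
    return ResolvedBatch(
        subtype_idx=(~ic).astype(np.int8),
        fatal=fatal,
        death_day=death_day,
        seq_level=seq_level.astype(np.int8),
        event_cost=event_cost.astype(float),
        trans_util=trans_util.astype(float),
        seq_util=seq_util.astype(float),
    )


def resolve_te_batch(
    subtype_idx: np.ndarray,
    u: np.ndarray,
    params: ParameterSet,
    days: np.ndarray | int = 0,
) -> ResolvedBatch:
    """Resolve thromboembolic events of known subtype from uniforms (k, 3).

    Column 1 decides fatality (and the death month for strokes); column 2
    is the death day within its window, or the survivor sequela for strokes.
    """
    u = np.atleast_2d(u)
    subtype_idx = np.atleast_1d(np.asarray(subtype_idx))
    if subtype_idx.min() < 0 or subtype_idx.max() >= len(TE_SUBTYPES):
        raise ValueError("unknown thromboembolic subtype index")
    days = np.broadcast_to(np.asarray(days), u.shape[:1])
    out = build_outcome_tables(params)

    is_stroke = subtype_idx == 0
    fatal = u[:, 1] < out.p_death_te[subtype_idx]

    # stroke deaths: month from the cumulative month partition
    month = np.searchsorted(out.stroke_death_month_cum, u[:, 1], side="right")
    month = np.clip(month, 0, 2)
    window_start = np.where(is_stroke, month * DEATH_WINDOW_DAYS, 0)
    death_day = np.where(
        fatal,
        days + 1 + window_start + (u[:, 2] * DEATH_WINDOW_DAYS).astype(np.int64),
        -1,
    )

    # stroke survivors: sequela from the renormalized (severe, mild, none)
    seq_draw = np.searchsorted(out.stroke_seq_cum, u[:, 2], side="right")
    seq_level = np.where(
        is_stroke & ~fatal,
        np.choose(np.clip(seq_draw, 0, 2), [SEQ_SEVERE, SEQ_MILD, SEQ_NONE]),
        SEQ_NONE,
    ).astype(np.int8)

    stroke_outcome = np.where(fatal, 3, np.choose(
        seq_level, [SEQ_NONE, SEQ_MILD, SEQ_SEVERE]
    ))
    event_cost = np.where(
        is_stroke, out.stroke_costs[stroke_outcome], out.te_costs[subtype_idx]
    )
    trans_util = np.where(
        is_stroke, out.stroke_utils[stroke_outcome], out.te_utils[subtype_idx]
    )
    seq_util = out.seq_utils_stroke[seq_level]
    return ResolvedBatch(
        subtype_idx=subtype_idx,
        fatal=fatal,
        death_day=death_day,
        seq_level=seq_level,
        event_cost=event_cost.astype(float),
        trans_util=trans_util.astype(float),
        seq_util=seq_util.astype(float),
    )


def _record_from_batch(
    batch: ResolvedBatch, day: int, category: str, subtype: str
) -> EventRecord:
    fatal = bool(batch.fatal[0])
    seq = SEQ_NAMES[int(batch.seq_level[0])]
    if subtype not in ("ich", "stroke"):
        seq = "none" if not fatal else "not_applicable"
    return EventRecord(
        day=day,
        category=category,
        subtype=subtype,
        fatal=fatal,
        death_day=int(batch.death_day[0]) if fatal else None,
        sequela=seq,
    )


def resolve_bleed(
    arm: str, stream: np.random.Generator, params: ParameterSet, day: int = 0
) -> EventRecord:
    """Resolve a single bleed using three uniforms from *stream*."""
    batch = resolve_bleed_batch(arm, stream.random((1, 3)), params, day)
    subtype = "ich" if batch.subtype_idx[0] == 0 else "extracranial_gi"
    return _record_from_batch(batch, day, "bleed", subtype)


def resolve_te(
    subtype: str, stream: np.random.Generator, params: ParameterSet, day: int = 0
) -> EventRecord:
    """Resolve a single thromboembolic event of the given subtype."""
    if subtype not in TE_SUBTYPES:
        raise ValueError(f"unknown thromboembolic subtype {subtype!r}")
    idx = TE_SUBTYPES.index(subtype)
    batch = resolve_te_batch(np.array([idx]), stream.random((1, 3)), params, day)
    return _record_from_batch(batch, day, "thromboembolic", subtype)
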