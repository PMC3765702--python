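"""Daily-cycle cohort simulation with cost and QALY accrual.

The whole cohort is advanced one day at a time with numpy operations; the
event-occurrence uniforms come from :class:`~afcua.cohort.SharedStreams`
so the three arms can share randomness (common random numbers).

Accrual conventions:

* A new event's state utility applies from its event day for 30 days (or
  until death for fatal events); mild/severe sequelae apply their utility
  and monthly follow-up cost permanently from 30 days after the event. An
  individual carries the minimum utility among active states.
* Treatment cessation takes effect the day after the bleed; drug and INR
  monitoring costs stop while off treatment.
* Day 0 charges the one-time items: genotyping (genotype-guided arm) and
  the bridging LMWH course (warfarin arms).
* Both costs and QALY increments are discounted by (1+r)^(-day/365).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..cohort import Cohort, SharedStreams
from ..parameters import ParameterSet
from .hazards import ARMS, TE_SUBTYPES, WARFARIN_ARMS, build_tables, DAYS_PER_YEAR
from .events import (
    EventRecord,
    SEQ_NAMES,
    build_outcome_tables,
    resolve_bleed_batch,
    resolve_te_batch,
)

BIG_DAY = np.iinfo(np.int64).max // 4

BLEED_SUBTYPE_NAMES = ("ich", "extracranial_gi")


@dataclass
class Trajectory:
    individual_id: int
    events: list[EventRecord]
    person_days: int
    discounted_cost: float
    discounted_qalys: float
    alive_at_end: bool


@dataclass
class ArmSummary:
    arm: str
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    bleeds_per_100py: float
    te_per_100py: float
    n_individuals: int
    n_replicates: int


@dataclass
class ReplicateResult:
    """Raw per-individual results for one (cohort, arm) simulation."""

    arm: str
    replicate_id: int
    cost: np.ndarray
    qaly: np.ndarray
    person_days: np.ndarray
    n_bleeds: np.ndarray
    n_te: np.ndarray
    alive_at_end: np.ndarray
    events: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.cost)

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())


def events_per_100py(total_events: float, total_person_days: float) -> float:
    """Events per 100 person-years."""
    if total_person_days <= 0:
        raise ValueError("person-time must be positive")
    return total_events / (total_person_days / DAYS_PER_YEAR) * 100.0


def _daily_base_cost(arm: str, year_block: int, params: ParameterSet) -> float:
    """Drug plus INR-monitoring cost for a day on treatment."""
    if arm == "dab150":
        return params.cost_dab_daily
    if year_block == 1:
        monthly = (
            params.cost_inr_month_sdw_y1 if arm == "sdw" else params.cost_inr_month_gtw_y1
        )
    else:
        monthly = params.cost_inr_month_later
    return params.cost_warfarin_daily + monthly / 30.0


def _day0_cost(arm: str, params: ParameterSet) -> float:
    if arm == "dab150":
        return 0.0
    extra = params.cost_lmwh_course
    if arm == "gtw":
        extra += params.cost_genotyping
    return extra


def accrue_day(
    day: int,
    arm: str,
    utility: float,
    on_treatment: bool,
    sequela_level: int,
    year_index: int,
    params: ParameterSet,
    event_cost: float = 0.0,
):
    """Single-day accrual: (cost, utility, discounted cost, discounted QALY).

    ``utility`` is the current health-state utility, ``sequela_level``
    0/1/2 adds the monthly follow-up cost when active.
    """
    cost = event_cost
    if on_treatment:
        cost += _daily_base_cost(arm, 1 if year_index == 1 else 2, params)
    if day == 0:
        cost += _day0_cost(arm, params)
    if sequela_level:
        key = "mild" if sequela_level == 1 else "severe"
        cost += params.post_event_monthly[key] / 30.0
    disc = (1.0 + params.discount_annual) ** (-day / DAYS_PER_YEAR)
    return cost, utility, cost * disc, utility / DAYS_PER_YEAR * disc


def simulate_cohort(
    n: int,
    arm: str,
    params: ParameterSet,
    streams: SharedStreams,
    collect_events: bool = False,
) -> ReplicateResult:
    """Simulate *n* individuals through the daily-cycle model for one arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    horizon = int(params.horizon_days)
    if streams.horizon_days < horizon or streams.n < n:
        raise ValueError("streams smaller than requested simulation")

    tables = build_tables(params)
    out_tables = build_outcome_tables(params)
    u_no_event = params.utilities[
        "no_event_dab" if arm == "dab150" else "no_event_warfarin"
    ]
    discount = (1.0 + params.discount_annual) ** (
        -np.arange(horizon, dtype=float) / DAYS_PER_YEAR
    )

    u_inr = streams.u_inr(arm)
    u_bleed = streams.u_bleed(arm)
    u_te = streams.u_te(arm)

    alive = np.ones(n, dtype=bool)
    dying = np.zeros(n, dtype=bool)
    death_day = np.full(n, -1, dtype=np.int64)
    perm_off = np.zeros(n, dtype=bool)
    off_days = np.zeros(n, dtype=np.int64)
    trans_util = np.ones(n)
    trans_end = np.zeros(n, dtype=np.int64)
    seq_level = np.zeros(n, dtype=np.int8)
    seq_start = np.full(n, BIG_DAY, dtype=np.int64)
    seq_util = np.ones(n)

    cost = np.zeros(n)
    qaly = np.zeros(n)
    person_days = np.zeros(n, dtype=np.int64)
    n_bleeds = np.zeros(n, dtype=np.int64)
    n_te = np.zeros(n, dtype=np.int64)
    event_log: list[dict] = []

    off_te_total = float(tables.off_te_sub.sum())
    off_te_cum = np.cumsum(tables.off_te_sub)

    for day in range(horizon):
        alive &= ~(dying & (death_day == day))
        if not alive.any():
            break
        year_block = 1 if day < DAYS_PER_YEAR else 2
        tab = tables.table(arm, day)
        cuts = np.cumsum(tab.state_probs)[:2]

        state = (u_inr[:n, day, None] >= cuts).sum(axis=1)
        on_tx = alive & ~perm_off & (off_days == 0)
        can_event = alive & ~dying

        p_b = np.where(on_tx, tab.p_bleed_by_state[state], 0.0)
        p_t = np.where(on_tx, tab.p_te_total_by_state[state], off_te_total)
        bleed = can_event & (u_bleed[:n, day] < p_b)
        te = can_event & ~bleed & (u_te[:n, day] < p_t)

        ev_cost_today = None
        pend_perm: np.ndarray | None = None
        pend_gi: np.ndarray | None = None
        if bleed.any() or te.any():
            ev_cost_today = np.zeros(n)
            b_idx = np.flatnonzero(bleed)
            t_idx = np.flatnonzero(te)
            rng = streams.resolve_rng(arm, day)
            u_res = rng.random((len(b_idx) + len(t_idx), 4))

            if len(b_idx):
                rb = resolve_bleed_batch(arm, u_res[: len(b_idx), :3], params, day)
                _apply_outcomes(
                    b_idx, rb, day, params, trans_util, trans_end, seq_level,
                    seq_start, seq_util, dying, death_day, ev_cost_today,
                )
                n_bleeds[b_idx] += 1
                pend_perm = b_idx[rb.subtype_idx == 0]
                pend_gi = b_idx[rb.subtype_idx == 1]
                if collect_events:
                    _log_events(event_log, arm, "bleed", b_idx, rb, day)

            if len(t_idx):
                ut = u_res[len(b_idx):, :]
                # subtype from the state-specific subtype mix
                sub_p = np.where(
                    on_tx[t_idx, None],
                    tab.p_te_by_state_sub[state[t_idx]],
                    tables.off_te_sub[None, :],
                )
                sub_cum = np.cumsum(sub_p, axis=1)
                sub_cum /= sub_cum[:, -1:]
                sub = (ut[:, 0:1] >= sub_cum[:, :3]).sum(axis=1)
                rt = resolve_te_batch(sub, ut[:, 1:4], params, day)
                _apply_outcomes(
                    t_idx, rt, day, params, trans_util, trans_end, seq_level,
                    seq_start, seq_util, dying, death_day, ev_cost_today,
                )
                n_te[t_idx] += 1
                if collect_events:
                    _log_events(event_log, arm, "thromboembolic", t_idx, rt, day)

        # ---- accrual (treatment costs use the pre-event cessation state) ----
        base = np.where(on_tx, _daily_base_cost(arm, year_block, params), 0.0)
        if day == 0:
            base = base + _day0_cost(arm, params)
        seq_active = (seq_level > 0) & (day >= seq_start)
        base = base + np.where(
            seq_active, out_tables.monthly_cost[seq_level] / 30.0, 0.0
        )
        if ev_cost_today is not None:
            base = base + ev_cost_today
        util = np.full(n, u_no_event)
        trans_active = day < trans_end
        util = np.where(trans_active, np.minimum(util, trans_util), util)
        util = np.where(seq_active, np.minimum(util, seq_util), util)

        disc = discount[day]
        cost += np.where(alive, base * disc, 0.0)
        qaly += np.where(alive, util / DAYS_PER_YEAR * disc, 0.0)
        person_days += alive

        # end of day: count down existing cessations, then apply today's,
        # so a 30-day cessation is off for exactly the next 30 days
        np.subtract(off_days, 1, out=off_days, where=off_days > 0)
        if pend_perm is not None and len(pend_perm):
            perm_off[pend_perm] = True
        if pend_gi is not None and len(pend_gi):
            off_days[pend_gi] = int(params.stop_after_gi_bleed_days)

    alive_at_end = ~dying | (death_day >= horizon)
    events = None
    if collect_events:
        events = pd.DataFrame(
            event_log,
            columns=["individual", "arm", "day", "category", "subtype",
                     "fatal", "death_day", "sequela"],
        )
    return ReplicateResult(
        arm=arm,
        replicate_id=streams.replicate_id,
        cost=cost,
        qaly=qaly,
        person_days=person_days,
        n_bleeds=n_bleeds,
        n_te=n_te,
        alive_at_end=alive_at_end,
        events=events,
    )


def _apply_outcomes(
    idx, res, day, params, trans_util, trans_end, seq_level, seq_start,
    seq_util, dying, death_day, ev_cost_today,
) -> None:
    ev_cost_today[idx] += res.event_cost
    # event-window utility: min with any still-active window
    active = trans_end[idx] > day
    trans_util[idx] = np.where(
        active, np.minimum(trans_util[idx], res.trans_util), res.trans_util
    )
    end = np.where(res.fatal, res.death_day + 1, day + 30)
    trans_end[idx] = np.maximum(trans_end[idx], end)
    # sequelae (survivors only)
    has_seq = res.seq_level > 0
    if has_seq.any():
        j = idx[has_seq]
        seq_level[j] = np.maximum(seq_level[j], res.seq_level[has_seq])
        seq_start[j] = np.minimum(seq_start[j], day + 30)
        seq_util[j] = np.minimum(seq_util[j], res.seq_util[has_seq])
    # deaths
    if res.fatal.any():
        j = idx[res.fatal]
        dying[j] = True
        death_day[j] = res.death_day[res.fatal]


def _log_events(log, arm, category, idx, res, day) -> None:
    for i, row in enumerate(idx):
        if category == "bleed":
            subtype = BLEED_SUBTYPE_NAMES[int(res.subtype_idx[i])]
        else:
            subtype = TE_SUBTYPES[int(res.subtype_idx[i])]
        fatal = bool(res.fatal[i])
        seq = SEQ_NAMES[int(res.seq_level[i])]
        if subtype not in ("ich", "stroke"):
            seq = "none" if not fatal else "not_applicable"
        log.append(
            {
                "individual": int(row),
                "arm": arm,
                "day": int(day),
                "category": category,
                "subtype": subtype,
                "fatal": fatal,
                "death_day": int(res.death_day[i]) if fatal else None,
                "sequela": seq,
            }
        )


def simulate_individual(
    individual, arm: str, params: ParameterSet, streams: SharedStreams,
) -> Trajectory:
    """Simulate a single individual; ``streams`` must be sized for n>=1."""
    res = simulate_cohort(1, arm, params, streams, collect_events=True)
    events = [
        EventRecord(
            day=int(r.day),
            category=r.category,
            subtype=r.subtype,
            fatal=bool(r.fatal),
            death_day=None if r.death_day is None or pd.isna(r.death_day)
            else int(r.death_day),
            sequela=r.sequela,
        )
        for r in res.events.itertuples()
    ]
    ind_id = individual.id if hasattr(individual, "id") else int(individual)
    return Trajectory(
        individual_id=ind_id,
        events=events,
        person_days=int(res.person_days[0]),
        discounted_cost=float(res.cost[0]),
        discounted_qalys=float(res.qaly[0]),
        alive_at_end=bool(res.alive_at_end[0]),
    )


def run_arm(
    cohort: Cohort,
    arm: str,
    params: ParameterSet,
    master_seed: int | None = None,
    crn: bool = True,
    collect_events: bool = False,
) -> ReplicateResult:
    """Simulate every individual of *cohort* under one arm."""
    seed = cohort.master_seed if master_seed is None else master_seed
    streams = SharedStreams(
        seed, cohort.replicate_id, cohort.n, int(params.horizon_days), crn=crn
    )
    return simulate_cohort(cohort.n, arm, params, streams, collect_events)


def run_study(
    params: ParameterSet,
    arms: tuple[str, ...] = ARMS,
    n_individuals: int | None = None,
    n_replicates: int | None = None,
    master_seed: int = 0,
    crn: bool = True,
    progress=None,
):
    """Run all arms on shared cohorts/streams over several replicates.

    Returns ``(summaries, replicate_table)`` where *summaries* maps arm to
    :class:`ArmSummary` and *replicate_table* holds per-replicate means.
    """
    n = int(params.cohort_size if n_individuals is None else n_individuals)
    reps = int(params.n_replicates if n_replicates is None else n_replicates)
    horizon = int(params.horizon_days)
    rows = []
    totals = {
        arm: {"cost": [], "qaly": [], "bleeds": 0.0, "te": 0.0, "pd": 0.0}
        for arm in arms
    }
    ind_se: dict[str, tuple[float, float]] = {}
    for rep in range(reps):
        streams = SharedStreams(master_seed, rep, n, horizon, crn=crn)
        for arm in arms:
            res = simulate_cohort(n, arm, params, streams)
            if reps == 1 and n > 1:
                ind_se[arm] = (
                    float(res.cost.std(ddof=1) / np.sqrt(n)),
                    float(res.qaly.std(ddof=1) / np.sqrt(n)),
                )
            totals[arm]["cost"].append(res.mean_cost)
            totals[arm]["qaly"].append(res.mean_qaly)
            totals[arm]["bleeds"] += float(res.n_bleeds.sum())
            totals[arm]["te"] += float(res.n_te.sum())
            totals[arm]["pd"] += float(res.person_days.sum())
            rows.append(
                {
                    "replicate": rep,
                    "arm": arm,
                    "mean_cost": res.mean_cost,
                    "mean_qaly": res.mean_qaly,
                    "bleeds": int(res.n_bleeds.sum()),
                    "te": int(res.n_te.sum()),
                    "person_days": int(res.person_days.sum()),
                }
            )
        if progress is not None:
            progress(rep)
    summaries = {}
    for arm in arms:
        costs = np.array(totals[arm]["cost"])
        qalys = np.array(totals[arm]["qaly"])
        if reps > 1:
            se_c = float(costs.std(ddof=1) / np.sqrt(reps))
            se_q = float(qalys.std(ddof=1) / np.sqrt(reps))
        else:
            se_c, se_q = ind_se.get(arm, (0.0, 0.0))
        summaries[arm] = ArmSummary(
            arm=arm,
            mean_cost=float(costs.mean()),
            mean_qaly=float(qalys.mean()),
            se_cost=se_c,
            se_qaly=se_q,
            bleeds_per_100py=events_per_100py(totals[arm]["bleeds"], totals[arm]["pd"]),
            te_per_100py=events_per_100py(totals[arm]["te"], totals[arm]["pd"]),
            n_individuals=n,
            n_replicates=reps,
        )
    return summaries, pd.DataFrame(rows)
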