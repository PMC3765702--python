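"""Economic endpoints: cost/utility ratios, incremental analysis with strict
and extended dominance, net monetary benefit and acceptability curves.

Reported ratios are rounded half-away-from-zero to the nearest dollar,
matching the granularity of published cost-utility tables; full precision
is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrontierRow",
    "CEACPoint",
    "round_dollar",
    "raw_cu_ratio",
    "icur",
    "nmb",
    "dominance_frontier",
    "build_ceac",
]

ON_FRONTIER = "on_frontier"
STRICTLY_DOMINATED = "strictly_dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass
class FrontierRow:
    arm: str
    mean_cost: float
    mean_qaly: float
    status: str
    comparator: str | None = None
    delta_cost: float | None = None
    delta_qaly: float | None = None
    icur: float | None = None


@dataclass(frozen=True)
class CEACPoint:
    threshold: float
    probability_ce: float


def round_dollar(x: float) -> int:
    """Round half away from zero to the nearest dollar."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def raw_cu_ratio(mean_cost: float, mean_qaly: float) -> int:
    """Cost per QALY, rounded to the nearest dollar."""
    if mean_qaly <= 0:
        raise ValueError("mean QALY must be positive for a cost/utility ratio")
    return round_dollar(mean_cost / mean_qaly)


def icur(ref_cost: float, ref_qaly: float, alt_cost: float, alt_qaly: float,
         rounded: bool = True) -> float | None:
    """Incremental cost-utility ratio of alternative vs reference.

    Returns ``None`` (undefined) when the QALYs are equal.
    """
    dq = alt_qaly - ref_qaly
    if dq == 0:
        return None
    value = (alt_cost - ref_cost) / dq
    return round_dollar(value) if rounded else value


def nmb(cost: float, qaly: float, threshold: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * qaly - cost


def dominance_frontier(arm_summaries: Iterable) -> list[FrontierRow]:
    """Incremental analysis over arm summaries (any objects with ``arm``,
    ``mean_cost`` and ``mean_qaly`` attributes, or (arm, cost, qaly) tuples).

    Strictly dominated arms cost at least as much and deliver at most as
    many QALYs as some other arm (with one inequality strict); extended
    dominated arms have a higher incremental ratio than the next more
    effective frontier option. Exactly tied arms share the frontier.
    """
    entries = []
    for s in arm_summaries:
        if hasattr(s, "mean_cost"):
            entries.append((s.arm, float(s.mean_cost), float(s.mean_qaly)))
        else:
            arm, cost, qaly = s
            entries.append((arm, float(cost), float(qaly)))
    if len(entries) < 2:
        return [
            FrontierRow(a, c, q, ON_FRONTIER) for a, c, q in entries
        ]

    rows = {a: FrontierRow(a, c, q, ON_FRONTIER) for a, c, q in entries}
    # strict dominance
    for a, c, q in entries:
        for a2, c2, q2 in entries:
            if a2 == a:
                continue
            if c2 <= c and q2 >= q and (c2 < c or q2 > q):
                rows[a].status = STRICTLY_DOMINATED
                break

    candidates = sorted(
        (e for e in entries if rows[e[0]].status == ON_FRONTIER),
        key=lambda e: (e[1], e[2]),
    )
    # extended dominance: remove middle options with a higher incremental
    # ratio than the next one until ratios increase along the frontier
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            a_prev, a_mid, a_next = candidates[i - 1], candidates[i], candidates[i + 1]
            r_mid = _ratio(a_prev, a_mid)
            r_next = _ratio(a_mid, a_next)
            if r_mid is not None and r_next is not None and r_mid > r_next:
                rows[a_mid[0]].status = EXTENDED_DOMINATED
                del candidates[i]
                changed = True
                break

    for i, (a, c, q) in enumerate(candidates):
        if i == 0:
            continue
        ref_arm, ref_c, ref_q = candidates[i - 1]
        row = rows[a]
        row.comparator = ref_arm
        row.delta_cost = c - ref_c
        row.delta_qaly = q - ref_q
        row.icur = icur(ref_c, ref_q, c, q)

    order = {a: i for i, (a, _, _) in enumerate(
        sorted(entries, key=lambda e: (e[1], e[2]))
    )}
    return sorted(rows.values(), key=lambda r: order[r.arm])


def _ratio(ref, alt) -> float | None:
    return icur(ref[1], ref[2], alt[1], alt[2], rounded=False)


def build_ceac(
    psa_draws,
    reference_arm: str,
    comparator_arm: str,
    thresholds: Sequence[float],
) -> tuple[list[CEACPoint], float]:
    """Pairwise acceptability curve of *comparator_arm* vs *reference_arm*.

    ``psa_draws`` is an iterable of per-iteration records with
    ``(iteration, arm, mean_cost, mean_qaly)`` fields (e.g. the data frame
    produced by :func:`afcua.sensitivity.run_psa` or a list of dicts).
    Returns the curve and the fraction of draws in which the comparator
    strictly dominates (cheaper and more effective).
    """
    thresholds = list(thresholds)
    if any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    d_cost, d_qaly = _paired_deltas(psa_draws, reference_arm, comparator_arm)
    if len(d_cost) == 0:
        raise ValueError("no PSA draws provided")
    points = [
        CEACPoint(
            float(lam),
            float(np.mean(lam * d_qaly - d_cost >= 0.0)),
        )
        for lam in thresholds
    ]
    p_dominant = float(np.mean((d_cost < 0) & (d_qaly > 0)))
    return points, p_dominant


def _paired_deltas(psa_draws, reference_arm: str, comparator_arm: str):
    ref: dict[int, tuple[float, float]] = {}
    comp: dict[int, tuple[float, float]] = {}
    if hasattr(psa_draws, "itertuples"):
        records = psa_draws.itertuples()
    else:
        records = psa_draws

    def unpack(r):
        if hasattr(r, "arm"):
            return int(r.iteration), r.arm, float(r.mean_cost), float(r.mean_qaly)
        return int(r["iteration"]), r["arm"], float(r["mean_cost"]), float(r["mean_qaly"])

    for r in records:
        it, arm, cost, qaly = unpack(r)
        if arm == reference_arm:
            ref[it] = (cost, qaly)
        elif arm == comparator_arm:
            comp[it] = (cost, qaly)
    common = sorted(set(ref) & set(comp))
    d_cost = np.array([comp[i][0] - ref[i][0] for i in common])
    d_qaly = np.array([comp[i][1] - ref[i][1] for i in common])
    return d_cost, d_qaly
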