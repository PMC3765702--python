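"""Virtual population generation and random-substream management.

Random numbers are organised so that the same cohort and the same
"does an event happen today" uniforms can be reused across treatment arms
(common random numbers), while arm-specific decisions (event resolution)
use streams salted with the arm tag. All streams are counter-based
(Philox keyed by a SeedSequence over integer tuples), so regeneration is
independent of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Cohort",
    "generate_cohort",
    "substream",
    "stream_descriptor",
    "stream_from_descriptor",
    "SharedStreams",
    "IndividualStreams",
]

AGE_BOUNDS = (18.0, 100.0)

# purpose codes used to separate streams
PURPOSE_COHORT = 0
PURPOSE_INR = 1
PURPOSE_BLEED = 2
PURPOSE_TE = 3
PURPOSE_RESOLVE = 4

ARM_CODES = {"shared": 0, "sdw": 1, "gtw": 2, "dab150": 3}


@dataclass(frozen=True)
class Individual:
    id: int
    age_years: float


@dataclass(frozen=True)
class Cohort:
    replicate_id: int
    individuals: tuple[Individual, ...]
    master_seed: int

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def ages(self) -> np.ndarray:
        return np.array([ind.age_years for ind in self.individuals])


def _seed_seq(*key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(tuple(int(k) for k in key))


def _rng(*key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(_seed_seq(*key)))


def generate_cohort(
    n: int,
    replicate_id: int,
    master_seed: int,
    age_mean: float = 64.0,
    age_sd: float = 8.0,
) -> Cohort:
    """Draw *n* individuals with Normal(age_mean, age_sd) ages truncated to
    [18, 100]. Bit-identical for identical inputs."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = _rng(master_seed, replicate_id, PURPOSE_COHORT)
    ages = rng.normal(age_mean, age_sd, size=n)
    lo, hi = AGE_BOUNDS
    # redraw out-of-bounds ages (truncated normal by rejection)
    bad = (ages < lo) | (ages > hi)
    while bad.any():
        ages[bad] = rng.normal(age_mean, age_sd, size=int(bad.sum()))
        bad = (ages < lo) | (ages > hi)
    individuals = tuple(Individual(i, float(a)) for i, a in enumerate(ages))
    return Cohort(replicate_id, individuals, master_seed)


def cohort_to_csv(cohort: Cohort, path) -> None:
    pd.DataFrame(
        {"id": [i.id for i in cohort.individuals],
         "age_years": [i.age_years for i in cohort.individuals]}
    ).to_csv(path, index=False)


def cohort_from_csv(path, replicate_id: int = 0, master_seed: int = 0) -> Cohort:
    df = pd.read_csv(path)
    individuals = tuple(
        Individual(int(r.id), float(r.age_years)) for r in df.itertuples()
    )
    return Cohort(replicate_id, individuals, master_seed)


# ---------------------------------------------------------------------------
# Substreams
# ---------------------------------------------------------------------------

def substream(
    master_seed: int,
    replicate_id: int,
    individual_id: int,
    arm_tag: str | None = None,
    purpose: int = PURPOSE_RESOLVE,
) -> np.random.Generator:
    """Counter-based random stream for one (replicate, individual) pair.

    ``arm_tag=None`` yields the arm-shared stream; passing an arm salts the
    key so arm-specific decisions decouple from the shared event uniforms.
    """
    arm_code = ARM_CODES["shared"] if arm_tag is None else ARM_CODES[arm_tag]
    return _rng(master_seed, replicate_id, individual_id, arm_code, purpose)


def stream_descriptor(
    master_seed: int,
    replicate_id: int,
    individual_id: int,
    arm_tag: str | None = None,
    purpose: int = PURPOSE_RESOLVE,
) -> str:
    """JSON descriptor from which the identical stream can be rebuilt."""
    return json.dumps(
        {
            "master_seed": int(master_seed),
            "replicate_id": int(replicate_id),
            "individual_id": int(individual_id),
            "arm_tag": arm_tag,
            "purpose": int(purpose),
        }
    )


def stream_from_descriptor(descriptor: str) -> np.random.Generator:
    d = json.loads(descriptor)
    return substream(
        d["master_seed"], d["replicate_id"], d["individual_id"],
        d["arm_tag"], d["purpose"],
    )


# ---------------------------------------------------------------------------
# Per-replicate uniform matrices consumed by the simulation engine
# ---------------------------------------------------------------------------

class SharedStreams:
    """Event-occurrence uniforms for one replicate, shared across arms.

    Three (n, horizon) matrices: the daily INR-category draw, the bleeding
    occurrence draw and the thromboembolism occurrence draw. A resolver
    factory provides arm-salted generators for event resolution.

    ``crn=False`` salts the occurrence matrices with the arm as well,
    giving fully independent arms (used to quantify the variance reduction
    of common random numbers).
    """

    def __init__(
        self,
        master_seed: int,
        replicate_id: int,
        n: int,
        horizon_days: int,
        crn: bool = True,
    ) -> None:
        self.master_seed = int(master_seed)
        self.replicate_id = int(replicate_id)
        self.n = int(n)
        self.horizon_days = int(horizon_days)
        self.crn = bool(crn)
        self._matrices: dict[tuple[int, int], np.ndarray] = {}

    def _matrix(self, purpose: int, arm_tag: str) -> np.ndarray:
        arm_code = ARM_CODES["shared"] if self.crn else ARM_CODES[arm_tag]
        key = (purpose, arm_code)
        if key not in self._matrices:
            rng = _rng(self.master_seed, self.replicate_id, arm_code, purpose)
            self._matrices[key] = rng.random((self.n, self.horizon_days))
        return self._matrices[key]

    def u_inr(self, arm_tag: str) -> np.ndarray:
        return self._matrix(PURPOSE_INR, arm_tag)

    def u_bleed(self, arm_tag: str) -> np.ndarray:
        return self._matrix(PURPOSE_BLEED, arm_tag)

    def u_te(self, arm_tag: str) -> np.ndarray:
        return self._matrix(PURPOSE_TE, arm_tag)

    def resolve_rng(self, arm_tag: str, day: int) -> np.random.Generator:
        return _rng(
            self.master_seed, self.replicate_id, ARM_CODES[arm_tag],
            PURPOSE_RESOLVE, day,
        )

    def for_individual(self, row: int, arm_tag: str) -> "IndividualStreams":
        return IndividualStreams(self, row, arm_tag)


@dataclass
class IndividualStreams:
    """Row view of :class:`SharedStreams` for a single individual."""

    shared: SharedStreams
    row: int
    arm_tag: str

    @property
    def u_inr(self) -> np.ndarray:
        return self.shared.u_inr(self.arm_tag)[self.row]

    @property
    def u_bleed(self) -> np.ndarray:
        return self.shared.u_bleed(self.arm_tag)[self.row]

    @property
    def u_te(self) -> np.ndarray:
        return self.shared.u_te(self.arm_tag)[self.row]
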