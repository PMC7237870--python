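"""Consensus CNS drug-likeness filter.

A primary guideline (default: the consensus ranges attributed to Pajouhesh,
with preferred and hard bounds written "preferred (hard)") is applied per
descriptor; a value breaking a hard bound may be *rescued* when it falls
inside the corresponding range of any rescue guideline (default: Ghose and
Wager).  Soft violations (beyond a preferred bound but within the hard bound)
are reported and never fatal.  The verdict counts unrescued hard violations:
0 -> pass, 1 -> pass_flagged (retained but highlighted), >=2 -> fail.

logS is excluded from filtering by default: the shipped Ghose logS range
(-0.4 .. 0.5) would reject nearly every lipophilic CNS compound, so it is kept
verbatim but inert unless explicitly enabled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Mapping, Sequence

from .compound_library import DESCRIPTOR_ORDER, DescriptorSet

__all__ = [
    "Bound",
    "GuidelineSet",
    "Status",
    "DescriptorStatus",
    "FilterVerdict",
    "evaluate_against_guideline",
    "consensus_filter",
    "PAJOUHESH",
    "GHOSE",
    "WAGER",
    "LIPINSKI_CNS",
    "LIPINSKI_NONCNS",
    "GUIDELINES",
]


class Status(str, Enum):
    OK = "ok"
    SOFT = "soft_violation"
    HARD = "hard_violation"
    RESCUED = "rescued"


@dataclass(frozen=True)
class Bound:
    """Per-descriptor bounds; all inclusive. ``minimum`` is a hard lower bound."""

    minimum: float | None = None
    preferred_max: float | None = None
    hard_max: float | None = None

    def __post_init__(self):
        lo = self.minimum if self.minimum is not None else -math.inf
        pm = self.preferred_max if self.preferred_max is not None else lo
        hm = self.hard_max if self.hard_max is not None else max(pm, lo)
        if not (lo <= pm <= hm):
            raise ValueError(f"inconsistent bound {self}")

    @property
    def upper(self) -> float:
        if self.hard_max is not None:
            return self.hard_max
        if self.preferred_max is not None:
            return self.preferred_max
        return math.inf

    @property
    def lower(self) -> float:
        return self.minimum if self.minimum is not None else -math.inf

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def status(self, value: float) -> Status:
        if value < self.lower:
            return Status.HARD
        if self.hard_max is not None and value > self.hard_max:
            return Status.HARD
        if self.hard_max is None and self.preferred_max is not None and value > self.preferred_max:
            # a guideline with only one printed maximum treats it as hard
            return Status.HARD
        if self.preferred_max is not None and self.hard_max is not None and value > self.preferred_max:
            return Status.SOFT
        return Status.OK


@dataclass(frozen=True)
class GuidelineSet:
    """Named immutable set of per-descriptor bounds."""

    name: str
    bounds: Mapping[str, Bound]

    def __post_init__(self):
        unknown = set(self.bounds) - set(DESCRIPTOR_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptors in guideline {self.name}: {unknown}")
        object.__setattr__(self, "bounds", MappingProxyType(dict(self.bounds)))


PAJOUHESH = GuidelineSet(
    "pajouhesh",
    {
        "mw": Bound(preferred_max=360, hard_max=500),
        "hbd": Bound(preferred_max=0.5, hard_max=3.5),
        "logp": Bound(preferred_max=3, hard_max=5),
        "psa": Bound(minimum=40, preferred_max=90, hard_max=120),
    },
)

GHOSE = GuidelineSet(
    "ghose",
    {
        "mw": Bound(minimum=141, hard_max=452),
        "hbd": Bound(minimum=0, hard_max=3),
        "hba": Bound(minimum=1, hard_max=8),
        "logp": Bound(minimum=0.16, hard_max=6),
        "logs": Bound(minimum=-0.4, hard_max=0.5),
        "psa": Bound(minimum=3.8, hard_max=109),
        "rotb": Bound(minimum=0, hard_max=8),
    },
)

WAGER = GuidelineSet(
    "wager",
    {
        "mw": Bound(hard_max=400),
        "hbd": Bound(hard_max=3),
        "hba": Bound(hard_max=7),
        "logp": Bound(hard_max=5),
    },
)

# numerically identical to the Wager column in this compilation; kept as a
# separate named set so rescue configurations can include or exclude it
LIPINSKI_CNS = GuidelineSet(
    "lipinski_cns",
    {
        "mw": Bound(hard_max=400),
        "hbd": Bound(hard_max=3),
        "hba": Bound(hard_max=7),
        "logp": Bound(hard_max=5),
    },
)

LIPINSKI_NONCNS = GuidelineSet(
    "lipinski_noncns",
    {
        "mw": Bound(hard_max=500),
        "hbd": Bound(hard_max=5),
        "hba": Bound(hard_max=10),
        "logp": Bound(hard_max=5),
        "psa": Bound(hard_max=140),
        "rotb": Bound(hard_max=10),
    },
)

GUIDELINES: Mapping[str, GuidelineSet] = MappingProxyType(
    {
        g.name: g
        for g in (PAJOUHESH, GHOSE, WAGER, LIPINSKI_CNS, LIPINSKI_NONCNS)
    }
)

DEFAULT_RESCUES: tuple[GuidelineSet, ...] = (GHOSE, WAGER)


def _effective_bounds(g: GuidelineSet, include_logs: bool) -> Mapping[str, Bound]:
    if include_logs or "logs" not in g.bounds:
        return g.bounds
    return {k: v for k, v in g.bounds.items() if k != "logs"}


def evaluate_against_guideline(
    d: DescriptorSet, g: GuidelineSet, include_logs: bool = False
) -> dict[str, Status]:
    """Per-descriptor status of ``d`` against one guideline (no rescue)."""
    bounds = _effective_bounds(g, include_logs)
    if not bounds:
        raise ValueError(f"guideline {g.name} has no bounds")
    statuses: dict[str, Status] = {}
    for desc in DESCRIPTOR_ORDER:
        bound = bounds.get(desc)
        if bound is None:
            statuses[desc] = Status.OK
            continue
        value = getattr(d, desc, None)
        if value is None:
            warnings.warn(f"descriptor {desc} missing; treated as ok", stacklevel=2)
            statuses[desc] = Status.OK
            continue
        statuses[desc] = bound.status(value)
    return statuses


@dataclass(frozen=True)
class DescriptorStatus:
    status: Status
    rescued_by: str | None = None


@dataclass(frozen=True)
class FilterVerdict:
    """pass / pass_flagged / fail plus the per-descriptor report.

    ``n_violations`` counts unrescued hard violations only.
    """

    verdict: str
    n_violations: int
    report: Mapping[str, DescriptorStatus] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "report", MappingProxyType(dict(self.report)))


def consensus_filter(
    d: DescriptorSet,
    primary: GuidelineSet = PAJOUHESH,
    rescues: Sequence[GuidelineSet] = DEFAULT_RESCUES,
    include_logs: bool = False,
) -> FilterVerdict:
    """Primary-guideline screen with rescue by alternative published ranges.

    A hard violation is rescued iff the value lies inside the corresponding
    bound of at least one rescue guideline (a rescue set with no bound for
    that descriptor cannot rescue it).
    """
    statuses = evaluate_against_guideline(d, primary, include_logs)
    report: dict[str, DescriptorStatus] = {}
    n_unrescued = 0
    for desc, status in statuses.items():
        if status is not Status.HARD:
            report[desc] = DescriptorStatus(status)
            continue
        value = getattr(d, desc)
        rescuer = next(
            (
                g.name
                for g in rescues
                if desc in _effective_bounds(g, include_logs)
                and g.bounds[desc].contains(value)
            ),
            None,
        )
        if rescuer is not None:
            report[desc] = DescriptorStatus(Status.RESCUED, rescued_by=rescuer)
        else:
            report[desc] = DescriptorStatus(Status.HARD)
            n_unrescued += 1
    verdict = "pass" if n_unrescued == 0 else ("pass_flagged" if n_unrescued == 1 else "fail")
    return FilterVerdict(verdict=verdict, n_violations=n_unrescued, report=report)
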