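"""Per-pose inhibition calls and per-compound aggregation.

Two criteria turn a geometric profile into an inhibition call:

(i)  *proximal inhibitory*: the pose is proximal (< 6 Å to the heme iron) and
     either a heme-coordination contact is present or the atom closest to Fe
     carries a functional group that is not a canonical oxidation site
     (hydroxyl, ether/methylenedioxy, amine, aliphatic carbon) — a group
     parked over the reactive oxygen without being turned over blocks the
     catalytic cycle;
(ii) *distal inhibitory*: the pose is distal but still inside the substrate
     access channel (min Fe distance <= ``occlusion_max``, default 12 Å) and
     makes an ionic or hydrogen-bond contact to an anchoring carboxylate
     (Glu216/Asp301 by default) — the quinidine-like mode that blocks
     substrate anchoring without touching the heme.

Calls from the top-N poses (default 10) of each receptor structure are then
aggregated per compound and variant: under the default "any" consensus a flag
is set when at least one structure has at least one qualifying call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

from .interaction_profiler import InteractionProfile, ProfilerParams

__all__ = [
    "ClassifierParams",
    "PoseCall",
    "VariantVerdict",
    "InhibitionVerdict",
    "call_pose_inhibition",
    "aggregate_compound_verdict",
    "DEFAULT_ANCHORS",
    "NONMETABOLIZED_LABELS",
]

DEFAULT_ANCHORS: frozenset[tuple[str, int]] = frozenset({("GLU", 216), ("ASP", 301)})

# closest-atom functional groups treated as "not normally metabolized"
NONMETABOLIZED_LABELS: frozenset[str] = frozenset(
    {"hydroxyl", "ether/methylenedioxy", "amine", "aliphatic carbon"}
)

_ANCHOR_CONTACT_TYPES = {"ionic", "hbond"}


@dataclass(frozen=True)
class ClassifierParams:
    top_n: int = 10
    anchor_residues: frozenset[tuple[str, int]] = DEFAULT_ANCHORS
    occlusion_max: float = 12.0
    consensus: str = "any"  # "any" | "majority" across receptor structures
    nonmetabolized_labels: frozenset[str] = NONMETABOLIZED_LABELS
    profiler: ProfilerParams = field(default_factory=ProfilerParams)

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.occlusion_max <= self.profiler.proximal_cutoff:
            raise ValueError("occlusion_max must exceed proximal_cutoff")
        if self.consensus not in ("any", "majority"):
            raise ValueError(f"unknown consensus rule {self.consensus!r}")


@dataclass(frozen=True)
class PoseCall:
    """proximal_inhibitory | distal_inhibitory | none, with the evidence."""

    call: str
    evidence: tuple[str, ...] = ()


def _anchor_residue_ids(anchors: frozenset[tuple[str, int]]) -> set[str]:
    return {f"{name} {seq}" for name, seq in anchors}


def call_pose_inhibition(
    profile: InteractionProfile, params: ClassifierParams = ClassifierParams()
) -> PoseCall:
    """Apply inhibition criteria (i)/(ii) to one pose profile."""
    if profile.proximity == "proximal":
        coordination = [c for c in profile.contacts if c.type == "heme_coordination"]
        if coordination:
            return PoseCall(
                "proximal_inhibitory",
                tuple(
                    f"heme_coordination:{c.ligand_atom}@{c.distance:.2f}Å"
                    for c in coordination
                ),
            )
        if profile.closest_atom_label in params.nonmetabolized_labels:
            return PoseCall(
                "proximal_inhibitory",
                (
                    f"closest_atom:{profile.closest_atom_label}"
                    f"@{profile.min_heme_fe_distance:.2f}Å",
                ),
            )
        return PoseCall("none")
    # distal branch: occluding the access channel while gripping an anchor
    if profile.min_heme_fe_distance > params.occlusion_max:
        return PoseCall("none")
    anchor_ids = _anchor_residue_ids(params.anchor_residues)
    anchored = [
        c
        for c in profile.contacts
        if c.type in _ANCHOR_CONTACT_TYPES and c.residue in anchor_ids
    ]
    if anchored:
        return PoseCall(
            "distal_inhibitory",
            tuple(f"{c.type}:{c.residue}@{c.distance:.2f}Å" for c in anchored),
        )
    return PoseCall("none")


@dataclass(frozen=True)
class VariantVerdict:
    """Aggregated flags for one compound in one receptor variant."""

    proximal: bool
    distal: bool
    per_structure: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "per_structure", MappingProxyType(dict(self.per_structure)))

    @property
    def none(self) -> bool:
        return not (self.proximal or self.distal)


@dataclass
class InhibitionVerdict:
    """Per-compound verdicts keyed by receptor variant (e.g. WT, *53)."""

    compound: str
    by_variant: dict[str, VariantVerdict] = field(default_factory=dict)

    @property
    def any_inhibition(self) -> bool:
        return any(not v.none for v in self.by_variant.values())


def aggregate_compound_verdict(
    calls_by_structure: Mapping[str, Sequence[PoseCall]],
    params: ClassifierParams = ClassifierParams(),
) -> VariantVerdict:
    """Aggregate ranked pose calls from one or more receptor structures.

    Under "any", a flag is set when >=1 structure has >=1 qualifying call in
    its top-N; under "majority", when more than half of the structures do.
    """
    if not calls_by_structure or all(len(v) == 0 for v in calls_by_structure.values()):
        raise ValueError("need at least one structure with at least one pose call")
    hits = {"proximal_inhibitory": 0, "distal_inhibitory": 0}
    per_structure: dict[str, tuple[str, ...]] = {}
    for structure, calls in calls_by_structure.items():
        top = list(calls)[: params.top_n]
        kinds = tuple(c.call for c in top)
        per_structure[structure] = kinds
        for kind in hits:
            if kind in kinds:
                hits[kind] += 1
    n_structures = len(calls_by_structure)
    threshold = 1 if params.consensus == "any" else n_structures // 2 + 1
    return VariantVerdict(
        proximal=hits["proximal_inhibitory"] >= threshold,
        distal=hits["distal_inhibitory"] >= threshold,
        per_structure=per_structure,
    )
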