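"""Mechanism-based-inhibition (MBI) structural alerts.

The default pattern is the methylenedioxyphenyl (benzodioxole) moiety: after
oxidation of its acetal carbon the group can form a carbene that coordinates
the heme iron, irreversibly inactivating the enzyme (the paroxetine/MDMA
pathway).  The moiety can also act reversibly, so an alert alone marks a
candidate; it is upgraded to "MBI-candidate" only when the compound also has
a proximal inhibition verdict with a moiety-compatible closest atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .compound_library import CompoundRecord
from .errors import CypscreenError
from .inhibition_classifier import InhibitionVerdict
from .interaction_profiler import InteractionProfile

__all__ = [
    "AlertPattern",
    "AlertResult",
    "load_patterns",
    "default_patterns",
    "detect_mbi_alert",
    "detect_alerts",
    "grade_alert",
]


@dataclass(frozen=True)
class AlertPattern:
    alert_id: str
    smarts: str

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise CypscreenError(
                f"invalid alert pattern {self.alert_id!r}: {self.smarts!r}"
            )
        return q


@dataclass(frozen=True)
class AlertResult:
    compound: str
    alert_id: str
    matches: tuple[tuple[int, ...], ...]  # distinct atom-index sets

    @property
    def count(self) -> int:
        return len(self.matches)


def load_patterns(path) -> list[AlertPattern]:
    """One pattern per line: ``id<TAB or space>SMARTS``; '#' comments allowed."""
    patterns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alert_id, smarts = line.split(None, 1)
        pattern = AlertPattern(alert_id, smarts.strip())
        pattern.query()  # fail fast on an invalid pattern
        patterns.append(pattern)
    return patterns


def default_patterns() -> list[AlertPattern]:
    with resources.as_file(
        resources.files("cypscreen").joinpath("data/alerts.tsv")
    ) as path:
        return load_patterns(path)


def _distinct_matches(mol: Chem.Mol, query: Chem.Mol) -> tuple[tuple[int, ...], ...]:
    seen: set[frozenset[int]] = set()
    out: list[tuple[int, ...]] = []
    for match in mol.GetSubstructMatches(query, uniquify=True):
        key = frozenset(match)
        if key not in seen:  # collapse symmetry-equivalent atom sets
            seen.add(key)
            out.append(tuple(sorted(match)))
    return tuple(out)


def detect_mbi_alert(
    record: CompoundRecord, patterns: list[AlertPattern] | None = None
) -> list[AlertResult]:
    """Substructure-match the MBI alert patterns against one compound.

    Returns one result per pattern with at least one occurrence; element,
    aromaticity and ring membership are respected by SMARTS semantics.
    """
    results = []
    for pattern in patterns if patterns is not None else default_patterns():
        matches = _distinct_matches(record.mol, pattern.query())
        if matches:
            results.append(AlertResult(record.name, pattern.alert_id, matches))
    return results


# alias matching the plural CLI surface
detect_alerts = detect_mbi_alert

_MOIETY_LABELS = {"ether/methylenedioxy", "aliphatic carbon"}


def grade_alert(
    alert: AlertResult,
    verdict: InhibitionVerdict | None = None,
    proximal_profiles: list[InteractionProfile] | None = None,
) -> str:
    """Alert severity: "alert" alone, "MBI-candidate" when a proximal verdict
    places a moiety-compatible atom closest to the heme iron."""
    if verdict is None or not any(v.proximal for v in verdict.by_variant.values()):
        return "alert"
    if proximal_profiles:
        moiety_atoms = {i for match in alert.matches for i in match}
        for profile in proximal_profiles:
            if profile.proximity != "proximal":
                continue
            if (
                profile.closest_atom_index in moiety_atoms
                or profile.closest_atom_label in _MOIETY_LABELS
            ):
                return "MBI-candidate"
        return "alert"
    return "MBI-candidate"
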