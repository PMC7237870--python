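"""Pipeline orchestration: descriptors -> filter -> profiling -> classification
-> alerts, aggregated into one safety-profile table, plus the external
docking-engine adapter.

Docking itself is never executed here: the scientific core consumes pose
files produced by any engine.  :func:`build_docking_command` only renders the
command line (seed, flexible side chains, search box with buffer) for an
external smina/vina-style engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .cns_filter import DEFAULT_RESCUES, PAJOUHESH, FilterVerdict, GuidelineSet, consensus_filter
from .compound_library import CompoundRecord, compute_descriptors
from .errors import CypscreenError
from .inhibition_classifier import (
    ClassifierParams,
    InhibitionVerdict,
    PoseCall,
    aggregate_compound_verdict,
    call_pose_inhibition,
)
from .interaction_profiler import InteractionProfile, ProfilerParams, profile_pose
from .pose_io import LigandPose
from .receptor_prep import FLEXIBLE_RESIDUES, ReceptorModel, SearchBox, compute_search_box
from .structural_alerts import detect_mbi_alert, grade_alert

__all__ = [
    "DockingConfig",
    "run_pipeline",
    "build_docking_command",
    "classify_poses",
    "profile_to_dict",
    "profile_from_dict",
]


# ------------------------------------------------------------- profiling glue

def classify_poses(
    poses_by_structure: Mapping[str, Sequence[LigandPose]],
    receptors_by_structure: Mapping[str, ReceptorModel],
    params: ClassifierParams = ClassifierParams(),
) -> tuple[dict[str, list[PoseCall]], list[InteractionProfile]]:
    """Profile and call every pose of one compound in one receptor variant."""
    calls: dict[str, list[PoseCall]] = {}
    profiles: list[InteractionProfile] = []
    for structure, poses in poses_by_structure.items():
        receptor = receptors_by_structure[structure]
        ranked = sorted(poses, key=lambda p: p.rank)[: params.top_n]
        structure_calls = []
        for pose in ranked:
            profile = profile_pose(pose, receptor, params.profiler)
            profiles.append(profile)
            structure_calls.append(call_pose_inhibition(profile, params))
        calls[structure] = structure_calls
    return calls, profiles


def profile_to_dict(profile: InteractionProfile) -> dict:
    return {
        "pose_name": profile.pose.name if profile.pose is not None else None,
        "rank": profile.pose.rank if profile.pose is not None else None,
        "min_heme_fe_distance": profile.min_heme_fe_distance,
        "closest_atom_index": profile.closest_atom_index,
        "closest_atom_element": profile.closest_atom_element,
        "closest_atom_label": profile.closest_atom_label,
        "proximity": profile.proximity,
        "contacts": [
            {
                "type": c.type,
                "ligand_atom": c.ligand_atom,
                "residue": c.residue,
                "rec_atom": c.rec_atom,
                "distance": c.distance,
                "annotation": c.annotation,
            }
            for c in profile.contacts
        ],
    }


def profile_from_dict(data: dict) -> InteractionProfile:
    from .interaction_profiler import Contact

    return InteractionProfile(
        pose=None,
        contacts=[
            Contact(
                c["type"], c["ligand_atom"], c["residue"], c["rec_atom"],
                c["distance"], c.get("annotation"),
            )
            for c in data["contacts"]
        ],
        min_heme_fe_distance=data["min_heme_fe_distance"],
        closest_atom_index=data["closest_atom_index"],
        closest_atom_element=data["closest_atom_element"],
        closest_atom_label=data["closest_atom_label"],
        proximity=data["proximity"],
    )


# ---------------------------------------------------------------- safety table

_NOT_RUN = "not_run"


def run_pipeline(
    records: Sequence[CompoundRecord],
    receptors: Mapping[str, Mapping[str, ReceptorModel]] | None = None,
    poses: Mapping[str, Mapping[str, Mapping[str, Sequence[LigandPose]]]] | None = None,
    primary: GuidelineSet = PAJOUHESH,
    rescues: Sequence[GuidelineSet] = DEFAULT_RESCUES,
    classifier_params: ClassifierParams = ClassifierParams(),
) -> tuple[pd.DataFrame, str]:
    """Compile the per-compound safety-profile table.

    ``receptors`` maps variant -> structure id -> prepared receptor;
    ``poses`` maps compound -> variant -> structure id -> ranked poses.
    Stages without inputs are marked not-run, never silently dropped.
    Returns (table, human-readable report).
    """
    if not records:
        raise CypscreenError("empty compound table")

    rows = []
    errors: list[str] = []
    # WT and the *53 variant are always reported; without structures the
    # inhibition stage shows not_run rather than disappearing
    variants = sorted(receptors) if receptors else ["WT", "*53"]
    for rec in records:
        row: dict = {"name": rec.name}
        try:
            d = compute_descriptors(rec)
            row.update(d.as_dict())
            verdict: FilterVerdict = consensus_filter(d, primary, rescues)
            row["filter_verdict"] = verdict.verdict
            row["filter_violations"] = verdict.n_violations
        except CypscreenError as exc:
            errors.append(f"{rec.name}: descriptor/filter stage failed: {exc}")
            row["filter_verdict"] = "error"

        alerts = detect_mbi_alert(rec)
        row["alerts"] = ";".join(a.alert_id for a in alerts) or "none"
        row["alert_count"] = sum(a.count for a in alerts)

        inhibition = InhibitionVerdict(compound=rec.name)
        proximal_profiles: list[InteractionProfile] = []
        for variant in variants:
            pose_map = (poses or {}).get(rec.name, {}).get(variant)
            if not pose_map:
                row[f"{variant}_prox"] = _NOT_RUN
                row[f"{variant}_dis"] = _NOT_RUN
                row[f"{variant}_none"] = _NOT_RUN
                continue
            calls, profiles = classify_poses(
                pose_map, receptors[variant], classifier_params
            )
            proximal_profiles.extend(p for p in profiles if p.proximity == "proximal")
            vv = aggregate_compound_verdict(calls, classifier_params)
            inhibition.by_variant[variant] = vv
            row[f"{variant}_prox"] = vv.proximal
            row[f"{variant}_dis"] = vv.distal
            row[f"{variant}_none"] = vv.none
        if alerts and inhibition.by_variant:
            row["alert_severity"] = grade_alert(alerts[0], inhibition, proximal_profiles)
        elif alerts:
            row["alert_severity"] = "alert"
        else:
            row["alert_severity"] = "none"

        for key, value in rec.annotations.items():
            row[f"annot_{key}"] = value
        rows.append(row)

    table = pd.DataFrame(rows)
    lines = [
        f"cypscreen {_pkg_version} safety-profile report",
        f"compounds: {len(records)}",
        f"primary guideline: {primary.name}; rescues: {[g.name for g in rescues]}",
        f"classifier: top_n={classifier_params.top_n}, "
        f"occlusion_max={classifier_params.occlusion_max} Å, "
        f"consensus={classifier_params.consensus}",
        f"profiler: proximal_cutoff={classifier_params.profiler.proximal_cutoff} Å",
        f"variants with structures: {variants or 'none (inhibition stage not run)'}",
    ]
    if errors:
        lines.append("stage errors:")
        lines.extend(f"  - {e}" for e in errors)
    counts = table["filter_verdict"].value_counts().to_dict()
    lines.append(f"filter verdicts: {counts}")
    flagged = table[table["alert_count"] > 0]["name"].tolist()
    lines.append(f"structural alerts: {flagged or 'none'}")
    report = "\n".join(lines)
    if errors:
        raise CypscreenError(report)
    return table, report


# --------------------------------------------------------------- engine adapter

@dataclass(frozen=True)
class DockingConfig:
    """Settings for an external smina/vina-style docking run.

    ``seed`` and the flexible side-chain list follow the triage protocol; the
    box may be given explicitly or auto-derived from reference ligands plus a
    buffer added to every face.
    """

    receptor: str | None = None
    engine: str = "smina"
    flexible_residues: tuple[int, ...] = FLEXIBLE_RESIDUES
    chain: str = "A"
    seed: int = 0
    box: SearchBox | None = None
    reference_ligands: tuple[LigandPose, ...] = ()
    box_buffer: float = 8.0
    exhaustiveness: int | None = None  # None -> engine default


def build_docking_command(cfg: DockingConfig, ligand_file: str) -> list[str]:
    """Render the external docking invocation (never executed here).

    The command records the random seed, the flexible-residue specification
    and the buffered search box.
    """
    if not cfg.receptor:
        raise CypscreenError("docking config has no receptor file")
    cmd = [
        cfg.engine,
        "--receptor", str(cfg.receptor),
        "--ligand", str(ligand_file),
        "--seed", str(cfg.seed),
    ]
    if cfg.flexible_residues:
        flex = ",".join(f"{cfg.chain}:{num}" for num in cfg.flexible_residues)
        cmd += ["--flexres", flex]
    box = cfg.box
    if box is None and cfg.reference_ligands:
        box = compute_search_box(cfg.reference_ligands, buffer=cfg.box_buffer)
    if box is not None:
        cx, cy, cz = box.center
        sx, sy, sz = box.extents
        cmd += [
            "--center_x", f"{cx:.3f}", "--center_y", f"{cy:.3f}", "--center_z", f"{cz:.3f}",
            "--size_x", f"{sx:.3f}", "--size_y", f"{sy:.3f}", "--size_z", f"{sz:.3f}",
        ]
    else:
        cmd += ["--autobox_ligand", str(ligand_file), "--autobox_add", f"{cfg.box_buffer:g}"]
    if cfg.exhaustiveness is not None:
        cmd += ["--exhaustiveness", str(cfg.exhaustiveness)]
    return cmd
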