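"""Transition-state conformer library generation.

Starting from a matched active site, the rotatable torsions of the TS are
enumerated on a grid and combined with small rigid-body perturbations of the
matched pose.  Each candidate pose is screened by placing rules (by default a
heavy-atom clash rule against the scaffold), by the active-site constraint
penalty, and deduplicated by heavy-atom RMSD.  The retained conformers play
the role of substrate "rotamers" during sequence design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import geometry
from .active_site import ActiveSiteModel, TRIAD_ROLES, constraint_penalty, default_model
from .matcher import MatchResult
from .structio import ProteinStructure

__all__ = [
    "PlacingRule",
    "TSConformerLibrary",
    "TSConformer",
    "LibraryParams",
    "default_placing_rules",
    "generate_ts_library",
    "assignment_geometry",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}


@dataclass
class PlacingRule:
    """A named yes/no predicate over a candidate TS pose."""

    rule_id: str
    description: str
    predicate: Callable[[dict, dict], bool]  # (pose atoms, context) -> keep?

    def __call__(self, pose: dict, context: dict) -> bool:
        return bool(self.predicate(pose, context))


@dataclass
class TSConformer:
    torsions: tuple[float, ...]
    atoms: dict[str, np.ndarray]
    penalty: float
    clash_score: float
    jitter_index: int = 0


@dataclass
class TSConformerLibrary:
    conformers: list[TSConformer]
    provenance: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class LibraryParams:
    """Grid and filter settings for conformer generation."""

    torsion_steps: tuple[int, ...] | int = 6
    n_jitter: int = 0                 # random rigid perturbations per torsion point
    jitter_translation_A: float = 0.25
    jitter_rotation_deg: float = 5.0
    penalty_cutoff: float = 5.0
    dedupe_tol_A: float = 0.3
    clash_factor: float = 0.8         # clash when d < factor * (r_i + r_j)


def assignment_geometry(
    structure: ProteinStructure, model: ActiveSiteModel, assignment: dict
) -> dict:
    """Role -> {logical atom: coords} for a fixed role assignment (native
    side-chain conformations), ready for :func:`constraint_penalty`."""
    placed: dict[str, dict[str, np.ndarray]] = {}
    for role_id, key in assignment.items():
        res = structure.residue(*key)
        role = model.role(role_id)
        placed[role_id] = {
            logical: res.atom(role.concrete_atom(logical, res.aa_type)).coords
            for logical in role.anchor_atoms
            if res.has_atom(role.concrete_atom(logical, res.aa_type))
        }
    return placed


def default_placing_rules(
    structure: ProteinStructure,
    match: MatchResult,
    clash_factor: float = 0.8,
) -> list[PlacingRule]:
    """The shipped rule set: a heavy-atom clash test against the scaffold.

    The nucleophile's side chain is exempt (it is the covalent partner of the
    sp3 carbon in the intermediate), as is the TS attack-direction marker ON.
    """
    nuc_key = match.role_assignment["nucleophile_ser"]
    scaffold_pts, scaffold_radii = [], []
    for res in structure.residues:
        for a in res.atoms:
            if a.element.upper() == "H":
                continue
            if res.key == nuc_key and not a.is_backbone:
                continue
            scaffold_pts.append(a.coords)
            scaffold_radii.append(VDW_RADII.get(a.element.upper(), 1.7))
    scaffold_pts = np.array(scaffold_pts).reshape(-1, 3)
    scaffold_radii = np.array(scaffold_radii)

    def no_clash(pose: dict, context: dict) -> bool:
        for name, pos in pose.items():
            if name == "ON" or name.startswith("H"):
                continue
            r_ts = VDW_RADII.get(context["elements"].get(name, "C"), 1.7)
            d = np.linalg.norm(scaffold_pts - pos, axis=1)
            if np.any(d < clash_factor * (scaffold_radii + r_ts)):
                return False
        return True

    return [
        PlacingRule(
            rule_id="no_scaffold_clash",
            description=f"no TS heavy atom within {clash_factor} x vdW-radius sum "
            "of a scaffold heavy atom (nucleophile side chain exempt)",
            predicate=no_clash,
        )
    ]


def _rigid_from_base(base_coords: np.ndarray, pose_coords: np.ndarray):
    """Exact rigid transform mapping the base conformer onto the pose."""
    _, rot, trans = geometry.superpose(pose_coords, base_coords)
    return rot, trans


def generate_ts_library(
    structure: ProteinStructure,
    match: MatchResult,
    model: ActiveSiteModel | None = None,
    params: LibraryParams | None = None,
    rules: list[PlacingRule] | None = None,
    seed: int = 0,
) -> TSConformerLibrary:
    """Enumerate, screen and deduplicate TS conformers around a match.

    The torsion grid spans each rotatable torsion uniformly
    (``torsion_steps`` per torsion); each grid point is optionally combined
    with ``n_jitter`` seeded rigid-body perturbations in addition to the
    unperturbed pose.  Candidates must pass every placing rule and have
    constraint penalty <= cutoff.  Deduplication keeps, per RMSD cluster, the
    lowest-penalty conformer (ties by torsion-vector lexicographic order) and
    is order-independent.  An empty library carries a rejection histogram in
    ``diagnostics``.
    """
    model = model or default_model()
    params = params or LibraryParams()
    rng = np.random.default_rng(seed)

    ts = model.ts
    names = list(ts.atoms)
    base = ts.coords_array(names)
    pose = np.array([match.ts_pose[n] for n in names])
    rot, trans = _rigid_from_base(base, pose)

    if rules is None:
        rules = default_placing_rules(structure, match, params.clash_factor)

    n_tor = len(ts.rotatable_torsions)
    steps = params.torsion_steps
    if isinstance(steps, int):
        steps = (steps,) * n_tor
    if len(steps) != n_tor:
        raise ValueError(f"expected {n_tor} torsion step counts, got {len(steps)}")
    grids = [np.linspace(-180.0, 180.0, s, endpoint=False) for s in steps]

    placed_roles = assignment_geometry(structure, model, match.role_assignment)
    context = {"elements": ts.elements, "structure": structure, "match": match}

    jitters = [(np.eye(3), np.zeros(3))]
    for _ in range(params.n_jitter):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.radians(rng.normal(scale=params.jitter_rotation_deg))
        from scipy.spatial.transform import Rotation

        jrot = Rotation.from_rotvec(axis * ang).as_matrix()
        jtrans = rng.normal(scale=params.jitter_translation_A, size=3)
        jitters.append((jrot, jtrans))

    rejected: dict[str, int] = {r.rule_id: 0 for r in rules}
    rejected["constraint_penalty"] = 0
    candidates: list[TSConformer] = []
    n_enumerated = 0

    import itertools

    pose_centroid = pose.mean(axis=0)
    for combo in itertools.product(*grids):
        mol = ts.with_torsions(list(combo))
        coords0 = mol.coords_array(names) @ rot.T + trans
        for j_idx, (jrot, jtrans) in enumerate(jitters):
            n_enumerated += 1
            coords = (coords0 - pose_centroid) @ jrot.T + pose_centroid + jtrans
            pose_atoms = {n: coords[i] for i, n in enumerate(names)}
            ok = True
            for rule in rules:
                if not rule(pose_atoms, context):
                    rejected[rule.rule_id] += 1
                    ok = False
                    break
            if not ok:
                continue
            placed = dict(placed_roles)
            placed["TS"] = pose_atoms
            pen, _ = constraint_penalty(model, placed)
            if pen > params.penalty_cutoff:
                rejected["constraint_penalty"] += 1
                continue
            clash = _min_gap_score(pose_atoms, context, structure, match)
            candidates.append(
                TSConformer(
                    torsions=tuple(round(float(t), 6) for t in combo),
                    atoms=pose_atoms,
                    penalty=pen,
                    clash_score=clash,
                    jitter_index=j_idx,
                )
            )

    # canonical dedupe: sort by (penalty, torsions, jitter), greedy RMSD gate
    candidates.sort(key=lambda c: (c.penalty, c.torsions, c.jitter_index))
    kept: list[TSConformer] = []
    heavy = [n for n in names if ts.elements.get(n, "C") != "H"]
    kept_coords: list[np.ndarray] = []
    for c in candidates:
        arr = np.array([c.atoms[n] for n in heavy])
        dup = any(
            geometry.kabsch_rmsd(arr, prev, superpose_first=False) < params.dedupe_tol_A
            for prev in kept_coords
        )
        if not dup:
            kept.append(c)
            kept_coords.append(arr)

    return TSConformerLibrary(
        conformers=kept,
        provenance={
            "seed": seed,
            "torsion_steps": tuple(steps),
            "n_jitter": params.n_jitter,
            "n_enumerated": n_enumerated,
            "n_before_dedupe": len(candidates),
        },
        diagnostics={"rejected": rejected},
    )


def _min_gap_score(pose_atoms: dict, context: dict, structure, match) -> float:
    """Worst (most negative) gap between pair distance and vdW contact."""
    nuc_key = match.role_assignment["nucleophile_ser"]
    worst = np.inf
    pts, radii = [], []
    for res in structure.residues:
        for a in res.atoms:
            if a.element.upper() == "H" or (res.key == nuc_key and not a.is_backbone):
                continue
            pts.append(a.coords)
            radii.append(VDW_RADII.get(a.element.upper(), 1.7))
    pts = np.array(pts).reshape(-1, 3)
    radii = np.array(radii)
    for name, pos in pose_atoms.items():
        if name == "ON" or name.startswith("H"):
            continue
        r_ts = VDW_RADII.get(context["elements"].get(name, "C"), 1.7)
        gap = np.linalg.norm(pts - pos, axis=1) - (radii + r_ts)
        worst = min(worst, float(gap.min()))
    return worst
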