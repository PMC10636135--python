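"""Anchor the active-site model into a scaffold.

The matcher enumerates Ser-His-Asp(Glu) triad assignments at positions whose
native residue type is admissible for the role (nucleophile at native Ser,
base at native His, acid at native Asp/Glu), places the transition-state
molecule against the triad by a coarse direction scan followed by rigid-body
penalty minimisation, completes the oxyanion-hole and carboxylate-binder
roles with the best available positions, and reports every assignment whose
constraint penalty falls below a cutoff.  The same placement routine serves
both the production search and brute-force enumeration oracles, so penalties
agree exactly wherever memberships do.

Torsional freedom of the TS is deliberately *not* explored here: matching
uses the reference conformer and the full conformer library is generated
afterwards (ts_placement), mirroring the two-stage plant-then-place pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import geometry
from .active_site import ActiveSiteModel, TRIAD_ROLES, constraint_penalty, default_model
from .structio import ProteinStructure, ResidueRecord

__all__ = [
    "PocketDefinition",
    "MatchResult",
    "MatchConfig",
    "detect_pockets",
    "match_active_site",
    "place_and_score",
    "rank_matches",
    "triad_rmsd_vs_native",
]


@dataclass
class PocketDefinition:
    """A detected surface cavity: member positions, centroid, size proxy."""

    pocket_id: int
    member_positions: list[tuple[str, int]]
    centroid: np.ndarray
    volume_proxy: float

    def __post_init__(self) -> None:
        if len(self.member_positions) > 100:
            raise ValueError("pocket membership capped at 100 positions")
        if len(set(self.member_positions)) != len(self.member_positions):
            raise ValueError("duplicate pocket member positions")


@dataclass
class MatchResult:
    """One placed active site: role assignment, rotamers, TS pose, penalty."""

    scaffold_id: str
    role_assignment: dict[str, tuple[str, int]]
    placed_rotamers: dict[str, dict[str, np.ndarray]]
    ts_pose: dict[str, np.ndarray]
    penalty: float
    breakdown: list = field(default_factory=list)
    triad_rmsd_vs_native: float | None = None

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        positions = list(self.role_assignment.values())
        if len(set(positions)) != len(positions):
            raise ValueError("role assignment must be injective over positions")


@dataclass
class MatchConfig:
    """Search settings for :func:`match_active_site`."""

    penalty_cutoff: float = 5.0
    n_directions: int = 40        # Fibonacci directions for the attack scan
    n_spins: int = 12             # spins about the attack axis per direction
    n_refine_starts: int = 5      # best coarse poses carried into refinement
    restrict_to_pockets: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# Pocket detection: grid buriedness + flood fill
# ---------------------------------------------------------------------------

_RAY_DIRECTIONS = np.array(
    [
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
        [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1],
    ],
    dtype=int,
)


def detect_pockets(
    structure: ProteinStructure,
    n_pockets: int = 3,
    spacing: float = 1.0,
    probe_radius: float = 2.2,
    buriedness_cut: float = 0.68,
    ray_range_A: float = 12.0,
    lining_distance_A: float = 4.5,
    min_points: int = 8,
) -> list[PocketDefinition]:
    """Detect up to ``n_pockets`` cavities on a grid, largest first.

    A grid point is a pocket point when it is empty, near the protein, and
    buried: at least ``buriedness_cut`` of 14 rays (axes + body diagonals)
    hit protein within ``ray_range_A``.  Pocket points are clustered by
    connectivity; clusters are ranked by volume proxy (point count x
    spacing^3) and report up to 100 lining residues each.
    """
    coords = structure.all_atom_coords(heavy_only=True)
    if coords.size == 0:
        return []
    lo = coords.min(axis=0) - 4.0
    hi = coords.max(axis=0) + 4.0
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    if int(np.prod(shape)) > 4_000_000:
        raise ValueError("structure too large for grid pocket detection at this spacing")

    idx = np.floor((coords - lo) / spacing).astype(int)
    occ = np.zeros(shape, dtype=bool)
    # occupancy: any cell whose centre lies within probe_radius of an atom
    reach = int(np.ceil(probe_radius / spacing))
    offsets = [
        np.array(o)
        for o in itertools.product(range(-reach, reach + 1), repeat=3)
        if np.linalg.norm(np.array(o)) * spacing <= probe_radius + 0.5 * spacing
    ]
    for off in offsets:
        cells = idx + off
        ok = np.all((cells >= 0) & (cells < shape), axis=1)
        occ[tuple(cells[ok].T)] = True

    empty = ~occ
    # near-protein mask: empty cells within ~probe+2 of an atom cell
    near = ndimage.binary_dilation(occ, iterations=2) & empty

    steps = int(ray_range_A / spacing)
    hits = np.zeros(shape, dtype=np.int8)
    for d in _RAY_DIRECTIONS:
        hit = np.zeros(shape, dtype=bool)
        shifted = occ
        for _k in range(1, steps + 1):
            shifted = _shift(shifted, d)
            hit |= shifted
        hits += hit.astype(np.int8)

    pocket_mask = near & (hits >= int(np.ceil(buriedness_cut * len(_RAY_DIRECTIONS))))
    labels, n_lab = ndimage.label(pocket_mask)
    if n_lab == 0:
        return []
    sizes = ndimage.sum(pocket_mask, labels, index=range(1, n_lab + 1))
    order = np.argsort(-sizes, kind="stable")

    pockets: list[PocketDefinition] = []
    for rank, lab_i in enumerate(order):
        if len(pockets) >= n_pockets:
            break
        npts = int(sizes[lab_i])
        if npts < min_points:
            continue
        pts_idx = np.argwhere(labels == lab_i + 1)
        pts = lo + (pts_idx + 0.5) * spacing
        centroid = pts.mean(axis=0)
        members: list[tuple[float, tuple[str, int]]] = []
        for r in structure.residues:
            rc = r.heavy_coords()
            if rc.size == 0:
                continue
            dmin = float(
                np.min(np.linalg.norm(rc[:, None, :] - pts[None, :, :], axis=2))
            )
            if dmin <= lining_distance_A:
                members.append((dmin, r.key))
        members.sort(key=lambda t: (t[0], t[1]))
        pockets.append(
            PocketDefinition(
                pocket_id=rank,
                member_positions=[k for _, k in members[:100]],
                centroid=centroid,
                volume_proxy=npts * spacing**3,
            )
        )
    return pockets


def _shift(arr: np.ndarray, d) -> np.ndarray:
    """Shift a boolean grid by integer vector d, zero-filling."""
    out = arr
    for axis, step in enumerate(d):
        if step == 0:
            continue
        out = np.roll(out, step, axis=axis)
        sl = [slice(None)] * 3
        if step > 0:
            sl[axis] = slice(0, step)
        else:
            sl[axis] = slice(step, None)
        out = out.copy()
        out[tuple(sl)] = False
    return out


# ---------------------------------------------------------------------------
# TS placement and scoring (shared by matcher and oracles)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


class _SiteScorer:
    """Fast penalty evaluation for a fixed triad with completion roles."""

    def __init__(self, structure: ProteinStructure, model: ActiveSiteModel, triple: dict):
        self.structure = structure
        self.model = model
        self.triple = triple  # role -> (chain, seq_pos)
        self.ts_names = list(model.ts.atoms)
        self.base_coords = model.ts.coords_array(self.ts_names)
        self.base_centroid = self.base_coords.mean(axis=0)

        self.anchors: dict[str, dict[str, np.ndarray]] = {}
        for role_id in TRIAD_ROLES:
            res = structure.residue(*triple[role_id])
            role = model.role(role_id)
            self.anchors[role_id] = {
                logical: res.atom(role.concrete_atom(logical, res.aa_type)).coords
                for logical in role.anchor_atoms
                if res.has_atom(role.concrete_atom(logical, res.aa_type))
            }

        self.completion_roles = [
            r for r in model.roles if r.role_id not in TRIAD_ROLES
        ]
        taken = set(triple.values())
        self.candidates: dict[str, list] = {}
        for role in self.completion_roles:
            cands = []
            for res in structure.residues:
                if res.key in taken or res.is_hetero:
                    continue
                if res.aa_type not in role.allowed_aa:
                    continue
                atom_map = {}
                ok = True
                for logical in role.anchor_atoms:
                    concrete = role.concrete_atom(logical, res.aa_type)
                    if not res.has_atom(concrete):
                        ok = False
                        break
                    atom_map[logical] = res.atom(concrete).coords
                if ok:
                    cands.append((res.key, atom_map))
            self.candidates[role.role_id] = cands

        # constraints touching each completion role (for candidate scoring)
        self.role_constraints = {
            role.role_id: [
                c for c in model.constraints if any(o == role.role_id for o, _ in c.atoms)
            ]
            for role in self.completion_roles
        }

        # fast path: pure-distance constraint tables with candidate arrays
        self._fast = self._build_fast_tables()

    def _build_fast_tables(self):
        """Vectorised tables when every constraint is a two-point distance and
        completion-role constraints pair the role atom with a TS atom or an
        already-anchored triad atom.  Returns None when inapplicable."""
        if any(c.kind != "distance" for c in self.model.constraints):
            return None
        comp_ids = {r.role_id for r in self.completion_roles}

        def endpoint(owner, logical):
            if owner == "TS":
                return ("ts", self.ts_names.index(logical))
            if owner in self.anchors and logical in self.anchors[owner]:
                return ("fixed", self.anchors[owner][logical])
            if owner in comp_ids:
                return ("role", owner, logical)
            return None

        core = []       # constraints not involving completion roles
        per_role: dict[str, list] = {r.role_id: [] for r in self.completion_roles}
        for c in self.model.constraints:
            eps = [endpoint(o, l) for o, l in c.atoms]
            if any(e is None for e in eps):
                return None
            role_eps = [e for e in eps if e[0] == "role"]
            if len(role_eps) > 1:
                return None
            if role_eps:
                other = eps[0] if eps[1][0] == "role" else eps[1]
                if other[0] == "role":
                    return None
                per_role[role_eps[0][1]].append((role_eps[0][2], other, c))
            else:
                core.append((eps[0], eps[1], c))

        cand_arrays = {}
        key_rank = {}
        for role in self.completion_roles:
            keys = [k for k, _ in self.candidates[role.role_id]]
            arrays = {}
            for logical in role.anchor_atoms:
                arrays[logical] = np.array(
                    [am[logical] for _, am in self.candidates[role.role_id]]
                ).reshape(-1, 3)
            cand_arrays[role.role_id] = (keys, arrays)
            rank = np.empty(len(keys), dtype=int)
            for r_i, i in enumerate(sorted(range(len(keys)), key=lambda j: keys[j])):
                rank[i] = r_i
            key_rank[role.role_id] = rank
        return {
            "core": core,
            "per_role": per_role,
            "cands": cand_arrays,
            "key_rank": key_rank,
        }

    def fixed_floor(self) -> float:
        """Penalty contribution from constraints whose endpoints are both
        already-anchored triad atoms; a lower bound on any pose's penalty."""
        if self._fast is not None:
            total = 0.0
            for e1, e2, c in self._fast["core"]:
                if e1[0] == "fixed" and e2[0] == "fixed":
                    ex = c.excess(float(np.linalg.norm(e1[1] - e2[1])))
                    total += c.weight * ex * ex
            return total
        total = 0.0
        for c in self.model.constraints:
            pts = []
            for owner, logical in c.atoms:
                if owner in self.anchors and logical in self.anchors[owner]:
                    pts.append(self.anchors[owner][logical])
                else:
                    pts = None
                    break
            if pts is not None:
                ex = c.excess(geometry.measure(c.kind, pts))
                total += c.weight * ex * ex
        return total

    def ts_dict(self, coords: np.ndarray) -> dict[str, np.ndarray]:
        return {n: coords[i] for i, n in enumerate(self.ts_names)}

    def complete_roles(self, ts_coords: np.ndarray) -> dict | None:
        """Deterministically pick completion-role positions for a TS pose."""
        if self._fast is not None:
            return self._complete_roles_fast(ts_coords)
        return self._complete_roles_generic(ts_coords)

    def _complete_roles_fast(self, ts_coords: np.ndarray) -> dict | None:
        chosen: dict[str, tuple] = {}
        used: set = set()
        for role in self.completion_roles:
            keys, arrays = self._fast["cands"][role.role_id]
            if not keys:
                return None
            cost = np.zeros(len(keys))
            tie = np.zeros(len(keys))
            for logical, other, c in self._fast["per_role"][role.role_id]:
                pt = ts_coords[other[1]] if other[0] == "ts" else other[1]
                d = np.linalg.norm(arrays[logical] - pt, axis=1)
                ex = np.maximum(c.tol_lo - d, 0.0) + np.maximum(d - c.tol_hi, 0.0)
                cost += c.weight * ex * ex
                tie += np.abs(d - c.target)
            key_rank = self._fast["key_rank"][role.role_id]
            order = np.lexsort((key_rank, tie, cost))
            pick = next((int(i) for i in order if keys[i] not in used), None)
            if pick is None:
                return None
            key = keys[pick]
            atom_map = dict(self.candidates[role.role_id][pick][1])
            chosen[role.role_id] = (key, atom_map)
            used.add(key)
        return chosen

    def _complete_roles_generic(self, ts_coords: np.ndarray) -> dict | None:
        ts = self.ts_dict(ts_coords)
        placed = dict(self.anchors)
        placed["TS"] = ts
        chosen: dict[str, tuple] = {}
        used = set()
        for role in self.completion_roles:
            best = None
            for key, atom_map in self.candidates[role.role_id]:
                if key in used:
                    continue
                cost = 0.0
                tie = 0.0
                feasible = True
                for c in self.role_constraints[role.role_id]:
                    pts = []
                    for owner, logical in c.atoms:
                        if owner == role.role_id:
                            pts.append(atom_map[logical])
                        elif owner == "TS":
                            pts.append(ts[logical])
                        elif owner in placed and logical in placed[owner]:
                            pts.append(placed[owner][logical])
                        else:
                            feasible = False
                            break
                    if not feasible:
                        break
                    val = geometry.measure(c.kind, pts)
                    ex = c.excess(val)
                    cost += c.weight * ex * ex
                    tie += abs(val - c.target)
                if not feasible:
                    continue
                rank = (cost, tie, key)
                if best is None or rank < best[0]:
                    best = (rank, key, atom_map)
            if best is None:
                return None
            chosen[role.role_id] = (best[1], best[2])
            used.add(best[1])
            placed[role.role_id] = best[2]
        return chosen

    def penalty(self, ts_coords: np.ndarray, chosen: dict) -> float:
        if self._fast is not None:
            return self._penalty_fast(ts_coords, chosen)
        return self._penalty_generic(ts_coords, chosen)

    def _penalty_fast(self, ts_coords: np.ndarray, chosen: dict) -> float:
        total = 0.0

        def point(ep):
            return ts_coords[ep[1]] if ep[0] == "ts" else ep[1]

        for e1, e2, c in self._fast["core"]:
            d = float(np.linalg.norm(point(e1) - point(e2)))
            ex = c.excess(d)
            total += c.weight * ex * ex
        for role_id, (_key, atom_map) in chosen.items():
            for logical, other, c in self._fast["per_role"][role_id]:
                d = float(np.linalg.norm(atom_map[logical] - point(other)))
                ex = c.excess(d)
                total += c.weight * ex * ex
        return total

    def _penalty_generic(self, ts_coords: np.ndarray, chosen: dict) -> float:
        placed = dict(self.anchors)
        placed["TS"] = self.ts_dict(ts_coords)
        for role_id, (_key, atom_map) in chosen.items():
            placed[role_id] = atom_map
        total = 0.0
        for c in self.model.constraints:
            pts = [placed[o][l] for o, l in c.atoms]
            ex = c.excess(geometry.measure(c.kind, pts))
            total += c.weight * ex * ex
        return total

    def full_penalty(self, ts_coords: np.ndarray, chosen: dict):
        placed = dict(self.anchors)
        placed["TS"] = self.ts_dict(ts_coords)
        for role_id, (_key, atom_map) in chosen.items():
            placed[role_id] = atom_map
        return constraint_penalty(self.model, placed)


def place_and_score(
    structure: ProteinStructure,
    triple: dict[str, tuple[str, int]],
    model: ActiveSiteModel | None = None,
    config: MatchConfig | None = None,
) -> MatchResult | None:
    """Place the TS against one triad assignment and score the geometry.

    ``triple`` maps the three triad role ids to (chain, seq_pos).  Returns a
    :class:`MatchResult` (regardless of cutoff; the caller filters), or None
    when a required completion role cannot be filled or the nucleophile lacks
    its anchor atom.  Deterministic.
    """
    model = model or default_model()
    config = config or MatchConfig()
    scorer = _SiteScorer(structure, model, triple)
    og = scorer.anchors["nucleophile_ser"].get("OG")
    if og is None:
        return None
    # triad-internal geometry bounds the penalty from below; skip the pose
    # search when that floor already exceeds the reporting cutoff
    if scorer.fixed_floor() > config.penalty_cutoff:
        return None

    base = scorer.base_coords
    names = scorer.ts_names
    i_c1 = names.index(model.ts.tetrahedral_center)
    i_on = names.index("ON") if "ON" in names else None
    attack_c = next(
        (c for c in model.constraints if c.label == "nucleophile_attack_distance"), None
    )
    d_attack = attack_c.target if attack_c else 2.5

    # local frame of the base TS: C1 at origin, ON direction as attack axis
    c1_0 = base[i_c1]
    if i_on is not None:
        axis0 = (base[i_on] - c1_0) / np.linalg.norm(base[i_on] - c1_0)
    else:
        axis0 = np.array([1.0, 0.0, 0.0])

    # coarse scan: C1 placed d_attack from OG along -dir, ON axis aligned to dir
    dirs = _fibonacci_sphere(config.n_directions)
    spins = np.linspace(0, 2 * np.pi, config.n_spins, endpoint=False)
    scored: list[tuple[float, np.ndarray]] = []
    for direction in dirs:
        r_align = Rotation.align_vectors([direction], [axis0])[0].as_matrix()
        c1_pos = og - d_attack * direction
        for spin in spins:
            r_spin = _axis_rot(direction, spin)
            rot = r_spin @ r_align
            coords = (base - c1_0) @ rot.T + c1_pos
            chosen = scorer.complete_roles(coords)
            if chosen is None:
                return None
            scored.append((scorer.penalty(coords, chosen), coords))
    scored.sort(key=lambda t: t[0])

    best_pen, best_coords, best_chosen = np.inf, None, None
    for pen0, coords0 in scored[: config.n_refine_starts]:
        coords, pen, chosen = _refine_pose(scorer, coords0)
        if pen < best_pen:
            best_pen, best_coords, best_chosen = pen, coords, chosen
        if best_pen < 1e-12:
            break
    if best_coords is None:
        return None

    pen_full, breakdown = scorer.full_penalty(best_coords, best_chosen)
    assignment = dict(triple)
    rotamers: dict[str, dict[str, np.ndarray]] = {}
    for role_id in TRIAD_ROLES:
        res = structure.residue(*triple[role_id])
        rotamers[role_id] = {a.name: a.coords.copy() for a in res.atoms if not a.is_backbone}
    for role_id, (key, atom_map) in best_chosen.items():
        assignment[role_id] = key
        rotamers[role_id] = {k: v.copy() for k, v in atom_map.items()}
    return MatchResult(
        scaffold_id=structure.id,
        role_assignment=assignment,
        placed_rotamers=rotamers,
        ts_pose=scorer.ts_dict(best_coords),
        penalty=pen_full,
        breakdown=breakdown,
    )


def _axis_rot(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(axis, float) * angle).as_matrix()


def _refine_pose(scorer: _SiteScorer, coords0: np.ndarray):
    """Rigid-body penalty minimisation with one completion re-selection."""
    centroid = coords0.mean(axis=0)
    local = coords0 - centroid
    chosen = scorer.complete_roles(coords0)

    def transform(x):
        rot = Rotation.from_rotvec(x[3:6]).as_matrix()
        return local @ rot.T + centroid + x[:3]

    def objective(x):
        return scorer.penalty(transform(x), chosen)

    x = np.zeros(6)
    for _round in range(2):
        res = minimize(objective, x, method="Powell",
                       options={"xtol": 1e-6, "ftol": 1e-10, "maxiter": 4000})
        x = res.x
        coords = transform(x)
        new_chosen = scorer.complete_roles(coords)
        if new_chosen is None or all(
            new_chosen[r][0] == chosen[r][0] for r in new_chosen
        ):
            chosen = new_chosen or chosen
            break
        chosen = new_chosen
    coords = transform(x)
    return coords, scorer.penalty(coords, chosen), chosen


# ---------------------------------------------------------------------------
# Enumeration, ranking, native comparison
# ---------------------------------------------------------------------------

def candidate_positions(
    structure: ProteinStructure,
    model: ActiveSiteModel,
    allowed_keys: set | None = None,
) -> dict[str, list[tuple[str, int]]]:
    """Admissible (chain, seq_pos) per triad role under the anchoring rules."""
    out: dict[str, list] = {r: [] for r in TRIAD_ROLES}
    for res in structure.residues:
        if res.is_hetero:
            continue
        if allowed_keys is not None and res.key not in allowed_keys:
            continue
        for role_id in TRIAD_ROLES:
            role = model.role(role_id)
            if res.aa_type in role.allowed_aa:
                concrete = {
                    role.concrete_atom(l, res.aa_type) for l in role.anchor_atoms
                }
                if all(res.has_atom(c) for c in concrete):
                    out[role_id].append(res.key)
    return out


def match_active_site(
    structure: ProteinStructure,
    model: ActiveSiteModel | None = None,
    config: MatchConfig | None = None,
) -> list[MatchResult]:
    """Enumerate triad assignments, place the TS and report sub-cutoff matches.

    With ``config.restrict_to_pockets`` the triad candidates are limited to
    members of the three largest detected pockets (large-scaffold mode);
    otherwise the whole chain is searched.
    """
    model = model or default_model()
    config = config or MatchConfig()
    allowed = None
    if config.restrict_to_pockets:
        pockets = detect_pockets(structure)
        allowed = {pos for p in pockets for pos in p.member_positions}
    cands = candidate_positions(structure, model, allowed)
    results = []
    for ser in cands["nucleophile_ser"]:
        for his in cands["base_his"]:
            for acid in cands["acid_asp_glu"]:
                if len({ser, his, acid}) != 3:
                    continue
                triple = {
                    "nucleophile_ser": ser,
                    "base_his": his,
                    "acid_asp_glu": acid,
                }
                m = place_and_score(structure, triple, model, config)
                if m is not None and m.penalty <= config.penalty_cutoff:
                    results.append(m)
    return rank_matches(results)


def _triad_compactness(match: MatchResult, structure: ProteinStructure | None = None) -> float:
    pts = []
    for role_id in TRIAD_ROLES:
        rot = match.placed_rotamers.get(role_id, {})
        if rot:
            pts.append(np.mean(list(rot.values()), axis=0))
    if len(pts) < 2:
        return 0.0
    return float(sum(np.linalg.norm(a - b) for a, b in itertools.combinations(pts, 2)))


def rank_matches(matches: list[MatchResult]) -> list[MatchResult]:
    """Ascending penalty; ties broken by triad compactness then positions."""
    def sort_key(m: MatchResult):
        positions = tuple(sorted(m.role_assignment.items()))
        return (round(m.penalty, 9), round(_triad_compactness(m), 6), positions)

    return sorted(matches, key=sort_key)


def triad_rmsd_vs_native(match: MatchResult, structure: ProteinStructure) -> float:
    """RMSD (same frame, no re-superposition) between placed triad side-chain
    atoms and the scaffold's native conformations at the matched positions."""
    placed_pts, native_pts, missing = [], [], []
    for role_id in TRIAD_ROLES:
        key = match.role_assignment[role_id]
        res = structure.residue(*key)
        for name, pos in sorted(match.placed_rotamers[role_id].items()):
            if name.startswith("H"):
                continue
            if not res.has_atom(name):
                missing.append(f"{key[0]}{key[1]}:{name}")
                continue
            placed_pts.append(pos)
            native_pts.append(res.atom(name).coords)
    if missing:
        raise ValueError(f"native atoms missing: {missing}")
    return geometry.kabsch_rmsd(np.array(native_pts), np.array(placed_pts), superpose_first=False)
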