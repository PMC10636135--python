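"""Synthetic data generators with planted ground truth.

Every generator is deterministic given its seed and returns both the data and
a *truth record* describing what was planted, so downstream tests can compare
recovered quantities against construction parameters:

* :func:`make_toy_scaffold` - a small protein with a Ser-His-Asp triad, two
  oxyanion-hole N-H donors and a carboxylate-binding Ser placed at (or at
  stated offsets from) the active-site constraint targets, plus decoys;
* :func:`synth_frames` - trajectory frame sets in which each catalytic
  indicator's geometric event occurs in exactly ``round(p * n)`` frames
  (a Bernoulli mode exists for statistical tests);
* :func:`synth_kinetics` - Michaelis-Menten initial rates with multiplicative
  log-normal noise;
* :func:`synth_timecourse` - cumulative product release tables for the PET
  conversion arithmetic;
* :func:`synth_design_set` - ddG fields for the candidate-selection filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import active_site as asite
from . import sidechains
from .geometry import nerf_place
from .structio import Atom3D, ProteinStructure, ResidueRecord

__all__ = [
    "make_toy_scaffold",
    "make_shell_scaffold",
    "synth_frames",
    "synth_kinetics",
    "synth_timecourse",
    "synth_design_set",
    "synth_funnel_inputs",
    "DEFAULT_WT_PROBS",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b (Rodrigues)."""
    a = _unit(np.asarray(a, float))
    b = _unit(np.asarray(b, float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = _unit(np.cross(a, perp))
        return _axis_rotation(axis, np.pi)
    axis = _unit(v)
    return _axis_rotation(axis, np.arccos(np.clip(c, -1, 1)))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, float))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _sphere_circle_point(c1, r1, c2, r2, prefer_away_from) -> np.ndarray:
    """A point on the intersection circle of two spheres, chosen as far as
    possible from ``prefer_away_from``."""
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    d = np.linalg.norm(c2 - c1)
    if d > r1 + r2 or d < abs(r1 - r2) or d < 1e-9:
        raise ValueError("spheres do not intersect")
    a = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    h = np.sqrt(max(r1 * r1 - a * a, 0.0))
    axis = _unit(c2 - c1)
    center = c1 + a * axis
    # orthonormal basis of the circle plane
    perp = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(axis, perp))
    v = np.cross(axis, u)
    best, best_d = None, -1.0
    for th in np.linspace(0, 2 * np.pi, 36, endpoint=False):
        p = center + h * (np.cos(th) * u + np.sin(th) * v)
        dist = np.linalg.norm(p - np.asarray(prefer_away_from, float))
        if dist > best_d:
            best, best_d = p, dist
    return best


def _plant_residue(
    aa: str,
    chis: list[float],
    anchor_atom: str,
    anchor_pos: np.ndarray,
    outward: np.ndarray,
    existing_coords: np.ndarray,
    rng: np.random.Generator,
    chain_id: str = "A",
    seq_pos: int = 1,
) -> ResidueRecord:
    """Build an ideal residue and rigidly place it so ``anchor_atom`` sits at
    ``anchor_pos`` with the residue body pointing ``outward``; the spin about
    the outward axis is chosen to maximise clearance from existing atoms."""
    template = sidechains.build_residue(aa, chis, chain_id=chain_id, seq_pos=seq_pos)
    pts = {a.name: a.coords.copy() for a in template.atoms}
    anchor = pts[anchor_atom]
    centroid = np.mean(list(pts.values()), axis=0)
    body_dir = centroid - anchor
    if np.linalg.norm(body_dir) < 1e-6:
        body_dir = pts["CA"] - anchor
    rot0 = _rotation_between(body_dir, outward)
    placed0 = {n: rot0 @ (p - anchor) for n, p in pts.items()}

    best_atoms, best_clearance = None, -1.0
    for spin in np.linspace(0, 2 * np.pi, 24, endpoint=False):
        rs = _axis_rotation(outward, spin)
        cand = {n: rs @ p + anchor_pos for n, p in placed0.items()}
        arr = np.array(list(cand.values()))
        if existing_coords.size:
            dmin = float(
                np.min(np.linalg.norm(arr[:, None, :] - existing_coords[None, :, :], axis=2))
            )
        else:
            dmin = np.inf
        # the anchor itself legitimately sits near its partner; clearance is
        # judged on non-anchor atoms
        non_anchor = np.array([p for n, p in cand.items() if n != anchor_atom])
        if existing_coords.size:
            dmin = float(
                np.min(
                    np.linalg.norm(non_anchor[:, None, :] - existing_coords[None, :, :], axis=2)
                )
            )
        if dmin > best_clearance:
            best_clearance = dmin
            best_atoms = cand

    atoms = []
    for a in template.atoms:
        atoms.append(
            Atom3D(
                name=a.name,
                element=a.element,
                coords=best_atoms[a.name],
                is_backbone=a.is_backbone,
                is_polar_h=a.is_polar_h,
            )
        )
    return ResidueRecord(chain_id=chain_id, seq_pos=seq_pos, aa_type=aa, atoms=atoms)


# ---------------------------------------------------------------------------
# toy scaffold with planted active site
# ---------------------------------------------------------------------------

_DECOY_AA = "AVLIFGMW"  # apolar decoys that can never take a catalytic role


def make_toy_scaffold(
    seed: int = 0,
    n_decoy_residues: int = 10,
    offsets: dict[str, float] | None = None,
    extra_sites: dict[str, int] | None = None,
    model: asite.ActiveSiteModel | None = None,
    decoy_radius: tuple[float, float] = (9.0, 14.0),
):
    """A toy scaffold with one planted MHET-hydrolysis active site.

    ``offsets`` maps a constraint label to an outward displacement in A of
    the corresponding planted anchor *beyond* the upper tolerance bound
    (0 or absent = anchor at the constraint target).  Supported labels:
    ``nucleophile_attack_distance``, ``oxyanion_hbond_1``, ``oxyanion_hbond_2``,
    ``carboxylate_hbond``, ``asp_his_relay``.

    ``extra_sites`` may request additional non-planted residues of catalytic
    types, e.g. ``{"S": 1, "H": 1, "D": 1}``, to exercise enumeration.

    Returns ``(structure, truth)``; ``truth`` records planted positions, the
    TS pose and the expected penalty of the planted geometry.
    """
    rng = np.random.default_rng(seed)
    model = model or asite.default_model()
    offsets = offsets or {}
    ts = asite.build_default_ts_molecule()
    a = ts.atoms
    site_center = a["C1"]

    def offset_of(label: str) -> float:
        return float(offsets.get(label, 0.0))

    def window(label: str):
        for c in model.constraints:
            if c.label == label:
                return c
        raise KeyError(label)

    def planted_value(label: str) -> float:
        """Target if no offset requested, else tol_hi + offset."""
        c = window(label)
        off = offset_of(label)
        return c.target if off == 0.0 else c.tol_hi + off

    # --- nucleophile Ser: OG on the C1 -> ON ray ---
    d_og = planted_value("nucleophile_attack_distance")
    og_pos = a["C1"] + d_og * _unit(a["ON"] - a["C1"])

    # --- His NE2: on the sphere intersection around OG and O2 ---
    ne2_pos = _sphere_circle_point(
        og_pos, window("his_ser_relay").target, a["O2"], window("his_leaving_group").target,
        prefer_away_from=site_center,
    )

    # --- oxyanion donors: two directions fanned around the O1 lone pairs ---
    u_o1 = _unit(a["O1"] - a["C1"])
    fan_axis = _unit(np.cross(u_o1, a["O2"] - a["C1"]))
    d1 = _axis_rotation(fan_axis, np.radians(45.0)) @ u_o1
    d2 = _axis_rotation(fan_axis, np.radians(-45.0)) @ u_o1
    n1_pos = a["O1"] + planted_value("oxyanion_hbond_1") * d1
    n2_pos = a["O1"] + planted_value("oxyanion_hbond_2") * d2

    # --- carboxylate binder: OG off the O4 oxygen, outward ---
    binder_pos = a["O4"] + planted_value("carboxylate_hbond") * _unit(a["O4"] - a["C7"])

    existing = ts.coords_array()
    residues: list[ResidueRecord] = []

    def add(res: ResidueRecord):
        nonlocal existing
        residues.append(res)
        existing = np.vstack([existing, np.array([at.coords for at in res.atoms])])

    ser = _plant_residue(
        "S", [62.0, 180.0], "OG", og_pos, _unit(og_pos - site_center), existing, rng
    )
    add(ser)
    his = _plant_residue(
        "H", [-65.0, -70.0], "NE2", ne2_pos, _unit(ne2_pos - site_center), existing, rng
    )
    add(his)
    # Asp OD1 relative to the placed His ND1, pointing away from the ring
    nd1 = his.atom("ND1").coords
    ring_centroid = np.mean(
        [his.atom(n).coords for n in ("CG", "ND1", "CD2", "CE1", "NE2")], axis=0
    )
    od1_pos = nd1 + planted_value("asp_his_relay") * _unit(nd1 - ring_centroid)
    asp = _plant_residue(
        "D", [-70.0, -15.0], "OD1", od1_pos, _unit(od1_pos - site_center), existing, rng
    )
    add(asp)
    don1 = _plant_residue("A", [], "N", n1_pos, _unit(n1_pos - site_center), existing, rng)
    add(don1)
    don2 = _plant_residue("A", [], "N", n2_pos, _unit(n2_pos - site_center), existing, rng)
    add(don2)
    binder = _plant_residue(
        "S", [-65.0, 180.0], "OG", binder_pos, _unit(binder_pos - site_center), existing, rng
    )
    add(binder)

    # --- extra catalytic-type residues (for enumeration tests) + decoys ---
    base = sidechains.base_rotamers()
    extra_list: list[str] = []
    for aa_type, count in (extra_sites or {}).items():
        extra_list.extend([aa_type] * count)
    decoy_aas = [str(rng.choice(list(_DECOY_AA))) for _ in range(n_decoy_residues)]
    for aa_type in extra_list + decoy_aas:
        for _attempt in range(60):
            direction = rng.normal(size=3)
            direction = _unit(direction)
            radius = rng.uniform(*decoy_radius)
            pos = site_center + radius * direction
            chis = list(base[aa_type][rng.integers(len(base[aa_type]))]) if base[aa_type] else []
            cand = _plant_residue(
                aa_type, [float(c) for c in chis], "CA", pos, direction, existing, rng
            )
            arr = np.array([at.coords for at in cand.atoms])
            dmin = float(
                np.min(np.linalg.norm(arr[:, None, :] - existing[None, :, :], axis=2))
            )
            if dmin > 3.0:
                add(cand)
                break
        else:
            add(cand)  # accept the last attempt rather than fail

    # shuffle residue order and assign author numbering
    order = rng.permutation(len(residues))
    final = []
    planted_keys = {}
    labels = ["nucleophile_ser", "base_his", "acid_asp_glu",
              "oxyanion_nh_1", "oxyanion_nh_2", "carboxylate_binder_ser"]
    for new_pos, idx in enumerate(order, start=1):
        r = residues[idx]
        r.seq_pos = new_pos
        final.append(r)
        if idx < 6:
            planted_keys[labels[idx]] = ("A", new_pos)
    final.sort(key=lambda r: r.seq_pos)

    structure = ProteinStructure(
        id=f"toy-{seed}", residues=final, source_meta={"generator": "make_toy_scaffold"}
    )

    # expected penalty of the planted geometry, from the model itself
    placed = {"TS": {n: ts.atoms[n] for n in ts.atoms}}
    anchor_map = {
        "nucleophile_ser": ("OG", og_pos),
        "base_his": None,
        "acid_asp_glu": None,
        "oxyanion_nh_1": ("N", n1_pos),
        "oxyanion_nh_2": ("N", n2_pos),
        "carboxylate_binder_ser": ("OG", binder_pos),
    }
    by_label = {r: structure.residue(*planted_keys[r]) for r in planted_keys}
    placed["nucleophile_ser"] = {"OG": by_label["nucleophile_ser"].atom("OG").coords,
                                 "CB": by_label["nucleophile_ser"].atom("CB").coords}
    placed["base_his"] = {"NE2": by_label["base_his"].atom("NE2").coords,
                          "ND1": by_label["base_his"].atom("ND1").coords}
    placed["acid_asp_glu"] = {"OD": by_label["acid_asp_glu"].atom("OD1").coords}
    placed["oxyanion_nh_1"] = {"N": by_label["oxyanion_nh_1"].atom("N").coords}
    placed["oxyanion_nh_2"] = {"N": by_label["oxyanion_nh_2"].atom("N").coords}
    placed["carboxylate_binder_ser"] = {"OG": by_label["carboxylate_binder_ser"].atom("OG").coords}
    expected_penalty, breakdown = asite.constraint_penalty(model, placed)

    truth = {
        "planted_positions": planted_keys,
        "ts_pose": {n: ts.atoms[n].copy() for n in ts.atoms},
        "expected_penalty": expected_penalty,
        "penalty_breakdown": breakdown,
        "offsets": dict(offsets),
        "seed": seed,
    }
    return structure, truth


# ---------------------------------------------------------------------------
# shell scaffolds for pocket detection
# ---------------------------------------------------------------------------

def make_shell_scaffold(
    kind: str = "cup",
    seed: int = 0,
    radius: float = 8.0,
    second_radius: float = 5.5,
):
    """Scaffolds with engineered concavities for pocket detection tests.

    ``kind``:
      * ``"helix"`` - residues along a straight helix (convex, no cavity);
      * ``"cup"`` - a hemispherical shell open on one side (one pocket);
      * ``"two"`` - two cups of different sizes back to back (two pockets,
        larger first).

    Returns ``(structure, truth)`` with the lining residue keys per pocket.
    """
    rng = np.random.default_rng(seed)
    residues: list[ResidueRecord] = []
    lining: dict[str, list] = {}

    def add_at(pos, aa="A"):
        i = len(residues) + 1
        bb = {
            "N": pos + np.array([-0.5, 1.36, 0.0]),
            "CA": pos,
            "C": pos + np.array([1.53, 0.0, 0.0]),
            "O": pos + np.array([2.15, 1.05, 0.0]),
        }
        res = sidechains.build_residue(aa, [], seq_pos=i, backbone=bb)
        res.seq_pos = i
        residues.append(res)
        return res

    def cup(center, r, axis, n_rings=4):
        """Hemispherical shell opening along +axis; returns lining residues."""
        axis = _unit(np.asarray(axis, float))
        perp = np.array([1.0, 0.0, 0.0])
        if abs(axis[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(axis, perp))
        v = np.cross(axis, u)
        members = []
        for i_ring in range(n_rings):
            phi = np.radians(95.0 + i_ring * (80.0 / max(n_rings - 1, 1)))  # 95..175 deg
            ring_r = r * np.sin(phi)
            z = r * np.cos(phi)
            n_pts = max(int(round(2 * np.pi * ring_r / 3.4)), 1)
            for k in range(n_pts):
                th = 2 * np.pi * k / n_pts
                pos = center + z * axis + ring_r * (np.cos(th) * u + np.sin(th) * v)
                members.append(add_at(pos))
        return members

    if kind == "helix":
        # alpha-helical rod: 2.3 A radius, 100 deg per residue, 1.5 A rise --
        # compact and convex, with no interior void at probe resolution
        for i in range(24):
            th = i * 100.0 * np.pi / 180
            pos = np.array([2.3 * np.cos(th), 2.3 * np.sin(th), i * 1.5])
            add_at(pos)
        truth = {"pockets": []}
    elif kind == "cup":
        members = cup(np.zeros(3), radius, np.array([0.0, 0.0, 1.0]))
        truth = {"pockets": [[(r.chain_id, r.seq_pos) for r in members]]}
    elif kind == "two":
        m1 = cup(np.zeros(3), radius, np.array([0.0, 0.0, 1.0]))
        offset = np.array([0.0, 0.0, -(radius + second_radius + 6.0)])
        m2 = cup(offset, second_radius, np.array([0.0, 0.0, -1.0]))
        truth = {
            "pockets": [
                [(r.chain_id, r.seq_pos) for r in m1],
                [(r.chain_id, r.seq_pos) for r in m2],
            ]
        }
    else:
        raise ValueError(f"unknown shell kind {kind!r}")

    structure = ProteinStructure(
        id=f"shell-{kind}-{seed}", residues=residues,
        source_meta={"generator": "make_shell_scaffold"},
    )
    return structure, truth


# ---------------------------------------------------------------------------
# trajectory frame ensembles with prescribed indicator fractions
# ---------------------------------------------------------------------------

INDICATOR_KEYS = ("rmsd", "attack", "hbond1", "hbond2")
DEFAULT_WT_PROBS = {"rmsd": 0.60, "attack": 0.12, "hbond1": 0.50, "hbond2": 0.40}


def _frame_template():
    """Template atom roster and coordinates for synthetic trajectories.

    A minimal labelled system: a nucleophile serine (O-gamma 2.6 A from the
    sp3 carbon), two alanine oxyanion donors (N 2.9 A from the oxyanion O,
    amide H on the N->O line), and the TS as hetero residue TSM.  Each
    catalytic indicator has a dedicated "event off" modification touching
    atoms no other indicator reads.
    """
    from .md_screen import LabelingConfig

    ts = asite.build_default_ts_molecule()
    a = ts.atoms
    og_good = a["C1"] + 2.6 * _unit(a["ON"] - a["C1"])
    og_bad = a["C1"] + 3.6 * _unit(a["ON"] - a["C1"])
    u_o1 = _unit(a["O1"] - a["C1"])
    fan_axis = _unit(np.cross(u_o1, a["O2"] - a["C1"]))
    d1 = _axis_rotation(fan_axis, np.radians(45.0)) @ u_o1
    d2 = _axis_rotation(fan_axis, np.radians(-45.0)) @ u_o1
    n1_good, n1_bad = a["O1"] + 2.9 * d1, a["O1"] + 4.0 * d1
    n2_good, n2_bad = a["O1"] + 2.9 * d2, a["O1"] + 4.0 * d2
    h1 = n1_good + 1.0 * _unit(a["O1"] - n1_good)
    h2 = n2_good + 1.0 * _unit(a["O1"] - n2_good)

    roster: list[tuple[str, int, str, str]] = []
    coords: list[np.ndarray] = []

    def put(chain, seq, resname, atom, pos):
        roster.append((chain, seq, resname, atom))
        coords.append(np.asarray(pos, dtype=float))

    # residue 1: nucleophile serine (backbone placed outward from OG)
    rng = np.random.default_rng(12345)
    ser = _plant_residue("S", [62.0, 180.0], "OG", og_good,
                         _unit(og_good - a["C1"]), ts.coords_array(), rng)
    for at in ser.atoms:
        put("A", 1, "SER", at.name, at.coords)
    # residues 2, 3: alanine donors with explicit amide H
    for seq, (npos, hpos, direction) in (
        (2, (n1_good, h1, d1)), (3, (n2_good, h2, d2)),
    ):
        ala = _plant_residue("A", [], "N", npos, direction,
                             ts.coords_array(), rng)
        for at in ala.atoms:
            put("A", seq, "ALA", at.name, at.coords)
        put("A", seq, "ALA", "H", hpos)
    # TS hetero residue
    for name in ts.atoms:
        put("T", 1, "TSM", name, ts.atoms[name])

    index = {(c, s, at): i for i, (c, s, _r, at) in enumerate(roster)}
    ts_heavy_count = len(ts.atoms)
    # RMSD event-off displacement: one distal TS atom moved so the TS
    # heavy-atom RMSD (backbone fixed) lands well above the 2.5 A cutoff
    rmsd_target = 4.0
    delta = rmsd_target * np.sqrt(ts_heavy_count)
    o3_bad = a["O3"] + delta * _unit(a["O3"] - a["C1"])

    mods = {
        "rmsd": [(index[("T", 1, "O3")], o3_bad)],
        "attack": [(index[("A", 1, "OG")], og_bad)],
        "hbond1": [(index[("A", 2, "N")], n1_bad),
                   (index[("A", 2, "H")], n1_bad + 1.0 * _unit(a["O1"] - n1_good))],
        "hbond2": [(index[("A", 3, "N")], n2_bad),
                   (index[("A", 3, "H")], n2_bad + 1.0 * _unit(a["O1"] - n2_good))],
    }
    labeling = LabelingConfig(ser_og=("A", 1, "OG"), donor1=("A", 2), donor2=("A", 3))
    return np.array(coords), roster, labeling, mods


_TEMPLATE_CACHE: dict = {}


def _cached_template():
    if "t" not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE["t"] = _frame_template()
    return _TEMPLATE_CACHE["t"]


def synth_frames(
    probabilities: dict[str, float],
    n_frames: int = 100,
    n_replicates: int = 1,
    seed: int = 0,
    bernoulli: bool = False,
    design_id: str = "design",
    frame_interval_ps: float = 10.0,
):
    """Frame sets in which each indicator holds in a prescribed fraction.

    In deterministic mode (default) the event occurs in exactly
    ``round(p * n_frames)`` frames per replicate, at seeded random frame
    positions; in Bernoulli mode each frame draws the event independently.
    The first frame always satisfies the RMSD indicator (it is its own
    reference), so ``round(p_rmsd * n_frames)`` must be at least 1.

    Returns ``(frame_sets, truth)`` with per-replicate planted fractions.
    """
    from .md_screen import FrameSet

    probs = {k: float(probabilities[k]) for k in INDICATOR_KEYS}
    for k, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {k} outside [0, 1]")
    if round(probs["rmsd"] * n_frames) < 1:
        raise ValueError(
            "rmsd fraction must allow at least one event frame "
            "(the reference frame always satisfies it)"
        )
    template, roster, labeling, mods = _cached_template()
    from .md_screen import _resolve_labels

    labels = _resolve_labels(roster, labeling)
    rng = np.random.default_rng(seed)

    frame_sets = []
    truth_fracs = []
    for rep in range(n_replicates):
        event_frames: dict[str, np.ndarray] = {}
        for key in INDICATOR_KEYS:
            p = probs[key]
            if bernoulli:
                ev = rng.random(n_frames) < p
                if key == "rmsd":
                    ev[0] = True
            else:
                k_count = int(round(p * n_frames))
                ev = np.zeros(n_frames, dtype=bool)
                if key == "rmsd":
                    rest = rng.permutation(np.arange(1, n_frames))[: k_count - 1]
                    ev[0] = True
                    ev[rest] = True
                else:
                    ev[rng.permutation(n_frames)[:k_count]] = True
            event_frames[key] = ev
        coords = np.repeat(template[None, :, :], n_frames, axis=0)
        for key in INDICATOR_KEYS:
            off = ~event_frames[key]
            for atom_idx, bad_pos in mods[key]:
                coords[off, atom_idx, :] = bad_pos
        frame_sets.append(
            FrameSet(
                design_id=design_id,
                replicate_id=rep,
                coords=coords,
                roster=list(roster),
                labels=labels,
                frame_interval_ps=frame_interval_ps,
            )
        )
        truth_fracs.append({k: float(np.mean(event_frames[k])) for k in INDICATOR_KEYS})
    truth = {
        "probabilities": probs,
        "per_replicate_fractions": truth_fracs,
        "pooled_fractions": {
            k: float(np.mean([t[k] for t in truth_fracs])) for k in INDICATOR_KEYS
        },
        "bernoulli": bernoulli,
        "seed": seed,
    }
    return frame_sets, truth


def synth_funnel_inputs(
    seed: int = 0,
    n_designs: int = 237,
    n_round1: int = 118,
    n_round2: int = 94,
    wt_probs: dict[str, float] | None = None,
    n_frames_r1: int = 100,
    reps_r1: int = 10,
    n_frames_r2: int = 500,
    reps_r2: int = 5,
):
    """A planted-truth cohort for the two-round screening funnel.

    ``n_round1`` of the ``n_designs`` designs improve all four indicators
    over the wild type in round 1; of those, ``n_round2`` improve again in
    round 2.  Indicator fractions are laid out on a 0.01 grid so strict
    comparisons are exact in deterministic mode.  Returns
    ``(designs_round1, wt_round1, round2_provider, wt_round2, truth)``;
    round-2 trajectories are generated lazily per design.
    """
    if not 0 < n_round2 <= n_round1 <= n_designs:
        raise ValueError("need n_round2 <= n_round1 <= n_designs")
    wt = dict(wt_probs or DEFAULT_WT_PROBS)
    rng = np.random.default_rng(seed)

    ids = [f"d{i:03d}" for i in range(n_designs)]
    improved_r1 = set(rng.choice(ids, size=n_round1, replace=False).tolist())
    improved_r2 = set(
        rng.choice(sorted(improved_r1), size=n_round2, replace=False).tolist()
    )

    def draw_probs(improve: bool, rng_local) -> dict[str, float]:
        out = {}
        worsen = None
        if not improve:
            worsen = set(
                rng_local.choice(
                    INDICATOR_KEYS,
                    size=int(rng_local.integers(1, len(INDICATOR_KEYS) + 1)),
                    replace=False,
                ).tolist()
            )
        for k in INDICATOR_KEYS:
            if improve or k not in worsen:
                delta = rng_local.integers(2, 31) / 100.0
                out[k] = min(round(wt[k] + delta, 2), 0.99)
            else:
                delta = rng_local.integers(0, 11) / 100.0
                out[k] = max(round(wt[k] - delta, 2), 0.01)
        return out

    probs_r1: dict[str, dict[str, float]] = {}
    probs_r2: dict[str, dict[str, float]] = {}
    for i, design_id in enumerate(ids):
        rng_d = np.random.default_rng((seed, 1, i))
        probs_r1[design_id] = draw_probs(design_id in improved_r1, rng_d)
        rng_d2 = np.random.default_rng((seed, 2, i))
        probs_r2[design_id] = draw_probs(design_id in improved_r2, rng_d2)

    designs_round1 = {}
    for i, design_id in enumerate(ids):
        fs, _ = synth_frames(
            probs_r1[design_id], n_frames=n_frames_r1, n_replicates=reps_r1,
            seed=int(np.random.default_rng((seed, 3, i)).integers(2**31)),
            design_id=design_id,
        )
        designs_round1[design_id] = fs
    wt_r1, _ = synth_frames(
        wt, n_frames=n_frames_r1, n_replicates=reps_r1,
        seed=int(np.random.default_rng((seed, 4)).integers(2**31)), design_id="WT",
    )
    wt_r2, _ = synth_frames(
        wt, n_frames=n_frames_r2, n_replicates=reps_r2,
        seed=int(np.random.default_rng((seed, 5)).integers(2**31)), design_id="WT",
    )

    id_index = {d: i for i, d in enumerate(ids)}

    def round2_provider(design_id: str):
        if design_id not in id_index:
            return None
        fs, _ = synth_frames(
            probs_r2[design_id], n_frames=n_frames_r2, n_replicates=reps_r2,
            seed=int(np.random.default_rng((seed, 6, id_index[design_id])).integers(2**31)),
            design_id=design_id,
        )
        return fs

    truth = {
        "round1_improved": sorted(improved_r1),
        "round2_improved": sorted(improved_r2),
        "wt_probs": wt,
        "seed": seed,
    }
    return designs_round1, wt_r1, round2_provider, wt_r2, truth


# ---------------------------------------------------------------------------
# kinetics / product tables
# ---------------------------------------------------------------------------

DEFAULT_SUBSTRATE_GRID_MM = (2.0, 3.2, 5.0, 8.0, 12.6, 20.0)  # geometric, assay range


def synth_kinetics(
    kcat: float,
    Km: float,
    substrate_grid_mM=None,
    noise_cv: float = 0.05,
    n_rep: int = 3,
    seed: int = 0,
):
    """Michaelis-Menten initial rates with multiplicative log-normal noise.

    The default substrate grid spans the 2-20 mM assay range geometrically
    (better Km identifiability than linear spacing) with triplicate
    measurements.  ``noise_cv`` is the coefficient of variation of the
    multiplicative error; 0 gives exact rates.
    """
    from .kinetics_products import KineticMeasurement

    if kcat <= 0 or Km <= 0:
        raise ValueError("kcat and Km must be positive")
    grid = np.asarray(
        substrate_grid_mM if substrate_grid_mM is not None else DEFAULT_SUBSTRATE_GRID_MM,
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    out = []
    for rep in range(n_rep):
        for s in grid:
            v = kcat * s / (Km + s)
            if sigma > 0:
                v *= np.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2)
            out.append(KineticMeasurement(substrate_mM=float(s), v0_over_E=float(v),
                                          replicate_id=rep))
    return out


def synth_timecourse(
    seed: int = 0,
    pet_mass_g: float = 0.005,
    volume_L: float = 0.003,
    times_h=(4, 8, 12, 24, 36, 48),
    final_conversion: float = 0.83,
    tpa_share: float = 0.95,
    repeat_unit_g_mol: float = 192.17,
):
    """A cumulative product time course with exponential saturation.

    Products split between TPA (``tpa_share`` of released aromatic units)
    and MHET/BHET for the remainder; concentrations are in mM in
    ``volume_L``.  Returns ``(ProductTimeCourse, truth)`` with the exact
    per-time conversion fractions used for construction.
    """
    from .kinetics_products import ProductTimeCourse

    rng = np.random.default_rng(seed)
    times = np.asarray(times_h, dtype=float)
    k = -np.log(1 - 0.95) / times[-1]
    conv = final_conversion * (1 - np.exp(-k * times)) / (1 - np.exp(-k * times[-1]))
    theoretical_mM = pet_mass_g / repeat_unit_g_mol / volume_L * 1000.0
    total_mM = conv * theoretical_mM
    tpa = total_mM * tpa_share
    mhet = total_mM * (1 - tpa_share) * 0.7
    bhet = total_mM * (1 - tpa_share) * 0.3
    tc = ProductTimeCourse(
        times_h=times, conc_BHET_mM=bhet, conc_MHET_mM=mhet, conc_TPA_mM=tpa,
        pet_mass_g=pet_mass_g, volume_L=volume_L,
    )
    truth = {"conversion_frac": conv.copy(), "tpa_share": tpa_share,
             "theoretical_mM": theoretical_mM}
    return tc, truth


def synth_design_set(
    seed: int = 0,
    n_designs: int = 704,
    n_single: int = 104,
    n_double: int = 400,
    n_triple: int = 200,
    positions=(26, 122, 127, 130, 167, 171, 195, 196),
    alphabet: str = "AILMFWYVCSTKHRNQ",
):
    """Randomised ddG fields over a realistic mutant-class composition.

    Mimics a design output of 104 single, 400 double and 200 triple mutants
    with binding/folding energy changes drawn around zero; used to exercise
    the candidate-selection filter against a set-comprehension oracle.
    Returns ``(designs, truth)``.
    """
    from .design import SequenceDesign

    if n_single + n_double + n_triple != n_designs:
        raise ValueError("class counts must sum to n_designs")
    rng = np.random.default_rng(seed)
    wt_types = {p: "AKMGLIMI"[i] for i, p in enumerate(positions)}

    designs = []
    seen = set()
    for n_mut, count in ((1, n_single), (2, n_double), (3, n_triple)):
        made = 0
        while made < count:
            pos_sel = tuple(sorted(rng.choice(positions, size=n_mut, replace=False)))
            muts = []
            for p in pos_sel:
                new = str(rng.choice([c for c in alphabet if c != wt_types[p]]))
                muts.append(f"{wt_types[p]}{p}{new}")
            key = tuple(muts)
            if key in seen:
                continue
            seen.add(key)
            made += 1
            g_unbound = float(rng.normal(0.0, 6.0))
            g_bind = float(rng.normal(-1.0, 4.0))
            g_bound = g_bind + g_unbound
            designs.append(
                SequenceDesign(
                    mutations=list(muts),
                    aa_choice={("A", int(m[1:-1])): m[-1] for m in muts},
                    g_bound=g_bound,
                    g_unbound=g_unbound,
                    g_bind=g_bind,
                    g_fold=g_unbound,
                    ddg_bind=g_bind,      # wild-type reference at 0 by construction
                    ddg_fold=g_unbound,
                    ddg_total=g_bind + g_unbound,
                )
            )
    truth = {
        "class_counts": {1: n_single, 2: n_double, 3: n_triple},
        "seed": seed,
    }
    return designs, truth
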