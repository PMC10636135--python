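"""Vector geometry primitives shared by matching and trajectory screening.

Distances are in angstroms, angles and dihedrals in degrees.  The
hydrogen-bond test implements the donor-acceptor distance / donor-H-acceptor
angle criterion used throughout serine-hydrolase screening: a bond is counted
when the donor-acceptor distance is *less than* 3.5 A and the donor-H-acceptor
angle is *greater than* 120 deg (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HBondCriteria",
    "measure",
    "distance",
    "angle",
    "dihedral",
    "kabsch_rmsd",
    "superpose",
    "is_hydrogen_bond",
    "idealized_polar_hydrogen",
]

_DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (strict inequalities at both cuts)."""

    max_donor_acceptor_A: float = 3.5
    min_donor_h_acceptor_deg: float = 120.0

    def __post_init__(self) -> None:
        if not self.max_donor_acceptor_A > 0:
            raise ValueError("donor-acceptor cutoff must be positive")
        if not 0.0 < self.min_donor_h_acceptor_deg < 180.0:
            raise ValueError("angle cutoff must lie in (0, 180) degrees")


def distance(a, b) -> float:
    """Euclidean distance |a-b| in angstroms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex ``b`` in degrees, in [0, 180]."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERATE_TOL or np.linalg.norm(n2) < _DEGENERATE_TOL:
        raise ValueError("degenerate dihedral: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return ang


def measure(kind: str, points) -> float:
    """Measure ``distance`` (2 points), ``angle`` (3) or ``dihedral`` (4)."""
    pts = [np.asarray(p, dtype=float) for p in points]
    expected = {"distance": 2, "angle": 3, "dihedral": 4}
    if kind not in expected:
        raise ValueError(f"unknown measurement kind {kind!r}")
    if len(pts) != expected[kind]:
        raise ValueError(f"{kind} needs {expected[kind]} points, got {len(pts)}")
    if kind == "distance":
        return distance(*pts)
    if kind == "angle":
        return angle(*pts)
    return dihedral(*pts)


def _kabsch_rotation(ref: np.ndarray, mob: np.ndarray):
    """Optimal rotation (mob -> ref) for centered coordinate sets."""
    h = mob.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(ref, mobile):
    """Least-squares superposition of ``mobile`` onto ``ref``.

    Returns ``(rmsd, rotation, translation)`` with the convention
    ``fitted = mobile @ rotation.T + translation``.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    cref = ref.mean(axis=0)
    cmob = mob.mean(axis=0)
    rot = _kabsch_rotation(ref - cref, mob - cmob)
    trans = cref - cmob @ rot.T
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rmsd, rot, trans


def kabsch_rmsd(ref, mobile, superpose_first: bool = True) -> float:
    """RMSD between two paired coordinate sets.

    With ``superpose_first`` the least-squares (Kabsch) minimum over rigid
    motions is returned; otherwise the raw RMSD in the given frame.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError("coordinate sets must have identical shapes")
    if superpose_first:
        rmsd, _, _ = superpose(ref, mob)
        return rmsd
    return float(np.sqrt(np.mean(np.sum((ref - mob) ** 2, axis=1))))


def idealized_polar_hydrogen(donor, antecedent, acceptor, bond_length: float = 1.0):
    """Place an idealized polar hydrogen on ``donor``.

    The hydrogen is placed in the donor-antecedent-acceptor plane, along the
    direction that bisects "away from the antecedent, towards the acceptor":
    concretely along the unit sum of the antecedent->donor direction and the
    donor->acceptor direction.  This favours the acceptor the way an optimally
    rotated hydroxyl or a backbone amide H (trans to CA) approximately does,
    and is only used when explicit hydrogens are absent.
    """
    donor = np.asarray(donor, dtype=float)
    antecedent = np.asarray(antecedent, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    u = donor - antecedent
    v = acceptor - donor
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise ValueError("degenerate geometry for hydrogen construction")
    direction = u / nu + v / nv
    nd = np.linalg.norm(direction)
    if nd < _DEGENERATE_TOL:  # antecedent-donor-acceptor exactly collinear
        direction = u
        nd = nu
    return donor + bond_length * direction / nd


def nerf_place(a, b, c, bond_length: float, bond_angle_deg: float, dihedral_deg: float):
    """Place atom D from internal coordinates relative to the chain a-b-c.

    Returns coordinates such that |c-D| = ``bond_length``, the angle b-c-D is
    ``bond_angle_deg`` and the dihedral a-b-c-D is ``dihedral_deg`` (natural
    extension reference frame construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _DEGENERATE_TOL:
        raise ValueError("collinear reference atoms for internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    theta = np.radians(bond_angle_deg)
    chi = np.radians(dihedral_deg)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), -np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def is_hydrogen_bond(
    donor,
    hydrogen,
    acceptor,
    criteria: HBondCriteria | None = None,
):
    """Strict geometric hydrogen-bond test.

    Parameters are coordinates (3-vectors) of donor heavy atom, its hydrogen
    and the acceptor heavy atom.  Returns ``(flag, d_donor_acceptor,
    angle_d_h_a)``.
    """
    crit = criteria or HBondCriteria()
    d = distance(donor, acceptor)
    ang = angle(donor, hydrogen, acceptor)
    ok = (d < crit.max_donor_acceptor_A) and (ang > crit.min_donor_h_acceptor_deg)
    return ok, d, ang
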