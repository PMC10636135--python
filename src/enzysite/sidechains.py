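"""Ideal-geometry amino-acid side-chain construction from chi angles.

Side chains are built atom by atom with internal coordinates (NeRF) from the
backbone N/CA/C triad, using a fixed table of ideal bond lengths and angles
per residue type.  Fused aromatic rings are approximated as planar chains of
internal-coordinate placements; the resulting geometry is self-consistent
with the table (bond lengths exact by construction) which is what the
rotamer-packing machinery needs.  Chi angles follow the usual convention
(chi1 = N-CA-CB-G, ...).  Hydroxyl hydrogens of Ser/Thr/Tyr are explicit
because their dihedral is itself a packing degree of freedom.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import numpy as np
import pandas as pd

from .geometry import nerf_place
from .structio import Atom3D, ResidueRecord

__all__ = [
    "N_CHI",
    "HYDROXYL_AA",
    "build_side_chain",
    "build_residue",
    "base_rotamers",
    "chi_angles_of",
]

# number of heavy-atom chi angles per residue type (hydroxyl-H dihedral extra)
N_CHI = {
    "A": 0, "G": 0, "S": 1, "C": 1, "T": 1, "V": 1, "P": 2,
    "I": 2, "L": 2, "F": 2, "Y": 2, "W": 2, "D": 2, "N": 2, "H": 2,
    "M": 3, "E": 3, "Q": 3,
    "K": 4, "R": 4,
}

HYDROXYL_AA = {"S": "HG", "T": "HG1", "Y": "HH"}

# each entry: (atom, (ref_a, ref_b, ref_c), bond, angle, dihedral_spec)
# dihedral_spec: ("chi", i) -> i-th chi angle; ("chi", i, offset) -> chi_i+offset;
# float -> fixed dihedral. CB is placed first for all non-Gly types.
_CB = ("CB", ("C", "N", "CA"), 1.53, 110.4, -122.5)

_TOPOLOGY: dict[str, list] = {
    "A": [],
    "G": [],
    "S": [
        ("OG", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1)),
        ("HG", ("CA", "CB", "OG"), 0.96, 109.5, ("chi", 2)),
    ],
    "C": [("SG", ("N", "CA", "CB"), 1.81, 114.4, ("chi", 1))],
    "T": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0)),
        ("HG1", ("CA", "CB", "OG1"), 0.96, 109.5, ("chi", 2)),
    ],
    "V": [
        ("CG1", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 120.0)),
    ],
    "I": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, -120.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2)),
    ],
    "L": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.5, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.5, ("chi", 2, 120.0)),
    ],
    "M": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1)),
        ("SD", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3)),
    ],
    "F": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "Y": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0),
        ("HH", ("CE1", "CZ", "OH"), 0.96, 109.5, ("chi", 3)),
    ],
    "W": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.40, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 127.0, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.40, 118.7, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.40, 117.5, 0.0),
    ],
    "D": [
        ("CG", ("N", "CA", "CB"), 1.52, 113.0, ("chi", 1)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180.0)),
    ],
    "E": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 180.0)),
    ],
    "N": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180.0)),
    ],
    "Q": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180.0)),
    ],
    "K": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4)),
    ],
    "R": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 3)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "H": [
        ("CG", ("N", "CA", "CB"), 1.49, 113.8, ("chi", 1)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), 1.35, 131.0, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
    ],
}

_ELEMENT_PREFIXES = ("CL",)  # none relevant; single-letter inference below


def _element_of(name: str) -> str:
    if name.startswith(("H",)) and not name.startswith("HG2"):
        # HG (Ser hydroxyl), HG1, HH are hydrogens; heavy names never start H
        return "H"
    return name[0]


def build_side_chain(aa: str, backbone: dict[str, np.ndarray], chis: list[float]) -> dict[str, np.ndarray]:
    """Coordinates of all side-chain atoms (incl. CB and hydroxyl H).

    ``backbone`` must provide N, CA, C.  ``chis`` supplies the chi angles in
    order; the hydroxyl dihedral of S/T/Y is the last entry when present and
    defaults to 180 if omitted.
    """
    aa = aa.upper()
    if aa not in _TOPOLOGY:
        raise KeyError(f"no side-chain topology for {aa!r}")
    coords: dict[str, np.ndarray] = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    if aa == "G":
        return {}
    name, refs, bond, ang, dih = _CB
    coords["CB"] = nerf_place(coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, ang, dih)
    out = {"CB": coords["CB"]}

    def chi_value(spec):
        if isinstance(spec, tuple):
            idx = spec[1]
            offset = spec[2] if len(spec) > 2 else 0.0
            if idx > len(chis):
                val = 180.0  # default for omitted trailing (hydroxyl) dihedral
            else:
                val = chis[idx - 1]
            return val + offset
        return spec

    for name, refs, bond, ang, dih in _TOPOLOGY[aa]:
        pos = nerf_place(
            coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, ang, chi_value(dih)
        )
        coords[name] = pos
        out[name] = pos
    return out


_IDEAL_BACKBONE = {
    "N": np.array([-0.525, 1.363, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.526, 0.0, 0.0]),
    "O": np.array([2.153, 1.047, 0.0]),
}


def build_residue(
    aa: str,
    chis: list[float],
    chain_id: str = "A",
    seq_pos: int = 1,
    backbone: dict[str, np.ndarray] | None = None,
) -> ResidueRecord:
    """A free-standing residue with ideal backbone and the given chi angles."""
    bb = {k: np.array(v, dtype=float) for k, v in (backbone or _IDEAL_BACKBONE).items()}
    side = build_side_chain(aa, bb, chis) if aa != "G" else {}
    atoms = [
        Atom3D(name=n, element=n[0], coords=bb[n], is_backbone=True)
        for n in ("N", "CA", "C", "O")
        if n in bb
    ]
    for n, pos in side.items():
        el = _element_of(n)
        atoms.append(Atom3D(name=n, element=el, coords=pos, is_polar_h=(el == "H")))
    return ResidueRecord(chain_id=chain_id, seq_pos=seq_pos, aa_type=aa, atoms=atoms)


def chi_angles_of(residue: ResidueRecord) -> list[float]:
    """Measure the heavy-atom chi angles of a residue's current conformation."""
    from .geometry import dihedral

    aa = residue.aa_type
    n = N_CHI.get(aa, 0)
    if n == 0:
        return []
    chains = {
        1: ("N", "CA", "CB", _first_gamma(aa)),
    }
    # walk the topology to find the atom defining each chi
    defs = _chi_defining_atoms(aa)
    out = []
    for i in range(1, n + 1):
        a, b, c, d = defs[i]
        try:
            out.append(
                dihedral(
                    residue.atom(a).coords,
                    residue.atom(b).coords,
                    residue.atom(c).coords,
                    residue.atom(d).coords,
                )
            )
        except KeyError:
            break
    return out


@lru_cache(maxsize=None)
def _chi_defining_atoms(aa: str) -> dict[int, tuple[str, str, str, str]]:
    defs = {}
    prev = {"1": ("N", "CA", "CB")}
    for name, refs, _b, _a, dih in _TOPOLOGY[aa]:
        if isinstance(dih, tuple) and len(dih) == 2:
            idx = dih[1]
            if idx not in defs and name not in ("HG", "HG1", "HH"):
                defs[idx] = (*refs, name)
    return defs


def _first_gamma(aa: str) -> str:
    return _TOPOLOGY[aa][0][0]


@lru_cache(maxsize=1)
def base_rotamers() -> dict[str, list[tuple[float, ...]]]:
    """The shipped coarse backbone-independent rotamer set (chi tuples per aa)."""
    ref = importlib.resources.files("enzysite.data") / "rotamers.csv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    out: dict[str, list[tuple[float, ...]]] = {}
    for _, row in df.iterrows():
        aa = str(row["aa"])
        chis = tuple(
            float(row[f"chi{i}"]) for i in range(1, 5) if not pd.isna(row.get(f"chi{i}"))
        )
        out.setdefault(aa, []).append(chis)
    for aa in ("A", "G"):
        out.setdefault(aa, [tuple()])
    return out
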