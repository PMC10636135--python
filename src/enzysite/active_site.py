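"""Active-site model for MHET hydrolysis: catalytic roles, the transition
state molecule, and the geometric constraint table.

The model follows the canonical serine-hydrolase acylation mechanism: a
Ser-His-Asp(Glu) charge-relay triad performs nucleophilic attack on the ester
carbon of MHET, producing a tetrahedral oxyanion intermediate (TI1) whose
negative charge is stabilised by two backbone N-H donors (the oxyanion hole);
a further Ser/Thr hydroxyl binds the terminal carboxylate of the substrate.
Each geometric relationship is a windowed constraint; geometry inside the
window costs nothing and the penalty grows quadratically with the excess
outside it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import geometry

__all__ = [
    "CatalyticRole",
    "GeometricConstraint",
    "TSMolecule",
    "ActiveSiteModel",
    "build_default_ts_molecule",
    "load_active_site_config",
    "default_model",
    "constraint_penalty",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
NON_PROLINE = sorted(AA20 - {"P"})

TRIAD_ROLES = ("nucleophile_ser", "base_his", "acid_asp_glu")
KNOWN_ROLES = TRIAD_ROLES + ("oxyanion_nh_1", "oxyanion_nh_2", "carboxylate_binder_ser")


@dataclass
class CatalyticRole:
    """A catalytic function assigned to one scaffold position.

    ``anchor_atoms`` maps a logical atom label used by constraints (e.g.
    ``OD``) to the concrete atom name per allowed amino acid (``OD1`` for Asp,
    ``OE1`` for Glu); a plain string applies to every allowed type.
    """

    role_id: str
    allowed_aa: list[str]
    anchor_atoms: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if not self.allowed_aa:
            raise ValueError(f"role {self.role_id}: allowed_aa is empty")
        bad = set(self.allowed_aa) - AA20
        if bad:
            raise ValueError(f"role {self.role_id}: unknown amino acids {sorted(bad)}")
        for logical, per_aa in self.anchor_atoms.items():
            missing = [aa for aa in self.allowed_aa if aa not in per_aa]
            if missing:
                raise ValueError(
                    f"role {self.role_id}: anchor atom {logical!r} undefined for {missing}"
                )

    def concrete_atom(self, logical: str, aa: str) -> str:
        return self.anchor_atoms[logical][aa]


@dataclass
class GeometricConstraint:
    """One windowed distance/angle/dihedral constraint between anchor atoms.

    ``atoms`` is a tuple of (owner, logical_atom) pairs, owner being a role id
    or the literal ``"TS"``.
    """

    kind: str
    atoms: tuple
    target: float
    tol_lo: float
    tol_hi: float
    weight: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        n_expected = {"distance": 2, "angle": 3, "dihedral": 4}
        if self.kind not in n_expected:
            raise ValueError(f"constraint {self.label!r}: unknown kind {self.kind}")
        if len(self.atoms) != n_expected[self.kind]:
            raise ValueError(f"constraint {self.label!r}: needs {n_expected[self.kind]} atoms")
        if not (self.tol_lo <= self.target <= self.tol_hi):
            raise ValueError(
                f"constraint {self.label!r}: target {self.target} outside "
                f"[{self.tol_lo}, {self.tol_hi}]"
            )
        if self.weight < 0:
            raise ValueError(f"constraint {self.label!r}: negative weight")

    def excess(self, value: float) -> float:
        """Distance of ``value`` outside the tolerance window (0 inside)."""
        if value < self.tol_lo:
            return self.tol_lo - value
        if value > self.tol_hi:
            return value - self.tol_hi
        return 0.0


@dataclass
class TSMolecule:
    """The tetrahedral-intermediate model of the substrate.

    Atom names, bonds, the sp3 centre and the rotatable torsions are all
    explicit; ``charges`` are charge-like weights used by the screened-Coulomb
    term of the design energy.
    """

    atoms: dict[str, np.ndarray]
    elements: dict[str, str]
    bonds: list[tuple[str, str]]
    tetrahedral_center: str
    rotatable_torsions: list[tuple[str, str, str, str]]
    charges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        for a, b in self.bonds:
            if a not in self.atoms or b not in self.atoms:
                raise ValueError(f"bond ({a}, {b}) references unknown atom")
        nbrs = self.neighbors(self.tetrahedral_center)
        if len(nbrs) != 4:
            raise ValueError(
                f"tetrahedral centre {self.tetrahedral_center} has {len(nbrs)} neighbours, not 4"
            )
        if not self._connected():
            raise ValueError("TS bond graph is not connected")

    def neighbors(self, name: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out

    def _connected(self) -> bool:
        names = list(self.atoms)
        seen = {names[0]}
        stack = [names[0]]
        while stack:
            cur = stack.pop()
            for nb in self.neighbors(cur):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(names)

    def coords_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.atoms)
        return np.array([self.atoms[n] for n in names])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TSMolecule":
        new_atoms = {k: v @ rotation.T + translation for k, v in self.atoms.items()}
        return TSMolecule(
            atoms=new_atoms,
            elements=dict(self.elements),
            bonds=list(self.bonds),
            tetrahedral_center=self.tetrahedral_center,
            rotatable_torsions=list(self.rotatable_torsions),
            charges=dict(self.charges),
        )

    def with_torsions(self, torsion_values_deg: list[float]) -> "TSMolecule":
        """Return a copy with each rotatable torsion set to the given value.

        Rotation moves the atoms on the far side of the torsion's central
        bond (the side of the fourth atom), found by graph traversal with the
        bond removed.
        """
        mol = self
        for (a, b, c, d), target in zip(self.rotatable_torsions, torsion_values_deg):
            current = geometry.dihedral(mol.atoms[a], mol.atoms[b], mol.atoms[c], mol.atoms[d])
            # rotating the far side by +x about b->c decreases the measured
            # dihedral by x under our sign convention
            delta = np.radians(current - target)
            moving = mol._far_side(b, c)
            axis = mol.atoms[c] - mol.atoms[b]
            axis = axis / np.linalg.norm(axis)
            origin = mol.atoms[b]
            new_atoms = dict(mol.atoms)
            cosd, sind = np.cos(delta), np.sin(delta)
            for name in moving:
                p = mol.atoms[name] - origin
                rot = (
                    p * cosd
                    + np.cross(axis, p) * sind
                    + axis * np.dot(axis, p) * (1 - cosd)
                )
                new_atoms[name] = origin + rot
            mol = TSMolecule(
                atoms=new_atoms,
                elements=dict(mol.elements),
                bonds=list(mol.bonds),
                tetrahedral_center=mol.tetrahedral_center,
                rotatable_torsions=list(mol.rotatable_torsions),
                charges=dict(mol.charges),
            )
        return mol

    def _far_side(self, b: str, c: str) -> set[str]:
        """Atoms on the ``c`` side when bond b-c is cut (excluding c itself kept)."""
        seen = {b, c}
        stack = [c]
        out = set()
        while stack:
            cur = stack.pop()
            for nb in self.neighbors(cur):
                if nb not in seen:
                    seen.add(nb)
                    out.add(nb)
                    stack.append(nb)
        return out

    def torsion_values(self) -> list[float]:
        return [
            geometry.dihedral(self.atoms[a], self.atoms[b], self.atoms[c], self.atoms[d])
            for a, b, c, d in self.rotatable_torsions
        ]


@dataclass
class ActiveSiteModel:
    """Roles + constraint table + TS molecule; the matcher's scoring target."""

    roles: list[CatalyticRole]
    constraints: list[GeometricConstraint]
    ts: TSMolecule

    def __post_init__(self) -> None:
        role_ids = {r.role_id for r in self.roles}
        missing_triad = [r for r in TRIAD_ROLES if r not in role_ids]
        if missing_triad:
            raise ValueError(f"model missing required roles: {missing_triad}")
        by_id = {r.role_id: r for r in self.roles}
        for c in self.constraints:
            for owner, logical in c.atoms:
                if owner == "TS":
                    if logical not in self.ts.atoms:
                        raise ValueError(
                            f"constraint {c.label!r}: TS atom {logical!r} undeclared"
                        )
                elif owner not in by_id:
                    raise ValueError(f"constraint {c.label!r}: unknown role {owner!r}")
                elif logical not in by_id[owner].anchor_atoms:
                    raise ValueError(
                        f"constraint {c.label!r}: role {owner} lacks anchor atom {logical!r}"
                    )

    def role(self, role_id: str) -> CatalyticRole:
        for r in self.roles:
            if r.role_id == role_id:
                return r
        raise KeyError(role_id)

    @property
    def role_ids(self) -> list[str]:
        return [r.role_id for r in self.roles]


# ---------------------------------------------------------------------------
# Default TS molecule: MHET first tetrahedral intermediate (heavy atoms)
# ---------------------------------------------------------------------------

def build_default_ts_molecule() -> TSMolecule:
    """Idealised heavy-atom model of the MHET acylation tetrahedral intermediate.

    C1 is the sp3 ester carbon with four substituents: the oxyanion O1, the
    glycol ester oxygen O2, the ring carbon CA1, and ON - the attack-direction
    oxygen marking where the serine nucleophile's OG sits in the intermediate.
    The aromatic ring carries a para carboxylate (C7, O4, O5) whose oxygens the
    carboxylate-binder hydroxyl targets.
    """
    t = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3)
    atoms: dict[str, np.ndarray] = {"C1": np.zeros(3)}
    atoms["ON"] = 1.60 * t[0]
    atoms["O1"] = 1.35 * t[1]
    atoms["O2"] = 1.45 * t[2]
    atoms["CA1"] = 1.52 * t[3]
    # aromatic ring (regular hexagon, side 1.39 A) in the plane through CA1
    u = t[3].copy()
    v = np.cross(u, t[1])
    v /= np.linalg.norm(v)
    center = atoms["CA1"] + 1.39 * u
    for k in range(1, 6):
        th = np.radians(60.0 * k)
        atoms[f"CA{k + 1}"] = center + 1.39 * (-np.cos(th) * u + np.sin(th) * v)
    # para carboxylate on CA4
    atoms["C7"] = atoms["CA4"] + 1.50 * u
    for sign, name in ((1.0, "O4"), (-1.0, "O5")):
        th = np.radians(63.0)
        atoms[name] = atoms["C7"] + 1.25 * (np.cos(th) * u + sign * np.sin(th) * v)
    # ethylene glycol leaving group on O2
    atoms["C2"] = geometry.nerf_place(atoms["O1"], atoms["C1"], atoms["O2"], 1.43, 117.0, 180.0)
    atoms["C3"] = geometry.nerf_place(atoms["C1"], atoms["O2"], atoms["C2"], 1.52, 110.0, 180.0)
    atoms["O3"] = geometry.nerf_place(atoms["O2"], atoms["C2"], atoms["C3"], 1.42, 110.0, 60.0)

    elements = {n: ("O" if n.startswith("O") else "C") for n in atoms}
    bonds = [
        ("C1", "ON"), ("C1", "O1"), ("C1", "O2"), ("C1", "CA1"),
        ("CA1", "CA2"), ("CA2", "CA3"), ("CA3", "CA4"),
        ("CA4", "CA5"), ("CA5", "CA6"), ("CA6", "CA1"),
        ("CA4", "C7"), ("C7", "O4"), ("C7", "O5"),
        ("O2", "C2"), ("C2", "C3"), ("C3", "O3"),
    ]
    charges = {
        "C1": 0.40, "O1": -0.80, "O2": -0.30, "ON": -0.30,
        "O4": -0.60, "O5": -0.60, "C7": 0.35, "O3": -0.40,
    }
    torsions = [
        ("O1", "C1", "CA1", "CA2"),      # ring twist about the C1-CA1 bond
        ("CA3", "CA4", "C7", "O4"),      # carboxylate rotation
        ("C1", "O2", "C2", "C3"),        # glycol tail
    ]
    return TSMolecule(
        atoms=atoms,
        elements=elements,
        bonds=bonds,
        tetrahedral_center="C1",
        rotatable_torsions=torsions,
        charges=charges,
    )


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def _expand_anchor_atoms(raw: dict, allowed_aa: list[str]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for logical, spec in raw.items():
        if isinstance(spec, str):
            out[logical] = {aa: spec for aa in allowed_aa}
        else:
            out[logical] = {str(k): str(v) for k, v in spec.items()}
    return out


def _parse_model_dict(doc: dict) -> ActiveSiteModel:
    roles = []
    for rd in doc.get("roles", []):
        allowed = rd["allowed_aa"]
        if allowed == "non_proline":
            allowed = list(NON_PROLINE)
        roles.append(
            CatalyticRole(
                role_id=rd["role_id"],
                allowed_aa=list(allowed),
                anchor_atoms=_expand_anchor_atoms(rd.get("anchor_atoms", {}), list(allowed)),
            )
        )
    constraints = []
    for cd in doc.get("constraints", []):
        atoms = tuple((str(a[0]), str(a[1])) for a in cd["atoms"])
        constraints.append(
            GeometricConstraint(
                kind=cd["kind"],
                atoms=atoms,
                target=float(cd["target"]),
                tol_lo=float(cd["tol_lo"]),
                tol_hi=float(cd["tol_hi"]),
                weight=float(cd.get("weight", 1.0)),
                label=str(cd.get("label", "")),
            )
        )
    ts_spec = doc.get("ts", "mhet_ti1")
    if ts_spec == "mhet_ti1":
        ts = build_default_ts_molecule()
    else:
        ts = TSMolecule(
            atoms={k: np.asarray(v, dtype=float) for k, v in ts_spec["atoms"].items()},
            elements=dict(ts_spec.get("elements", {})),
            bonds=[tuple(b) for b in ts_spec["bonds"]],
            tetrahedral_center=ts_spec["tetrahedral_center"],
            rotatable_torsions=[tuple(t) for t in ts_spec.get("rotatable_torsions", [])],
            charges=dict(ts_spec.get("charges", {})),
        )
    return ActiveSiteModel(roles=roles, constraints=constraints, ts=ts)


def load_active_site_config(path) -> ActiveSiteModel:
    """Load and validate an active-site model from a YAML config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_model_dict(doc)


def default_model() -> ActiveSiteModel:
    """The shipped MHET-hydrolysis active-site model (6 roles, 8 constraints)."""
    ref = importlib.resources.files("enzysite.data") / "mhet_active_site.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_active_site_config(p)


# ---------------------------------------------------------------------------
# Penalty
# ---------------------------------------------------------------------------

def _resolve_atom(owner: str, logical: str, placed_geometry: dict, constraint_label: str):
    try:
        group = placed_geometry[owner]
    except KeyError:
        raise KeyError(
            f"constraint {constraint_label!r}: no placed geometry for {owner!r}"
        ) from None
    try:
        return np.asarray(group[logical], dtype=float)
    except KeyError:
        raise KeyError(
            f"constraint {constraint_label!r}: atom {logical!r} missing for {owner!r}"
        ) from None


def constraint_penalty(model: ActiveSiteModel, placed_geometry: dict):
    """Score a placed active-site geometry against the constraint table.

    ``placed_geometry`` maps each role id (and ``"TS"``) to a dict of logical
    atom name -> coordinates.  Returns ``(penalty, breakdown)`` where penalty
    is ``sum(w_i * excess_i**2)`` and the breakdown lists per-constraint
    measured value, excess and contribution.
    """
    total = 0.0
    breakdown = []
    for c in model.constraints:
        pts = [_resolve_atom(owner, logical, placed_geometry, c.label) for owner, logical in c.atoms]
        value = geometry.measure(c.kind, pts)
        excess = c.excess(value)
        contrib = c.weight * excess * excess
        total += contrib
        breakdown.append(
            {
                "label": c.label,
                "kind": c.kind,
                "value": value,
                "target": c.target,
                "window": (c.tol_lo, c.tol_hi),
                "excess": excess,
                "penalty": contrib,
            }
        )
    return total, breakdown
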