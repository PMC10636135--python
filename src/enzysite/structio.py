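"""Protein structure I/O and scaffold metadata handling.

Structures are held in lightweight dataclasses (:class:`ProteinStructure`)
backed by PDB files read and written through gemmi.  Conventions:

* waters (HOH) and monoatomic ions are dropped by default (``keep_het`` to
  retain other heteroatoms such as a bound ligand);
* only the first alternate location of each atom is kept;
* author residue numbering is authoritative; an internal 0-based index is
  maintained alongside;
* hydrogens are read when present but never required.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "SO4", "PO4"}


@dataclass
class Atom3D:
    """A single atom: label, element, coordinates (A) and role flags."""

    name: str
    element: str
    coords: np.ndarray
    is_backbone: bool = False
    is_polar_h: bool = False
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class ResidueRecord:
    """One residue: identity, author numbering and atom list."""

    chain_id: str
    seq_pos: int
    aa_type: str
    atoms: list[Atom3D] = field(default_factory=list)
    protonation_tag: str | None = None
    insertion_code: str = ""
    is_hetero: bool = False
    incomplete_backbone: bool = False

    def atom(self, name: str) -> Atom3D:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.chain_id}{self.seq_pos} {self.aa_type}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.element.upper() != "H"]
        return np.array(pts, dtype=float)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_pos)


@dataclass
class ProteinStructure:
    """An ordered collection of residues plus provenance."""

    id: str
    residues: list[ResidueRecord]
    resolution: float | None = None
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a structure needs at least one residue")
        keys = [(r.chain_id, r.seq_pos, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, seq_pos) residue keys")

    def residue(self, chain_id: str, seq_pos: int) -> ResidueRecord:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_pos == seq_pos:
                return r
        raise KeyError(f"no residue {chain_id}{seq_pos} in {self.id}")

    def index_of(self, chain_id: str, seq_pos: int) -> int:
        """Internal 0-based index of an author-numbered residue."""
        for i, r in enumerate(self.residues):
            if r.chain_id == chain_id and r.seq_pos == seq_pos:
                return i
        raise KeyError(f"no residue {chain_id}{seq_pos} in {self.id}")

    def all_atom_coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = []
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.element.upper() == "H":
                    continue
                pts.append(a.coords)
        return np.array(pts, dtype=float)


@dataclass
class ScaffoldMeta:
    """Library-level metadata for one candidate scaffold entry."""

    id: str
    expressible_flag: bool = True
    resolution_A: float | None = None
    seq_length: int = 0
    keywords: list[str] = field(default_factory=list)
    ec_class: str = ""

    def __post_init__(self) -> None:
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _from_gemmi_model(model: gemmi.Model, keep_het: bool) -> list[ResidueRecord]:
    residues: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            rname = res.name.strip().upper()
            if rname in _WATER_NAMES:
                continue
            is_standard = rname in THREE_TO_ONE
            if not is_standard:
                if not keep_het or rname in _ION_NAMES:
                    continue
            atoms: list[Atom3D] = []
            seen = set()
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # first altLoc only
                if atom.name in seen:
                    continue
                seen.add(atom.name)
                el = atom.element.name if atom.element else ""
                atoms.append(
                    Atom3D(
                        name=atom.name,
                        element=el or atom.name[0],
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_backbone=is_standard and atom.name in BACKBONE_ATOMS,
                        is_polar_h=atom.name in ("H", "HG", "HG1", "HH", "HE2", "HD1"),
                    )
                )
            aa = THREE_TO_ONE.get(rname, rname)
            rec = ResidueRecord(
                chain_id=chain.name,
                seq_pos=res.seqid.num,
                aa_type=aa,
                atoms=atoms,
                insertion_code=(res.seqid.icode or "").strip(),
                is_hetero=not is_standard,
            )
            if is_standard and rname != "GLY":
                missing = [n for n in BACKBONE_ATOMS if not rec.has_atom(n)]
            elif is_standard:
                missing = [n for n in ("N", "CA", "C") if not rec.has_atom(n)]
            else:
                missing = []
            if missing:
                rec.incomplete_backbone = True
                warnings.warn(
                    f"residue {chain.name}{res.seqid.num} {rname} missing backbone atoms {missing}",
                    stacklevel=3,
                )
            residues.append(rec)
    return residues


def read_structure(path, keep_het: bool = False) -> ProteinStructure:
    """Read a (single- or first-model) PDB file.

    Waters and ions are always dropped; other hetero residues (e.g. a bound
    transition-state analog) are kept only with ``keep_het``.  Residues with
    missing backbone atoms are flagged and kept, with a warning.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    residues = _from_gemmi_model(st[0], keep_het=keep_het)
    if not residues:
        raise ValueError(f"no residues retained from {path}")
    res = st.resolution if st.resolution and st.resolution > 0 else None
    return ProteinStructure(
        id=st.name or str(path),
        residues=residues,
        resolution=res,
        source_meta={"path": str(path)},
    )


def _to_gemmi_structure(structure: ProteinStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in structure.residues:
        ch = chains.get(r.chain_id)
        if ch is None:
            ch = gemmi.Chain(r.chain_id)
            chains[r.chain_id] = ch
        res = gemmi.Residue()
        res.name = ONE_TO_THREE.get(r.aa_type, r.aa_type if len(r.aa_type) > 1 else "UNK")
        res.seqid = gemmi.SeqId(r.seq_pos, r.insertion_code or " ")
        res.het_flag = "H" if r.is_hetero else "A"
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            res.add_atom(atom)
        ch.add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    return st


def write_structure(structure: ProteinStructure, path) -> None:
    """Write a structure as a PDB file."""
    st = _to_gemmi_structure(structure)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Neighborhood queries
# ---------------------------------------------------------------------------

def neighbors_within(structure: ProteinStructure, center, radius: float) -> list[ResidueRecord]:
    """Residues with any atom within ``radius`` A of ``center``.

    Sorted by the minimal atom-to-center distance (ascending).  Used e.g. to
    pick the design shell around a placed substrate (the 10 A shell around
    the bound transition state).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    hits: list[tuple[float, int, ResidueRecord]] = []
    for i, r in enumerate(structure.residues):
        if not r.atoms:
            continue
        pts = np.array([a.coords for a in r.atoms])
        dmin = float(np.min(np.linalg.norm(pts - center, axis=1)))
        if dmin <= radius:
            hits.append((dmin, i, r))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [r for _, _, r in hits]


# ---------------------------------------------------------------------------
# Scaffold library filtering
# ---------------------------------------------------------------------------

@dataclass
class LibraryCriteria:
    """Filter settings for assembling a scaffold library.

    Defaults follow the thermophilic-hydrolase library recipe: resolution
    better than 3.0 A, chain length 200-800, thermophile keywords, hydrolase
    EC class, pairwise sequence identity below 95%.
    """

    max_resolution_A: float = 3.0
    min_length: int = 200
    max_length: int = 800
    required_keywords: list[str] = field(
        default_factory=lambda: ["thermophilic", "thermophile", "thermophila", "thermophilus"]
    )
    ec_class_prefix: str = "3"
    require_expressible: bool = True
    max_identity: float = 0.95


def filter_scaffold_library(
    records: list[ScaffoldMeta],
    criteria: LibraryCriteria | None = None,
    identity_matrix: pd.DataFrame | None = None,
) -> list[ScaffoldMeta]:
    """Apply the library filters; records failing any filter are dropped.

    ``identity_matrix`` (square, indexed by record id, fractional identities)
    enables greedy keep-first de-duplication at ``max_identity``; without it
    the identity filter is skipped.  Missing fields fail the record with a
    logged reason.
    """
    crit = criteria or LibraryCriteria()
    passed: list[ScaffoldMeta] = []
    for rec in records:
        reason = None
        if crit.require_expressible and not rec.expressible_flag:
            reason = "not expressible"
        elif rec.resolution_A is None:
            reason = "missing resolution"
        elif rec.resolution_A > crit.max_resolution_A:
            reason = f"resolution {rec.resolution_A} worse than {crit.max_resolution_A}"
        elif not (crit.min_length <= rec.seq_length <= crit.max_length):
            reason = f"length {rec.seq_length} outside [{crit.min_length}, {crit.max_length}]"
        elif crit.required_keywords and not any(
            kw.lower() in (k.lower() for k in rec.keywords) for kw in crit.required_keywords
        ):
            reason = "no required keyword"
        elif crit.ec_class_prefix and not rec.ec_class.startswith(crit.ec_class_prefix):
            reason = f"EC class {rec.ec_class!r} not {crit.ec_class_prefix}.x"
        if reason:
            logger.info("scaffold %s rejected: %s", rec.id, reason)
            continue
        passed.append(rec)

    if identity_matrix is not None:
        kept: list[ScaffoldMeta] = []
        for rec in passed:
            redundant = False
            for prev in kept:
                try:
                    ident = float(identity_matrix.loc[rec.id, prev.id])
                except KeyError:
                    continue
                if ident >= crit.max_identity:
                    redundant = True
                    logger.info("scaffold %s redundant with %s (id %.2f)", rec.id, prev.id, ident)
                    break
            if not redundant:
                kept.append(rec)
        passed = kept
    return passed


def read_scaffold_meta(path) -> list[ScaffoldMeta]:
    """Read scaffold metadata from a TSV/CSV with columns
    id, resolution, length, keywords (semicolon-separated), ec[, expressible]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, row in df.iterrows():
        out.append(
            ScaffoldMeta(
                id=str(row["id"]),
                expressible_flag=bool(row.get("expressible", True)),
                resolution_A=None if pd.isna(row["resolution"]) else float(row["resolution"]),
                seq_length=int(row["length"]),
                keywords=[k.strip() for k in str(row.get("keywords", "")).split(";") if k.strip()],
                ec_class=str(row.get("ec", "")),
            )
        )
    return out
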