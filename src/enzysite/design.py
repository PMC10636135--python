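"""Active-site sequence redesign.

The design stage treats the scaffold backbone as rigid, discretises side-chain
conformations into rotamers at the design positions, scores a pairwise-
decomposable energy (Lennard-Jones 12-6 + geometric hydrogen bonds + screened
Coulomb with a distance-dependent dielectric + per-residue reference
energies), prunes with Goldstein dead-end elimination, and finds the global
minimum energy conformation (GMEC) by exact branch-and-bound.  Sequences near
the optimum are enumerated under a mutation-diversity restriction, and each
design's binding and folding free-energy changes are accounted as

    G_bind  = G_bound - G_unbound        (TS present vs removed)
    G_fold  = G_unbound                  (apo enzyme)
    ddG_x   = G_x(mutant) - G_x(wild type)
    ddG_total = ddG_bind + ddG_fold

where the unbound state repeats the rotamer optimisation without the
rotamer-TS terms.  The energy function is a deliberately simple, fully
documented surrogate: the pipeline logic (tables -> DEE -> enumeration ->
ddG accounting -> candidate filter), not any absolute kcal/mol value, is the
tested contribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import geometry, sidechains
from .structio import ProteinStructure
from .ts_placement import TSConformerLibrary, VDW_RADII

__all__ = [
    "DesignSpec",
    "Rotamer",
    "RotamerLibrary",
    "EnergyModelParams",
    "EnergyTables",
    "SequenceDesign",
    "SelectionCriteria",
    "build_rotamer_library",
    "compute_energy_tables",
    "search_gmec",
    "dee_prune",
    "enumerate_designs",
    "select_candidates",
    "PackingProblem",
]

HYDROXYL_DIHEDRALS = (60.0, 180.0, -60.0)

# charge-like weights for polar protein atoms (screened-Coulomb term)
_CHARGES: dict[str, dict[str, float]] = {
    "S": {"OG": -0.40, "HG": 0.30},
    "T": {"OG1": -0.40, "HG1": 0.30},
    "Y": {"OH": -0.35, "HH": 0.30},
    "C": {"SG": -0.20},
    "D": {"OD1": -0.60, "OD2": -0.60, "CG": 0.35},
    "E": {"OE1": -0.60, "OE2": -0.60, "CD": 0.35},
    "N": {"OD1": -0.50, "ND2": -0.45, "CG": 0.45},
    "Q": {"OE1": -0.50, "NE2": -0.45, "CD": 0.45},
    "K": {"NZ": 0.80},
    "R": {"NE": 0.30, "CZ": 0.40, "NH1": 0.35, "NH2": 0.35},
    "H": {"ND1": -0.30, "NE2": -0.30},
    "W": {"NE1": -0.20},
}

# hydrogen-bond participants: donors as (heavy atom -> antecedent for
# idealized-H construction when no explicit H is present), acceptors as names
_DONOR_ANTECEDENT: dict[str, dict[str, str]] = {
    "S": {"OG": "CB"},
    "T": {"OG1": "CB"},
    "Y": {"OH": "CZ"},
    "K": {"NZ": "CE"},
    "R": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "N": {"ND2": "CG"},
    "Q": {"NE2": "CD"},
    "W": {"NE1": "CE2"},
}
_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "S": ("OG",), "T": ("OG1",), "Y": ("OH",),
    "D": ("OD1", "OD2"), "E": ("OE1", "OE2"),
    "N": ("OD1",), "Q": ("OE1",), "H": ("ND1", "NE2"),
}
_EXPLICIT_H = {"OG": "HG", "OG1": "HG1", "OH": "HH"}

_TS_ACCEPTORS = ("O1", "O2", "O3", "O4", "O5", "ON")
_TS_DONORS = {"O3": "C3"}  # glycol hydroxyl


@dataclass
class DesignSpec:
    """Mutable positions (with allowed amino acids), repack positions (native
    type, flexible side chain), everything else rigid."""

    mutable_positions: dict[tuple[str, int], str]
    repack_positions: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.mutable_positions) & set(self.repack_positions)
        if overlap:
            raise ValueError(f"positions both mutable and repack: {sorted(overlap)}")
        for key, aas in self.mutable_positions.items():
            bad = set(aas) - set("ACDEFGHIKLMNPQRSTVWY")
            if bad:
                raise ValueError(f"position {key}: unknown amino acids {sorted(bad)}")

    @property
    def design_positions(self) -> list[tuple[str, int]]:
        return list(self.mutable_positions) + list(self.repack_positions)

    def allowed(self, key: tuple[str, int], native_aa: str) -> str:
        if key in self.mutable_positions:
            aas = self.mutable_positions[key]
            # the wild-type reference must always be representable
            return aas if native_aa in aas else native_aa + aas
        return native_aa


@dataclass
class Rotamer:
    aa: str
    chis: tuple[float, ...]
    atoms: dict[str, np.ndarray]      # side-chain atoms incl CB and polar H
    is_crystal: bool = False


class RotamerLibrary:
    """Per (position, amino acid) lists of placed rotamers."""

    def __init__(self, entries: dict[tuple[tuple[str, int], str], list[Rotamer]]):
        self.entries = entries
        for (key, aa), rots in entries.items():
            if not rots:
                raise ValueError(f"no rotamers for {key} {aa}")

    def rotamers(self, key: tuple[str, int], aa: str) -> list[Rotamer]:
        return self.entries[(key, aa)]


def build_rotamer_library(
    spec: DesignSpec,
    structure: ProteinStructure,
    base_library: dict[str, list[tuple[float, ...]]] | None = None,
) -> RotamerLibrary:
    """Place rotamers at every design position.

    Base chi sets come from the shipped coarse backbone-independent table;
    the crystal (native) conformation is appended for each position's native
    type; Ser/Thr/Tyr entries are expanded over the hydroxyl-hydrogen
    dihedral grid (60/180/-60 deg).  Gly and Ala yield a single rotamer.
    """
    base = base_library or sidechains.base_rotamers()
    entries: dict[tuple[tuple[str, int], str], list[Rotamer]] = {}
    for key in spec.design_positions:
        res = structure.residue(*key)
        backbone = {n: res.atom(n).coords for n in ("N", "CA", "C") if res.has_atom(n)}
        if len(backbone) < 3:
            raise ValueError(f"position {key}: incomplete backbone")
        for aa in spec.allowed(key, res.aa_type):
            if aa not in base and aa not in ("A", "G"):
                raise ValueError(f"no base rotamers for amino acid {aa!r}")
            chi_sets: list[tuple[tuple[float, ...], bool]] = [
                (tuple(c), False) for c in base.get(aa, [tuple()])
            ]
            if aa == res.aa_type and sidechains.N_CHI.get(aa, 0) > 0:
                native_chis = tuple(sidechains.chi_angles_of(res))
                chi_sets.append((native_chis, True))
            rots: list[Rotamer] = []
            for chis, crystal in chi_sets:
                if aa in HYDROXYL_EXPANSION_AA:
                    for hchi in HYDROXYL_DIHEDRALS:
                        full = tuple(chis) + (hchi,)
                        atoms = sidechains.build_side_chain(aa, backbone, list(full))
                        rots.append(Rotamer(aa=aa, chis=full, atoms=atoms, is_crystal=crystal))
                else:
                    atoms = sidechains.build_side_chain(aa, backbone, list(chis))
                    rots.append(Rotamer(aa=aa, chis=tuple(chis), atoms=atoms, is_crystal=crystal))
            entries[(key, aa)] = rots
    return RotamerLibrary(entries)


HYDROXYL_EXPANSION_AA = set(sidechains.HYDROXYL_AA)


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

@dataclass
class EnergyModelParams:
    """Parameters of the surrogate energy function (kcal/mol, A)."""

    lj_epsilon: float = 0.15
    coulomb_k: float = 332.0
    dielectric_factor: float = 4.0    # eps(r) = factor * r
    hbond_bonus: float = -2.0
    clash_cap: float = 50.0
    reference_energies: dict[str, float] = field(default_factory=dict)
    hbond_criteria: geometry.HBondCriteria = field(default_factory=geometry.HBondCriteria)


class _AtomGroup:
    """Flat arrays for one interacting group of atoms."""

    def __init__(self, items):
        # items: list of (name, element, coords, charge, aa_context)
        self.names = [i[0] for i in items]
        self.elements = [i[1] for i in items]
        self.coords = np.array([i[2] for i in items], dtype=float).reshape(-1, 3)
        self.charges = np.array([i[3] for i in items], dtype=float)
        self.heavy = np.array([e.upper() != "H" for e in self.elements])
        self.radii = np.array([VDW_RADII.get(e.upper(), 1.7) for e in self.elements])
        self.donors = []    # (donor_idx, h_coords or None, antecedent_idx)
        self.acceptors = []  # indices


def _rotamer_group(aa: str, rot_atoms: dict[str, np.ndarray]) -> _AtomGroup:
    charges = _CHARGES.get(aa, {})
    items = []
    index = {}
    for name, pos in rot_atoms.items():
        el = "H" if name.startswith("H") else name[0]
        index[name] = len(items)
        items.append((name, el, pos, charges.get(name, 0.0), aa))
    g = _AtomGroup(items)
    for donor, ante in _DONOR_ANTECEDENT.get(aa, {}).items():
        if donor in index and ante in index:
            h_name = _EXPLICIT_H.get(donor)
            h = rot_atoms.get(h_name) if h_name else None
            g.donors.append((index[donor], h, index[ante]))
    for acc in _ACCEPTORS.get(aa, ()):
        if acc in index:
            g.acceptors.append(index[acc])
    return g


def _template_group(structure: ProteinStructure, exclude_keys: set) -> _AtomGroup:
    items = []
    for res in structure.residues:
        for a in res.atoms:
            if res.key in exclude_keys and not a.is_backbone:
                continue
            q = 0.0
            if res.key not in exclude_keys:
                q = _CHARGES.get(res.aa_type, {}).get(a.name, 0.0)
            items.append((a.name, a.element, a.coords, q, res.aa_type))
    return _AtomGroup(items)


def _ts_group(ts_atoms: dict[str, np.ndarray], charges: dict[str, float]) -> _AtomGroup:
    items = []
    index = {}
    for name, pos in ts_atoms.items():
        index[name] = len(items)
        items.append((name, "O" if name.startswith("O") else "C", pos, charges.get(name, 0.0), "TS"))
    g = _AtomGroup(items)
    for acc in _TS_ACCEPTORS:
        if acc in index:
            g.acceptors.append(index[acc])
    for donor, ante in _TS_DONORS.items():
        if donor in index and ante in index:
            g.donors.append((index[donor], None, index[ante]))
    return g


def interaction_energy(a: _AtomGroup, b: _AtomGroup, params: EnergyModelParams) -> float:
    """Pairwise group-group energy: LJ (heavy atoms) + screened Coulomb +
    geometric hydrogen bonds; total capped at ``clash_cap``."""
    if a.coords.size == 0 or b.coords.size == 0:
        return 0.0
    d = np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=2)
    d = np.maximum(d, 0.5)  # guard the singularity; capped anyway

    heavy = np.outer(a.heavy, b.heavy)
    sigma = (a.radii[:, None] + b.radii[None, :]) * 2 ** (-1 / 6)
    sr6 = (sigma / d) ** 6
    lj = 4.0 * params.lj_epsilon * (sr6**2 - sr6)
    e_lj = float(np.sum(lj[heavy]))

    qq = np.outer(a.charges, b.charges)
    mask_q = qq != 0.0
    e_coul = float(
        np.sum(params.coulomb_k * qq[mask_q] / (params.dielectric_factor * d[mask_q] ** 2))
    )

    e_hb = 0.0
    e_hb += _hbond_energy(a, b, params)
    e_hb += _hbond_energy(b, a, params)
    return float(min(e_lj + e_coul + e_hb, params.clash_cap))


def _hbond_energy(donor_g: _AtomGroup, acceptor_g: _AtomGroup, params: EnergyModelParams) -> float:
    total = 0.0
    for d_idx, h, ante_idx in donor_g.donors:
        dpos = donor_g.coords[d_idx]
        for a_idx in acceptor_g.acceptors:
            apos = acceptor_g.coords[a_idx]
            if np.linalg.norm(dpos - apos) >= params.hbond_criteria.max_donor_acceptor_A:
                continue
            hpos = h
            if hpos is None:
                try:
                    hpos = geometry.idealized_polar_hydrogen(
                        dpos, donor_g.coords[ante_idx], apos
                    )
                except ValueError:
                    continue
            ok, _, _ = geometry.is_hydrogen_bond(dpos, hpos, apos, params.hbond_criteria)
            if ok:
                total += params.hbond_bonus
    return total


@dataclass
class EnergyTables:
    """Pairwise-decomposed design energies.

    ``positions`` orders the design positions; ``rotamers[i]`` lists
    (aa, Rotamer) choices at position i; ``singles[i]`` the rotamer-template
    energies (+ reference energy); ``singles_ts[i]`` an (n_rot, n_ts) array of
    rotamer-TS energies; ``pairs[(i, j)]`` (i<j) rotamer-rotamer matrices;
    ``ts_template`` the per-TS-conformer template interaction.
    """

    positions: list[tuple[str, int]]
    rotamers: list[list[tuple[str, Rotamer]]]
    singles: list[np.ndarray]
    singles_ts: list[np.ndarray]
    pairs: dict[tuple[int, int], np.ndarray]
    ts_template: np.ndarray
    native_aa: dict[tuple[str, int], str]

    def pair(self, i: int, ri: int, j: int, rj: int) -> float:
        if i == j:
            return 0.0
        if i < j:
            return float(self.pairs[(i, j)][ri, rj])
        return float(self.pairs[(j, i)][rj, ri])


def compute_energy_tables(
    structure: ProteinStructure,
    library: RotamerLibrary,
    ts_library: TSConformerLibrary | None,
    spec: DesignSpec,
    params: EnergyModelParams | None = None,
    ts_charges: dict[str, float] | None = None,
) -> EnergyTables:
    """Assemble singles/pairs/TS energy tables for the design problem."""
    params = params or EnergyModelParams()
    positions = spec.design_positions
    pos_set = set(positions)
    template = _template_group(structure, exclude_keys=pos_set)

    rot_choices: list[list[tuple[str, Rotamer]]] = []
    groups: list[list[_AtomGroup]] = []
    native_aa = {}
    for key in positions:
        res = structure.residue(*key)
        native_aa[key] = res.aa_type
        choices = []
        gs = []
        for aa in spec.allowed(key, res.aa_type):
            for rot in library.rotamers(key, aa):
                choices.append((aa, rot))
                gs.append(_rotamer_group(aa, rot.atoms))
        rot_choices.append(choices)
        groups.append(gs)

    ts_groups: list[_AtomGroup] = []
    if ts_library is not None:
        charges = ts_charges or {}
        for conf in ts_library.conformers:
            ts_groups.append(_ts_group(conf.atoms, charges))

    singles = []
    singles_ts = []
    for i, key in enumerate(positions):
        e = np.empty(len(groups[i]))
        ets = np.zeros((len(groups[i]), len(ts_groups)))
        for ri, g in enumerate(groups[i]):
            aa = rot_choices[i][ri][0]
            e[ri] = interaction_energy(g, template, params) + params.reference_energies.get(aa, 0.0)
            for k, tg in enumerate(ts_groups):
                ets[ri, k] = interaction_energy(g, tg, params)
        singles.append(e)
        singles_ts.append(ets)

    pairs = {}
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            m = np.empty((len(groups[i]), len(groups[j])))
            for ri, gi in enumerate(groups[i]):
                for rj, gj in enumerate(groups[j]):
                    m[ri, rj] = interaction_energy(gi, gj, params)
            pairs[(i, j)] = m

    ts_template = np.array(
        [interaction_energy(tg, template, params) for tg in ts_groups]
    )
    return EnergyTables(
        positions=positions,
        rotamers=rot_choices,
        singles=singles,
        singles_ts=singles_ts,
        pairs=pairs,
        ts_template=ts_template,
        native_aa=native_aa,
    )


# ---------------------------------------------------------------------------
# GMEC search: Goldstein DEE + exact branch-and-bound
# ---------------------------------------------------------------------------

@dataclass
class PackingProblem:
    """A generic pairwise packing instance: per-position singles and pair
    matrices over rotamer choices (the bound state appends the TS conformer
    as an extra 'position')."""

    singles: list[np.ndarray]
    pairs: dict[tuple[int, int], np.ndarray]

    def pair(self, i: int, ri, j: int, rj) -> float:
        if i < j:
            key = (i, j)
            if key not in self.pairs:
                return 0.0
            return float(self.pairs[key][ri, rj])
        key = (j, i)
        if key not in self.pairs:
            return 0.0
        return float(self.pairs[key][rj, ri])

    def energy(self, assignment) -> float:
        total = 0.0
        for i, ri in enumerate(assignment):
            total += float(self.singles[i][ri])
            for j in range(i + 1, len(assignment)):
                total += self.pair(i, ri, j, assignment[j])
        return total

    @property
    def n_positions(self) -> int:
        return len(self.singles)


def dee_prune(problem: PackingProblem, domains: list[list[int]] | None = None):
    """Goldstein singles dead-end elimination to a fixed point.

    Rotamer r at position i is eliminated when some alternative t satisfies
    E(i,r) - E(i,t) + sum_j min_s [E(i,r;j,s) - E(i,t;j,s)] > 0.
    Returns (pruned_domains, eliminated) with eliminated as (pos, rot) pairs.
    """
    n = problem.n_positions
    domains = [list(d) for d in (domains or [list(range(len(s))) for s in problem.singles])]
    eliminated: list[tuple[int, int]] = []
    changed = True
    while changed:
        changed = False
        for i in range(n):
            keep = []
            for r in domains[i]:
                dead = False
                for t in domains[i]:
                    if t == r:
                        continue
                    margin = float(problem.singles[i][r] - problem.singles[i][t])
                    for j in range(n):
                        if j == i:
                            continue
                        margin += min(
                            problem.pair(i, r, j, s) - problem.pair(i, t, j, s)
                            for s in domains[j]
                        )
                    if margin > 0:
                        dead = True
                        break
                if dead:
                    eliminated.append((i, r))
                    changed = True
                else:
                    keep.append(r)
            domains[i] = keep
            if not keep:
                raise RuntimeError(f"DEE emptied the domain at position {i}")
    return domains, eliminated


def _branch_and_bound(problem: PackingProblem, domains: list[list[int]], ceiling: int):
    """Exact DFS with additive lower bounds; certified optimum."""
    n = problem.n_positions
    space = 1
    for d in domains:
        space *= len(d)
        if space > ceiling:
            raise RuntimeError(
                f"search space after pruning exceeds ceiling ({ceiling}); "
                "tighten the design spec or raise the ceiling"
            )
    order = sorted(range(n), key=lambda i: len(domains[i]))

    # lower bound contribution of unassigned position j given partial fill
    best_energy = np.inf
    best_assign = None
    assign = [None] * n

    def lower_bound(depth):
        lb = 0.0
        for jj in order[depth:]:
            cand = []
            for s in domains[jj]:
                e = float(problem.singles[jj][s])
                for kk in order[:depth]:
                    e += problem.pair(jj, s, kk, assign[kk])
                for kk in order[depth:]:
                    if kk == jj or kk < jj:
                        continue
                    e += min(problem.pair(jj, s, kk, t) for t in domains[kk])
                cand.append(e)
            lb += min(cand)
        return lb

    def dfs(depth, partial_e):
        nonlocal best_energy, best_assign
        if depth == n:
            if partial_e < best_energy:
                best_energy = partial_e
                best_assign = assign.copy()
            return
        if partial_e + lower_bound(depth) > best_energy + 1e-12:
            return
        i = order[depth]
        choices = sorted(
            domains[i],
            key=lambda r: problem.singles[i][r]
            + sum(problem.pair(i, r, order[k], assign[order[k]]) for k in range(depth)),
        )
        for r in choices:
            delta = float(problem.singles[i][r]) + sum(
                problem.pair(i, r, order[k], assign[order[k]]) for k in range(depth)
            )
            assign[i] = r
            dfs(depth + 1, partial_e + delta)
            assign[i] = None

    dfs(0, 0.0)
    return best_assign, float(best_energy)


def solve_packing(
    problem: PackingProblem,
    domains: list[list[int]] | None = None,
    use_dee: bool = True,
    ceiling: int = 2_000_000,
):
    """DEE + exact search; returns (assignment, energy, eliminated)."""
    domains = domains or [list(range(len(s))) for s in problem.singles]
    eliminated: list[tuple[int, int]] = []
    if use_dee:
        domains, eliminated = dee_prune(problem, domains)
    assignment, energy = _branch_and_bound(problem, domains, ceiling)
    return assignment, energy, eliminated


def _problem_for(
    tables: EnergyTables,
    aa_choice: dict[tuple[str, int], str] | None,
    bound: bool,
) -> tuple[PackingProblem, list[list[int]]]:
    """Build a packing problem, optionally restricted to one aa per position;
    the bound state appends the TS conformer as the last position."""
    singles = [s.copy() for s in tables.singles]
    pairs = dict(tables.pairs)
    domains = []
    for i, key in enumerate(tables.positions):
        if aa_choice is None:
            domains.append(list(range(len(tables.rotamers[i]))))
        else:
            aa = aa_choice[key]
            domains.append(
                [ri for ri, (a, _r) in enumerate(tables.rotamers[i]) if a == aa]
            )
            if not domains[-1]:
                raise ValueError(f"no rotamers of type {aa} at {key}")
    if bound and len(tables.ts_template):
        ts_pos = len(singles)
        singles.append(tables.ts_template.copy())
        for i in range(ts_pos):
            pairs[(i, ts_pos)] = tables.singles_ts[i]
        domains.append(list(range(len(tables.ts_template))))
    return PackingProblem(singles=singles, pairs=pairs), domains


def search_gmec(
    tables: EnergyTables,
    aa_choice: dict[tuple[str, int], str] | None = None,
    bound: bool = True,
    use_dee: bool = True,
    ceiling: int = 2_000_000,
):
    """Certified global minimum of the decomposed energy.

    With ``aa_choice`` None the search runs over all amino-acid choices in
    the tables (sequence + rotamer optimisation); otherwise rotamer domains
    are restricted to the stated sequence.  ``bound`` includes the TS terms.
    Returns ``(assignment, energy, eliminated)`` where assignment maps
    position -> (aa, rotamer index within tables) and, in the bound state,
    ``assignment["TS"]`` gives the chosen TS conformer index.
    """
    problem, domains = _problem_for(tables, aa_choice, bound)
    raw, energy, eliminated = solve_packing(problem, domains, use_dee, ceiling)
    out: dict = {}
    for i, key in enumerate(tables.positions):
        aa, _rot = tables.rotamers[i][raw[i]]
        out[key] = (aa, raw[i])
    if bound and len(tables.ts_template):
        out["TS"] = raw[len(tables.positions)]
    return out, energy, eliminated


# ---------------------------------------------------------------------------
# Sequence enumeration and ddG accounting
# ---------------------------------------------------------------------------

@dataclass
class SequenceDesign:
    """One designed sequence with its energy accounting (kcal/mol)."""

    mutations: list[str]
    aa_choice: dict[tuple[str, int], str]
    g_bound: float
    g_unbound: float
    g_bind: float
    g_fold: float
    ddg_bind: float
    ddg_fold: float
    ddg_total: float
    rank_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.g_bind - (self.g_bound - self.g_unbound)) > 1e-9:
            raise ValueError("g_bind must equal g_bound - g_unbound")
        if abs(self.g_fold - self.g_unbound) > 1e-9:
            raise ValueError("g_fold must equal g_unbound")
        if abs(self.ddg_total - (self.ddg_bind + self.ddg_fold)) > 1e-9:
            raise ValueError("ddg_total must equal ddg_bind + ddg_fold")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def _mutation_labels(aa_choice, native_aa) -> list[str]:
    out = []
    for key in sorted(aa_choice, key=lambda k: (k[0], k[1])):
        wt = native_aa[key]
        mut = aa_choice[key]
        if mut != wt:
            out.append(f"{wt}{key[1]}{mut}")
    return out


def _design_energies(tables: EnergyTables, aa_choice, ceiling: int):
    _, g_bound, _ = search_gmec(tables, aa_choice, bound=True, ceiling=ceiling)
    _, g_unbound, _ = search_gmec(tables, aa_choice, bound=False, ceiling=ceiling)
    return g_bound, g_unbound


def enumerate_designs(
    tables: EnergyTables,
    count: int,
    diversity: int = 1,
    max_mutations: int | None = None,
    ceiling: int = 2_000_000,
    sequence_ceiling: int = 200_000,
) -> list[SequenceDesign]:
    """Enumerate sequences around the optimum with a diversity restriction.

    All amino-acid sequences over the mutable positions are solved exactly
    (bound and unbound rotamer optimisation per sequence), ranked by bound
    energy, and greedily accepted so that any two returned designs differ in
    at least ``diversity`` positions' amino-acid types.  ddG fields are
    accounted against the all-native (wild-type) sequence.
    """
    mutable = [
        (i, key)
        for i, key in enumerate(tables.positions)
        if len({aa for aa, _ in tables.rotamers[i]}) > 1
    ]
    aa_options = [sorted({aa for aa, _ in tables.rotamers[i]}) for i, _ in mutable]
    total = 1
    for opts in aa_options:
        total *= len(opts)
        if total > sequence_ceiling:
            raise RuntimeError("sequence space exceeds the enumeration ceiling")

    wt_choice = {key: tables.native_aa[key] for key in tables.positions}
    wt_bound, wt_unbound = _design_energies(tables, wt_choice, ceiling)
    wt_bind = wt_bound - wt_unbound

    scored: list[SequenceDesign] = []
    for combo in itertools.product(*aa_options):
        aa_choice = dict(wt_choice)
        for (i, key), aa in zip(mutable, combo):
            aa_choice[key] = aa
        muts = _mutation_labels(aa_choice, tables.native_aa)
        if max_mutations is not None and len(muts) > max_mutations:
            continue
        g_bound, g_unbound = _design_energies(tables, aa_choice, ceiling)
        g_bind = g_bound - g_unbound
        d = SequenceDesign(
            mutations=muts,
            aa_choice=aa_choice,
            g_bound=g_bound,
            g_unbound=g_unbound,
            g_bind=g_bind,
            g_fold=g_unbound,
            ddg_bind=g_bind - wt_bind,
            ddg_fold=g_unbound - wt_unbound,
            ddg_total=(g_bind - wt_bind) + (g_unbound - wt_unbound),
        )
        scored.append(d)
    scored.sort(key=lambda d: (d.g_bound, tuple(d.mutations)))

    selected: list[SequenceDesign] = []
    for d in scored:
        if all(_aa_differences(d, prev) >= diversity for prev in selected):
            selected.append(d)
        if len(selected) >= count:
            break
    return selected


def _aa_differences(a: SequenceDesign, b: SequenceDesign) -> int:
    return sum(1 for k in a.aa_choice if a.aa_choice[k] != b.aa_choice[k])


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionCriteria:
    """The screening filter ahead of MD evaluation: keep a design when
    (ddG_bind < bind_cut and ddG_fold < fold_cut) or its ddG_total rank is
    within the top ``top_total_rank``."""

    bind_cut: float = 0.0
    fold_cut: float = 8.0
    top_total_rank: int = 30


def select_candidates(
    designs: list[SequenceDesign],
    criteria: SelectionCriteria | None = None,
    extra_filters: list | None = None,
):
    """Apply the selection clauses; returns (selected, audit_log).

    Ranking of ddG_total is ascending with ties broken by the lexicographic
    mutation list, making the filter deterministic and order-invariant.
    ``extra_filters`` are optional callables(design) -> bool applied after
    the energy clauses (mutation-diversity / manual-inspection hooks).
    """
    crit = criteria or SelectionCriteria()
    order = sorted(
        range(len(designs)),
        key=lambda i: (designs[i].ddg_total, tuple(designs[i].mutations)),
    )
    rank = {idx: r + 1 for r, idx in enumerate(order)}
    selected = []
    audit = []
    for i, d in enumerate(designs):
        clause1 = d.ddg_bind < crit.bind_cut and d.ddg_fold < crit.fold_cut
        clause2 = rank[i] <= crit.top_total_rank
        admitted = clause1 or clause2
        if admitted and extra_filters:
            admitted = all(f(d) for f in extra_filters)
        audit.append(
            {
                "mutations": list(d.mutations),
                "ddg_bind": d.ddg_bind,
                "ddg_fold": d.ddg_fold,
                "ddg_total": d.ddg_total,
                "rank_total": rank[i],
                "energy_clause": clause1,
                "rank_clause": clause2,
                "selected": admitted,
            }
        )
        if admitted:
            selected.append(d)
    return selected, audit
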