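import itertools

import numpy as np
import pytest

from enzysite import design, fixtures, sidechains
from enzysite.design import (
    DesignSpec,
    EnergyModelParams,
    PackingProblem,
    SelectionCriteria,
    SequenceDesign,
    build_rotamer_library,
    compute_energy_tables,
    dee_prune,
    enumerate_designs,
    interaction_energy,
    search_gmec,
    select_candidates,
    solve_packing,
)
from enzysite.matcher import match_active_site
from enzysite.ts_placement import LibraryParams, generate_ts_library


@pytest.fixture(scope="module")
def designed(model):
    """Shared matched scaffold + TS library + a 2-mutable-position spec."""
    s, _ = fixtures.make_toy_scaffold(seed=1, n_decoy_residues=8, model=model)
    m = match_active_site(s, model)[0]
    ts_lib = generate_ts_library(s, m, model, LibraryParams(torsion_steps=(3, 2, 1)))
    assigned = set(m.role_assignment.values())
    decoys = [r.key for r in s.residues if r.key not in assigned][:2]
    spec = DesignSpec(
        mutable_positions={decoys[0]: "AVLK", decoys[1]: "ASF"},
        repack_positions=[m.role_assignment["nucleophile_ser"]],
    )
    library = build_rotamer_library(spec, s)
    tables = compute_energy_tables(s, library, ts_lib, spec, ts_charges=model.ts.charges)
    return s, m, spec, library, tables


class TestDesignSpec:
    def test_disjoint_sets_enforced(self):
        with pytest.raises(ValueError, match="both"):
            DesignSpec(mutable_positions={("A", 1): "AV"}, repack_positions=[("A", 1)])

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            DesignSpec(mutable_positions={("A", 1): "AXZ"})


class TestRotamerLibrary:
    def test_ser_hydroxyl_expansion_count(self, designed):
        """Native Ser with 3 base chi1 rotamers: 3x3 hydroxyl-expanded plus
        3 crystal-chi variants = 12."""
        s, m, spec, library, _ = designed
        ser_key = m.role_assignment["nucleophile_ser"]
        rots = library.rotamers(ser_key, "S")
        assert len(rots) == (3 + 1) * 3
        assert sum(r.is_crystal for r in rots) == 3
        hydroxyl_dihedrals = {r.chis[-1] for r in rots}
        assert hydroxyl_dihedrals == {60.0, 180.0, -60.0}

    def test_gly_ala_single_rotamer(self, model):
        s, _ = fixtures.make_toy_scaffold(seed=4, n_decoy_residues=6, model=model)
        key = s.residues[0].key
        spec = DesignSpec(mutable_positions={key: "AG"})
        lib = build_rotamer_library(spec, s)
        assert len(lib.rotamers(key, "A")) == 1
        assert len(lib.rotamers(key, "G")) == 1

    def test_bond_lengths_match_ideal_geometry(self, designed):
        """Every generated rotamer reproduces the ideal bond-length table."""
        s, m, spec, library, _ = designed
        checks = {
            ("S", "CB", "OG"): 1.42,
            ("K", "CB", "CG"): 1.52,
            ("K", "CE", "NZ"): 1.49,
            ("F", "CG", "CD1"): 1.39,
            ("L", "CG", "CD1"): 1.52,
            ("V", "CB", "CG1"): 1.52,
        }
        seen = set()
        for (key, aa), rots in library.entries.items():
            for rot in rots:
                for (caa, a, b), ideal in checks.items():
                    if caa == aa and a in rot.atoms and b in rot.atoms:
                        d = np.linalg.norm(rot.atoms[a] - rot.atoms[b])
                        assert d == pytest.approx(ideal, abs=1e-2)
                        seen.add((caa, a, b))
        assert len(seen) >= 4

    def test_crystal_rotamer_reproduces_native_coordinates(self, designed):
        s, m, spec, library, _ = designed
        ser_key = m.role_assignment["nucleophile_ser"]
        res = s.residue(*ser_key)
        crystal = [r for r in library.rotamers(ser_key, "S") if r.is_crystal]
        best = min(
            np.linalg.norm(r.atoms["OG"] - res.atom("OG").coords) for r in crystal
        )
        assert best < 1e-6


class TestEnergyModel:
    def test_lj_zero_at_sigma(self):
        params = EnergyModelParams()
        from enzysite.design import _AtomGroup

        sigma = (1.7 + 1.7) * 2 ** (-1 / 6)
        a = _AtomGroup([("C1", "C", np.zeros(3), 0.0, "A")])
        b = _AtomGroup([("C2", "C", np.array([sigma, 0, 0]), 0.0, "A")])
        assert interaction_energy(a, b, params) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_depth(self):
        params = EnergyModelParams()
        from enzysite.design import _AtomGroup

        rmin = 1.7 + 1.7
        a = _AtomGroup([("C1", "C", np.zeros(3), 0.0, "A")])
        b = _AtomGroup([("C2", "C", np.array([rmin, 0, 0]), 0.0, "A")])
        assert interaction_energy(a, b, params) == pytest.approx(-params.lj_epsilon)

    def test_clash_capped(self):
        params = EnergyModelParams()
        from enzysite.design import _AtomGroup

        a = _AtomGroup([("C1", "C", np.zeros(3), 0.0, "A")])
        b = _AtomGroup([("C2", "C", np.array([0.3, 0, 0]), 0.0, "A")])
        assert interaction_energy(a, b, params) == params.clash_cap

    def test_hbond_bonus_counted_exactly_once(self, model):
        """A serine hydroxyl donating to the TS oxyanion receives the
        configured bonus once (term-level audit against LJ+Coulomb-only)."""
        from enzysite.design import _rotamer_group, _ts_group

        params = EnergyModelParams()
        ts = model.ts
        u = ts.atoms["O1"] - ts.atoms["C1"]
        u = u / np.linalg.norm(u)  # outward oxyanion direction, clash-free
        og = ts.atoms["O1"] + 2.9 * u
        hg = og + 0.96 * (ts.atoms["O1"] - og) / np.linalg.norm(ts.atoms["O1"] - og)
        cb = og + 1.42 * u
        rot = _rotamer_group("S", {"CB": cb, "OG": og, "HG": hg})
        tsg = _ts_group({n: ts.atoms[n] for n in ts.atoms}, {})
        with_hb = interaction_energy(rot, tsg, params)
        no_hb = interaction_energy(rot, tsg, EnergyModelParams(hbond_bonus=0.0))
        assert with_hb - no_hb == pytest.approx(params.hbond_bonus)

    def test_pair_table_symmetric(self, designed):
        *_, tables = designed
        for (i, j), m in tables.pairs.items():
            for ri, rj in itertools.product(
                range(min(4, m.shape[0])), range(min(4, m.shape[1]))
            ):
                assert tables.pair(i, ri, j, rj) == tables.pair(j, rj, i, ri)

    def test_entries_finite(self, designed):
        *_, tables = designed
        for s in tables.singles:
            assert np.all(np.isfinite(s))
        for m in tables.pairs.values():
            assert np.all(np.isfinite(m))
            assert np.all(m <= EnergyModelParams().clash_cap + 1e-9)


class TestGmecSearch:
    def test_single_position_picks_minimum(self):
        prob = PackingProblem(singles=[np.array([5.0, 1.0, 3.0])], pairs={})
        a, e, _ = solve_packing(prob)
        assert a == [1]
        assert e == 1.0

    def test_random_instances_match_exhaustive(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sizes = [int(rng.integers(2, 6)) for _ in range(4)]
            singles = [rng.normal(size=s) * 3 for s in sizes]
            pairs = {
                (i, j): rng.normal(size=(sizes[i], sizes[j])) * 2
                for i in range(4) for j in range(i + 1, 4)
            }
            prob = PackingProblem(singles=singles, pairs=pairs)
            _, e, _ = solve_packing(prob)
            best = min(
                prob.energy(c)
                for c in itertools.product(*[range(s) for s in sizes])
            )
            assert e == pytest.approx(best, abs=1e-9)

    def test_dee_never_eliminates_the_optimum(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            sizes = [int(rng.integers(2, 7)) for _ in range(int(rng.integers(2, 5)))]
            n = len(sizes)
            singles = [rng.normal(size=s) * 3 for s in sizes]
            pairs = {
                (i, j): rng.normal(size=(sizes[i], sizes[j])) * 2
                for i in range(n) for j in range(i + 1, n)
            }
            prob = PackingProblem(singles=singles, pairs=pairs)
            _, eliminated = dee_prune(prob)
            opt = min(
                itertools.product(*[range(s) for s in sizes]), key=prob.energy
            )
            for i, r in eliminated:
                assert opt[i] != r

    def test_ceiling_raises_explicitly(self):
        singles = [np.zeros(10)] * 8  # 10^8 assignments, nothing prunable
        prob = PackingProblem(singles=singles, pairs={})
        with pytest.raises(RuntimeError, match="ceiling"):
            solve_packing(prob, use_dee=False, ceiling=10_000)

    def test_gmec_on_tables(self, designed):
        *_, tables = designed
        a, e, _ = search_gmec(tables)
        assert "TS" in a
        a2, e2, _ = search_gmec(tables, bound=False)
        assert "TS" not in a2


class TestEnumerateDesigns:
    def test_matches_exhaustive_on_toy(self, designed):
        """Brute-force oracle: distinct sequences in bound-energy order."""
        *_, tables = designed
        designs = enumerate_designs(tables, count=100, diversity=1)
        energies = [d.g_bound for d in designs]
        assert energies == sorted(energies)
        # exhaustive recomputation of each sequence's optimal bound energy
        for d in designs[:6]:
            _, e, _ = search_gmec(tables, d.aa_choice, bound=True, use_dee=False)
            assert e == pytest.approx(d.g_bound, abs=1e-9)

    def test_wild_type_has_zero_ddg(self, designed):
        *_, tables = designed
        designs = enumerate_designs(tables, count=100, diversity=1)
        wt = [d for d in designs if not d.mutations]
        assert len(wt) == 1
        assert wt[0].ddg_bind == pytest.approx(0.0, abs=1e-12)
        assert wt[0].ddg_fold == pytest.approx(0.0, abs=1e-12)

    def test_energy_identities_hold(self, designed):
        *_, tables = designed
        for d in enumerate_designs(tables, count=100, diversity=1):
            assert d.g_bind == pytest.approx(d.g_bound - d.g_unbound, abs=1e-9)
            assert d.g_fold == pytest.approx(d.g_unbound, abs=1e-9)
            assert d.ddg_total == pytest.approx(d.ddg_bind + d.ddg_fold, abs=1e-9)

    def test_diversity_two_enforced_pairwise(self, designed):
        from enzysite.design import _aa_differences

        *_, tables = designed
        designs = enumerate_designs(tables, count=10, diversity=2)
        for a, b in itertools.combinations(designs, 2):
            assert _aa_differences(a, b) >= 2

    def test_mutation_class_counting(self, designed):
        *_, tables = designed
        designs = enumerate_designs(tables, count=100, diversity=1)
        for d in designs:
            expected = sum(
                1 for k, aa in d.aa_choice.items() if aa != tables.native_aa[k]
            )
            assert d.n_mutations == expected


def _mk_design(muts, ddg_bind, ddg_fold):
    return SequenceDesign(
        mutations=muts,
        aa_choice={},
        g_bound=ddg_bind + ddg_fold,
        g_unbound=ddg_fold,
        g_bind=ddg_bind,
        g_fold=ddg_fold,
        ddg_bind=ddg_bind,
        ddg_fold=ddg_fold,
        ddg_total=ddg_bind + ddg_fold,
    )


class TestSelectCandidates:
    def test_energy_clause_admits(self):
        d = _mk_design(["I1K"], -1.0, 7.9)
        sel, audit = select_candidates([d])
        assert sel == [d]
        assert audit[0]["energy_clause"] is True

    def test_rank_clause_admits_high_fold_design(self):
        good = [_mk_design([f"A{i}V"], -5.0 - i, 0.0) for i in range(5)]
        bad = _mk_design(["B9W"], 2.0, 20.0)
        sel, audit = select_candidates(good + [bad], SelectionCriteria(top_total_rank=30))
        assert bad in sel
        assert audit[-1]["energy_clause"] is False
        assert audit[-1]["rank_clause"] is True

    def test_704_design_set_matches_comprehension_oracle(self):
        designs, truth = fixtures.synth_design_set(seed=3)
        assert len(designs) == 704
        crit = SelectionCriteria()
        sel, _ = select_candidates(designs, crit)
        ranked = sorted(designs, key=lambda d: (d.ddg_total, tuple(d.mutations)))
        top30 = set(id(d) for d in ranked[:30])
        oracle = [
            d for d in designs
            if (d.ddg_bind < 0 and d.ddg_fold < 8) or id(d) in top30
        ]
        assert [id(d) for d in sel] == [id(d) for d in oracle]

    def test_idempotent_and_order_invariant(self, rng):
        designs, _ = fixtures.synth_design_set(seed=5, n_designs=100,
                                               n_single=30, n_double=40, n_triple=30)
        sel1, _ = select_candidates(designs)
        sel2, _ = select_candidates(sel1)
        assert sel2 == sel1
        shuffled = list(designs)
        rng.shuffle(shuffled)
        sel3, _ = select_candidates(shuffled)
        assert {tuple(d.mutations) for d in sel3} == {tuple(d.mutations) for d in sel1}

    def test_mutant_class_composition_of_fixture(self):
        designs, truth = fixtures.synth_design_set(seed=0)
        counts = {1: 0, 2: 0, 3: 0}
        for d in designs:
            counts[d.n_mutations] += 1
        assert counts == {1: 104, 2: 400, 3: 200}
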