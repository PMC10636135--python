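import itertools

import numpy as np
import pytest

from enzysite import fixtures
from enzysite.matcher import (
    MatchConfig,
    MatchResult,
    detect_pockets,
    match_active_site,
    place_and_score,
    rank_matches,
    triad_rmsd_vs_native,
)

TRIAD = ("nucleophile_ser", "base_his", "acid_asp_glu")


def oracle_matches(structure, model, config):
    """Brute-force oracle: enumerate every admissible triad triple directly
    from residue types and score it with the shared placement routine."""
    sers = [r.key for r in structure.residues if r.aa_type == "S"]
    hiss = [r.key for r in structure.residues if r.aa_type == "H"]
    acids = [r.key for r in structure.residues if r.aa_type in ("D", "E")]
    out = []
    for ser, his, acid in itertools.product(sers, hiss, acids):
        if len({ser, his, acid}) != 3:
            continue
        m = place_and_score(
            structure,
            {"nucleophile_ser": ser, "base_his": his, "acid_asp_glu": acid},
            model,
            config,
        )
        if m is not None and m.penalty <= config.penalty_cutoff:
            out.append(m)
    return out


class TestDetectPockets:
    def test_convex_helix_has_no_pockets(self):
        s, _ = fixtures.make_shell_scaffold("helix")
        assert detect_pockets(s) == []

    def test_cup_yields_one_pocket_with_lining(self):
        s, truth = fixtures.make_shell_scaffold("cup")
        pockets = detect_pockets(s)
        assert len(pockets) == 1
        lining = set(truth["pockets"][0])
        members = set(pockets[0].member_positions)
        # the pocket lining is recovered (most of the cup residues)
        assert len(members & lining) >= 0.8 * len(lining)

    def test_two_cavities_larger_first(self):
        s, truth = fixtures.make_shell_scaffold("two")
        pockets = detect_pockets(s, n_pockets=2, min_points=20)
        assert len(pockets) == 2
        assert pockets[0].volume_proxy > pockets[1].volume_proxy
        big = set(truth["pockets"][0])
        small = set(truth["pockets"][1])
        assert len(set(pockets[0].member_positions) & big) > len(
            set(pockets[0].member_positions) & small
        )

    def test_deterministic(self):
        s, _ = fixtures.make_shell_scaffold("cup")
        p1 = detect_pockets(s)
        p2 = detect_pockets(s)
        assert [p.member_positions for p in p1] == [p.member_positions for p in p2]


class TestMatchActiveSite:
    def test_planted_site_found_with_zero_penalty(self, model, toy_scaffold):
        s, truth = toy_scaffold
        ms = match_active_site(s, model)
        assert len(ms) == 1
        m = ms[0]
        assert m.penalty < 1e-6
        for role in TRIAD:
            assert m.role_assignment[role] == truth["planted_positions"][role]

    def test_nucleophile_mutated_to_ala_gives_no_match(self, model):
        s, truth = fixtures.make_toy_scaffold(seed=21, n_decoy_residues=8)
        ser_key = truth["planted_positions"]["nucleophile_ser"]
        res = s.residue(*ser_key)
        res.aa_type = "A"
        res.atoms = [a for a in res.atoms if a.name not in ("OG", "HG")]
        ms = match_active_site(s, model)
        planted_triads = [
            m for m in ms if m.role_assignment["nucleophile_ser"] == ser_key
        ]
        assert planted_triads == []

    def test_matches_exhaustive_enumeration_2s2h2d(self, model):
        """30-residue fixture with 2 Ser / 2 His / 2 Asp: the matcher equals
        exhaustive enumeration over the triples in membership and penalty."""
        s, _ = fixtures.make_toy_scaffold(
            seed=30, n_decoy_residues=21, extra_sites={"H": 1, "D": 1}
        )
        assert len(s.residues) == 29
        config = MatchConfig()
        got = match_active_site(s, model, config)
        expected = rank_matches(oracle_matches(s, model, config))
        assert len(got) == len(expected)
        for a, b in zip(got, expected):
            assert a.role_assignment == b.role_assignment
            assert a.penalty == pytest.approx(b.penalty, abs=1e-6)

    def test_far_decoys_do_not_change_the_match(self, model):
        s1, truth = fixtures.make_toy_scaffold(seed=5, n_decoy_residues=6)
        m1 = match_active_site(s1, model)[0]
        # same fixture, extra decoys planted far (>20 A) from the site
        s2, _ = fixtures.make_toy_scaffold(
            seed=5, n_decoy_residues=6, decoy_radius=(9.0, 14.0)
        )
        import copy

        rng = np.random.default_rng(99)
        far = fixtures.make_toy_scaffold(seed=77, n_decoy_residues=4)[0]
        next_pos = max(r.seq_pos for r in s2.residues) + 1
        for r in copy.deepcopy(far.residues[:4]):
            r.seq_pos = next_pos
            for a in r.atoms:
                a.coords = a.coords + np.array([40.0, 0.0, 0.0])
            s2.residues.append(r)
            next_pos += 1
        m2 = match_active_site(s2, model)[0]
        for role in TRIAD:
            assert m2.role_assignment[role] == m1.role_assignment[role]
        assert m2.penalty == pytest.approx(m1.penalty, abs=1e-9)

    def test_deterministic_across_runs(self, model, toy_scaffold):
        s, _ = toy_scaffold
        a = match_active_site(s, model)
        b = match_active_site(s, model)
        assert [m.role_assignment for m in a] == [m.role_assignment for m in b]
        assert [m.penalty for m in a] == [m.penalty for m in b]


def _dummy_match(penalty, positions, rot_spread=1.0):
    rots = {}
    for i, role in enumerate(TRIAD):
        rots[role] = {"CB": np.array([i * rot_spread, 0.0, 0.0])}
    return MatchResult(
        scaffold_id="x",
        role_assignment=dict(zip(TRIAD, positions)),
        placed_rotamers=rots,
        ts_pose={},
        penalty=penalty,
    )


class TestRankMatches:
    def test_ascending_with_deterministic_tie_break(self):
        ms = [
            _dummy_match(2.0, [("A", 1), ("A", 2), ("A", 3)]),
            _dummy_match(0.5, [("A", 4), ("A", 5), ("A", 6)], rot_spread=2.0),
            _dummy_match(0.5, [("A", 1), ("A", 5), ("A", 6)], rot_spread=1.0),
        ]
        ranked = rank_matches(ms)
        assert [m.penalty for m in ranked] == [0.5, 0.5, 2.0]
        # tie broken by compactness: tighter triad first
        assert ranked[0].role_assignment["nucleophile_ser"] == ("A", 1)

    def test_single_match_is_itself(self):
        m = _dummy_match(1.0, [("A", 1), ("A", 2), ("A", 3)])
        assert rank_matches([m]) == [m]

    def test_permutation_invariance(self, rng):
        ms = [
            _dummy_match(float(p), [("A", i * 3 + 1), ("A", i * 3 + 2), ("A", i * 3 + 3)])
            for i, p in enumerate([3.0, 1.0, 1.0, 0.2, 2.5])
        ]
        ref = rank_matches(list(ms))
        for _ in range(5):
            shuffled = list(ms)
            rng.shuffle(shuffled)
            assert rank_matches(shuffled) == ref


class TestTriadRmsdVsNative:
    def test_identical_to_native_is_zero(self, model, toy_scaffold):
        s, _ = toy_scaffold
        m = match_active_site(s, model)[0]
        assert triad_rmsd_vs_native(m, s) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_displacement_gives_that_rmsd(self, model, toy_scaffold):
        s, _ = toy_scaffold
        m = match_active_site(s, model)[0]
        shifted = {
            role: {n: p + np.array([0.5, 0.0, 0.0]) for n, p in rots.items()}
            for role, rots in m.placed_rotamers.items()
        }
        m2 = MatchResult(
            scaffold_id=m.scaffold_id,
            role_assignment=m.role_assignment,
            placed_rotamers=shifted,
            ts_pose=m.ts_pose,
            penalty=m.penalty,
        )
        assert triad_rmsd_vs_native(m2, s) == pytest.approx(0.5, abs=1e-9)

    def test_equals_unsuper_posed_kabsch_on_same_atoms(self, model, toy_scaffold):
        """Cross-module oracle: same-frame RMSD over the identical atom list."""
        from enzysite.geometry import kabsch_rmsd

        s, _ = toy_scaffold
        m = match_active_site(s, model)[0]
        rng = np.random.default_rng(3)
        jittered = {
            role: {n: p + rng.normal(scale=0.3, size=3) for n, p in rots.items()}
            for role, rots in m.placed_rotamers.items()
        }
        m2 = MatchResult(
            scaffold_id=m.scaffold_id, role_assignment=m.role_assignment,
            placed_rotamers=jittered, ts_pose=m.ts_pose, penalty=m.penalty,
        )
        placed, native = [], []
        for role in TRIAD:
            res = s.residue(*m.role_assignment[role])
            for name, pos in sorted(jittered[role].items()):
                if name.startswith("H"):
                    continue
                placed.append(pos)
                native.append(res.atom(name).coords)
        expected = kabsch_rmsd(np.array(native), np.array(placed), superpose_first=False)
        assert triad_rmsd_vs_native(m2, s) == pytest.approx(expected, abs=1e-12)

    def test_missing_native_atoms_listed(self, model):
        s, _ = fixtures.make_toy_scaffold(seed=1, n_decoy_residues=8, model=model)
        m = match_active_site(s, model)[0]
        res = s.residue(*m.role_assignment["base_his"])
        res.atoms = [a for a in res.atoms if a.name != "NE2"]
        with pytest.raises(ValueError, match="NE2"):
            triad_rmsd_vs_native(m, s)


class TestInjectivity:
    def test_role_assignment_must_be_injective(self):
        with pytest.raises(ValueError, match="injective"):
            MatchResult(
                scaffold_id="x",
                role_assignment={"a": ("A", 1), "b": ("A", 1)},
                placed_rotamers={},
                ts_pose={},
                penalty=0.0,
            )
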