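import numpy as np
import pytest
import yaml

from enzysite import geometry
from enzysite.active_site import (
    GeometricConstraint,
    build_default_ts_molecule,
    constraint_penalty,
    load_active_site_config,
)


class TestDefaultModel:
    def test_shipped_config_shape(self, model):
        assert len(model.roles) == 6
        assert len(model.constraints) >= 8
        assert {r.role_id for r in model.roles} >= {
            "nucleophile_ser", "base_his", "acid_asp_glu",
            "oxyanion_nh_1", "oxyanion_nh_2", "carboxylate_binder_ser",
        }

    def test_oxyanion_roles_exclude_proline(self, model):
        for rid in ("oxyanion_nh_1", "oxyanion_nh_2"):
            assert "P" not in model.role(rid).allowed_aa
            assert len(model.role(rid).allowed_aa) == 19

    def test_acid_role_maps_asp_and_glu_atoms(self, model):
        role = model.role("acid_asp_glu")
        assert role.concrete_atom("OD", "D") == "OD1"
        assert role.concrete_atom("OD", "E") == "OE1"


class TestConfigValidation:
    def _write(self, tmp_path, doc):
        p = tmp_path / "m.yaml"
        p.write_text(yaml.safe_dump(doc))
        return p

    def _minimal_doc(self):
        return {
            "roles": [
                {"role_id": "nucleophile_ser", "allowed_aa": ["S"],
                 "anchor_atoms": {"OG": "OG"}},
                {"role_id": "base_his", "allowed_aa": ["H"],
                 "anchor_atoms": {"NE2": "NE2", "ND1": "ND1"}},
                {"role_id": "acid_asp_glu", "allowed_aa": ["D"],
                 "anchor_atoms": {"OD": {"D": "OD1"}}},
            ],
            "constraints": [
                {"label": "attack", "kind": "distance",
                 "atoms": [["nucleophile_ser", "OG"], ["TS", "C1"]],
                 "target": 2.5, "tol_lo": 2.0, "tol_hi": 3.0},
            ],
            "ts": "mhet_ti1",
        }

    def test_minimal_config_loads(self, tmp_path):
        m = load_active_site_config(self._write(tmp_path, self._minimal_doc()))
        assert len(m.roles) == 3

    def test_missing_base_his_rejected(self, tmp_path):
        doc = self._minimal_doc()
        doc["roles"] = [r for r in doc["roles"] if r["role_id"] != "base_his"]
        with pytest.raises(ValueError, match="base_his"):
            load_active_site_config(self._write(tmp_path, doc))

    def test_inverted_tolerance_window_rejected(self, tmp_path):
        doc = self._minimal_doc()
        doc["constraints"][0]["tol_lo"] = 3.5
        with pytest.raises(ValueError, match="outside"):
            load_active_site_config(self._write(tmp_path, doc))

    def test_dangling_role_reference_names_constraint(self, tmp_path):
        doc = self._minimal_doc()
        doc["constraints"].append(
            {"label": "ghost", "kind": "distance",
             "atoms": [["no_such_role", "X"], ["TS", "C1"]],
             "target": 3.0, "tol_lo": 2.0, "tol_hi": 4.0}
        )
        with pytest.raises(ValueError, match="ghost"):
            load_active_site_config(self._write(tmp_path, doc))


class TestTSMolecule:
    def test_tetrahedral_center_has_four_neighbors(self):
        ts = build_default_ts_molecule()
        assert sorted(ts.neighbors("C1")) == ["CA1", "O1", "O2", "ON"]

    def test_bond_graph_connected_and_torsions_settable(self):
        ts = build_default_ts_molecule()
        target = [45.0, 120.0, -90.0]
        moved = ts.with_torsions(target)
        assert np.allclose(moved.torsion_values(), target, atol=1e-8)

    def test_torsion_rotation_is_rigid_on_the_moving_side(self):
        ts = build_default_ts_molecule()
        moved = ts.with_torsions([ts.torsion_values()[0] + 60.0,
                                  ts.torsion_values()[1], ts.torsion_values()[2]])
        # bond lengths preserved
        for a, b in ts.bonds:
            d0 = np.linalg.norm(ts.atoms[a] - ts.atoms[b])
            d1 = np.linalg.norm(moved.atoms[a] - moved.atoms[b])
            assert d1 == pytest.approx(d0, abs=1e-9)


def _ideal_geometry(model):
    """Anchor coordinates at every constraint target (the planted layout)."""
    ts = model.ts
    a = ts.atoms

    def unit(v):
        return v / np.linalg.norm(v)

    og = a["C1"] + 2.5 * unit(a["ON"] - a["C1"])
    ne2 = None
    # reuse the fixture trick: intersect spheres around OG (3.0) and O2 (3.2)
    from enzysite.fixtures import _sphere_circle_point

    ne2 = _sphere_circle_point(og, 3.0, a["O2"], 3.2, prefer_away_from=a["C1"])
    nd1 = ne2 + 2.0 * unit(ne2 - a["C1"])  # any point; only OD-ND1 pair matters
    od = nd1 + 2.8 * unit(nd1 - a["C1"])
    u1 = unit(a["O1"] - a["C1"])
    n1 = a["O1"] + 2.9 * u1
    perp = unit(np.cross(u1, a["O2"] - a["C1"]))
    n2 = a["O1"] + 2.9 * unit(u1 + 0.8 * perp)
    bog = a["O4"] + 2.8 * unit(a["O4"] - a["C7"])
    return {
        "TS": dict(a),
        "nucleophile_ser": {"OG": og},
        "base_his": {"NE2": ne2, "ND1": nd1},
        "acid_asp_glu": {"OD": od},
        "oxyanion_nh_1": {"N": n1},
        "oxyanion_nh_2": {"N": n2},
        "carboxylate_binder_ser": {"OG": bog},
    }


class TestConstraintPenalty:
    def test_geometry_at_targets_scores_zero(self, model):
        pen, breakdown = constraint_penalty(model, _ideal_geometry(model))
        assert pen == pytest.approx(0.0, abs=1e-12)
        assert all(b["excess"] == 0.0 for b in breakdown)

    def test_half_angstrom_excess_quarter_penalty(self, model):
        placed = _ideal_geometry(model)
        ts = model.ts.atoms
        # push oxyanion donor 1 to tol_hi + 0.5 (weight 1)
        u = placed["oxyanion_nh_1"]["N"] - ts["O1"]
        u /= np.linalg.norm(u)
        placed["oxyanion_nh_1"] = {"N": ts["O1"] + 4.0 * u}  # tol_hi 3.5
        pen, _ = constraint_penalty(model, placed)
        assert pen == pytest.approx(0.25, abs=1e-12)

    def test_matches_hand_summed_breakdown(self, model, rng):
        """Brute-force re-summation oracle on randomly perturbed geometry."""
        placed = _ideal_geometry(model)
        for role in placed:
            if role == "TS":
                continue
            placed[role] = {
                k: v + rng.normal(scale=0.8, size=3) for k, v in placed[role].items()
            }
        pen, breakdown = constraint_penalty(model, placed)
        by_hand = 0.0
        for c in model.constraints:
            pts = [placed[o][l] for o, l in c.atoms]
            val = geometry.measure(c.kind, pts)
            ex = max(c.tol_lo - val, 0.0) + max(val - c.tol_hi, 0.0)
            by_hand += c.weight * ex * ex
        assert pen == pytest.approx(by_hand, abs=1e-12)
        assert pen == pytest.approx(sum(b["penalty"] for b in breakdown), abs=1e-12)

    def test_zero_iff_all_inside_windows(self, model, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            placed = _ideal_geometry(model)
            role = "oxyanion_nh_2"
            placed[role] = {"N": placed[role]["N"] + r.normal(scale=1.5, size=3)}
            pen, breakdown = constraint_penalty(model, placed)
            inside = all(b["excess"] == 0.0 for b in breakdown)
            assert (pen == 0.0) == inside

    def test_penalty_monotone_in_single_violation(self, model):
        ts = model.ts.atoms
        u = np.array([0.0, 0.0, 1.0])
        pens = []
        for extra in np.linspace(0.0, 2.0, 9):
            placed = _ideal_geometry(model)
            placed["oxyanion_nh_1"] = {"N": ts["O1"] + (3.5 + extra) * u}
            pens.append(constraint_penalty(model, placed)[0])
        assert all(b >= a - 1e-12 for a, b in zip(pens, pens[1:]))

    def test_unresolvable_atom_names_constraint(self, model):
        placed = _ideal_geometry(model)
        del placed["base_his"]["ND1"]
        with pytest.raises(KeyError, match="asp_his_relay"):
            constraint_penalty(model, placed)

    def test_constraint_validation(self):
        with pytest.raises(ValueError, match="outside"):
            GeometricConstraint(
                kind="distance", atoms=(("a", "X"), ("b", "Y")),
                target=5.0, tol_lo=1.0, tol_hi=4.0,
            )
        with pytest.raises(ValueError, match="weight"):
            GeometricConstraint(
                kind="distance", atoms=(("a", "X"), ("b", "Y")),
                target=2.0, tol_lo=1.0, tol_hi=4.0, weight=-1.0,
            )
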