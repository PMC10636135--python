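# Default active-site model for MHET hydrolysis (serine-hydrolase acylation).
#
# Six catalytic roles: the Ser-His-Asp(Glu) charge-relay triad, two backbone
# N-H oxyanion-hole donors (any non-proline residue), and a Ser/Thr hydroxyl
# binding the substrate's terminal carboxylate.  Distance windows follow the
# canonical geometry of serine hydrolases bound to tetrahedral-intermediate
# analogs (hydrogen-bonding heavy-atom separations 2.6-3.5 A; nucleophile
# oxygen 2-3 A from the sp3 carbon).  Every value here is overridable.

roles:
  - role_id: nucleophile_ser
    allowed_aa: [S]
    anchor_atoms:
      OG: OG
      CB: CB
  - role_id: base_his
    allowed_aa: [H]
    anchor_atoms:
      NE2: NE2
      ND1: ND1
  - role_id: acid_asp_glu
    allowed_aa: [D, E]
    anchor_atoms:
      OD:
        D: OD1
        E: OE1
  - role_id: oxyanion_nh_1
    allowed_aa: non_proline
    anchor_atoms:
      "N": "N"
  - role_id: oxyanion_nh_2
    allowed_aa: non_proline
    anchor_atoms:
      "N": "N"
  - role_id: carboxylate_binder_ser
    allowed_aa: [S, T]
    anchor_atoms:
      OG:
        S: OG
        T: OG1

constraints:
  - label: nucleophile_attack_distance
    kind: distance
    atoms: [[nucleophile_ser, OG], [TS, C1]]
    target: 2.5
    tol_lo: 2.0
    tol_hi: 3.0
    weight: 1.0
  - label: attack_direction
    kind: distance
    # ON marks the nucleophile-oxygen position of the tetrahedral intermediate;
    # keeping OG near it enforces the attack trajectory without an angle term.
    atoms: [[nucleophile_ser, OG], [TS, "ON"]]
    target: 0.8
    tol_lo: 0.0
    tol_hi: 1.6
    weight: 0.5
  - label: his_ser_relay
    kind: distance
    atoms: [[base_his, NE2], [nucleophile_ser, OG]]
    target: 3.0
    tol_lo: 2.6
    tol_hi: 3.5
    weight: 1.0
  - label: asp_his_relay
    kind: distance
    atoms: [[acid_asp_glu, OD], [base_his, ND1]]
    target: 2.8
    tol_lo: 2.6
    tol_hi: 3.5
    weight: 1.0
  - label: oxyanion_hbond_1
    kind: distance
    atoms: [[oxyanion_nh_1, "N"], [TS, O1]]
    target: 2.9
    tol_lo: 2.6
    tol_hi: 3.5
    weight: 1.0
  - label: oxyanion_hbond_2
    kind: distance
    atoms: [[oxyanion_nh_2, "N"], [TS, O1]]
    target: 2.9
    tol_lo: 2.6
    tol_hi: 3.5
    weight: 1.0
  - label: carboxylate_hbond
    kind: distance
    atoms: [[carboxylate_binder_ser, OG], [TS, O4]]
    target: 2.8
    tol_lo: 2.5
    tol_hi: 3.5
    weight: 1.0
  - label: his_leaving_group
    kind: distance
    atoms: [[base_his, NE2], [TS, O2]]
    target: 3.2
    tol_lo: 2.6
    tol_hi: 4.0
    weight: 0.5

ts: mhet_ti1
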