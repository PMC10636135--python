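"""Catalytic-indicator screening of MD trajectory frames.

Four per-trajectory indicators monitor whether a design holds the substrate
in a catalytically productive pose:

* ``freq_rmsd_ts`` - fraction of frames whose TS heavy-atom RMSD (after
  superposing the protein backbone onto the first frame) is below 2.5 A,
  with the first frame as reference;
* ``attack_frac_3A`` - fraction of frames with the nucleophilic attack
  distance (Ser O-gamma to the sp3 ester carbon) below 3.0 A (the mean
  distance is reported alongside for diagnostics);
* ``hbond_freq_1`` / ``hbond_freq_2`` - occupancy of the two oxyanion-hole
  hydrogen bonds (donor-acceptor < 3.5 A and donor-H-acceptor > 120 deg,
  strict).

A design "improves" on the wild type only when **all four** pooled indicators
are strictly better (higher).  The two-round funnel screens every design on
short replicate trajectories first, then re-screens the survivors on longer
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import gemmi
import numpy as np

from .geometry import HBondCriteria, superpose

__all__ = [
    "FrameSet",
    "CatalyticIndicatorSet",
    "FunnelConfig",
    "ScreeningReport",
    "LabelingConfig",
    "load_frames",
    "write_frames",
    "catalytic_indicators",
    "aggregate_and_compare",
    "improves_on",
    "two_round_funnel",
]


@dataclass
class LabelingConfig:
    """How to find the catalytic atoms in a frame roster.

    Atom addresses are (chain, seq_pos, atom_name); the TS residue is
    identified by residue name and all its non-hydrogen atoms define the
    RMSD_TS atom set.
    """

    ser_og: tuple[str, int, str]
    ts_residue: str = "TSM"
    ts_center: str = "C1"
    ts_oxyanion: str = "O1"
    donor1: tuple[str, int] = ("A", 2)
    donor2: tuple[str, int] = ("A", 3)
    donor_atom: str = "N"
    donor_h: str = "H"


@dataclass
class FrameSet:
    """Replicate trajectory: (n_frames, n_atoms, 3) coordinates + roster."""

    design_id: str
    replicate_id: int
    coords: np.ndarray
    roster: list[tuple[str, int, str, str]]  # (chain, seq_pos, resname, atom)
    labels: dict
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a frame set needs at least 2 frames")
        if self.coords.shape[1] != len(self.roster):
            raise ValueError("coords second axis must match the roster")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class CatalyticIndicatorSet:
    """The four screening statistics for one design (or one replicate)."""

    freq_rmsd_ts: float
    attack_dist_mean: float
    attack_frac_3A: float
    hbond_freq_1: float
    hbond_freq_2: float
    n_frames_total: int

    def __post_init__(self) -> None:
        for name in ("freq_rmsd_ts", "attack_frac_3A", "hbond_freq_1", "hbond_freq_2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.freq_rmsd_ts, self.attack_frac_3A, self.hbond_freq_1, self.hbond_freq_2)


@dataclass
class FunnelConfig:
    """Replicate counts / lengths of the two screening rounds and ranking."""

    round1_replicates: int = 10
    round1_length_ns: float = 1.0
    round2_replicates: int = 5
    round2_length_ns: float = 5.0
    ranking_keys: tuple[str, ...] = (
        "attack_frac_3A", "freq_rmsd_ts", "hbond_freq_1", "hbond_freq_2"
    )


@dataclass
class ScreeningReport:
    round1_survivors: list[str]
    round2_survivors: list[str]
    pending: list[str]
    table: dict[str, dict]
    shortlist: list[str]
    wt_round1: CatalyticIndicatorSet | None = None
    wt_round2: CatalyticIndicatorSet | None = None


# ---------------------------------------------------------------------------
# Frame I/O (multi-model PDB)
# ---------------------------------------------------------------------------

def _resolve_labels(roster: list, labeling: LabelingConfig) -> dict:
    index = {(c, s, a): i for i, (c, s, _rn, a) in enumerate(roster)}

    def need(addr, what):
        if addr not in index:
            raise KeyError(f"{what} atom {addr} absent from the frame roster")
        return index[addr]

    ts_heavy = [
        i for i, (_c, _s, rn, a) in enumerate(roster)
        if rn == labeling.ts_residue and not a.startswith("H")
    ]
    if not ts_heavy:
        raise KeyError(f"no TS residue {labeling.ts_residue!r} in the frame roster")
    ts_idx = {roster[i][3]: i for i in ts_heavy}
    for name, what in ((labeling.ts_center, "TS centre"), (labeling.ts_oxyanion, "TS oxyanion")):
        if name not in ts_idx:
            raise KeyError(f"{what} atom {name!r} absent in TS residue")
    backbone = [
        i for i, (_c, _s, rn, a) in enumerate(roster)
        if rn != labeling.ts_residue and a in ("N", "CA", "C", "O")
    ]
    d1c, d1s = labeling.donor1
    d2c, d2s = labeling.donor2
    return {
        "ser_og": need(labeling.ser_og, "nucleophile O-gamma"),
        "ts_c1": ts_idx[labeling.ts_center],
        "ts_o1": ts_idx[labeling.ts_oxyanion],
        "ts_heavy": ts_heavy,
        "don1_n": need((d1c, d1s, labeling.donor_atom), "oxyanion donor 1 N"),
        "don1_h": need((d1c, d1s, labeling.donor_h), "oxyanion donor 1 H"),
        "don2_n": need((d2c, d2s, labeling.donor_atom), "oxyanion donor 2 N"),
        "don2_h": need((d2c, d2s, labeling.donor_h), "oxyanion donor 2 H"),
        "backbone": backbone,
    }


def load_frames(
    path,
    labeling: LabelingConfig,
    design_id: str = "",
    replicate_id: int = 0,
    frame_interval_ps: float = 10.0,
) -> FrameSet:
    """Read a multi-model PDB trajectory; all models must share one roster."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    rosters = []
    frames = []
    for model in st:
        roster = []
        coords = []
        for chain in model:
            for res in chain:
                for atom in res:
                    roster.append((chain.name, res.seqid.num, res.name.strip(), atom.name))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        rosters.append(roster)
        frames.append(coords)
    for k, r in enumerate(rosters[1:], start=2):
        if r != rosters[0]:
            missing = set(map(tuple, rosters[0])) - set(map(tuple, r))
            detail = f"; missing {sorted(missing)[:3]}" if missing else ""
            raise ValueError(f"model {k} roster differs from model 1{detail}")
    labels = _resolve_labels(rosters[0], labeling)
    return FrameSet(
        design_id=design_id or st.name,
        replicate_id=replicate_id,
        coords=np.array(frames, dtype=float),
        roster=rosters[0],
        labels=labels,
        frame_interval_ps=frame_interval_ps,
    )


def write_frames(frames: FrameSet, path) -> None:
    """Write a frame set as a multi-model PDB."""
    st = gemmi.Structure()
    st.name = frames.design_id or "frames"
    # group roster indices by (chain, seq, resname), preserving order
    groups: list[tuple[tuple[str, int, str], list[int]]] = []
    for i, (chain_id, seq, resname, _atom) in enumerate(frames.roster):
        key = (chain_id, seq, resname)
        if not groups or groups[-1][0] != key:
            groups.append((key, []))
        groups[-1][1].append(i)

    for f in range(frames.n_frames):
        model = gemmi.Model(str(f + 1))
        chains: dict[str, gemmi.Chain] = {}
        chain_order: list[str] = []
        for (chain_id, seq, resname), atom_idx in groups:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(seq, " ")
            res.het_flag = "H" if resname == "TSM" else "A"
            for i in atom_idx:
                atom = gemmi.Atom()
                atom_name = frames.roster[i][3]
                atom.name = atom_name
                atom.element = gemmi.Element("H" if atom_name.startswith("H") else atom_name[0])
                atom.pos = gemmi.Position(*frames.coords[f, i])
                res.add_atom(atom)
            if chain_id not in chains:
                chains[chain_id] = gemmi.Chain(chain_id)
                chain_order.append(chain_id)
            chains[chain_id].add_residue(res)
        for chain_id in chain_order:
            model.add_chain(chains[chain_id])
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def catalytic_indicators(
    frames: FrameSet,
    criteria: HBondCriteria | None = None,
    rmsd_cut: float = 2.5,
    attack_cut: float = 3.0,
) -> CatalyticIndicatorSet:
    """Compute the four indicators over all frames of one replicate."""
    crit = criteria or HBondCriteria()
    L = frames.labels
    X = frames.coords
    n = frames.n_frames

    # RMSD_TS vs the first frame, after backbone superposition
    bb = L["backbone"]
    ts = L["ts_heavy"]
    ref_bb = X[0][bb]
    ref_ts = X[0][ts]
    n_below = 0
    for f in range(n):
        if len(bb) >= 3:
            _, rot, trans = superpose(ref_bb, X[f][bb])
            fitted = X[f][ts] @ rot.T + trans
        else:
            fitted = X[f][ts]
        rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_ts) ** 2, axis=1))))
        if rmsd < rmsd_cut:
            n_below += 1

    d_attack = np.linalg.norm(X[:, L["ser_og"], :] - X[:, L["ts_c1"], :], axis=1)

    def hbond_fraction(n_idx: int, h_idx: int) -> float:
        dn = X[:, n_idx, :]
        hh = X[:, h_idx, :]
        acc = X[:, L["ts_o1"], :]
        d = np.linalg.norm(dn - acc, axis=1)
        u = dn - hh
        v = acc - hh
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (d < crit.max_donor_acceptor_A) & (ang > crit.min_donor_h_acceptor_deg)
        return float(np.mean(ok))

    return CatalyticIndicatorSet(
        freq_rmsd_ts=n_below / n,
        attack_dist_mean=float(np.mean(d_attack)),
        attack_frac_3A=float(np.mean(d_attack < attack_cut)),
        hbond_freq_1=hbond_fraction(L["don1_n"], L["don1_h"]),
        hbond_freq_2=hbond_fraction(L["don2_n"], L["don2_h"]),
        n_frames_total=n,
    )


def pool_indicators(per_replicate: list[CatalyticIndicatorSet]) -> CatalyticIndicatorSet:
    """Frame-weighted pooling across replicates."""
    if not per_replicate:
        raise ValueError("need at least one replicate")
    w = np.array([r.n_frames_total for r in per_replicate], dtype=float)
    total = int(w.sum())

    def mean(attr):
        return float(np.sum(w * np.array([getattr(r, attr) for r in per_replicate])) / w.sum())

    return CatalyticIndicatorSet(
        freq_rmsd_ts=mean("freq_rmsd_ts"),
        attack_dist_mean=mean("attack_dist_mean"),
        attack_frac_3A=mean("attack_frac_3A"),
        hbond_freq_1=mean("hbond_freq_1"),
        hbond_freq_2=mean("hbond_freq_2"),
        n_frames_total=total,
    )


def improves_on(design: CatalyticIndicatorSet, wt: CatalyticIndicatorSet) -> bool:
    """Strict simultaneous improvement of all four indicators (higher is
    better for every fraction; the mean attack distance is diagnostic only)."""
    return all(d > w for d, w in zip(design.as_tuple(), wt.as_tuple()))


def aggregate_and_compare(
    per_replicate: list[CatalyticIndicatorSet],
    wt: CatalyticIndicatorSet,
) -> tuple[CatalyticIndicatorSet, bool]:
    """Pool replicate indicators and compare against the wild type."""
    pooled = pool_indicators(per_replicate)
    return pooled, improves_on(pooled, wt)


# ---------------------------------------------------------------------------
# Two-round funnel
# ---------------------------------------------------------------------------

def _pooled_for(frame_sets: list[FrameSet], **kwargs) -> CatalyticIndicatorSet:
    return pool_indicators([catalytic_indicators(fs, **kwargs) for fs in frame_sets])


def two_round_funnel(
    designs_round1: Mapping[str, list[FrameSet]],
    wt_round1: list[FrameSet],
    round2_provider: Callable[[str], list[FrameSet] | None] | Mapping[str, list[FrameSet]],
    wt_round2: list[FrameSet],
    config: FunnelConfig | None = None,
    criteria: HBondCriteria | None = None,
) -> ScreeningReport:
    """Screen all designs in round 1, re-screen survivors in round 2.

    ``round2_provider`` supplies the longer trajectories for round-1
    survivors (callable or mapping); survivors without round-2 data are
    listed as pending and excluded from the final ranking.  Deterministic:
    designs are processed in sorted order.
    """
    config = config or FunnelConfig()
    wt1 = _pooled_for(wt_round1, criteria=criteria)
    wt2 = _pooled_for(wt_round2, criteria=criteria)

    table: dict[str, dict] = {}
    round1_survivors: list[str] = []
    for design_id in sorted(designs_round1):
        pooled = _pooled_for(designs_round1[design_id], criteria=criteria)
        ok = improves_on(pooled, wt1)
        table[design_id] = {"round1": pooled, "round1_improves": ok}
        if ok:
            round1_survivors.append(design_id)

    getter = round2_provider if callable(round2_provider) else round2_provider.get
    round2_survivors: list[str] = []
    pending: list[str] = []
    for design_id in round1_survivors:
        fs = getter(design_id)
        if not fs:
            pending.append(design_id)
            table[design_id]["round2"] = None
            continue
        pooled = _pooled_for(fs, criteria=criteria)
        ok = improves_on(pooled, wt2)
        table[design_id]["round2"] = pooled
        table[design_id]["round2_improves"] = ok
        if ok:
            round2_survivors.append(design_id)

    def rank_key(design_id):
        ind = table[design_id]["round2"]
        return tuple(-getattr(ind, k) for k in config.ranking_keys) + (design_id,)

    shortlist = sorted(round2_survivors, key=rank_key)
    return ScreeningReport(
        round1_survivors=round1_survivors,
        round2_survivors=round2_survivors,
        pending=pending,
        table=table,
        shortlist=shortlist,
        wt_round1=wt1,
        wt_round2=wt2,
    )
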