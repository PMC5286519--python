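"""Hydrogen-bond and salt-bridge detection and ensemble occupancy.

Distance-only criteria: a hydrogen bond is any donor–acceptor pair with
d(D,A) <= 3.9 Å (plus d(H,A) <= 2.5 Å when the model carries hydrogens);
a salt bridge is any acidic-oxygen/basic-nitrogen pair with d <= 3.2 Å.
An optional D-H...A >= 90° angular switch is provided for stricter
detection but is off by default since only the distance thresholds are
part of the standard criteria used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .flexibility import CoordinateEnsemble
from .structure import AtomRecord, LoopDefinition, StructureModel

__all__ = [
    "DonorAcceptorTable",
    "HydrogenBond",
    "SaltBridge",
    "OccupancySeries",
    "find_hbonds",
    "find_salt_bridges",
    "count_per_loop",
    "occupancy",
    "interactions_to_table",
]

HBOND_DA_CUTOFF = 3.9
HBOND_HA_CUTOFF = 2.5
SALT_BRIDGE_CUTOFF = 3.2

_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
_ACIDIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_BASIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
}
_BASIC_ATOMS_HIS = {"HIS": {"ND1", "NE2"}}


@dataclass
class DonorAcceptorTable:
    """Which atom names act as H-bond donors/acceptors and which carry formal
    charge, per residue name.  ``include_his_basic`` adds His imidazole
    nitrogens to the basic set (off by default: protonation unknown)."""

    donors: dict[str, set[str]] = field(default_factory=lambda: dict(_SIDECHAIN_DONORS))
    acceptors: dict[str, set[str]] = field(default_factory=lambda: dict(_SIDECHAIN_ACCEPTORS))
    acidic: dict[str, set[str]] = field(default_factory=lambda: dict(_ACIDIC_ATOMS))
    basic: dict[str, set[str]] = field(default_factory=lambda: dict(_BASIC_ATOMS))
    include_backbone: bool = True
    include_his_basic: bool = False

    def __post_init__(self):
        if self.include_his_basic:
            self.basic = {**self.basic, **_BASIC_ATOMS_HIS}

    def is_donor(self, atom: AtomRecord) -> bool:
        if atom.is_hetero or atom.is_hydrogen:
            return False
        if self.include_backbone and atom.name == "N" and atom.residue_name != "PRO":
            return True
        return atom.name in self.donors.get(atom.residue_name, ())

    def is_acceptor(self, atom: AtomRecord) -> bool:
        if atom.is_hetero or atom.is_hydrogen:
            return False
        if self.include_backbone and atom.name in ("O", "OXT"):
            return True
        return atom.name in self.acceptors.get(atom.residue_name, ())

    def is_acidic(self, atom: AtomRecord) -> bool:
        if atom.is_hetero or atom.is_hydrogen:
            return False
        if atom.name == "OXT":  # C-terminal carboxylate
            return True
        return atom.name in self.acidic.get(atom.residue_name, ())

    def is_basic(self, atom: AtomRecord) -> bool:
        if atom.is_hetero or atom.is_hydrogen:
            return False
        return atom.name in self.basic.get(atom.residue_name, ())


@dataclass(frozen=True)
class HydrogenBond:
    donor_index: int
    acceptor_index: int
    d_da: float
    hydrogen_index: int | None = None
    d_ha: float | None = None

    def participants(self) -> tuple[int, int]:
        return (self.donor_index, self.acceptor_index)


@dataclass(frozen=True)
class SaltBridge:
    acidic_index: int
    basic_index: int
    distance: float
    acidic_residue: tuple[str, int] = ("", 0)
    basic_residue: tuple[str, int] = ("", 0)

    def participants(self) -> tuple[int, int]:
        return (self.acidic_index, self.basic_index)


@dataclass
class OccupancySeries:
    """Per-frame satisfaction of a distance criterion for one atom pair."""

    satisfied: np.ndarray  # boolean per frame
    frame_interval: float  # ps
    distances: np.ndarray | None = None

    @property
    def total_time(self) -> float:
        """Total time (ps) the interaction is intact."""
        return float(np.count_nonzero(self.satisfied)) * self.frame_interval

    def to_frame(self) -> pd.DataFrame:
        n = len(self.satisfied)
        df = pd.DataFrame(
            {
                "frame": np.arange(n),
                "time": np.arange(n) * self.frame_interval,
                "satisfied": self.satisfied.astype(bool),
            }
        )
        if self.distances is not None:
            df["distance"] = self.distances
        return df


def _attached_hydrogens(model: StructureModel, donor_idx: int,
                        bond_cutoff: float = 1.3) -> list[int]:
    donor = model.atoms[donor_idx]
    d_xyz = np.asarray(donor.coordinates)
    out = []
    for i, a in enumerate(model.atoms):
        if not a.is_hydrogen or a.residue_key != donor.residue_key:
            continue
        if np.linalg.norm(np.asarray(a.coordinates) - d_xyz) <= bond_cutoff:
            out.append(i)
    return out


def find_hbonds(
    model: StructureModel,
    table: DonorAcceptorTable | None = None,
    exclude_intra_residue: bool = True,
    require_angle: bool = False,
) -> list[HydrogenBond]:
    """All donor–acceptor pairs within the D-A cutoff (3.9 Å).

    When the model carries hydrogens, a pair additionally needs some donor
    hydrogen within the H-A cutoff (2.5 Å); without hydrogens only the D-A
    criterion is evaluable.  Symmetric duplicates (both atoms donor+acceptor)
    are reported once per unordered atom pair.
    """
    table = table or DonorAcceptorTable()
    donors = [i for i, a in enumerate(model.atoms) if table.is_donor(a)]
    acceptors = [i for i, a in enumerate(model.atoms) if table.is_acceptor(a)]
    if not donors or not acceptors:
        return []
    has_hydrogens = any(a.is_hydrogen for a in model.atoms)
    d_xyz = np.array([model.atoms[i].coordinates for i in donors])
    a_xyz = np.array([model.atoms[i].coordinates for i in acceptors])
    pairs = cKDTree(d_xyz).query_ball_tree(cKDTree(a_xyz), HBOND_DA_CUTOFF)

    bonds: list[HydrogenBond] = []
    seen: set[tuple[int, int]] = set()
    for di, acc_list in zip(donors, pairs):
        datom = model.atoms[di]
        hyd_idx = _attached_hydrogens(model, di) if has_hydrogens else []
        for aj in acc_list:
            ai = acceptors[aj]
            if ai == di:
                continue
            aatom = model.atoms[ai]
            if exclude_intra_residue and aatom.residue_key == datom.residue_key:
                continue
            key = (min(di, ai), max(di, ai))
            if key in seen:
                continue
            d_da = float(np.linalg.norm(
                np.asarray(datom.coordinates) - np.asarray(aatom.coordinates)))
            h_best: int | None = None
            d_ha: float | None = None
            if has_hydrogens:
                if hyd_idx:
                    ha = [
                        float(np.linalg.norm(
                            np.asarray(model.atoms[h].coordinates)
                            - np.asarray(aatom.coordinates)))
                        for h in hyd_idx
                    ]
                    best = int(np.argmin(ha))
                    if ha[best] > HBOND_HA_CUTOFF:
                        continue
                    h_best, d_ha = hyd_idx[best], ha[best]
                    if require_angle and not _dha_angle_ok(model, h_best, di, ai):
                        continue
                else:
                    continue  # donor without modelled H cannot satisfy H-A
            seen.add(key)
            bonds.append(HydrogenBond(di, ai, d_da, h_best, d_ha))
    bonds.sort(key=lambda b: (b.donor_index, b.acceptor_index))
    return bonds


def _dha_angle_ok(model: StructureModel, h: int, d: int, a: int,
                  min_angle_deg: float = 90.0) -> bool:
    hx = np.asarray(model.atoms[h].coordinates)
    v1 = np.asarray(model.atoms[d].coordinates) - hx
    v2 = np.asarray(model.atoms[a].coordinates) - hx
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= min_angle_deg


def find_salt_bridges(
    model: StructureModel,
    table: DonorAcceptorTable | None = None,
) -> list[SaltBridge]:
    """All acidic-oxygen/basic-nitrogen pairs within 3.2 Å, reported per
    residue pair at the minimum atom-pair distance."""
    table = table or DonorAcceptorTable()
    acidic = [i for i, a in enumerate(model.atoms) if table.is_acidic(a)]
    basic = [i for i, a in enumerate(model.atoms) if table.is_basic(a)]
    if not acidic or not basic:
        return []
    ax = np.array([model.atoms[i].coordinates for i in acidic])
    bx = np.array([model.atoms[i].coordinates for i in basic])
    pairs = cKDTree(ax).query_ball_tree(cKDTree(bx), SALT_BRIDGE_CUTOFF)

    best: dict[tuple, SaltBridge] = {}
    for ii, blist in zip(range(len(acidic)), pairs):
        ai = acidic[ii]
        aatom = model.atoms[ai]
        for jj in blist:
            bi = basic[jj]
            batom = model.atoms[bi]
            if aatom.residue_key == batom.residue_key:
                continue
            dist = float(np.linalg.norm(
                np.asarray(aatom.coordinates) - np.asarray(batom.coordinates)))
            key = (aatom.residue_key, batom.residue_key)
            if key not in best or dist < best[key].distance:
                best[key] = SaltBridge(ai, bi, dist, aatom.residue_key, batom.residue_key)
    bridges = list(best.values())
    bridges.sort(key=lambda b: (b.acidic_residue, b.basic_residue))
    return bridges


def count_per_loop(
    interactions: Sequence[HydrogenBond | SaltBridge],
    loop: LoopDefinition,
    model: StructureModel,
    chains: str = "both",
) -> int:
    """Count interactions with at least one participating atom inside the
    loop's residue range.  ``chains``: a chain id, or ``"both"`` to accept
    the loop's residue range on any chain (the homodimer convention)."""
    count = 0
    for itx in interactions:
        for idx in itx.participants():
            atom = model.atoms[idx]
            if chains != "both" and atom.chain_id != chains:
                continue
            if loop.covers(atom.residue_number):
                count += 1
                break
    return count


def mean_hbonds_per_loop(
    ensemble: CoordinateEnsemble,
    loop: LoopDefinition,
    window: tuple[int, int] | None = None,
    table: DonorAcceptorTable | None = None,
) -> float:
    """Average per-frame hydrogen-bond count for a loop over an ensemble
    window (the count fluctuates frame to frame; the mean is reported)."""
    sl = ensemble.window_slice(window)
    counts = []
    for f in range(sl.start, sl.stop):
        frame_model = StructureModel(
            [
                _with_coordinates(a, ensemble.frames[f, i])
                for i, a in enumerate(ensemble.atom_metadata)
            ]
        )
        bonds = find_hbonds(frame_model, table)
        counts.append(count_per_loop(bonds, loop, frame_model))
    return float(np.mean(counts))


def _with_coordinates(atom: AtomRecord, xyz: np.ndarray) -> AtomRecord:
    from dataclasses import replace

    return replace(atom, coordinates=tuple(float(v) for v in xyz))


def occupancy(
    ensemble: CoordinateEnsemble,
    atom_pair: tuple[tuple[str, int, str], tuple[str, int, str]],
    threshold: float = SALT_BRIDGE_CUTOFF,
    window: tuple[int, int] | None = None,
) -> OccupancySeries:
    """Fraction of frames an atom pair is within ``threshold`` Å.

    ``atom_pair`` gives two (chain, residue_number, atom_name) keys, e.g.
    the carboxylate oxygen and ammonium nitrogen of a salt bridge; the
    series' ``total_time`` is satisfied-frame count x frame interval.
    """
    i = ensemble.atom_index(*atom_pair[0])
    j = ensemble.atom_index(*atom_pair[1])
    sl = ensemble.window_slice(window)
    diff = ensemble.frames[sl, i] - ensemble.frames[sl, j]
    dist = np.linalg.norm(diff, axis=1)
    return OccupancySeries(dist <= threshold, ensemble.frame_interval, dist)


def interactions_to_table(
    interactions: Sequence[HydrogenBond | SaltBridge],
    model: StructureModel,
) -> pd.DataFrame:
    rows = []
    for itx in interactions:
        i, j = itx.participants()
        a, b = model.atoms[i], model.atoms[j]
        rows.append(
            {
                "type": "hbond" if isinstance(itx, HydrogenBond) else "salt_bridge",
                "chain_1": a.chain_id, "residue_1": a.residue_number, "atom_1": a.name,
                "chain_2": b.chain_id, "residue_2": b.residue_number, "atom_2": b.name,
                "distance": itx.d_da if isinstance(itx, HydrogenBond) else itx.distance,
            }
        )
    return pd.DataFrame(rows, columns=[
        "type", "chain_1", "residue_1", "atom_1",
        "chain_2", "residue_2", "atom_2", "distance",
    ])
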