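"""Residue depth: distance to the nearest bulk water.

A simplified solvation-cycle procedure: each cycle places candidate water
sites on a randomly rotated and offset cubic lattice around the protein,
removes sites clashing with protein atoms, then iteratively strips
non-bulk sites (those with fewer than ``min_neighbour_waters`` water
neighbours within ``neighbourhood_radius``) until stable — this empties
narrow clefts and internal cavities so only bulk-like water survives.
Atom depth is the distance to the nearest surviving site, averaged over
cycles.  Defaults follow common practice for this family of methods:
25 cycles, 4.2 Å neighbourhood, 2 minimum neighbours; the 2.75 Å lattice
spacing approximates bulk-water packing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import LoopDefinition, StructureModel

__all__ = ["DepthParameters", "DepthResult", "compute_depth", "loop_depth"]


@dataclass(frozen=True)
class DepthParameters:
    n_cycles: int = 25
    neighbourhood_radius: float = 4.2
    min_neighbour_waters: int = 2
    lattice_spacing: float = 2.75
    clash_distance: float = 2.6
    box_margin: float = 8.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("neighbourhood_radius", "lattice_spacing", "clash_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DepthResult:
    atom_keys: list[tuple[str, int, str]]  # (chain, residue_number, atom_name)
    atom_depth: np.ndarray                 # Å, mean over cycles
    cycle_std: np.ndarray                  # Å, between-cycle std
    residue_keys: list[tuple[str, int]] = field(default_factory=list)
    residue_depth: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.atom_keys],
                "residue": [k[1] for k in self.atom_keys],
                "atom": [k[2] for k in self.atom_keys],
                "depth": self.atom_depth,
                "cycle_std": self.cycle_std,
            }
        )

    def residue_value(self, chain: str, residue_number: int) -> float:
        return float(self.residue_depth[self.residue_keys.index((chain, residue_number))])


def _lattice_sites(coords: np.ndarray, params: DepthParameters,
                   rng: np.random.Generator) -> np.ndarray:
    """Cubic lattice, randomly rotated and offset, covering the protein box
    plus a bulk margin."""
    centre = coords.mean(axis=0)
    half_span = np.abs(coords - centre).max() + params.box_margin
    n = int(np.ceil(2 * half_span / params.lattice_spacing)) + 1
    axis = (np.arange(n) - (n - 1) / 2) * params.lattice_spacing
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    rot = Rotation.random(rng=rng).as_matrix()
    offset = rng.uniform(-0.5, 0.5, size=3) * params.lattice_spacing
    sites = grid @ rot.T + centre + offset
    # keep sites within the margin shell of the protein's bounding sphere
    dist_from_centre = np.linalg.norm(sites - centre, axis=1)
    protein_radius = np.linalg.norm(coords - centre, axis=1).max()
    return sites[dist_from_centre <= protein_radius + params.box_margin]


def _solvate_once(coords: np.ndarray, params: DepthParameters,
                  rng: np.random.Generator) -> np.ndarray:
    sites = _lattice_sites(coords, params, rng)
    protein_tree = cKDTree(coords)
    clash = protein_tree.query_ball_point(sites, params.clash_distance)
    sites = sites[[len(c) == 0 for c in clash]]
    if sites.shape[0] == 0:
        raise RuntimeError("no water sites survive clash removal")
    # iteratively strip non-bulk sites (cleft/cavity water)
    while params.min_neighbour_waters > 0:
        tree = cKDTree(sites)
        n_neigh = np.array([
            len(nb) - 1 for nb in tree.query_ball_point(sites, params.neighbourhood_radius)
        ])
        keep = n_neigh >= params.min_neighbour_waters
        if keep.all():
            break
        sites = sites[keep]
        if sites.shape[0] == 0:
            raise RuntimeError("all water sites removed during bulk filtering")
    return sites


def compute_depth(model: StructureModel, params: DepthParameters | None = None) -> DepthResult:
    """Per-atom and per-residue depth of all non-hydrogen protein atoms."""
    params = params or DepthParameters()
    atoms = [a for a in model.atoms if not a.is_hydrogen and not a.is_hetero]
    if not atoms:
        raise ValueError("model has no non-hydrogen protein atoms")
    coords = np.array([a.coordinates for a in atoms])
    rng = np.random.default_rng(params.rng_seed)

    per_cycle = np.empty((params.n_cycles, len(atoms)))
    for c in range(params.n_cycles):
        waters = _solvate_once(coords, params, rng)
        dists, _ = cKDTree(waters).query(coords)
        per_cycle[c] = dists
    atom_depth = per_cycle.mean(axis=0)
    cycle_std = per_cycle.std(axis=0, ddof=0)

    atom_keys = [(a.chain_id, a.residue_number, a.name) for a in atoms]
    res_keys: list[tuple[str, int]] = []
    res_groups: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(atoms):
        key = a.residue_key
        if key not in res_groups:
            res_groups[key] = []
            res_keys.append(key)
        res_groups[key].append(i)
    residue_depth = np.array([atom_depth[res_groups[k]].mean() for k in res_keys])
    return DepthResult(atom_keys, atom_depth, cycle_std, res_keys, residue_depth)


def loop_depth(result: DepthResult, loop: LoopDefinition) -> float:
    """Mean per-residue depth over the loop's residues."""
    vals = [
        result.residue_depth[i]
        for i, (chain, num) in enumerate(result.residue_keys)
        if chain == loop.chain_id and loop.covers(num)
    ]
    if not vals:
        raise ValueError(f"no depth residues inside loop {loop.loop_id}")
    return float(np.mean(vals))
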