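"""Hydrogen bonds, salt bridges, per-loop counts and ensemble occupancy."""

import numpy as np
import pytest

from loopstab import synthetic
from loopstab.flexibility import CoordinateEnsemble
from loopstab.interactions import (
    HBOND_DA_CUTOFF,
    SALT_BRIDGE_CUTOFF,
    DonorAcceptorTable,
    count_per_loop,
    find_hbonds,
    find_salt_bridges,
    interactions_to_table,
    occupancy,
)
from loopstab.structure import LoopDefinition, StructureModel
from tests.conftest import make_atom


class TestHbonds:
    def test_backbone_pair_within_cutoff(self, scene_builder):
        model = scene_builder([
            ("N", "N", "A", 1, "ALA", (0, 0, 0)),
            ("O", "O", "A", 5, "ALA", (3.5, 0, 0)),
        ])
        bonds = find_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].d_da == pytest.approx(3.5)

    def test_beyond_cutoff(self, scene_builder):
        model = scene_builder([
            ("N", "N", "A", 1, "ALA", (0, 0, 0)),
            ("O", "O", "A", 5, "ALA", (4.0, 0, 0)),
        ])
        assert find_hbonds(model) == []

    def test_hydrogen_criterion(self, scene_builder):
        # donor H points away: d(H, A) > 2.5 despite d(D, A) < 3.9
        model = scene_builder([
            ("N", "N", "A", 1, "ALA", (0, 0, 0)),
            ("H", "H", "A", 1, "ALA", (-1.0, 0, 0)),
            ("O", "O", "A", 5, "ALA", (3.5, 0, 0)),
        ])
        assert find_hbonds(model) == []
        # H towards the acceptor satisfies both criteria
        model2 = scene_builder([
            ("N", "N", "A", 1, "ALA", (0, 0, 0)),
            ("H", "H", "A", 1, "ALA", (1.0, 0, 0)),
            ("O", "O", "A", 5, "ALA", (3.5, 0, 0)),
        ])
        bonds = find_hbonds(model2)
        assert len(bonds) == 1 and bonds[0].d_ha == pytest.approx(2.5)

    def test_stripped_hydrogens_superset(self, scene_builder):
        """Removing hydrogens can only add candidate bonds (the H-A criterion
        only removes them)."""
        rng = np.random.default_rng(0)
        rows = []
        resnum = 1
        for i in range(12):
            base = rng.uniform(0, 12, 3)
            rows.append(("N", "N", "A", resnum, "ALA", tuple(base)))
            rows.append(("H", "H", "A", resnum, "ALA", tuple(base + rng.normal(0, 0.7, 3))))
            rows.append(("O", "O", "A", resnum + 1, "ALA", tuple(rng.uniform(0, 12, 3))))
            resnum += 2
        model = scene_builder(rows)
        stripped = StructureModel([a for a in model.atoms if not a.is_hydrogen])
        pairs_with_h = {
            (model.atoms[b.donor_index].residue_key,
             model.atoms[b.acceptor_index].residue_key)
            for b in find_hbonds(model)
        }
        pairs_no_h = {
            (stripped.atoms[b.donor_index].residue_key,
             stripped.atoms[b.acceptor_index].residue_key)
            for b in find_hbonds(stripped)
        }
        assert pairs_with_h <= pairs_no_h

    def test_brute_force_oracle(self, scene_builder):
        """KD-tree detection equals the all-pairs filter on a random scene."""
        rng = np.random.default_rng(42)
        rows = []
        resnum = 1
        for i in range(25):
            rows.append(("N", "N", "A", resnum, "ALA", tuple(rng.uniform(0, 20, 3))))
            rows.append(("O", "O", "A", resnum, "ALA", tuple(rng.uniform(0, 20, 3))))
            resnum += 1
        model = scene_builder(rows)
        table = DonorAcceptorTable()
        bonds = find_hbonds(model, table)
        got = {frozenset(b.participants()) for b in bonds}

        expected = set()
        for i, a in enumerate(model.atoms):
            for j, b in enumerate(model.atoms):
                if i == j or not (table.is_donor(a) and table.is_acceptor(b)):
                    continue
                if a.residue_key == b.residue_key:
                    continue
                d = np.linalg.norm(np.asarray(a.coordinates) - np.asarray(b.coordinates))
                if d <= HBOND_DA_CUTOFF:
                    expected.add(frozenset((i, j)))
        assert got == expected


class TestSaltBridges:
    def test_examples(self, scene_builder):
        close = scene_builder([
            ("OE2", "O", "A", 1, "GLU", (0, 0, 0)),
            ("NZ", "N", "A", 5, "LYS", (3.0, 0, 0)),
        ])
        assert len(find_salt_bridges(close)) == 1
        far = scene_builder([
            ("OE2", "O", "A", 1, "GLU", (0, 0, 0)),
            ("NZ", "N", "A", 5, "LYS", (3.3, 0, 0)),
        ])
        assert find_salt_bridges(far) == []

    def test_reported_per_residue_pair_minimum_distance(self, scene_builder):
        model = scene_builder([
            ("OD1", "O", "A", 1, "ASP", (0, 0, 0)),
            ("OD2", "O", "A", 1, "ASP", (0.5, 0, 0)),
            ("NH1", "N", "A", 9, "ARG", (3.1, 0, 0)),
        ])
        bridges = find_salt_bridges(model)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(2.6)  # OD2..NH1

    def test_brute_force_oracle(self, scene_builder):
        rng = np.random.default_rng(7)
        rows = []
        resnum = 1
        for i in range(20):
            rows.append(("OD1", "O", "A", resnum, "ASP", tuple(rng.uniform(0, 15, 3))))
            rows.append(("NH1", "N", "A", resnum + 1, "ARG", tuple(rng.uniform(0, 15, 3))))
            resnum += 2
        model = scene_builder(rows)
        table = DonorAcceptorTable()
        got = {(b.acidic_residue, b.basic_residue, round(b.distance, 6))
               for b in find_salt_bridges(model, table)}

        best = {}
        for i, a in enumerate(model.atoms):
            for j, b in enumerate(model.atoms):
                if not (table.is_acidic(a) and table.is_basic(b)):
                    continue
                if a.residue_key == b.residue_key:
                    continue
                d = np.linalg.norm(np.asarray(a.coordinates) - np.asarray(b.coordinates))
                if d <= SALT_BRIDGE_CUTOFF:
                    key = (a.residue_key, b.residue_key)
                    best[key] = min(best.get(key, np.inf), d)
        expected = {(k[0], k[1], round(v, 6)) for k, v in best.items()}
        assert got == expected

    def test_his_optional(self, scene_builder):
        model = scene_builder([
            ("OE2", "O", "A", 1, "GLU", (0, 0, 0)),
            ("ND1", "N", "A", 5, "HIS", (3.0, 0, 0)),
        ])
        assert find_salt_bridges(model) == []
        table = DonorAcceptorTable(include_his_basic=True)
        assert len(find_salt_bridges(model, table)) == 1


def test_rigid_transform_invariance(scene_builder):
    rng = np.random.default_rng(3)
    rows = []
    resnum = 1
    for i in range(15):
        rows.append(("N", "N", "A", resnum, "ALA", tuple(rng.uniform(0, 18, 3))))
        rows.append(("O", "O", "A", resnum + 1, "ALA", tuple(rng.uniform(0, 18, 3))))
        resnum += 2
    model = scene_builder(rows)
    theta = 1.1
    rot = np.array([[np.cos(theta), 0, np.sin(theta)],
                    [0, 1, 0],
                    [-np.sin(theta), 0, np.cos(theta)]])
    shift = np.array([10.0, -4.0, 2.5])
    moved = StructureModel([
        make_atom(a.serial, a.name, a.element, a.chain_id, a.residue_number,
                  a.residue_name, tuple(rot @ np.asarray(a.coordinates) + shift))
        for a in model.atoms
    ])
    before = {frozenset(b.participants()) for b in find_hbonds(model)}
    after = {frozenset(b.participants()) for b in find_hbonds(moved)}
    assert before == after


class TestCountPerLoop:
    def test_counts(self, scene_builder):
        model = scene_builder([
            ("N", "N", "A", 10, "ALA", (0, 0, 0)),
            ("O", "O", "A", 11, "ALA", (3.0, 0, 0)),
            ("N", "N", "A", 12, "ALA", (6.0, 0, 0)),
            ("O", "O", "A", 50, "ALA", (9.0, 0, 0)),  # outside the loop
        ])
        bonds = find_hbonds(model)
        loop = LoopDefinition(1, "A", 10, 12)
        assert count_per_loop([], loop, model) == 0
        # one end inside the loop is enough for membership
        n_total = count_per_loop(bonds, loop, model)
        internal = [b for b in bonds
                    if all(loop.covers(model.atoms[i].residue_number)
                           for i in b.participants())]
        edge = [b for b in bonds
                if any(loop.covers(model.atoms[i].residue_number)
                       for i in b.participants())
                and b not in internal]
        assert n_total == len(internal) + len(edge)
        assert len(edge) >= 1  # the 12-50 bond crosses the boundary


class TestOccupancy:
    def _pair_ensemble(self, distances, interval):
        a1 = make_atom(1, "OE2", "O", "A", 275, "GLU", (0, 0, 0))
        a2 = make_atom(2, "NZ", "N", "A", 280, "LYS", (3.0, 0, 0))
        frames = np.array([[[0.0, 0, 0], [d, 0, 0]] for d in distances])
        return CoordinateEnsemble(frames, [a1, a2], interval)

    def test_fixed_distance(self):
        ens = self._pair_ensemble([3.0] * 100, 2.0)
        occ = occupancy(ens, (("A", 275, "OE2"), ("A", 280, "NZ")))
        assert occ.total_time == pytest.approx(200.0)  # 100 frames x 2 ps

    def test_never_satisfied(self):
        ens = self._pair_ensemble([4.0] * 50, 2.0)
        occ = occupancy(ens, (("A", 275, "OE2"), ("A", 280, "NZ")))
        assert occ.total_time == 0.0

    def test_alternating_gives_half_time(self):
        ens = self._pair_ensemble([3.0, 4.0] * 500, 10.0)
        occ = occupancy(ens, (("A", 275, "OE2"), ("A", 280, "NZ")))
        assert occ.total_time == pytest.approx(5000.0)  # 500 x 10 ps = 5 ns

    def test_missing_atom(self):
        ens = self._pair_ensemble([3.0] * 5, 2.0)
        with pytest.raises(KeyError):
            occupancy(ens, (("A", 275, "OE2"), ("B", 1, "NZ")))


def test_interactions_table_export(scene_builder):
    model = scene_builder([
        ("OE2", "O", "A", 1, "GLU", (0, 0, 0)),
        ("NZ", "N", "A", 5, "LYS", (3.0, 0, 0)),
    ])
    df = interactions_to_table(find_salt_bridges(model), model)
    assert df.iloc[0]["type"] == "salt_bridge"
    assert df.iloc[0]["distance"] == pytest.approx(3.0)
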