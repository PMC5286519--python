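"""B-factor and RMSF profiles, loop summaries, correlations."""

import numpy as np
import pytest

from loopstab import synthetic
from loopstab.flexibility import (
    CoordinateEnsemble,
    FlexibilityProfile,
    average_profiles,
    delta_rmsf,
    loop_bfactor,
    loop_rmsd_series,
    normalize_rmsf,
    pearson,
    read_frames_table,
    residue_bfactor,
    rmsf,
    write_frames_table,
)
from loopstab.structure import LoopDefinition, StructureModel
from tests.conftest import make_atom


class TestResidueBfactor:
    def test_mean_excludes_hydrogens(self, scene_builder):
        model = scene_builder([
            ("N", "N", "A", 1, "ALA", (0, 0, 0)),
            ("CA", "C", "A", 1, "ALA", (1, 0, 0)),
            ("C", "C", "A", 1, "ALA", (2, 0, 0)),
            ("H", "H", "A", 1, "ALA", (0, 1, 0)),
        ])
        bs = [10.0, 20.0, 30.0, 99.0]
        model = StructureModel(
            [make_atom(i + 1, a.name, a.element, "A", 1, "ALA", a.coordinates, b)
             for i, (a, b) in enumerate(zip(model.atoms, bs))]
        )
        prof = residue_bfactor(model)
        assert prof.values.tolist() == [20.0]

    def test_chain_average(self):
        model, _ = synthetic.make_toy_structure(1, b_profile=[20.0], homodimer=True)
        atoms = [a if a.chain_id == "A" else
                 make_atom(a.serial, a.name, a.element, "B", a.residue_number,
                           a.residue_name, a.coordinates, 30.0)
                 for a in model.atoms]
        prof = residue_bfactor(StructureModel(atoms), average_chains=True)
        assert prof.values.tolist() == [25.0]

    def test_generator_bookkeeping(self, toy_model_and_truth):
        model, truth = toy_model_and_truth
        prof = residue_bfactor(model)
        assert np.allclose(prof.values, truth["b_means"]["A"])


class TestLoopBfactor:
    def test_examples(self):
        prof = FlexibilityProfile([("A", i) for i in range(1, 11)],
                                  np.arange(1.0, 11.0), "bfactor")
        assert loop_bfactor(prof, LoopDefinition(1, "A", 3, 4)) == pytest.approx(3.5)
        assert loop_bfactor(prof, LoopDefinition(1, "A", 7, 7)) == 7.0
        assert loop_bfactor(prof, LoopDefinition(1, "A", 1, 10)) == pytest.approx(5.5)

    def test_whole_chain_equals_profile_mean(self, toy_model):
        prof = residue_bfactor(toy_model)
        whole = LoopDefinition(1, "A", 1, 30)
        assert loop_bfactor(prof, whole) == pytest.approx(prof.values.mean())

    def test_empty_intersection(self):
        prof = FlexibilityProfile([("A", 1)], [5.0], "bfactor")
        with pytest.raises(ValueError):
            loop_bfactor(prof, LoopDefinition(1, "A", 10, 12))


class TestRmsf:
    def test_frozen_ensemble_zero(self, toy_model):
        ens, _ = synthetic.make_ensemble(toy_model, 0.0, n_frames=10)
        assert np.allclose(rmsf(ens).values, 0.0, atol=1e-10)

    def test_alternating_atom(self):
        """One atom alternating +/- d along x has RMSF exactly d."""
        d = 0.7
        atom = make_atom(1, "CA", "C", "A", 1, "GLY", (0, 0, 0))
        frames = np.array([[[+d, 0, 0]], [[-d, 0, 0]]] * 5)
        ens = CoordinateEnsemble(frames, [atom])
        prof = rmsf(ens, superpose_frames=False)
        assert prof.values[0] == pytest.approx(d)

    def test_gaussian_amplitude_recovery(self, toy_model):
        """Isotropic Gaussian fluctuation of amplitude sigma per axis gives
        residue RMSF ~ sigma*sqrt(3) within 5% at 2000 frames."""
        sigma = np.linspace(0.3, 1.2, 30)
        ens, truth = synthetic.make_ensemble(toy_model, sigma, n_frames=2000,
                                             rng_seed=7)
        prof = rmsf(ens, superpose_frames=False)
        expected = sigma * np.sqrt(3.0)
        assert np.all(np.abs(prof.values - expected) / expected < 0.05)

    def test_translation_invariance_with_superposition(self, toy_model):
        ens, _ = synthetic.make_ensemble(toy_model, 0.4, n_frames=50, rng_seed=3)
        shifted = CoordinateEnsemble(
            ens.frames + np.arange(50)[:, None, None] * np.array([1.0, -2.0, 0.5]),
            ens.atom_metadata, ens.frame_interval)
        a = rmsf(ens, superpose_frames=True).values
        b = rmsf(shifted, superpose_frames=True).values
        assert np.allclose(a, b, atol=1e-8)

    def test_window_validation(self, toy_model):
        ens, _ = synthetic.make_ensemble(toy_model, 0.4, n_frames=20)
        with pytest.raises(ValueError):
            rmsf(ens, window=(10, 30))
        with pytest.raises(ValueError):
            rmsf(ens, window=(5, 6))  # single frame


class TestNormalize:
    def test_examples(self):
        keys = [("A", 1), ("A", 2)]
        const = normalize_rmsf(FlexibilityProfile(keys, [3.0, 3.0], "rmsf_raw"))
        assert const.values.tolist() == [1.0, 1.0]
        two = normalize_rmsf(FlexibilityProfile(keys, [1.0, 3.0], "rmsf_raw"))
        assert two.values.tolist() == [0.5, 1.5]

    def test_mean_one_and_idempotent(self, toy_model):
        ens, _ = synthetic.make_ensemble(toy_model, 0.5, n_frames=100, rng_seed=2)
        prof = normalize_rmsf(rmsf(ens))
        assert prof.values.mean() == pytest.approx(1.0, abs=1e-9)
        again = normalize_rmsf(prof)
        assert np.allclose(prof.values, again.values, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_rmsf(FlexibilityProfile([("A", 1)], [0.0], "rmsf_raw"))


class TestDeltaRmsf:
    def _norm(self, keys, values, label):
        return normalize_rmsf(FlexibilityProfile(keys, values, "rmsf_raw", label))

    def test_identical_profiles_zero(self):
        keys = [("A", i) for i in range(1, 7)]
        p = self._norm(keys, np.arange(1.0, 7.0), "300K")
        loops = [LoopDefinition(1, "A", 1, 3), LoopDefinition(2, "A", 4, 6)]
        df = delta_rmsf(p, p, loops)
        assert np.allclose(df["delta_rmsf"], 0.0)

    def test_uniform_doubling(self):
        keys = [("A", 1), ("A", 2)]
        low = FlexibilityProfile(keys, [1.0, 1.0], "rmsf_normalized", "300K")
        high = FlexibilityProfile(keys, [2.0, 2.0], "rmsf_normalized", "370K")
        df = delta_rmsf(high, low, [LoopDefinition(1, "A", 1, 2)])
        assert df["delta_rmsf"].iloc[0] == pytest.approx(1.0)

    def test_designated_hot_loop_ranks_first(self, toy_model):
        """A +0.8 normalized offset on one loop puts it on top of the ranking."""
        keys = [("A", i) for i in range(1, 31)]
        base = np.ones(30)
        hot = base.copy()
        hot[10:20] += 0.8  # residues 11-20
        low = FlexibilityProfile(keys, base, "rmsf_normalized", "300K")
        high = FlexibilityProfile(keys, hot, "rmsf_normalized", "370K")
        loops = [LoopDefinition(1, "A", 1, 10), LoopDefinition(2, "A", 11, 20),
                 LoopDefinition(3, "A", 21, 30)]
        df = delta_rmsf(high, low, loops).sort_values("delta_rmsf", ascending=False)
        assert df.iloc[0]["loop_id"] == 2
        assert df.iloc[0]["delta_rmsf"] == pytest.approx(0.8)

    def test_requires_normalized_and_matching_keys(self):
        keys = [("A", 1), ("A", 2)]
        raw = FlexibilityProfile(keys, [1.0, 2.0], "rmsf_raw")
        norm = normalize_rmsf(raw)
        with pytest.raises(ValueError):
            delta_rmsf(raw, norm, [])
        other = FlexibilityProfile([("A", 5), ("A", 6)], [1.0, 1.0],
                                   "rmsf_normalized")
        with pytest.raises(ValueError):
            delta_rmsf(norm, other, [])


class TestLoopRmsd:
    def test_frozen_zero(self, toy_model):
        ens, _ = synthetic.make_ensemble(toy_model, 0.0, n_frames=4)
        series = loop_rmsd_series(ens, LoopDefinition(1, "A", 11, 20))
        assert np.allclose(series, 0.0, atol=1e-10)

    def test_single_atom_two_frames(self):
        """Single-atom loop at x=0 then x=2: average x=1, RMSD {1, 1}."""
        atom = make_atom(1, "CA", "C", "A", 1, "GLY", (0, 0, 0))
        frames = np.array([[[0.0, 0, 0]], [[2.0, 0, 0]]])
        ens = CoordinateEnsemble(frames, [atom])
        series = loop_rmsd_series(ens, LoopDefinition(1, "A", 1, 1),
                                  superpose_frames=False)
        assert series == pytest.approx([1.0, 1.0])

    def test_amplitude_scaling(self, toy_model):
        """Doubling a loop's fluctuation amplitude about doubles its RMSD."""
        loop = LoopDefinition(1, "A", 11, 20)
        sigma = np.full(30, 0.05)
        sigma[10:20] = 0.4
        ens1, _ = synthetic.make_ensemble(toy_model, sigma, n_frames=800, rng_seed=5)
        sigma2 = sigma.copy()
        sigma2[10:20] = 0.8
        ens2, _ = synthetic.make_ensemble(toy_model, sigma2, n_frames=800, rng_seed=6)
        m1 = loop_rmsd_series(ens1, loop, superpose_frames=False).mean()
        m2 = loop_rmsd_series(ens2, loop, superpose_frames=False).mean()
        assert m2 / m1 == pytest.approx(2.0, rel=0.1)


class TestPearson:
    def test_examples(self):
        keys = [("A", 1), ("A", 2), ("A", 3)]
        a = FlexibilityProfile(keys, [1.0, 2.0, 3.0], "bfactor")
        b = FlexibilityProfile(keys, [2.0, 4.0, 6.0], "bfactor")
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, b) == pytest.approx(1.0)

    def test_sigma_profile_recovery(self, toy_model):
        """RMSF correlates with the generating sigma profile (r > 0.95)."""
        sigma = np.linspace(0.2, 1.5, 30)
        ens, _ = synthetic.make_ensemble(toy_model, sigma, n_frames=2000, rng_seed=11)
        prof = rmsf(ens, superpose_frames=False)
        truth = FlexibilityProfile(prof.residue_keys, sigma, "bfactor")
        assert pearson(prof, truth) > 0.95

    def test_zero_variance_rejected(self):
        keys = [("A", 1), ("A", 2), ("A", 3)]
        flat = FlexibilityProfile(keys, [1.0, 1.0, 1.0], "bfactor")
        vary = FlexibilityProfile(keys, [1.0, 2.0, 3.0], "bfactor")
        with pytest.raises(ValueError):
            pearson(flat, vary)


def test_replicate_averaging(toy_model):
    """Replicate profiles are normalized per run before averaging."""
    profs = []
    for seed in (1, 2, 3):
        ens, _ = synthetic.make_ensemble(toy_model, 0.5, n_frames=100, rng_seed=seed)
        profs.append(normalize_rmsf(rmsf(ens)))
    avg = average_profiles(profs)
    assert avg.values.mean() == pytest.approx(1.0, abs=1e-9)


def test_frames_table_round_trip(toy_model, tmp_path):
    ens, _ = synthetic.make_ensemble(toy_model, 0.3, n_frames=5, rng_seed=1)
    path = tmp_path / "frames.tsv"
    write_frames_table(ens, path)
    back = read_frames_table(path, ens.atom_metadata, ens.frame_interval)
    assert np.allclose(back.frames, ens.frames, atol=1e-9)
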