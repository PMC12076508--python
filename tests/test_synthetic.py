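import numpy as np
import pytest

from ohecc import (
    GeneratorConfig,
    assign_surrogate_rotation,
    encode_coulomb,
    encode_ohecc,
    find_stereocenters,
    make_dataset,
    make_enantiomer_pair,
    make_molecule,
    standard_orientation,
)
from ohecc.synthetic import _exact_counts


class TestMakeMolecule:
    def test_achiral_molecule_has_no_stereocenters(self):
        cfg = GeneratorConfig()
        for seed in range(10):
            sm = make_molecule(cfg, 0, seed=seed)
            assert sm.n_centers == 0
            assert find_stereocenters(sm.molecule, sm.bonds) == []

    def test_zero_jitter_single_center_round_trip(self):
        cfg = GeneratorConfig(jitter_sd=0.0)
        for seed in range(20):
            sm = make_molecule(cfg, 1, seed=seed)
            found = find_stereocenters(sm.molecule, sm.bonds)
            assert len(found) == 1
            assert found[0].label == sm.stereocenters[0].label

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_detected_count_and_labels_match_construction(self, k):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(k)
        for _ in range(50):
            sm = make_molecule(cfg, k, rng)
            found = find_stereocenters(sm.molecule, sm.bonds)
            truth = {s.center: s.label for s in sm.stereocenters}
            assert {s.center: s.label for s in found} == truth
            assert len(found) == k

    def test_capacity_respected_and_encodable(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        for k in range(5):
            for _ in range(25):
                sm = make_molecule(cfg, k, rng)
                assert len(sm.molecule) <= cfg.max_atoms
                encode_ohecc(sm.molecule)  # must not raise

    def test_too_many_centers_rejected(self):
        with pytest.raises(ValueError, match="0..4"):
            make_molecule(GeneratorConfig(), 5, seed=0)

    def test_standard_orientation_centers_charge(self):
        sm = make_molecule(GeneratorConfig(), 2, seed=4)
        Z = sm.molecule.atomic_numbers.astype(float)
        centroid = (Z[:, None] * sm.molecule.coords).sum(0) / Z.sum()
        assert np.allclose(centroid, 0.0, atol=1e-9)

    def test_standard_orientation_is_pose_invariant(self):
        from scipy.stats import special_ortho_group
        from ohecc import transform

        sm = make_molecule(GeneratorConfig(), 1, seed=8)
        rng = np.random.default_rng(3)
        moved = transform(sm.molecule, special_ortho_group.rvs(3, random_state=rng),
                          rng.normal(0, 6, 3))
        a = standard_orientation(sm.molecule).coords
        b = standard_orientation(moved).coords
        assert np.allclose(a, b, atol=1e-7)

    def test_random_orientation_mode(self):
        cfg = GeneratorConfig(orientation="random")
        sm = make_molecule(cfg, 1, seed=1)
        assert len(find_stereocenters(sm.molecule, sm.bonds)) == 1


class TestEnantiomerPair:
    def test_coulomb_equal_ohecc_different_labels_opposite(self, single_center_config):
        for seed in range(15):
            a, b = make_enantiomer_pair(single_center_config, seed=seed)
            cma = encode_coulomb(a.molecule).values
            cmb = encode_coulomb(b.molecule).values
            assert np.allclose(cma, cmb, atol=1e-10)
            assert np.abs(encode_ohecc(a.molecule).values
                          - encode_ohecc(b.molecule).values).max() > 0
            assert a.labels == ["S" if l == "R" else "R" for l in b.labels]
            assert a.molecule.elements == b.molecule.elements

    def test_pair_with_multiple_centers(self):
        cfg = GeneratorConfig(center_distribution={3: 1.0})
        a, b = make_enantiomer_pair(cfg, seed=2)
        assert a.n_centers == b.n_centers == 3
        det_b = find_stereocenters(b.molecule, b.bonds)
        assert {s.center: s.label for s in det_b} == {
            s.center: s.label for s in b.stereocenters
        }


class TestSurrogateRotation:
    def test_single_r_center_closed_form(self, single_center_config):
        sm = make_molecule(single_center_config, 1, seed=0)
        sm.stereocenters[0].label = "R"
        assert assign_surrogate_rotation(sm, weights=(10.0,), noise_sd=0.0) == 10.0

    def test_enantiomer_pair_values_opposite_at_zero_noise(self):
        cfg = GeneratorConfig(center_distribution={2: 1.0})
        a, b = make_enantiomer_pair(cfg, seed=5)
        va = assign_surrogate_rotation(a, noise_sd=0.0)
        vb = assign_surrogate_rotation(b, noise_sd=0.0)
        assert va == pytest.approx(-vb)
        assert va != 0.0

    def test_achiral_molecule_gets_pure_noise(self):
        cfg = GeneratorConfig()
        sm = make_molecule(cfg, 0, seed=1)
        assert assign_surrogate_rotation(sm, noise_sd=0.0) == 0.0
        rng = np.random.default_rng(99)
        signs = [np.sign(assign_surrogate_rotation(sm, noise_sd=1.0, seed=rng))
                 for _ in range(10000)]
        frac_pos = np.mean(np.array(signs) > 0)
        assert 0.485 <= frac_pos <= 0.515  # fair coin within 1.5 points

    def test_no_weight_combination_cancels_to_zero(self):
        # default weights are chosen so every signed sum is nonzero
        w = GeneratorConfig().rotation_weights
        for mask in range(16):
            s = sum((1 if mask >> k & 1 else -1) * w[k] for k in range(4))
            assert abs(s) > 1.0


class TestMakeDataset:
    def test_exact_class_balance(self):
        ds = make_dataset(GeneratorConfig(n_molecules=100, seed=1))
        assert np.bincount(ds.n_centers(), minlength=5).tolist() == [20] * 5

    def test_largest_remainder_apportionment(self):
        counts = _exact_counts({0: 0.5, 1: 0.3, 2: 0.2}, 7)
        assert sum(counts.values()) == 7
        assert counts[0] == 4 and counts[1] == 2 and counts[2] == 1

    def test_features_shape_and_reproducibility(self):
        a = make_dataset(GeneratorConfig(n_molecules=40, seed=7))
        b = make_dataset(GeneratorConfig(n_molecules=40, seed=7))
        assert a.features().shape == (40, 216)
        assert np.array_equal(a.features(), b.features())
        c = make_dataset(GeneratorConfig(n_molecules=40, seed=8))
        assert not np.array_equal(a.features(), c.features())

    def test_every_molecule_detectable(self, mixed_dataset):
        for sm in mixed_dataset.molecules:
            found = find_stereocenters(sm.molecule, sm.bonds)
            assert {s.center: s.label for s in found} == {
                s.center: s.label for s in sm.stereocenters
            }

    def test_rotation_signs_follow_labels_at_low_noise(self):
        ds = make_dataset(GeneratorConfig(n_molecules=60, seed=2, noise_sd=0.0,
                                          center_distribution={1: 1.0}))
        rs = ds.rs_labels()
        rot = ds.rotations()
        assert np.array_equal(rot > 0, rs == "R")
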