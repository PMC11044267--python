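"""Model geometry, equivariance contracts and the forward pass."""

import numpy as np
import pytest

from glycosite import InterfaceModel, ModelConfig
from glycosite.autograd import Parameter
from glycosite.dataset import protein_residues
from glycosite.geomnet import ELEMENTS, knn_geometry
from glycosite.structio import Atom, AtomicStructure, partition_subunits
from glycosite.synthetic import ToyComplexConfig, make_toy_complex, random_rigid_transform
from glycosite.training import weighted_bce


def _protein_inputs(model, structure, partition):
    residues = protein_residues(structure, partition)
    atom_idx = [i for _, _, idx in residues for i in idx]
    coords = structure.coords[atom_idx]
    elements = [structure.atoms[i].element for i in atom_idx]
    return coords, elements


class TestConfig:
    def test_default_schedule_shape(self):
        cfg = ModelConfig()
        assert len(cfg.nn_schedule) == 24
        assert cfg.nn_schedule[0] == 8 and cfg.nn_schedule[-1] == 64
        assert all(b >= a for a, b in zip(cfg.nn_schedule, cfg.nn_schedule[1:]))

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(nn_schedule=(8,) * 24)
        with pytest.raises(ValueError):
            ModelConfig(n_layers=4, nn_schedule=(8, 64))


class TestInitStates:
    def test_same_element_same_embedding(self, small_model):
        q, p = small_model.init_atom_states(["C", "N", "C"])
        np.testing.assert_array_equal(q.data[0], q.data[2])
        assert not np.allclose(q.data[0], q.data[1])

    def test_vector_state_starts_at_zero(self, small_model):
        _, p = small_model.init_atom_states(["C", "O", "FE"])
        assert np.all(p.data == 0.0)

    def test_unknown_element_routes_to_catch_all(self, small_model):
        q, _ = small_model.init_atom_states(["UUO", "XQ"])
        onehot = small_model.element_onehot(["UUO", "XQ", "C"])
        assert onehot[0, -1] == 1.0 and onehot[1, -1] == 1.0
        np.testing.assert_array_equal(q.data[0], q.data[1])


class TestKnnGeometry:
    def test_collinear_atoms(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        g = knn_geometry(coords, nn=2)
        np.testing.assert_allclose(g.D[0], [1.0, 2.0])
        np.testing.assert_allclose(g.R[0], [[1, 0, 0], [1, 0, 0]])
        assert list(g.indices[0]) == [1, 2]

    def test_sink_slots_for_small_structures(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        g = knn_geometry(coords, nn=8)
        assert g.mask[0].sum() == 1
        assert np.all(g.D[0, 1:] == 0)
        assert np.all(g.R[0, 1:] == 0)

    def test_real_displacements_are_unit_norm(self, rng):
        coords = rng.uniform(-10, 10, size=(30, 3))
        g = knn_geometry(coords, nn=5)
        norms = np.linalg.norm(g.R, axis=-1)
        np.testing.assert_allclose(norms[g.mask == 1], 1.0, atol=1e-6)
        assert np.all(g.D[g.mask == 1] > 0)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.uniform(-15, 15, size=(50, 3))
        g = knn_geometry(coords, nn=8)
        for i in range(50):
            d = np.linalg.norm(coords - coords[i], axis=1)
            order = np.lexsort((np.arange(50), d))
            expected = [j for j in order if j != i][:8]
            assert list(g.indices[i]) == expected

    def test_nonfinite_coords_raise(self):
        with pytest.raises(ValueError):
            knn_geometry(np.array([[0.0, 0, np.nan]]), nn=2)


class TestLayerContracts:
    def test_rotation_equivariance_of_one_layer(self, small_model, toy_complex):
        st, part, _ = toy_complex
        coords, elements = _protein_inputs(small_model, st, part)
        tr = random_rigid_transform(99)
        q0, p0 = small_model.init_atom_states(elements)
        # start from a nonzero vector state to exercise the p_i / p_j tracks
        q, p = small_model.gt_layer(0, q0, p0, knn_geometry(coords, 8))
        c2 = tr.apply(coords)
        q2, p2 = small_model.gt_layer(0, q0, p0, knn_geometry(c2, 8))
        q_out, p_out = small_model.gt_layer(1, q, p, knn_geometry(coords, 8))
        q2_out, p2_out = small_model.gt_layer(1, q2, p2, knn_geometry(c2, 8))
        assert np.abs(q2_out.data - q_out.data).max() < 1e-5
        rotated = p_out.data @ tr.rotation.T
        assert np.abs(p2_out.data - rotated).max() < 1e-5

    def test_translation_invariance(self, small_model, toy_complex):
        st, part, _ = toy_complex
        probs, _, _ = small_model.forward_tensor(st, part)
        shifted = st.transformed(np.eye(3), np.array([10.0, -5.0, 3.0]))
        probs2, _, _ = small_model.forward_tensor(shifted, part)
        assert np.abs(probs.data - probs2.data).max() < 1e-6

    def test_single_atom_structure_is_finite(self, small_model):
        q, p = small_model.init_atom_states(["C"])
        g = knn_geometry(np.zeros((1, 3)), nn=8)
        q1, p1 = small_model.gt_layer(0, q, p, g)
        assert np.isfinite(q1.data).all() and np.isfinite(p1.data).all()

    def test_sink_padding_is_inert(self, small_model):
        """Adding sink slots must not change the update of a small structure."""
        rng = np.random.default_rng(5)
        coords = rng.uniform(-4, 4, size=(5, 3))
        q, p = small_model.init_atom_states(["C", "N", "O", "C", "S"])
        g8 = knn_geometry(coords, nn=8)    # 4 real + 4 sink
        g16 = knn_geometry(coords, nn=16)  # 4 real + 12 sink
        q8, p8 = small_model.gt_layer(0, q, p, g8)
        q16, p16 = small_model.gt_layer(0, q, p, g16)
        assert np.abs(q8.data - q16.data).max() < 1e-9
        assert np.abs(p8.data - p16.data).max() < 1e-9


class TestForward:
    def test_probabilities_in_unit_interval(self, small_model, toy_complex):
        st, part, _ = toy_complex
        probs, keys, names = small_model.forward_tensor(st, part)
        assert probs.data.shape == (10, 2)
        assert np.all(probs.data >= 0) and np.all(probs.data <= 1)

    def test_rigid_transform_invariance_of_probabilities(self, small_model, toy_complex):
        st, part, _ = toy_complex
        probs, _, _ = small_model.forward_tensor(st, part)
        tr = random_rigid_transform(17)
        probs2, _, _ = small_model.forward_tensor(
            st.transformed(tr.rotation, tr.translation), part
        )
        assert np.abs(probs.data - probs2.data).max() < 1e-4

    def test_atom_order_permutation_invariance(self, small_model, toy_complex):
        st, part, _ = toy_complex
        probs, keys, _ = small_model.forward_tensor(st, part)
        rng = np.random.default_rng(3)
        # permute atoms within each residue
        atoms = list(st.atoms)
        by_res = {}
        for a in atoms:
            by_res.setdefault(a.residue_key, []).append(a)
        shuffled = []
        for key in dict.fromkeys(a.residue_key for a in atoms):
            group = by_res[key]
            shuffled.extend([group[i] for i in rng.permutation(len(group))])
        st2 = AtomicStructure(shuffled, st.source_id)
        part2 = partition_subunits(st2)
        probs2, keys2, _ = small_model.forward_tensor(st2, part2)
        assert keys == keys2
        assert np.abs(probs.data - probs2.data).max() < 1e-6

    def test_no_protein_raises(self, small_model):
        st = AtomicStructure([Atom("C", (0, 0, 0), "C1", ("L:1", 1, ""), "GLC", False)])
        with pytest.raises(ValueError):
            small_model.forward_tensor(st)

    def test_zeroed_layers_reduce_to_embedding_decode(self, toy_complex):
        st, part, _ = toy_complex
        model = InterfaceModel(ModelConfig.scaled_down(16, 4), seed=2)
        for name, p in model.params.items():
            if name.startswith("l"):
                model.params[name] = Parameter(np.zeros_like(p.data))
        probs, keys, _ = model.forward_tensor(st, part)
        # all atoms pass the identity residual path; the pooled state of a
        # residue then depends only on its atoms' elements
        q, p0 = model.init_atom_states([a.element for a in st.atoms if a.is_polymer])
        q_r, p_r = model._pool_residues(q, p0, [list(range(4 * r, 4 * r + 4)) for r in range(10)])
        expected = model._decode(q_r, p_r)
        np.testing.assert_allclose(probs.data, expected.data, atol=1e-12)

    def test_gradients_flow_to_every_parameter(self, toy_complex):
        st, part, labels = toy_complex
        model = InterfaceModel(ModelConfig.scaled_down(16, 4), seed=4)
        probs, keys, _ = model.forward_tensor(st, part)
        y = np.stack([labels, np.zeros_like(labels)], axis=1).astype(float)
        weighted_bce(probs, y).backward()
        for name, p in model.params.items():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            assert np.abs(p.grad).max() > 0, name


def test_checkpoint_roundtrip(tmp_path, small_model, toy_complex):
    st, part, _ = toy_complex
    path = tmp_path / "model.ckpt.npz"
    small_model.save(path)
    again = InterfaceModel.load(path)
    assert again.config == small_model.config
    a, _, _ = small_model.forward_tensor(st, part)
    b, _, _ = again.forward_tensor(st, part)
    np.testing.assert_array_equal(a.data, b.data)


def test_element_list_size():
    assert len(ELEMENTS) == 29  # + 1 catch-all = 30 one-hot classes
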