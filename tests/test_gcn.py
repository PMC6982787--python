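import numpy as np
import pytest
import scipy.sparse as sp

from admetnet._autograd import Tensor
from admetnet.gcn import (GraphConvConfig, GraphConvModel, graph_conv_layer,
                          pack_graphs, readout)
from admetnet.losses import LossConfig, masked_mse_loss
from admetnet.mol import MolecularGraph, mol_to_graph, standardize_molecule
from admetnet.training import TrainConfig, train


def _graph(features, adjacency):
    adjacency = np.asarray(adjacency, bool)
    return MolecularGraph(node_features=np.asarray(features, float),
                          adjacency=adjacency,
                          degrees=adjacency.sum(axis=1).astype(int))


def test_conv_layer_two_node_path_oracle():
    """With identity weights and zero bias, each node outputs ReLU(h_v + h_u)."""
    h = np.array([[1.0, -2.0], [0.5, 3.0]])
    adj = sp.csr_matrix(np.array([[0, 1], [1, 0]], float))
    eye = Tensor(np.eye(2))
    out = graph_conv_layer(Tensor(h), adj, eye, eye, Tensor(np.zeros(2)))
    expected = np.maximum(h + h[::-1], 0.0)
    assert np.allclose(out.data, expected)


def test_conv_layer_isolated_node():
    h = np.array([[1.0, -1.0, 2.0]])
    adj = sp.csr_matrix((1, 1))
    w_self = Tensor(np.arange(9.0).reshape(3, 3))
    w_nb = Tensor(np.full((3, 3), 100.0))  # must not contribute
    b = Tensor(np.array([0.1, -5.0, 0.0]))
    out = graph_conv_layer(Tensor(h), adj, w_self, w_nb, b)
    assert np.allclose(out.data, np.maximum(h @ w_self.data + b.data, 0.0))


def test_readout_single_atom_halves_equal():
    batch = pack_graphs([_graph(np.random.default_rng(0).normal(size=(1, 75)), np.zeros((1, 1)))])
    feats = Tensor(np.random.default_rng(1).normal(size=(1, 256)))
    out = readout(feats, batch).data
    assert out.shape == (1, 512)
    assert np.allclose(out[:, :256], out[:, 256:])
    assert (np.abs(out) < 1.0).all()


def test_embedding_dimension_chain():
    cfg = GraphConvConfig(n_tasks=3)
    model = GraphConvModel(cfg, np.random.default_rng(0))
    assert model.params["conv0_W_self"].shape == (75, 128)
    assert model.params["conv1_W_self"].shape == (128, 128)
    assert model.params["dense_W"].shape == (128, 256)
    assert cfg.readout_dim == 512
    assert model.params["W_out"].shape == (512, 3)
    g = mol_to_graph(standardize_molecule("CCO"))
    assert model.embed([g]).shape == (1, 512)
    assert model.forward([g]).shape == (1, 3)


def test_zero_weights_predict_output_bias():
    model = GraphConvModel(GraphConvConfig(n_tasks=2), np.random.default_rng(0))
    for name, p in model.params.items():
        p.data[:] = 0.0
    model.params["b_out"].data[:] = (1.5, -2.0)
    g = mol_to_graph(standardize_molecule("c1ccccc1O"))
    pred = model.predict([g])
    assert np.allclose(pred, [[1.5, -2.0]])


@pytest.mark.parametrize("flags", [
    {}, {"degree_specific_weights": True}, {"neighbor_maxpool": True},
    {"batch_norm": True},
])
def test_permutation_invariance_variants(flags):
    from rdkit import Chem
    from dataclasses import replace
    model = GraphConvModel(GraphConvConfig(n_tasks=2, **flags), np.random.default_rng(1))
    sm = standardize_molecule("CC(=O)Nc1ccc(O)cc1")
    perm = np.random.default_rng(2).permutation(sm.n_atoms).tolist()
    sm_perm = replace(sm, mol=Chem.RenumberAtoms(sm.mol, perm))
    a = model.predict([mol_to_graph(sm)])
    b = model.predict([mol_to_graph(sm_perm)])
    assert np.allclose(a, b, atol=1e-5)


def test_gradients_match_finite_differences_on_batch():
    """Backprop vs central differences on a 3-molecule batch."""
    model = GraphConvModel(GraphConvConfig(conv_dims=(8, 8), dense_dim=6, n_tasks=2),
                           np.random.default_rng(3))
    graphs = [mol_to_graph(standardize_molecule(s)) for s in ("CCO", "c1ccccc1", "CC(N)=O")]
    batch = pack_graphs(graphs)
    target = np.array([[0.3, -0.1], [1.0, 0.2], [-0.5, 0.7]])
    mask = np.ones((3, 2), bool)

    def loss_value():
        return masked_mse_loss(model.forward(batch), target, mask).data.item()

    loss = masked_mse_loss(model.forward(batch), target, mask)
    for p in model.params.values():
        p.grad = None
    loss.backward()

    h = 1e-5
    rng = np.random.default_rng(0)
    for name, p in model.params.items():
        flat = p.data.reshape(-1)
        for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            old = flat[k]
            flat[k] = old + h
            fp = loss_value()
            flat[k] = old - h
            fm = loss_value()
            flat[k] = old
            num = (fp - fm) / (2 * h)
            got = p.grad.reshape(-1)[k]
            assert got == pytest.approx(num, rel=1e-4, abs=1e-7), name


def test_overfits_small_batch():
    """200 training steps on 32 molecules drive the loss below 10% of start."""
    from admetnet.synthetic import generate_molecules
    from admetnet.mol import standardize_molecule

    smiles = generate_molecules(32, seed=11)
    graphs = [mol_to_graph(standardize_molecule(s, canonical_tautomer=False))
              for s in smiles]
    rng = np.random.default_rng(5)
    targets = rng.normal(size=(32, 1))
    mask = np.ones((32, 1), bool)
    model = GraphConvModel(GraphConvConfig(conv_dims=(32, 32), dense_dim=32, n_tasks=1),
                           np.random.default_rng(0))
    initial = masked_mse_loss(model.forward(pack_graphs(graphs)), targets, mask).data.item()
    result = train(model, graphs, targets, mask,
                   TrainConfig(epochs=200, batch_size=32, seed=0))
    assert result.n_steps == 200
    final = masked_mse_loss(model.forward(pack_graphs(graphs)), targets, mask).data.item()
    assert final < 0.1 * initial
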