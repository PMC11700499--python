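"""Encoders and decoder: closed-form decoder values, training sanity,
flat-curvature equivalence, shallow baseline, checkpoints."""

import numpy as np
import pytest

import hyperbrain.autograd as ag
import hyperbrain.geometry as geo
import hyperbrain.models as M
from hyperbrain import synthetic as syn
from hyperbrain.connectivity import BrainGraph
from hyperbrain.models import HgcnConfig

from conftest import graph_from_adjacency


# ---------------------------------------------------------------------------
# config and feature lift
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        HgcnConfig(model="transformer")
    with pytest.raises(ValueError):
        HgcnConfig(decoder_t=0.0)
    with pytest.raises(ValueError):
        HgcnConfig(learning_rate=-1)
    with pytest.raises(ValueError):
        HgcnConfig(batch_size=4)


def test_lift_features_rules():
    rows = M.lift_features(np.zeros((2, 3)))
    assert np.allclose(rows, 0.0)
    one_hot = np.eye(4)
    lifted = M.lift_features(one_hot, c=1.0, lift_scale=0.1)
    assert np.allclose(np.linalg.norm(lifted, axis=1), np.tanh(0.1), atol=1e-12)
    # distinct rows stay distinct
    assert len({tuple(np.round(r, 12)) for r in lifted}) == 4


# ---------------------------------------------------------------------------
# Fermi-Dirac decoder
# ---------------------------------------------------------------------------

def test_decoder_half_at_inflection():
    # d^2 = r: probability exactly 1/2
    d = np.sqrt(2.0)
    x = np.array([np.tanh(d / 2) , 0.0])   # dist0 = d at c=1
    p = M.decode_edge(x, np.zeros(2), c=1.0, r=2.0, t=1.0)
    assert float(p) == pytest.approx(0.5, abs=1e-12)


def test_decoder_value_at_zero_distance():
    x = np.array([0.3, 0.1])
    p = M.decode_edge(x, x, c=1.0, r=2.0, t=1.0)
    assert float(p) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-9)


def test_decoder_monotone_decreasing_in_distance():
    xs = [np.array([v, 0.0]) for v in np.linspace(0.0, 0.9, 12)]
    ps = [float(M.decode_edge(x, np.zeros(2), c=1.0)) for x in xs]
    assert np.all(np.diff(ps) < 0)


def test_decoder_temperature_validation():
    with pytest.raises(ValueError):
        M.decode_edge(np.zeros(2), np.zeros(2), t=0.0)


def test_reconstruction_loss_examples():
    tgt = np.array([[0, 1, 0.5], [1, 0, 0.2], [0.5, 0.2, 0]])
    assert M.reconstruction_loss(tgt, tgt) == 0.0
    pred = np.zeros((3, 3))
    ones = np.ones((3, 3))
    np.fill_diagonal(ones, 0)
    assert M.reconstruction_loss(pred, ones) == pytest.approx(1.0)
    # hand-computed 3-node example: pairs (0,1),(0,2),(1,2)
    pred2 = np.array([[0, 0.5, 0.1], [0.5, 0, 0.9], [0.1, 0.9, 0]])
    hand = ((0.5 - 1) ** 2 + (0.1 - 0.5) ** 2 + (0.9 - 0.2) ** 2) / 3
    assert M.reconstruction_loss(pred2, tgt) == pytest.approx(hand, abs=1e-12)
    with pytest.raises(ValueError):
        M.reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# layer behavior
# ---------------------------------------------------------------------------

def test_no_edges_aggregation_is_identity_neighborhood(rng):
    """With no edges the Frechet aggregation sees only the node itself."""
    n = 6
    g_empty = BrainGraph(np.zeros((n, n), dtype=int),
                         np.zeros((n, n)), 0.5)
    model = M.HgcnModel(HgcnConfig(output_dim=2, seed=0), n)
    emb_empty, _ = model.forward(g_empty.adjacency, numpy=True)
    # independent reference: same transform without aggregation
    W1, W2, b1, b2, k1, k2 = model._params(True)
    c1 = float(np.logaddexp(0, k1))
    c2 = float(np.logaddexp(0, k2))
    x = geo.expmap0(np.eye(n), 1.0)
    h = geo.mobius_add(geo.mobius_matvec(W1, x, 1.0),
                       geo.expmap0(b1[None], 1.0), 1.0)
    x = geo.project(geo.expmap0(M.selu(geo.logmap0(h, 1.0)), c1), c1)
    h = geo.mobius_add(geo.mobius_matvec(W2, x, c1),
                       geo.expmap0(b2[None], c1), c1)
    ref = geo.project(geo.expmap0(M.selu(geo.logmap0(h, c1)), c2), c2)
    assert np.allclose(emb_empty, ref, atol=1e-8)


def test_identical_nodes_get_identical_outputs():
    adj = np.array([[0, 1], [1, 0]])
    g = graph_from_adjacency(adj)
    model = M.HgcnModel(HgcnConfig(output_dim=3, seed=1), 2)
    # identical features for both nodes of a 2-clique -> symmetric outputs
    feats = np.ones((2, 2))
    emb, _ = model.forward(adj, numpy=True, features=feats)
    assert np.allclose(emb[0], emb[1], atol=1e-10)


def test_gcn_layer_matches_independent_euclidean_implementation(rng):
    n, din, dout = 8, 8, 4
    adj = (rng.uniform(size=(n, n)) < 0.4).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    W = rng.normal(size=(dout, din))
    b = rng.normal(size=dout)
    x = rng.normal(size=(n, din))
    model = M.GcnModel(HgcnConfig(model="gcn", output_dim=dout, seed=0), n)
    w = adj + np.eye(n)
    w = w / w.sum(1, keepdims=True)
    mine = model._layer(x, W, b, w)
    h = x @ W.T + b
    y = np.stack([h[np.concatenate(([i], np.where(adj[i])[0]))].mean(0)
                  for i in range(n)])
    lam, al = M.SELU_LAMBDA, M.SELU_ALPHA
    ref = np.where(y > 0, lam * y, lam * al * (np.exp(y) - 1))
    assert np.allclose(mine, ref, atol=1e-7)
    # zero-edge graph reduces to a per-node MLP
    w0 = np.eye(n)
    assert np.allclose(model._layer(x, W, b, w0),
                       np.where(h > 0, lam * h, lam * al * (np.exp(h) - 1)),
                       atol=1e-12)


def test_selu_matches_published_constants():
    x = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
    out = M.selu(x)
    ref = 1.0507009873554805 * np.where(
        x > 0, x, 1.6732632423543772 * (np.expm1(x)))
    assert np.allclose(out, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_training_reduces_loss_and_is_deterministic():
    g = syn.gen_hyperbolic_rg(30, seed=0)
    cfg = HgcnConfig(output_dim=2, epochs=30, seed=0)
    m1 = M.train_model([g], cfg)
    assert m1.loss_history[-1] < m1.loss_history[0]
    m2 = M.train_model([g], cfg)
    assert abs(m1.loss_history[-1] - m2.loss_history[-1]) < 1e-9


def test_learned_curvatures_stay_negative():
    g = syn.gen_hyperbolic_rg(20, seed=2)
    model = M.HgcnModel(HgcnConfig(output_dim=2, seed=0), 20)
    opt = ag.Adam(model.parameters(), lr=0.02)
    for _ in range(15):
        loss = model.loss(g)
        opt.zero_grad()
        loss.backward()
        opt.step()
        k1, k2 = model.curvatures
        assert k1 < 0 and k2 < 0


def test_fixed_curvature_mode_freezes_k():
    g = syn.gen_hyperbolic_rg(20, seed=2)
    m = M.train_model([g], HgcnConfig(output_dim=2, epochs=10, seed=0,
                                      curvature_mode="fixed"))
    assert m.curvatures == (-1.0, -1.0)


def test_gradient_check_on_small_graph(path_graph5):
    """Numerical vs analytic gradients for W, b and curvature."""
    model = M.HgcnModel(HgcnConfig(output_dim=2, seed=1), 5)
    loss = model.loss(path_graph5)
    loss.backward()
    h = 1e-6
    for p in model.parameters():
        flat = p.data.ravel()
        gflat = np.atleast_1d(np.asarray(p.grad)).ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            fp = float(model.loss(path_graph5).data)
            flat[i] = orig - h
            fm = float(model.loss(path_graph5).data)
            flat[i] = orig
            num = (fp - fm) / (2 * h)
            if abs(num) > 1e-8:
                assert abs(num - gflat[i]) / abs(num) < 1e-4


def test_two_block_graph_decodes_block_structure(rng):
    n = 30
    blocks = np.repeat([0, 1], n // 2)
    p = np.where(blocks[:, None] == blocks[None, :], 0.7, 0.1)
    adj = (rng.uniform(size=(n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    g = graph_from_adjacency(adj)
    m = M.train_model([g], HgcnConfig(output_dim=2, epochs=60, seed=0))
    P = m.decode_probabilities(g)
    same = (blocks[:, None] == blocks[None, :]) & ~np.eye(n, dtype=bool)
    assert P[same].mean() > P[~same & ~np.eye(n, dtype=bool)].mean()


def test_inference_is_permutation_equivariant(rng):
    g = syn.gen_hyperbolic_rg(20, seed=3)
    m = M.train_model([g], HgcnConfig(output_dim=3, epochs=10, seed=0))
    emb = m.embed(g, center=False)
    perm = rng.permutation(20)
    gp = BrainGraph(g.adjacency[np.ix_(perm, perm)],
                    g.edge_probability[np.ix_(perm, perm)], g.threshold)
    embp = m.embed(gp, center=False, features=np.eye(20)[perm])
    c = -m.curvatures[1]
    D = geo.dist_arcosh(emb.coords[:, None, :], emb.coords[None, :, :], c)
    Dp = geo.dist_arcosh(embp.coords[:, None, :], embp.coords[None, :, :], c)
    assert np.allclose(D[np.ix_(perm, perm)], Dp, atol=1e-7)


def test_embeddings_stay_inside_ball():
    g = syn.gen_hyperbolic_rg(25, seed=5)
    m = M.train_model([g], HgcnConfig(output_dim=3, epochs=20, seed=0))
    emb = m.embed(g)
    c = -m.curvatures[1]
    assert np.all(np.sqrt(c) * np.linalg.norm(emb.coords, axis=1) < 1.0)
    assert np.allclose(emb.radii, geo.dist0(emb.coords, c))


def test_mismatched_graph_sizes_raise():
    g1 = syn.gen_hyperbolic_rg(15, seed=0)
    g2 = syn.gen_hyperbolic_rg(20, seed=0)
    with pytest.raises(ValueError, match="node set"):
        M.train_model([g1, g2], HgcnConfig(output_dim=2, epochs=1))


# ---------------------------------------------------------------------------
# shallow Poincare baseline
# ---------------------------------------------------------------------------

def test_shallow_fit_tree_hierarchy():
    """Balanced binary tree: leaves end up farther from the center than
    the root."""
    t = syn.gen_tree_graph(2, 3)
    emb = M.shallow_poincare_fit(t, dim=2, epochs=500, seed=0)
    depth = t.meta["depth"]
    assert emb.radii[depth == 3].mean() > emb.radii[0]


def test_shallow_fit_loss_decreases_and_stays_in_ball():
    g = syn.gen_hyperbolic_rg(20, seed=1)
    emb = M.shallow_poincare_fit(g, dim=2, epochs=200, seed=0)
    assert emb.loss_history[-1] < emb.loss_history[0]
    assert np.all(np.linalg.norm(emb.coords, axis=1) < 1.0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path):
    g = syn.gen_hyperbolic_rg(15, seed=0)
    m = M.train_model([g], HgcnConfig(output_dim=2, epochs=5, seed=3))
    M.save_model(m, tmp_path / "model.json")
    back = M.load_model(tmp_path / "model.json")
    assert back.config == m.config
    assert np.allclose(back.embed(g).coords, m.embed(g).coords)
    assert back.loss_history == m.loss_history


def test_embedding_tsv_export(tmp_path):
    import pandas as pd
    g = syn.gen_hyperbolic_rg(12, seed=0)
    m = M.train_model([g], HgcnConfig(output_dim=3, epochs=3, seed=0))
    emb = m.embed(g)
    M.export_embedding_tsv(emb, tmp_path / "emb.tsv")
    df = pd.read_csv(tmp_path / "emb.tsv", sep="\t")
    assert list(df.columns) == ["node", "dim0", "dim1", "dim2", "radius", "K_out"]
    assert len(df) == 12
    assert np.allclose(df["radius"], emb.radii)
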