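"""Hyperbolic graph convolutional encoder and baselines.

The encoder is a two-layer graph network operating in Poincare balls of
(optionally learned) negative curvature.  Each layer applies a Mobius
linear map with bias, aggregates neighborhoods (self included) with a
differentiable Frechet mean, and applies SELU through the tangent space,
moving features from the input-curvature ball to the output-curvature
ball.  Edges are decoded with a Fermi-Dirac function of squared geodesic
distance and trained by mean squared error against continuous edge
probabilities (min-max scaled PLV), with Adam on an unconstrained
parameterization: weights are Euclidean, biases live in the tangent
space at the origin, and curvature is K = -softplus(kappa_raw), which
keeps K strictly negative throughout training.

Baselines: a flat-curvature GCN with identical architecture (exp/log as
identities, arithmetic-mean aggregation, Euclidean decoder distance) and
a shallow Poincare embedding with free per-node coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import geometry as geo
from .connectivity import BrainGraph

__all__ = [
    "HgcnConfig", "EmbeddingResult", "HgcnModel", "GcnModel",
    "train_model", "shallow_poincare_fit", "decode_edge",
    "reconstruction_loss", "lift_features", "selu",
    "save_model", "load_model",
]

SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805
_KRAW_INIT = float(np.log(np.expm1(1.0)))   # softplus(kraw) = 1  =>  K = -1


@dataclass
class HgcnConfig:
    """Architecture and optimization constants.

    Defaults follow the reference setting: hidden width 6, Fermi-Dirac
    decoder with r=2 and t=1, learning rate 0.02, 100 epochs, one graph
    per optimizer step.
    """

    model: str = "hgcn"                 # "hgcn" | "gcn"
    input_dim: int | None = None        # n_rois for one-hot features
    hidden_dim: int = 6
    output_dim: int = 3
    curvature_mode: str = "learned"     # "learned" | "fixed"
    learning_rate: float = 0.02
    epochs: int = 100
    batch_size: int = 1
    seed: int = 0
    decoder_r: float = 2.0
    decoder_t: float = 1.0
    lift_scale: float = 1.0
    agg_iters: int = 8

    def __post_init__(self):
        if self.model not in ("hgcn", "gcn"):
            raise ValueError("model must be 'hgcn' or 'gcn'")
        if self.curvature_mode not in ("learned", "fixed"):
            raise ValueError("curvature_mode must be 'learned' or 'fixed'")
        if min(self.hidden_dim, self.output_dim) < 1:
            raise ValueError("dimensions must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.decoder_t <= 0:
            raise ValueError("decoder temperature t must be positive")
        if self.batch_size != 1:
            raise ValueError("one graph per optimizer step is the supported mode")


@dataclass
class EmbeddingResult:
    """Node embeddings with their hierarchy radii."""

    coords: np.ndarray                  # [n_nodes x D]
    radii: np.ndarray                   # [n_nodes]
    curvatures: tuple | None            # (K1, K2) for hyperbolic models
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not self.roi_names:
            self.roi_names = [f"node{i}" for i in range(self.coords.shape[0])]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def selu(x):
    """Scaled exponential linear unit (works on Tensor or ndarray)."""
    xd = ag.data(x)
    neg = SELU_ALPHA * (ag.exp(ag.clamp(x, max=0.0)) - 1.0)
    return SELU_LAMBDA * ag.where(xd > 0, x, neg)


def lift_features(features, c=1.0, lift_scale: float = 1.0):
    """Map Euclidean node features into the c-ball via a scaled expmap0."""
    return geo.expmap0(lift_scale * np.asarray(features, dtype=float), c)


def decode_edge(xi, xj, c=1.0, r: float = 2.0, t: float = 1.0):
    """Fermi-Dirac edge probability 1 / (exp((d^2 - r)/t) + 1).

    Accepts arrays (rows are points) or :class:`~hyperbrain.geometry.PoincarePoint`
    pairs; ``d`` is the geodesic distance at curvature scale ``c``.
    """
    if t <= 0:
        raise ValueError("decoder temperature t must be positive")
    if isinstance(xi, geo.PoincarePoint):
        if xi.curvature != xj.curvature:
            raise ValueError("curvature mismatch")
        c = xi.curvature.c
        xi, xj = xi.coords, xj.coords
    d = geo.dist(np.atleast_2d(xi), np.atleast_2d(xj), c)
    p = ag.sigmoid(-(d * d - r) / t)
    if not ag.is_tensor(p) and np.size(p) == 1:
        return float(np.reshape(p, ()))
    return p


def reconstruction_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over off-diagonal upper-triangle pairs."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch between prediction and target")
    iu, ju = np.triu_indices(pred.shape[0], 1)
    return float(np.mean((pred[iu, ju] - target[iu, ju]) ** 2))


def _pair_loss(pred_pairs, target_pairs):
    diff = pred_pairs - target_pairs
    return ag.tsum(diff * diff) / float(ag.data(pred_pairs).size)


def _glorot(rng, out_dim, in_dim):
    lim = np.sqrt(6.0 / (in_dim + out_dim))
    return rng.uniform(-lim, lim, size=(out_dim, in_dim))


def _norm_weights(adj):
    A = np.asarray(adj, dtype=float) + np.eye(adj.shape[0])
    return A / A.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _BaseModel:
    """Shared training/inference machinery for the two-layer encoders."""

    def __init__(self, config: HgcnConfig, n_nodes: int):
        if config.input_dim is not None and config.input_dim != n_nodes:
            raise ValueError("input_dim must equal n_nodes for one-hot features")
        self.config = config
        self.n_nodes = n_nodes
        rng = np.random.default_rng(config.seed)
        self.W1 = ag.Tensor(_glorot(rng, config.hidden_dim, n_nodes),
                            requires_grad=True)
        self.W2 = ag.Tensor(_glorot(rng, config.output_dim, config.hidden_dim),
                            requires_grad=True)
        self.b1 = ag.Tensor(np.zeros(config.hidden_dim), requires_grad=True)
        self.b2 = ag.Tensor(np.zeros(config.output_dim), requires_grad=True)
        learned = config.curvature_mode == "learned"
        self.kraw1 = ag.Tensor(_KRAW_INIT, requires_grad=learned)
        self.kraw2 = ag.Tensor(_KRAW_INIT, requires_grad=learned)
        self.loss_history: list[float] = []

    def parameters(self):
        ps = [self.W1, self.W2, self.b1, self.b2]
        if self.config.curvature_mode == "learned":
            ps += [self.kraw1, self.kraw2]
        return ps

    @property
    def curvatures(self):
        """(K1, K2): strictly negative layer curvatures."""
        return (-float(ag.softplus(self.kraw1.data)),
                -float(ag.softplus(self.kraw2.data)))

    def _params(self, numpy: bool):
        if numpy:
            return (self.W1.data, self.W2.data, self.b1.data, self.b2.data,
                    self.kraw1.data, self.kraw2.data)
        return self.W1, self.W2, self.b1, self.b2, self.kraw1, self.kraw2

    # subclasses implement forward(adj, numpy) -> (emb, c_out)
    #  and _pair_scores(emb, c_out, iu, ju)

    def loss(self, graph: BrainGraph):
        emb, c_out = self.forward(graph.adjacency, numpy=False)
        iu, ju = np.triu_indices(graph.n_nodes, 1)
        pred = self._pair_scores(emb, c_out, iu, ju)
        return _pair_loss(pred, graph.edge_probability[iu, ju])

    def decode_probabilities(self, graph: BrainGraph) -> np.ndarray:
        """Full matrix of decoded edge probabilities (inference)."""
        emb, c_out = self.forward(graph.adjacency, numpy=True)
        n = graph.n_nodes
        iu, ju = np.triu_indices(n, 1)
        p = self._pair_scores(emb, c_out, iu, ju)
        out = np.zeros((n, n))
        out[iu, ju] = p
        out[ju, iu] = p
        return out

    def embed(self, graph: BrainGraph, center: bool = True,
              features=None) -> EmbeddingResult:
        """Inductive inference: one-hot features + adjacency only.

        The decoder objective fixes embeddings only up to an isometry, so
        by default the cloud is centered (Frechet mean at the origin; the
        arithmetic mean for the flat model) before radii are computed,
        making radii comparable across graphs.
        """
        emb, c_out = self.forward(graph.adjacency, numpy=True, features=features)
        if center:
            emb = self._center(emb, c_out)
        radii = self._radii(emb, c_out)
        return EmbeddingResult(emb, radii, self._curvature_tuple(),
                               list(graph.roi_names))


class HgcnModel(_BaseModel):
    """Two-layer hyperbolic graph convolutional encoder."""

    def forward(self, adj, numpy: bool = True, features=None):
        W1, W2, b1, b2, kraw1, kraw2 = self._params(numpy)
        cfg = self.config
        w = _norm_weights(adj)
        c0 = 1.0
        c1 = ag.softplus(kraw1)
        c2 = ag.softplus(kraw2)
        feats = (np.eye(adj.shape[0]) if features is None
                 else np.asarray(features, dtype=float)) * cfg.lift_scale
        x = geo.expmap0(feats, c0)
        x = self._layer(x, W1, b1, c0, c1, w)
        x = self._layer(x, W2, b2, c1, c2, w)
        return x, c2

    def _layer(self, x, W, b, c_in, c_out, w):
        h = geo.mobius_matvec(W, x, c_in)
        h = geo.mobius_add(h, geo.expmap0(ag.reshape(b, 1, -1), c_in), c_in)
        y = geo.frechet_agg(h, w, c_in, iters=self.config.agg_iters)
        v = selu(geo.logmap0(y, c_in))
        return geo.project(geo.expmap0(v, c_out), c_out)

    def _pair_scores(self, emb, c_out, iu, ju):
        cfg = self.config
        xi = ag.take(emb, iu)
        xj = ag.take(emb, ju)
        m = geo.mobius_add(-xi, xj, c_out)
        sqc = ag.sqrt(c_out)
        d = (2.0 / sqc) * ag.artanh(ag.clamp(sqc * ag.norm(m),
                                             max=1.0 - 1e-12))
        d = ag.reshape(d, len(iu))
        return ag.sigmoid(-(d * d - cfg.decoder_r) / cfg.decoder_t)

    def _center(self, emb, c_out):
        return geo.center_embedding(emb, float(ag.data(c_out)))

    def _radii(self, emb, c_out):
        return geo.dist0(emb, float(ag.data(c_out)))

    def _curvature_tuple(self):
        return self.curvatures


class GcnModel(_BaseModel):
    """Identical architecture with flat curvature: exp/log maps become
    identities, Mobius ops become matvec/addition, the Frechet mean
    reduces to the arithmetic mean, and the decoder uses Euclidean
    distance."""

    def forward(self, adj, numpy: bool = True, features=None):
        W1, W2, b1, b2, _, _ = self._params(numpy)
        cfg = self.config
        w = _norm_weights(adj)
        feats = (np.eye(adj.shape[0]) if features is None
                 else np.asarray(features, dtype=float)) * cfg.lift_scale
        x = self._layer(feats, W1, b1, w)
        x = self._layer(x, W2, b2, w)
        return x, None

    def _layer(self, x, W, b, w):
        h = ag.matmul(x, ag.transpose(W)) + ag.reshape(b, 1, -1)
        y = ag.matmul(w, h)
        return selu(y)

    def _pair_scores(self, emb, c_out, iu, ju):
        cfg = self.config
        diff = ag.take(emb, iu) - ag.take(emb, ju)
        d2 = ag.tsum(diff * diff, axis=-1)
        return ag.sigmoid(-(d2 - cfg.decoder_r) / cfg.decoder_t)

    def _center(self, emb, c_out):
        return emb - emb.mean(axis=0, keepdims=True)

    def _radii(self, emb, c_out):
        return np.linalg.norm(emb, axis=-1)

    def _curvature_tuple(self):
        return None

    @property
    def curvatures(self):
        return None

    def parameters(self):
        return [self.W1, self.W2, self.b1, self.b2]


def train_model(graphs, config: HgcnConfig):
    """Train an encoder on a list of :class:`BrainGraph` (one per step).

    An epoch is one pass over all training graphs in a seed-shuffled
    order.  Returns the trained model; embeddings for any graph (seen or
    unseen) come from ``model.embed(graph)``.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one training graph")
    n = graphs[0].n_nodes
    if any(g.n_nodes != n for g in graphs):
        raise ValueError("all graphs must share the node set size")
    cls = HgcnModel if config.model == "hgcn" else GcnModel
    model = cls(config, n)
    opt = ag.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    for epoch in range(config.epochs):
        order = rng.permutation(len(graphs))
        losses = []
        for gi in order:
            loss = model.loss(graphs[gi])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_history.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# shallow Poincare baseline
# ---------------------------------------------------------------------------

def shallow_poincare_fit(graph: BrainGraph, dim: int = 2, epochs: int = 300,
                         lr: float = 0.3, seed: int = 0, r: float = 2.0,
                         t: float = 1.0, burn_in: int = 10,
                         center: bool = True) -> EmbeddingResult:
    """Free per-node coordinates in the unit-curvature ball, optimized
    against the Fermi-Dirac + MSE objective with Riemannian gradient
    scaling and ball projection.  The first ``burn_in`` epochs use a
    tenth of the learning rate.  The fitted cloud is centered (Frechet
    mean at the origin) before radii are computed unless ``center`` is
    False."""
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    X = ag.Tensor(rng.uniform(-1e-3, 1e-3, size=(n, dim)), requires_grad=True)
    iu, ju = np.triu_indices(n, 1)
    target = graph.edge_probability[iu, ju]
    c = 1.0
    history = []
    for epoch in range(epochs):
        xi = ag.take(X, iu)
        xj = ag.take(X, ju)
        m = geo.mobius_add(-xi, xj, c)
        d = 2.0 * ag.artanh(ag.clamp(ag.norm(m), max=1.0 - 1e-12))
        d = ag.reshape(d, len(iu))
        pred = ag.sigmoid(-(d * d - r) / t)
        loss = _pair_loss(pred, target)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"shallow embedding diverged at epoch {epoch}")
        X.zero_grad()
        loss.backward()
        # Riemannian gradient on the Poincare ball
        conf = ((1.0 - np.sum(X.data ** 2, axis=1, keepdims=True)) / 2.0) ** 2
        step = lr / 10.0 if epoch < burn_in else lr
        X.data = geo.project(X.data - step * conf * X.grad, c)
        history.append(float(loss.data))
    coords = geo.center_embedding(X.data, c) if center else X.data.copy()
    radii = geo.dist0(coords, c)
    res = EmbeddingResult(coords, radii, (-1.0, -1.0),
                          list(graph.roi_names))
    res.loss_history = history
    return res


# ---------------------------------------------------------------------------
# checkpoints (plain-text JSON)
# ---------------------------------------------------------------------------

def save_model(model: _BaseModel, path):
    payload = {
        "config": asdict(model.config),
        "n_nodes": model.n_nodes,
        "params": {
            "W1": model.W1.data.tolist(), "W2": model.W2.data.tolist(),
            "b1": model.b1.data.tolist(), "b2": model.b2.data.tolist(),
            "kraw1": float(model.kraw1.data), "kraw2": float(model.kraw2.data),
        },
        "curvatures": model.curvatures,
        "loss_history": model.loss_history,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    payload = json.loads(Path(path).read_text())
    config = HgcnConfig(**payload["config"])
    cls = HgcnModel if config.model == "hgcn" else GcnModel
    model = cls(config, payload["n_nodes"])
    p = payload["params"]
    model.W1.data = np.asarray(p["W1"], dtype=float)
    model.W2.data = np.asarray(p["W2"], dtype=float)
    model.b1.data = np.asarray(p["b1"], dtype=float)
    model.b2.data = np.asarray(p["b2"], dtype=float)
    model.kraw1.data = np.asarray(p["kraw1"], dtype=float)
    model.kraw2.data = np.asarray(p["kraw2"], dtype=float)
    model.loss_history = list(payload.get("loss_history", []))
    return model


def export_embedding_tsv(result: EmbeddingResult, path):
    """TSV export: node label, coordinates, radius (and final curvature)."""
    import pandas as pd
    D = result.coords.shape[1]
    df = pd.DataFrame(result.coords,
                      columns=[f"dim{i}" for i in range(D)])
    df.insert(0, "node", result.roi_names)
    df["radius"] = result.radii
    if result.curvatures is not None:
        df["K_out"] = result.curvatures[1]
    df.to_csv(path, sep="\t", index=False)
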