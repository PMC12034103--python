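"""Graph isomorphism network classifier and embedding extractor.

The model stacks three message-passing layers.  At layer k the hidden
vector of node v is updated as

    h_v^k = MLP_k( (1 + eps) * h_v^{k-1}  +  sum_{u in N(v)} m(h_u^{k-1}, e_uv) )

where N(v) is the in-neighborhood (all other nodes, since loop graphs are
complete digraphs), eps defaults to 0, and the message m either ignores
the 23-dim edge feature (``edge_mode="ignore"``, the plain sum-aggregation
update) or adds a learned linear projection of it to the neighbor state
(``edge_mode="project_add"``, the default, since loop edges carry the
distance / pair / stacking attributes).  Each MLP_k is Linear ->
LeakyReLU -> Linear with a shared hidden width.

Readout averages node states per layer, sums the per-layer means, applies
LeakyReLU and projects to the embedding width (128 by default).  A softmax
head over the embedding is trained with categorical cross-entropy; the
weights of the epoch with the highest validation accuracy are retained
(ties broken by the latest such epoch, so margins keep improving after
accuracy saturates).
Everything is plain NumPy with manual gradients and Adam, deterministic
under a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, LoopGraph

__all__ = [
    "ModelConfig",
    "GINEmbedder",
    "TrainedModel",
    "gin_layer",
    "readout",
    "train",
    "embed",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


def _leaky(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x >= 0, x, alpha * x)


def _leaky_grad(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, alpha)


def gin_layer(
    h_prev: np.ndarray,
    graph: LoopGraph | None = None,
    epsilon: float = 0.0,
    mlp=None,
    edge_mode: str = "ignore",
    edge_projection: np.ndarray | None = None,
) -> np.ndarray:
    """One GIN update on a complete directed graph (functional form).

    ``h_prev`` is (N, d).  With ``edge_mode="project_add"`` the graph's
    edge features are projected by ``edge_projection`` (23 x d) and added
    to the neighbor messages.  ``mlp`` is any callable on (N, d) arrays;
    ``None`` means identity.
    """
    h = np.asarray(h_prev, dtype=float)
    if h.ndim != 2:
        raise ValueError("h_prev must be (N, d)")
    total = h.sum(axis=0, keepdims=True)
    agg = (1.0 + epsilon) * h + (total - h)
    if edge_mode == "project_add":
        if graph is None or edge_projection is None:
            raise ValueError("project_add needs a graph and an edge projection")
        agg = agg + graph.incoming_edge_sums() @ edge_projection
    elif edge_mode != "ignore":
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    return agg if mlp is None else mlp(agg)


def readout(
    per_layer_node_reps,
    projection: np.ndarray | None = None,
    bias: np.ndarray | None = None,
    alpha: float = 0.01,
) -> np.ndarray:
    """Graph-level feature: mean per layer, summed, LeakyReLU, projected."""
    means = [np.asarray(H, dtype=float).mean(axis=0) for H in per_layer_node_reps]
    pooled = _leaky(np.sum(means, axis=0), alpha)
    if projection is None:
        return pooled
    out = pooled @ projection
    return out if bias is None else out + bias


@dataclass
class ModelConfig:
    """Hyperparameters of the GIN classifier/embedder."""

    num_layers: int = 3
    hidden_dim: int = 128
    embed_dim: int = 128
    epsilon: float = 0.0
    learn_epsilon: bool = False
    leaky_alpha: float = 0.01
    edge_mode: str = "project_add"
    num_classes: int | None = None
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")


def _pack(graphs: list[LoopGraph]):
    """Pad a graph list into batch tensors (node feats, edge sums, mask, n)."""
    sizes = np.array([g.n_nodes for g in graphs])
    nmax = int(sizes.max())
    B = len(graphs)
    X = np.zeros((B, nmax, NODE_FEATURE_DIM))
    Ein = np.zeros((B, nmax, EDGE_FEATURE_DIM))
    mask = np.zeros((B, nmax, 1))
    for b, g in enumerate(graphs):
        n = g.n_nodes
        X[b, :n] = g.node_features
        Ein[b, :n] = g.incoming_edge_sums()
        mask[b, :n] = 1.0
    return X, Ein, mask, sizes.astype(float)


class GINEmbedder(BaseEstimator, TransformerMixin):
    """GIN graph classifier exposing 128-dim embeddings (sklearn-style).

    ``fit`` takes a list of :class:`LoopGraph` and family labels,
    ``transform`` returns the embedding matrix, ``predict`` /
    ``predict_proba`` the softmax head's output.  Training keeps the
    checkpoint with the highest validation accuracy.
    """

    def __init__(
        self,
        num_layers: int = 3,
        hidden_dim: int = 128,
        embed_dim: int = 128,
        epsilon: float = 0.0,
        learn_epsilon: bool = False,
        leaky_alpha: float = 0.01,
        edge_mode: str = "project_add",
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.num_layers = num_layers
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.epsilon = epsilon
        self.learn_epsilon = learn_epsilon
        self.leaky_alpha = leaky_alpha
        self.edge_mode = edge_mode
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.seed = seed

    # -- parameter plumbing -------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        dh, de, C = self.hidden_dim, self.embed_dim, len(self.classes_)
        params: dict[str, np.ndarray] = {}
        din = NODE_FEATURE_DIM
        for k in range(self.num_layers):
            if self.edge_mode == "project_add":
                params[f"P{k}"] = glorot((EDGE_FEATURE_DIM, din))
            params[f"W1_{k}"] = glorot((din, dh))
            params[f"b1_{k}"] = np.zeros(dh)
            params[f"W2_{k}"] = glorot((dh, dh))
            params[f"b2_{k}"] = np.zeros(dh)
            din = dh
        params["W_out"] = glorot((dh, de))
        params["b_out"] = np.zeros(de)
        params["W_cls"] = glorot((de, C))
        params["b_cls"] = np.zeros(C)
        if self.learn_epsilon:
            params["eps"] = np.full(self.num_layers, float(self.epsilon))
        return params

    def _epsilons(self, params) -> np.ndarray:
        if self.learn_epsilon:
            return params["eps"]
        return np.full(self.num_layers, float(self.epsilon))

    # -- forward / backward -------------------------------------------------

    def _forward(self, params, X, Ein, mask, nvec, want_cache=False):
        alpha = self.leaky_alpha
        eps = self._epsilons(params)
        H = X * mask
        layer_states, caches = [], []
        for k in range(self.num_layers):
            total = H.sum(axis=1, keepdims=True)
            A = eps[k] * H + total
            if self.edge_mode == "project_add":
                A = A + Ein @ params[f"P{k}"]
            A = A * mask
            Z = A @ params[f"W1_{k}"] + params[f"b1_{k}"]
            L = _leaky(Z, alpha)
            Hk = (L @ params[f"W2_{k}"] + params[f"b2_{k}"]) * mask
            if want_cache:
                caches.append({"H_in": H, "A": A, "Z": Z, "L": L})
            H = Hk
            layer_states.append(Hk)
        R = sum(Hk.sum(axis=1) for Hk in layer_states) / nvec[:, None]
        G = _leaky(R, alpha)
        EMB = G @ params["W_out"] + params["b_out"]
        logits = EMB @ params["W_cls"] + params["b_cls"]
        if want_cache:
            return logits, EMB, {"caches": caches, "R": R, "G": G, "EMB": EMB}
        return logits, EMB, None

    def _loss_and_grads(self, params, X, Ein, mask, nvec, Y):
        logits, _, cache = self._forward(params, X, Ein, mask, nvec, want_cache=True)
        B = X.shape[0]
        alpha = self.leaky_alpha
        eps = self._epsilons(params)

        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(B), Y] + 1e-12))

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), Y] -= 1.0
        dlogits /= B

        grads["W_cls"] = cache["EMB"].T @ dlogits
        grads["b_cls"] = dlogits.sum(axis=0)
        dEMB = dlogits @ params["W_cls"].T
        grads["W_out"] = cache["G"].T @ dEMB
        grads["b_out"] = dEMB.sum(axis=0)
        dG = dEMB @ params["W_out"].T
        dR = dG * _leaky_grad(cache["R"], alpha)

        # readout distributes dR/n to every (real) node of every layer
        d_next = None  # gradient flowing into H_k from layer k+1
        dR_nodes = (dR / nvec[:, None])[:, None, :] * mask
        for k in range(self.num_layers - 1, -1, -1):
            c = cache["caches"][k]
            dHk = dR_nodes.copy()
            if d_next is not None:
                dHk += d_next
            dHk *= mask
            grads[f"W2_{k}"] = np.einsum("bnh,bnd->hd", c["L"], dHk)
            grads[f"b2_{k}"] = dHk.sum(axis=(0, 1))
            dL = dHk @ params[f"W2_{k}"].T
            dZ = dL * _leaky_grad(c["Z"], alpha)
            grads[f"W1_{k}"] = np.einsum("bnd,bnh->dh", c["A"], dZ)
            grads[f"b1_{k}"] = dZ.sum(axis=(0, 1))
            dA = (dZ @ params[f"W1_{k}"].T) * mask
            if self.edge_mode == "project_add":
                grads[f"P{k}"] = np.einsum("bnt,bnd->td", Ein, dA)
            if self.learn_epsilon:
                grads["eps"][k] = float(np.sum(dA * c["H_in"]))
            # A = eps*H + sum_nodes(H) + Ein P  =>  dH = eps*dA + broadcast(colsum dA)
            d_next = (eps[k] * dA + dA.sum(axis=1, keepdims=True)) * mask
        return loss, grads, probs

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y, val_graphs=None, val_y=None):
        """Train on labelled loop graphs.

        When no explicit validation set is given, a stratified
        ``val_fraction`` of the input is held out (seeded).
        """
        graphs = list(X)
        y = np.asarray(y)
        if len(graphs) != len(y):
            raise ValueError("X and y lengths differ")
        if len(graphs) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training needs at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        codes = np.array([class_index[v] for v in y])

        rng = np.random.default_rng(self.seed)
        if val_graphs is None:
            val_idx = []
            for c in range(len(self.classes_)):
                members = np.flatnonzero(codes == c)
                members = members[rng.permutation(len(members))]
                k = max(1, int(round(self.val_fraction * len(members))))
                if k >= len(members):
                    k = len(members) - 1
                val_idx.extend(members[:k])
            val_idx = np.array(sorted(val_idx))
            train_idx = np.setdiff1d(np.arange(len(graphs)), val_idx)
            if len(train_idx) == 0 or len(val_idx) == 0:
                raise ValueError("not enough data for a train/validation split")
            train_graphs = [graphs[i] for i in train_idx]
            train_codes = codes[train_idx]
            val_graphs = [graphs[i] for i in val_idx]
            val_codes = codes[val_idx]
        else:
            val_y = np.asarray(val_y)
            unknown = set(val_y) - set(self.classes_)
            if unknown:
                raise ValueError(f"validation labels outside vocabulary: {unknown}")
            train_graphs, train_codes = graphs, codes
            val_graphs = list(val_graphs)
            val_codes = np.array([class_index[v] for v in val_y])
        if len(val_graphs) == 0:
            raise ValueError("empty validation split")

        Xtr, Etr, Mtr, ntr = _pack(train_graphs)
        Xva, Eva, Mva, nva = _pack(val_graphs)

        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        step = 0

        best = {"val_accuracy": -1.0, "params": None, "epoch": -1}
        history = []
        n_train = len(train_graphs)
        for epoch in range(self.epochs):
            order = rng.permutation(n_train)
            epoch_loss, epoch_hits = 0.0, 0
            for start in range(0, n_train, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, grads, probs = self._loss_and_grads(
                    params, Xtr[idx], Etr[idx], Mtr[idx], ntr[idx], train_codes[idx]
                )
                epoch_loss += loss * len(idx)
                epoch_hits += int(np.sum(probs.argmax(axis=1) == train_codes[idx]))
                step += 1
                for key in params:
                    g = grads[key]
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**step)
                    vhat = v[key] / (1 - beta2**step)
                    params[key] = params[key] - self.learning_rate * mhat / (
                        np.sqrt(vhat) + adam_eps
                    )
            val_logits, _, _ = self._forward(params, Xva, Eva, Mva, nva)
            val_acc = float(np.mean(val_logits.argmax(axis=1) == val_codes))
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": epoch_loss / n_train,
                    "train_accuracy": epoch_hits / n_train,
                    "val_accuracy": val_acc,
                }
            )
            if val_acc >= best["val_accuracy"]:
                best = {
                    "val_accuracy": val_acc,
                    "params": {k: p.copy() for k, p in params.items()},
                    "epoch": epoch,
                }

        self.params_ = best["params"]
        self.best_val_accuracy_ = best["val_accuracy"]
        self.best_epoch_ = best["epoch"]
        self.history_ = history
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    def _batched_forward(self, graphs):
        self._check_fitted()
        graphs = list(graphs)
        for g in graphs:
            if g.node_features.shape[1] != NODE_FEATURE_DIM or g.edge_features.shape[2] != EDGE_FEATURE_DIM:
                raise ValueError("graph feature dimensions do not match the training schema")
        X, Ein, mask, nvec = _pack(graphs)
        logits, emb, _ = self._forward(self.params_, X, Ein, mask, nvec)
        return logits, emb

    def transform(self, X) -> np.ndarray:
        """Embed graphs: one ``embed_dim``-vector per graph, input order kept."""
        _, emb = self._batched_forward(X)
        return emb

    def predict_proba(self, X) -> np.ndarray:
        logits, _ = self._batched_forward(X)
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        return expz / expz.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class TrainedModel:
    """A fitted embedder plus its bookkeeping, for checkpointing."""

    embedder: GINEmbedder
    config: ModelConfig
    label_vocabulary: list[str]
    best_val_accuracy: float
    test_accuracy: float | None = None
    history: list[dict] = field(default_factory=list)


def train(graphs, split, config: ModelConfig | None = None) -> TrainedModel:
    """Train a GIN classifier on labelled graphs with a (train, val, test) split.

    ``split`` is a triple of index arrays into ``graphs``.  Labels are the
    graphs' own ``label`` fields.  Returns the best-validation checkpoint
    with its test accuracy.
    """
    config = config or ModelConfig()
    graphs = list(graphs)
    labels = np.array([g.label for g in graphs])
    if any(lbl is None for lbl in labels):
        raise ValueError("all training graphs need labels")
    train_idx, val_idx, test_idx = (np.asarray(ix, dtype=int) for ix in split)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation splits must be nonempty")
    est = GINEmbedder(
        num_layers=config.num_layers,
        hidden_dim=config.hidden_dim,
        embed_dim=config.embed_dim,
        epsilon=config.epsilon,
        learn_epsilon=config.learn_epsilon,
        leaky_alpha=config.leaky_alpha,
        edge_mode=config.edge_mode,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    est.fit(
        [graphs[i] for i in train_idx],
        labels[train_idx],
        val_graphs=[graphs[i] for i in val_idx],
        val_y=labels[val_idx],
    )
    test_acc = (
        est.score([graphs[i] for i in test_idx], labels[test_idx])
        if len(test_idx)
        else None
    )
    config.num_classes = len(est.classes_)
    return TrainedModel(
        embedder=est,
        config=config,
        label_vocabulary=[str(c) for c in est.classes_],
        best_val_accuracy=est.best_val_accuracy_,
        test_accuracy=test_acc,
        history=est.history_,
    )


def embed(graphs, model: TrainedModel | GINEmbedder) -> np.ndarray:
    est = model.embedder if isinstance(model, TrainedModel) else model
    return est.transform(graphs)


def predict(graphs, model: TrainedModel | GINEmbedder):
    est = model.embedder if isinstance(model, TrainedModel) else model
    return est.predict(graphs), est.predict_proba(graphs)


def save_checkpoint(model: TrainedModel, directory) -> None:
    """Weights as .npz plus a JSON sidecar with config and vocabulary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.embedder.params_)
    sidecar = {
        "config": asdict(model.config),
        "label_vocabulary": model.label_vocabulary,
        "best_val_accuracy": model.best_val_accuracy,
        "test_accuracy": model.test_accuracy,
        "schema": {"node_dim": NODE_FEATURE_DIM, "edge_dim": EDGE_FEATURE_DIM},
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(directory) -> TrainedModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    config = ModelConfig(**sidecar["config"])
    est = GINEmbedder(
        num_layers=config.num_layers,
        hidden_dim=config.hidden_dim,
        embed_dim=config.embed_dim,
        epsilon=config.epsilon,
        learn_epsilon=config.learn_epsilon,
        leaky_alpha=config.leaky_alpha,
        edge_mode=config.edge_mode,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        val_fraction=config.val_fraction,
        seed=config.seed,
    )
    with np.load(directory / "weights.npz") as blob:
        est.params_ = {k: blob[k] for k in blob.files}
    est.classes_ = np.array(sidecar["label_vocabulary"])
    est.best_val_accuracy_ = sidecar["best_val_accuracy"]
    est.history_ = []
    return TrainedModel(
        embedder=est,
        config=config,
        label_vocabulary=sidecar["label_vocabulary"],
        best_val_accuracy=sidecar["best_val_accuracy"],
        test_accuracy=sidecar.get("test_accuracy"),
    )
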