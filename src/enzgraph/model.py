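"""LE-ClusterGCN network for hierarchical multi-label enzyme classification.

Architecture: the node input H0 = [X | E] (one-hot identities
concatenated with per-residue embeddings) passes through a stack of
local-extremum graph convolutions (LEConv),

    h_i' = ReLU( h_i W1 + sum_{j in N(i)} e_ji (h_i W2 - h_j W3) ),

then cluster graph convolutions (ClusterGCNConv),

    H' = ReLU( (A~ + lambda diag(A~)) H W1 + H W2 ),
    A~ = (D + I)^-1 (A + I),

followed by global mean pooling, two ReLU fully-connected layers and a
final layer with independent per-class sigmoids, so a chain can carry
several EC numbers at once.  Training minimizes the focal loss

    FL(p_t) = -(1 - p_t)^gamma log(p_t),   p_t = p if y=1 else 1-p,

with Adam, stopping early when none of training loss, validation loss
or validation micro-F1 improves for `patience` consecutive epochs; the
checkpoint with the best validation F1 is returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, as_tensor
from .graphs import ProteinGraph
from .metrics import micro_classification_metrics

logger = logging.getLogger(__name__)

#: clamp applied to probabilities inside the focal loss to keep log finite
PROB_EPS = 1e-7


@dataclass
class ModelConfig:
    input_dim: int                       # 20 + embedding dim
    n_classes: int
    layer_dims: tuple[int, ...] = (256, 256, 256)
    n_leconv: int = 2
    n_clustergcn: int = 1
    lambda_diag: float = 1.0
    fc_dims: tuple[int, int] = (128, 64)
    gamma: float = 2.0
    lr: float = 1e-4
    batch_size: int = 20
    max_epochs: int = 500
    patience: int = 30
    seed: int = 0
    #: expected residue contact-map degree, used only to scale the
    #: initialization variance of the neighbor-aggregation weights so the
    #: summed messages keep unit-order variance at the start of training
    expected_degree: float = 10.0

    def __post_init__(self):
        if len(self.layer_dims) != self.n_leconv + self.n_clustergcn:
            raise ValueError("layer_dims must list one width per graph layer")
        if min(self.layer_dims) < 1 or self.input_dim < 1 or self.n_classes < 1:
            raise ValueError("dimensions must be positive")
        if self.gamma < 0 or self.patience < 1:
            raise ValueError("gamma must be >= 0 and patience >= 1")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: ModelConfig) -> dict[str, Tensor]:
    """Seeded Glorot-uniform initialization of all trainable weights."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}
    d_in = config.input_dim
    layer = 0
    agg_scale = 1.0 / np.sqrt(max(config.expected_degree, 1.0))
    for i in range(config.n_leconv):
        d_out = config.layer_dims[layer]
        params[f"leconv{i}_W1"] = Tensor(_glorot(rng, d_in, d_out),
                                         requires_grad=True)
        # W2/W3 feed a sum over ~expected_degree neighbors
        for w in ("W2", "W3"):
            params[f"leconv{i}_{w}"] = Tensor(
                _glorot(rng, d_in, d_out) * agg_scale, requires_grad=True)
        d_in, layer = d_out, layer + 1
    for i in range(config.n_clustergcn):
        d_out = config.layer_dims[layer]
        for w in ("W1", "W2"):
            params[f"cluster{i}_{w}"] = Tensor(_glorot(rng, d_in, d_out),
                                               requires_grad=True)
        d_in, layer = d_out, layer + 1
    widths = [d_in, *config.fc_dims]
    for i in range(2):
        params[f"fc{i}_W"] = Tensor(_glorot(rng, widths[i], widths[i + 1]),
                                    requires_grad=True)
        params[f"fc{i}_b"] = Tensor(np.zeros(widths[i + 1]), requires_grad=True)
    params["out_W"] = Tensor(_glorot(rng, widths[-1], config.n_classes),
                             requires_grad=True)
    params["out_b"] = Tensor(np.zeros(config.n_classes), requires_grad=True)
    return params


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _leconv_t(H: Tensor, A: np.ndarray, W1: Tensor, W2: Tensor,
              W3: Tensor) -> Tensor:
    deg = A.sum(axis=1, keepdims=True)          # |N(i)| as a column
    return (H @ W1 + (H @ W2) * deg - as_tensor(A) @ (H @ W3)).relu()


def _cluster_operator(A: np.ndarray, lambda_diag: float) -> np.ndarray:
    """(A~ + lambda diag(A~)) with A~ = (D+I)^-1 (A+I)."""
    L = A.shape[0]
    deg = A.sum(axis=1)
    A_hat = (A + np.eye(L)) / (deg + 1.0)[:, None]
    return A_hat + lambda_diag * np.diag(np.diag(A_hat))


def _clustergcn_t(H: Tensor, A: np.ndarray, W1: Tensor, W2: Tensor,
                  lambda_diag: float) -> Tensor:
    M = _cluster_operator(A, lambda_diag)
    return (as_tensor(M) @ (H @ W1) + H @ W2).relu()


def _forward_t(H0: Tensor, A: np.ndarray, params: dict[str, Tensor],
               config: ModelConfig) -> Tensor:
    """Full network on tensors; returns per-class probabilities (n_classes,)."""
    H = H0
    for i in range(config.n_leconv):
        H = _leconv_t(H, A, params[f"leconv{i}_W1"], params[f"leconv{i}_W2"],
                      params[f"leconv{i}_W3"])
    for i in range(config.n_clustergcn):
        H = _clustergcn_t(H, A, params[f"cluster{i}_W1"],
                          params[f"cluster{i}_W2"], config.lambda_diag)
    L = A.shape[0]
    pool = as_tensor(np.full((1, L), 1.0 / L)) @ H      # global mean pooling
    h = (pool @ params["fc0_W"] + params["fc0_b"]).relu()
    h = (h @ params["fc1_W"] + params["fc1_b"]).relu()
    logits = h @ params["out_W"] + params["out_b"]
    return logits.sigmoid()[0]


def leconv_forward(H: np.ndarray, A: np.ndarray, W1: np.ndarray,
                   W2: np.ndarray, W3: np.ndarray) -> np.ndarray:
    """Single LEConv layer on plain arrays."""
    out = _leconv_t(as_tensor(H), np.asarray(A, dtype=float),
                    as_tensor(W1), as_tensor(W2), as_tensor(W3))
    return out.value


def clustergcn_forward(H: np.ndarray, A: np.ndarray, W1: np.ndarray,
                       W2: np.ndarray, lambda_diag: float = 1.0) -> np.ndarray:
    """Single ClusterGCNConv layer on plain arrays."""
    out = _clustergcn_t(as_tensor(H), np.asarray(A, dtype=float),
                        as_tensor(W1), as_tensor(W2), lambda_diag)
    return out.value


def model_forward(graph: ProteinGraph, params: dict[str, Tensor],
                  config: ModelConfig) -> np.ndarray:
    """Per-class probability vector for one graph."""
    H0 = graph.node_input
    if H0.shape[1] != config.input_dim:
        raise ValueError(f"graph input dim {H0.shape[1]} != config "
                         f"{config.input_dim}")
    return _forward_t(as_tensor(H0), graph.adjacency, params, config).value


def focal_loss(probs, targets, gamma: float = 2.0):
    """Focal loss, mean-reduced over all elements.

    Accepts plain arrays (returns a float) or a Tensor (returns a Tensor
    for backpropagation).  Probabilities are clamped to
    [PROB_EPS, 1 - PROB_EPS] so the logarithm stays finite.
    """
    y = np.asarray(targets, dtype=np.float64)
    is_tensor = isinstance(probs, Tensor)
    p = as_tensor(probs).clip(PROB_EPS, 1.0 - PROB_EPS)
    pt = p * y + (1.0 - p) * (1.0 - y)
    loss = ((1.0 - pt) ** gamma * pt.log() * -1.0).mean()
    return loss if is_tensor else float(loss.value)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(self.epochs).to_csv(path, sep="\t", index=False,
                                         float_format="%.10g")


def _dataset_loss_and_probs(graphs: list[ProteinGraph],
                            params: dict[str, Tensor], config: ModelConfig
                            ) -> tuple[float, np.ndarray]:
    losses, probs = [], []
    for g in graphs:
        p = model_forward(g, params, config)
        probs.append(p)
        losses.append(focal_loss(p, g.target, config.gamma))
    return float(np.mean(losses)), np.stack(probs)


def train_model(train: list[ProteinGraph], valid: list[ProteinGraph],
                config: ModelConfig,
                params: dict[str, Tensor] | None = None
                ) -> tuple[dict[str, Tensor], TrainingLog]:
    """Train with Adam on the focal loss; return the best checkpoint.

    Early stopping: training stops once none of {training loss,
    validation loss, validation micro-F1} has improved for
    ``config.patience`` consecutive epochs, or at ``max_epochs``.  The
    returned parameters are the snapshot with the highest validation
    micro-F1 (threshold 0.5).
    """
    if not train or not valid:
        raise ValueError("train and validation sets must be non-empty")
    if params is None:
        params = init_params(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(params, lr=config.lr)
    log = TrainingLog()
    targets_valid = np.stack([g.target for g in valid])

    best = {"train_loss": np.inf, "valid_loss": np.inf, "valid_f1": -np.inf}
    best_params: dict[str, np.ndarray] = {k: p.value.copy()
                                          for k, p in params.items()}
    stall = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            opt.zero_grad()
            loss = None
            for g in batch:
                probs = _forward_t(as_tensor(g.node_input), g.adjacency,
                                   params, config)
                lg = focal_loss(probs, g.target, config.gamma)
                loss = lg if loss is None else loss + lg
            loss = loss * (1.0 / len(batch))
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.value))
        train_loss = float(np.mean(batch_losses))
        valid_loss, valid_probs = _dataset_loss_and_probs(valid, params, config)
        valid_f1 = micro_classification_metrics(valid_probs,
                                                targets_valid)["f1"]
        log.append(epoch=epoch, train_loss=train_loss,
                   valid_loss=valid_loss, valid_f1=valid_f1)

        improved = False
        if train_loss < best["train_loss"]:
            best["train_loss"] = train_loss
            improved = True
        if valid_loss < best["valid_loss"]:
            best["valid_loss"] = valid_loss
            improved = True
        if valid_f1 > best["valid_f1"]:
            best["valid_f1"] = valid_f1
            best_params = {k: p.value.copy() for k, p in params.items()}
            improved = True
        stall = 0 if improved else stall + 1
        if stall >= config.patience:
            logger.info("early stop at epoch %d (no improvement for %d epochs)",
                        epoch, config.patience)
            break
    return ({k: Tensor(v, requires_grad=True) for k, v in best_params.items()},
            log)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, params: dict[str, Tensor],
                    config: ModelConfig, classes: list[str]) -> None:
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(config),
            "classes": classes}
    arrays = {k: p.value for k, p in params.items()}
    np.savez(Path(path), __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path
                    ) -> tuple[dict[str, Tensor], ModelConfig, list[str]]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = meta["config"]
        cfg["layer_dims"] = tuple(cfg["layer_dims"])
        cfg["fc_dims"] = tuple(cfg["fc_dims"])
        config = ModelConfig(**cfg)
        params = {k: Tensor(data[k], requires_grad=True)
                  for k in data.files if k != "__meta__"}
    return params, config, meta["classes"]


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------

class GraphEnzymeClassifier:
    """Multi-label enzyme-class classifier over residue graphs.

    scikit-learn-style estimator: constructor stores hyperparameters
    verbatim, :meth:`fit` learns and sets trailing-underscore
    attributes, :meth:`predict_proba` / :meth:`predict` score new
    graphs.  Inputs are :class:`~enzgraph.graphs.ProteinGraph` objects
    whose ``target`` vectors supply the labels (or pass ``y`` to
    ``fit`` explicitly).
    """

    _param_names = ("layer_dims", "n_leconv", "n_clustergcn", "lambda_diag",
                    "fc_dims", "gamma", "lr", "batch_size", "max_epochs",
                    "patience", "validation_fraction", "seed")

    def __init__(self, layer_dims=(256, 256, 256), n_leconv=2, n_clustergcn=1,
                 lambda_diag=1.0, fc_dims=(128, 64), gamma=2.0, lr=1e-4,
                 batch_size=20, max_epochs=500, patience=30,
                 validation_fraction=0.2, seed=0):
        self.layer_dims = layer_dims
        self.n_leconv = n_leconv
        self.n_clustergcn = n_clustergcn
        self.lambda_diag = lambda_diag
        self.fc_dims = fc_dims
        self.gamma = gamma
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- sklearn plumbing -----------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **kwargs) -> "GraphEnzymeClassifier":
        for key, value in kwargs.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- learning --------------------------------------------------------
    def fit(self, graphs: list[ProteinGraph], y: np.ndarray | None = None,
            valid_graphs: list[ProteinGraph] | None = None
            ) -> "GraphEnzymeClassifier":
        if not graphs:
            raise ValueError("no training graphs")
        if y is not None:
            graphs = [ProteinGraph(g.features, g.adjacency, g.embeddings,
                                   np.asarray(y[i], dtype=np.int8),
                                   g.chain_ref)
                      for i, g in enumerate(graphs)]
        if any(g.target is None for g in graphs):
            raise ValueError("training graphs need target vectors")
        n_classes = len(graphs[0].target)
        input_dim = graphs[0].node_input.shape[1]
        self.config_ = ModelConfig(
            input_dim=input_dim, n_classes=n_classes,
            layer_dims=tuple(self.layer_dims), n_leconv=self.n_leconv,
            n_clustergcn=self.n_clustergcn, lambda_diag=self.lambda_diag,
            fc_dims=tuple(self.fc_dims), gamma=self.gamma, lr=self.lr,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, seed=self.seed)
        if valid_graphs is None:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(graphs))
            n_valid = max(1, int(round(self.validation_fraction * len(graphs))))
            if n_valid >= len(graphs):
                raise ValueError("validation fraction leaves no training data")
            valid_graphs = [graphs[i] for i in order[:n_valid]]
            train_graphs = [graphs[i] for i in order[n_valid:]]
        else:
            train_graphs = list(graphs)
        self.params_, self.history_ = train_model(train_graphs, valid_graphs,
                                                  self.config_)
        self.n_classes_ = n_classes
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, graphs: list[ProteinGraph]) -> np.ndarray:
        self._check_fitted()
        return np.stack([model_forward(g, self.params_, self.config_)
                         for g in graphs])

    def predict(self, graphs: list[ProteinGraph],
                threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(graphs) >= threshold).astype(np.int8)

    def score(self, graphs: list[ProteinGraph],
              y: np.ndarray | None = None) -> float:
        """Micro-averaged F1 at threshold 0.5."""
        if y is None:
            y = np.stack([g.target for g in graphs])
        return micro_classification_metrics(self.predict_proba(graphs),
                                            np.asarray(y))["f1"]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path, classes: list[str] | None = None) -> None:
        self._check_fitted()
        save_checkpoint(path, self.params_, self.config_,
                        classes or [str(i) for i in range(self.n_classes_)])

    @classmethod
    def load(cls, path: str | Path
             ) -> tuple["GraphEnzymeClassifier", list[str]]:
        params, config, classes = load_checkpoint(path)
        est = cls(layer_dims=config.layer_dims, n_leconv=config.n_leconv,
                  n_clustergcn=config.n_clustergcn,
                  lambda_diag=config.lambda_diag, fc_dims=config.fc_dims,
                  gamma=config.gamma, lr=config.lr,
                  batch_size=config.batch_size, max_epochs=config.max_epochs,
                  patience=config.patience, seed=config.seed)
        est.params_ = params
        est.config_ = config
        est.n_classes_ = config.n_classes
        est.history_ = TrainingLog()
        return est, classes
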