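"""Single-task and hierarchical multi-task risk models.

The single-task model (STM) maps a user's text embedding through a stack of
fully connected layers to one sigmoid suicide-risk output.  The multi-task
model (MTM) adds three auxiliary subnetworks arranged along a theory-driven
mediation chain — personality traits, psychosocial risks, psychiatric
disorders — each a small FC stack with a linear regression head.  A shared
FC trunk is computed from the input; the personality subnetwork reads the
input directly, every later subnetwork reads the previous subnetwork's
output concatenated with the shared trunk, and the suicide head reads the
psychiatric output concatenated with the trunk.  Auxiliary supervision is
used only in training; prediction consumes embeddings alone.

Partial variants retain a single auxiliary subnetwork wired in the same
pattern (the retained middle/top subnetwork reads the raw input in place of
a predecessor's output).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .nn import Adam, MLPBlock, bce_with_logits, mse_loss, sigmoid

__all__ = [
    "VARIANTS", "AUX_DIMS", "ModelConfig", "build_stm", "build_mtm",
    "build_partial_model", "build_model", "composite_loss", "train",
    "predict", "TrainedModel", "save_model", "load_model",
]

AUX_DIMS = {"personality": 5, "psychosocial": 4, "psychiatric": 2}
_LAYER_ORDER = ("personality", "psychosocial", "psychiatric")
VARIANTS = ("stm", "mtm", "partial-personality", "partial-psychosocial",
            "partial-psychiatric")


@dataclasses.dataclass
class ModelConfig:
    variant: str = "mtm"
    task: str = "general"
    input_dim: int = 1024
    shared_layers: tuple[int, ...] = (256, 64)
    subnetwork_layers: tuple[int, ...] = (64,)
    dropout: float = 0.2
    loss_weights: dict = dataclasses.field(default_factory=lambda: {
        "personality": 1.0, "psychosocial": 1.0, "psychiatric": 1.0,
        "suicide": 1.0})
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    pos_weight: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.task not in ("general", "high"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.loss_weights.get("suicide", 0.0) <= 0.0:
            raise ValueError("suicide loss weight must be positive")
        if any(w <= 0 for w in self.shared_layers) or \
                any(w <= 0 for w in self.subnetwork_layers):
            raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def aux_layers(self) -> tuple[str, ...]:
        if self.variant == "stm":
            return ()
        if self.variant == "mtm":
            return _LAYER_ORDER
        return (self.variant.removeprefix("partial-"),)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shared_layers"] = list(self.shared_layers)
        d["subnetwork_layers"] = list(self.subnetwork_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["shared_layers"] = tuple(d["shared_layers"])
        d["subnetwork_layers"] = tuple(d["subnetwork_layers"])
        return cls(**d)


class RiskModel:
    """Forward/backward machinery shared by all variants."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        D = config.input_dim
        sub = list(config.subnetwork_layers)
        drop = config.dropout
        self.subnets: dict[str, MLPBlock] = {}
        if config.variant == "stm":
            self.shared = None
            self.head = MLPBlock(D, list(config.shared_layers), 1, self.rng,
                                 dropout=drop)
        else:
            s_dim = config.shared_layers[-1]
            self.shared = MLPBlock(D, list(config.shared_layers[:-1]), s_dim,
                                   self.rng, dropout=drop, relu_out=True)
            prev_dim = None
            for name in config.aux_layers:
                n_in = D if prev_dim is None and name == "personality" \
                    else (D if prev_dim is None else prev_dim) + s_dim
                self.subnets[name] = MLPBlock(n_in, sub, AUX_DIMS[name],
                                              self.rng, dropout=drop)
                prev_dim = AUX_DIMS[name]
            self.head = MLPBlock(prev_dim + s_dim, sub, 1, self.rng,
                                 dropout=drop)

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False) -> dict:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"embedding dimension {X.shape[1]} does not match model "
                f"input_dim {self.config.input_dim}")
        out: dict[str, np.ndarray] = {}
        if self.shared is None:
            out["logit"] = self.head.forward(X, train)
        else:
            s = self.shared.forward(X, train)
            self._input_kind: dict[str, str] = {}
            prev = None
            for name in self.config.aux_layers:
                if prev is None and name == "personality":
                    inp, kind = X, "input"
                elif prev is None:
                    inp, kind = np.concatenate([X, s], axis=1), "input+shared"
                else:
                    inp, kind = np.concatenate([prev, s], axis=1), \
                        "prev+shared"
                self._input_kind[name] = kind
                prev = self.subnets[name].forward(inp, train)
                out[name] = prev
            out["logit"] = self.head.forward(
                np.concatenate([prev, s], axis=1), train)
        out["suicide"] = sigmoid(out["logit"])
        return out

    # -- loss + gradients --------------------------------------------------
    def zero_grad(self) -> None:
        for block in self.blocks():
            block.zero_grad()

    def blocks(self) -> list[MLPBlock]:
        blocks = [] if self.shared is None else [self.shared]
        blocks += [self.subnets[n] for n in self.config.aux_layers]
        blocks.append(self.head)
        return blocks

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [pg for b in self.blocks() for pg in b.params()]

    def loss_and_backward(self, X: np.ndarray, y: np.ndarray,
                          aux_targets: dict | None = None,
                          train: bool = False) -> float:
        """Composite loss on a batch; accumulates parameter gradients."""
        cfg = self.config
        self.zero_grad()
        out = self.forward(X, train=train)
        w = cfg.loss_weights
        loss, g_logit = bce_with_logits(out["logit"], y,
                                        pos_weight=cfg.pos_weight)
        loss *= w["suicide"]
        g_logit = g_logit * w["suicide"]

        if self.shared is None:
            self.head.backward(g_logit)
            return loss

        s_dim = self.shared.layers[-1].W.shape[1]
        g_head_in = self.head.backward(g_logit)
        g_prev, g_s = g_head_in[:, :-s_dim], g_head_in[:, -s_dim:]
        for name in reversed(self.config.aux_layers):
            g_out = g_prev
            if aux_targets is not None and w.get(name, 0.0) > 0.0:
                aux_l, g_aux = mse_loss(out[name], aux_targets[name])
                loss += w[name] * aux_l
                g_out = g_out + w[name] * g_aux
            g_in = self.subnets[name].backward(g_out)
            kind = self._input_kind[name]
            if kind == "input":
                g_prev = None       # personality root: gradient stops at X
            else:
                g_s = g_s + g_in[:, -s_dim:]
                g_prev = None if kind == "input+shared" \
                    else g_in[:, :-s_dim]
        self.shared.backward(g_s)
        return loss


def build_stm(config: ModelConfig) -> RiskModel:
    if config.variant != "stm":
        raise ValueError("config.variant must be 'stm'")
    return RiskModel(config)


def build_mtm(config: ModelConfig) -> RiskModel:
    if config.variant != "mtm":
        raise ValueError("config.variant must be 'mtm'")
    return RiskModel(config)


def build_partial_model(config: ModelConfig) -> RiskModel:
    if not config.variant.startswith("partial-"):
        raise ValueError("config.variant must name a partial variant")
    return RiskModel(config)


def build_model(config: ModelConfig) -> RiskModel:
    return RiskModel(config)


def composite_loss(outputs: dict, targets: dict, loss_weights: dict
                   ) -> float:
    """Weighted BCE(suicide) + MSE(auxiliary layers); reference form used by
    training (the gradients live in the model) and by tests."""
    loss, _ = bce_with_logits(outputs["logit"], targets["suicide"])
    total = loss_weights["suicide"] * loss
    for name in _LAYER_ORDER:
        if name in outputs and name in targets \
                and loss_weights.get(name, 0.0) > 0.0:
            l, _ = mse_loss(outputs[name], targets[name])
            total += loss_weights[name] * l
    return total


@dataclasses.dataclass
class TrainedModel:
    model: RiskModel
    config: ModelConfig
    history: list[dict]
    best_epoch: int
    best_dev_auc: float

    def predict(self, X: np.ndarray) -> dict:
        return predict(self, X)


def _snapshot(model: RiskModel) -> list[np.ndarray]:
    return [p.copy() for p, _ in model.params()]


def _restore(model: RiskModel, snap: list[np.ndarray]) -> None:
    for (p, _), s in zip(model.params(), snap):
        p[:] = s


def train(model: RiskModel, X_train: np.ndarray, y_train: np.ndarray,
          X_dev: np.ndarray, y_dev: np.ndarray,
          aux_train: dict | None = None) -> TrainedModel:
    """Minibatch Adam with early stopping on dev AUC.

    Auxiliary targets (a dict of per-layer (n, k) arrays, standardized with
    training statistics) are consumed only when the variant has the matching
    subnetworks.  The best-dev-AUC parameter snapshot is restored before
    returning.  Fully reproducible for a fixed config seed.
    """
    cfg = model.config
    if cfg.aux_layers and aux_train is None:
        raise ValueError("this variant requires auxiliary training targets")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = len(X_train)
    opt = Adam([p for p, _ in model.params()], lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    history: list[dict] = []
    best_auc, best_epoch, best_snap = -np.inf, -1, _snapshot(model)
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            aux_b = None
            if aux_train is not None and cfg.aux_layers:
                aux_b = {k: v[idx] for k, v in aux_train.items()
                         if k in cfg.aux_layers}
            loss = model.loss_and_backward(X_train[idx], y_train[idx],
                                           aux_b, train=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.step([g for _, g in model.params()])
            epoch_loss += loss * len(idx)
        dev_scores = model.forward(X_dev, train=False)["suicide"].ravel()
        dev_auc = float(roc_auc_score(y_dev, dev_scores))
        history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                        "dev_auc": dev_auc})
        if dev_auc > best_auc:
            best_auc, best_epoch, best_snap = dev_auc, epoch, _snapshot(model)
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    _restore(model, best_snap)
    return TrainedModel(model=model, config=cfg, history=history,
                        best_epoch=best_epoch, best_dev_auc=best_auc)


def predict(trained: TrainedModel | RiskModel, X: np.ndarray) -> dict:
    """Per-task outputs from embeddings alone: 'suicide' probabilities in
    (0, 1) plus a prediction array per retained auxiliary layer."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    out = model.forward(np.asarray(X, dtype=float), train=False)
    return {k: v for k, v in out.items() if k != "logit"} | {
        "logit": out["logit"]}


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(trained: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(trained.model.params())}
    meta = json.dumps({"format": "textrisk-checkpoint-v1",
                       "config": trained.config.to_dict(),
                       "best_epoch": trained.best_epoch,
                       "best_dev_auc": trained.best_dev_auc,
                       "history": trained.history})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        config = ModelConfig.from_dict(meta["config"])
        model = RiskModel(config)
        for i, (p, _) in enumerate(model.params()):
            p[:] = data[f"p{i}"]
    return TrainedModel(model=model, config=config, history=meta["history"],
                        best_epoch=meta["best_epoch"],
                        best_dev_auc=meta["best_dev_auc"])
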