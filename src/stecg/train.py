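"""Training harness: focal loss, SMOTE balancing, RAdam with schedulers,
early stopping, and prediction.

Class imbalance is the central difficulty of arrhythmia classification —
normal beats outnumber fusion beats by orders of magnitude — and is attacked
from two sides: SMOTE oversamples minority classes in feature space by
convex interpolation between same-class nearest neighbours, and focal loss
down-weights well-classified examples by the factor (1 − p)^γ so rare, hard
classes dominate the gradient.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from . import nn
from .nn import Tensor

__all__ = ["TrainConfig", "History", "focal_loss", "smote_oversample",
           "fit", "predict", "stratified_split"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 3e-4
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 15
    scheduler: str = "cosine_warm_restarts"  # or "exponential" / "none"
    focal_gamma: float = 2.0
    focal_alpha: np.ndarray | None = None    # per-class weights; None = uniform
    smote_enabled: bool = True
    smote_k: int = 5
    seed: int = 0
    mixed_precision: bool = False            # reserved; float32 throughout

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""


def focal_loss(logits, targets, gamma: float = 2.0, alpha=None) -> Tensor:
    """Mean focal loss  −α_y (1 − p_y)^γ log p_y  with p = softmax(logits).

    ``logits`` may be a numpy array or an autograd Tensor (for training).
    γ = 0 with uniform α reduces exactly to cross-entropy.  Probabilities are
    clamped at 1e-12 so the loss stays finite for any finite logits.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=float))
    targets = np.asarray(targets)
    K = logits.shape[-1]
    if targets.min() < 0 or targets.max() >= K:
        raise ValueError("target index outside [0, n_classes)")
    logp = nn.log_softmax(logits, axis=-1)
    logp_y = nn.gather_rows(logp, targets).clip_min(float(np.log(1e-12)))
    p_y = logp_y.exp()
    mod = (1.0 - p_y) ** gamma if gamma != 0 else 1.0
    if alpha is not None:
        alpha = np.asarray(alpha, dtype=float)
        a_y = Tensor(alpha[targets] if alpha.ndim else np.full(targets.shape, alpha))
        term = a_y * mod * logp_y if gamma != 0 else a_y * logp_y
    else:
        term = mod * logp_y
    return -(term.mean())


def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: equalise every class count to the majority count.

    Each synthetic row is  x_i + u (x_nn − x_i)  with u ~ Uniform(0, 1) and
    x_nn one of x_i's k nearest same-class neighbours (Euclidean).  Original
    rows are returned unchanged and first, in their input order.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("SMOTE expects a 2-D feature matrix")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = n_max - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has a single member; SMOTE needs >= 2 "
                "(duplicate the row or drop the class instead)")
        Xc = X[y == cls]
        kk = min(k, cnt - 1)
        nbrs = NearestNeighbors(n_neighbors=kk + 1).fit(Xc)
        _, idx = nbrs.kneighbors(Xc)      # idx[:, 0] is the point itself
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(1, kk + 1, size=need)
        u = rng.random(need)
        neigh = idx[base, pick]
        synth = Xc[base] + u[:, None] * (Xc[neigh] - Xc[base])
        new_X.append(synth.astype(X.dtype))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    if len(new_X) == 1:
        return X.copy(), y.copy()
    return np.concatenate(new_X), np.concatenate(new_y)


def stratified_split(y: np.ndarray, frac: float, seed: int = 0):
    """Index split with per-class proportions preserved; returns
    (idx_a, idx_b) with ~``frac`` of every class in ``idx_a``."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    a, b = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        cut = int(round(frac * idx.size))
        a.append(idx[:cut])
        b.append(idx[cut:])
    return np.sort(np.concatenate(a)), np.sort(np.concatenate(b))


def _epoch_eval(model, X, y, config, batch_size) -> tuple[float, float]:
    model.eval()
    losses, hits, n = [], 0, len(y)
    with nn.no_grad():
        for s in range(0, n, batch_size):
            xb = X[s:s + batch_size]
            yb = y[s:s + batch_size]
            logits = model(Tensor(xb))
            loss = focal_loss(logits, yb, config.focal_gamma, config.focal_alpha)
            losses.append(float(loss.data) * len(yb))
            hits += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / n, hits / n


def fit(model, train_data, val_data, config: TrainConfig = TrainConfig()):
    """Train with RAdam + scheduler and loss-based early stopping.

    ``train_data``/``val_data`` are ``(X, y)`` pairs of numpy arrays (inputs
    on the model's expected [B, C, H, W] layout).  Stops when the validation
    loss has not improved for ``patience`` epochs or at ``max_epochs``;
    restores and returns the best-validation-loss weights.
    """
    X_tr, y_tr = train_data
    X_va, y_va = val_data
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("empty training or validation split")
    X_tr = np.asarray(X_tr, dtype=np.float32)
    X_va = np.asarray(X_va, dtype=np.float32)
    y_tr = np.asarray(y_tr)
    y_va = np.asarray(y_va)

    rng = np.random.default_rng(config.seed)
    model.seed_rng(int(rng.integers(0, 2 ** 31 - 1)))
    opt = nn.RAdam(model.parameters(), lr=config.lr)
    sched = nn.make_scheduler(config.scheduler, opt)

    history = History()
    best_loss = np.inf
    best_state = None
    since_best = 0

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(y_tr))
        ep_loss, hits = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            sel = order[s:s + config.batch_size]
            xb, yb = X_tr[sel], y_tr[sel]
            opt.zero_grad()
            logits = model(Tensor(xb))
            loss = focal_loss(logits, yb, config.focal_gamma, config.focal_alpha)
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(sel)
            hits += int((logits.data.argmax(axis=1) == yb).sum())
        if sched is not None:
            sched.step()

        va_loss, va_acc = _epoch_eval(model, X_va, y_va, config,
                                      config.batch_size)
        history.train_loss.append(ep_loss / len(y_tr))
        history.train_acc.append(hits / len(y_tr))
        history.val_loss.append(va_loss)
        history.val_acc.append(va_acc)

        if va_loss < best_loss:
            best_loss = va_loss
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stop_reason = f"early stop (patience={config.patience})"
                break
    else:
        history.stop_reason = "max_epochs reached"

    if best_state is not None:
        model.load_state_dict(best_state)
    return best_state, history


def predict(model, X, batch_size: int = 64) -> np.ndarray:
    """Argmax class per sample (eval mode; ties go to the lower index)."""
    model.eval()
    X = np.asarray(X, dtype=np.float32)
    out = []
    with nn.no_grad():
        for s in range(0, len(X), batch_size):
            logits = model(Tensor(X[s:s + batch_size]))
            out.append(logits.data.argmax(axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)
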