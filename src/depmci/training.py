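"""Loss, AdamW, training loop, metrics, grid tuning, baselines, heatmap.

The optimizer follows the decoupled-weight-decay update

    m_t = b1 m_{t-1} + (1-b1) g_t          v_t = b2 v_{t-1} + (1-b2) g_t^2
    m^_t = m_t / (1 - b1^t)                v^_t = v_t / (1 - b2^t)
    theta_t = theta_{t-1} - alpha * m^_t / (sqrt(v^_t) + eps) - lambda * theta_{t-1}

with defaults alpha=3e-4, b1=0.9, b2=0.999, lambda=0.01, eps=1e-8.  Note the
decay term is applied as written, without the learning-rate multiplier.

Training uses mean-reduced binary cross-entropy so that gradient accumulation
over k equal mini-batches is exactly one step on their union; the sum-form
loss is available for reporting.  Early stopping monitors a validation metric
and restores the best checkpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import ModelConfig, init_params, forward_predict
from .pipeline import WindowSample

__all__ = [
    "OptimizerState",
    "AdamW",
    "TrainConfig",
    "MetricsReport",
    "bce_loss",
    "adamw_step",
    "compute_gradients",
    "train",
    "predict",
    "compute_metrics",
    "roc_curve_points",
    "tune_grid",
    "run_baselines",
    "export_attention_heatmap",
    "samples_to_arrays",
]

_CLAMP_EPS = 1e-12


def samples_to_arrays(samples: list[WindowSample]):
    X = np.stack([s.features for s in samples]).astype(np.float64)
    y = np.array([s.label for s in samples], dtype=np.float64)
    return X, y


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(y, p, reduction: str = "sum"):
    """Binary cross-entropy; probabilities clamped to [eps, 1-eps].

    ``reduction='sum'`` is the textbook form
    -sum_i [y_i log p_i + (1-y_i) log(1-p_i)]; ``'mean'`` divides by N and is
    what the trainer optimizes (it makes accumulation equivalence exact).
    Accepts numpy arrays or autodiff tensors.
    """
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    if isinstance(p, Tensor):
        y = Tensor.as_tensor(np.asarray(y, dtype=float))
        pc = _clamp_tensor(p)
        terms = y * pc.log() + (1.0 - y) * (1.0 - pc).log()
        total = -terms.sum()
        return total * (1.0 / p.data.size) if reduction == "mean" else total
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    vals = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(vals.mean()) if reduction == "mean" else float(vals.sum())


def _clamp_tensor(p: Tensor) -> Tensor:
    lo, hi = _CLAMP_EPS, 1.0 - _CLAMP_EPS
    clipped = np.clip(p.data, lo, hi)
    out = Tensor(clipped, _parents=(p,))
    inside = (p.data > lo) & (p.data < hi)
    out._backward = lambda g: p._accum(g * inside)
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

@dataclass
class OptimizerState:
    """Moment estimates and hyperparameters for one parameter array."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    lr: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    eps: float = 1e-8

    @classmethod
    def zeros_like(cls, theta: np.ndarray, **hyper) -> "OptimizerState":
        return cls(m=np.zeros_like(theta), v=np.zeros_like(theta), **hyper)


def adamw_step(theta: np.ndarray, grad: np.ndarray, state: OptimizerState) -> np.ndarray:
    """One update; increments ``state.t`` before bias correction."""
    if theta.shape != grad.shape:
        raise ValueError(f"gradient shape {grad.shape} != parameter shape {theta.shape}")
    state.t += 1
    state.m = state.beta1 * state.m + (1.0 - state.beta1) * grad
    state.v = state.beta2 * state.v + (1.0 - state.beta2) * grad**2
    m_hat = state.m / (1.0 - state.beta1**state.t)
    v_hat = state.v / (1.0 - state.beta2**state.t)
    return (theta
            - state.lr * m_hat / (np.sqrt(v_hat) + state.eps)
            - state.weight_decay * theta)


class AdamW:
    """Dict-of-parameters wrapper around :func:`adamw_step`."""

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 weight_decay: float = 0.01, eps: float = 1e-8):
        self.params = params
        self.state = {
            name: OptimizerState.zeros_like(
                p.data, lr=lr, beta1=beta1, beta2=beta2,
                weight_decay=weight_decay, eps=eps)
            for name, p in params.items()
        }

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            p.data = adamw_step(p.data, grads[name], self.state[name])


# ---------------------------------------------------------------------------
# gradients / training
# ---------------------------------------------------------------------------

def compute_gradients(params: dict[str, Tensor], config: ModelConfig,
                      X: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator | None = None):
    """Mean-reduced BCE gradients for one mini-batch; returns (grads, loss)."""
    probs = forward_predict(params, config, X, rng=rng)
    loss = bce_loss(y, probs, reduction="mean")
    loss.backward()
    grads = {name: p.grad.copy() for name, p in params.items()}
    return grads, float(loss.data)


def predict(params: dict[str, Tensor], config: ModelConfig, X: np.ndarray) -> np.ndarray:
    """Deterministic (dropout-free) risk probabilities."""
    return forward_predict(params, config, X).data


@dataclass
class TrainConfig:
    batch_size: int = 32
    accumulation: int = 4
    max_epochs: int = 40
    patience: int = 5
    monitor: str = "auc"  # 'auc', 'f1' or 'loss'
    seed: int = 0
    lr: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    eps: float = 1e-8

    def __post_init__(self):
        if self.accumulation < 1:
            raise ValueError("accumulation must be >= 1")


@dataclass
class TrainResult:
    params: dict
    config: ModelConfig
    history: list = field(default_factory=list)
    best_epoch: int = -1


def _monitor_value(monitor, y_val, p_val):
    if monitor == "loss":
        return -bce_loss(y_val, p_val, reduction="mean")
    rep = compute_metrics(y_val, p_val)
    value = getattr(rep, monitor)
    return -np.inf if value is None else value


def train(model_config: ModelConfig, splits, train_config: TrainConfig) -> TrainResult:
    """Fit the transformer with AdamW, gradient accumulation and early stopping.

    ``splits`` is the (train, validation, test) triple of window samples from
    :func:`depmci.pipeline.split_dataset` (test is unused here).  Gradients of
    ``accumulation`` consecutive mini-batches are averaged per optimizer step.
    Fully seeded: shuffling, initialization and dropout all derive from
    ``train_config.seed``.
    """
    tr, va = splits[0], splits[1]
    X_tr, y_tr = samples_to_arrays(tr)
    X_va, y_va = samples_to_arrays(va)
    if len(np.unique(y_va)) < 2:
        raise ValueError("validation split lacks a class; cannot monitor")

    params = init_params(model_config, seed=train_config.seed)
    opt = AdamW(params, lr=train_config.lr, beta1=train_config.beta1,
                beta2=train_config.beta2, weight_decay=train_config.weight_decay,
                eps=train_config.eps)
    shuffle_rng = np.random.default_rng(train_config.seed)
    dropout_rng = np.random.default_rng(train_config.seed + 1)

    best_score, best_params, best_epoch = -np.inf, None, -1
    stale = 0
    history = []
    n = len(y_tr)
    for epoch in range(train_config.max_epochs):
        perm = shuffle_rng.permutation(n)
        batches = [perm[i:i + train_config.batch_size]
                   for i in range(0, n, train_config.batch_size)]
        accum, losses = [], []
        for bi, idx in enumerate(batches):
            grads, loss = compute_gradients(params, model_config,
                                            X_tr[idx], y_tr[idx], rng=dropout_rng)
            accum.append(grads)
            losses.append(loss)
            if len(accum) == train_config.accumulation or bi == len(batches) - 1:
                mean_grads = {
                    k: np.mean([g[k] for g in accum], axis=0) for k in grads
                }
                opt.step(mean_grads)
                accum = []
        p_va = predict(params, model_config, X_va)
        score = _monitor_value(train_config.monitor, y_va, p_va)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            f"val_{train_config.monitor}": float(score if train_config.monitor != 'loss' else -score),
        })
        if score > best_score:
            best_score, best_epoch, stale = score, epoch, 0
            best_params = {k: Tensor(p.data.copy(), requires_grad=True)
                           for k, p in params.items()}
        else:
            stale += 1
            if stale > train_config.patience:
                break
    return TrainResult(params=best_params, config=model_config,
                       history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    specificity: float | None
    f1: float | None
    auc: float | None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def roc_curve_points(labels: np.ndarray, scores: np.ndarray):
    """(fpr, tpr) points at every distinct score threshold, ends included."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    labels, scores = labels[order], scores[order]
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    tps = np.cumsum(labels)
    fps = np.cumsum(1 - labels)
    distinct = np.r_[np.flatnonzero(np.diff(scores)), len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``threshold`` plus trapezoidal-ROC AUC.

    Raises on single-class label vectors (AUC undefined); a metric with a
    zero denominator is reported as ``None`` with the reason in ``notes``.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must align")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    notes: dict = {}

    def ratio(num, den, name):
        if den == 0:
            notes[name] = "undefined: zero denominator"
            return None
        return num / den

    accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    precision = ratio(tp, tp + fp, "precision")
    specificity = ratio(tn, tn + fp, "specificity")
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        notes["f1"] = "undefined: precision + sensitivity is zero"
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    fpr, tpr = roc_curve_points(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                         sensitivity=sensitivity, precision=precision,
                         specificity=specificity, f1=f1, auc=auc, notes=notes)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def tune_grid(grid: dict, model_config: ModelConfig, splits,
              base: TrainConfig | None = None):
    """Exhaustive grid search over lr / weight_decay / batch_size.

    Every grid cell is trained on the train split and scored on validation;
    the best cell is chosen by validation AUC, ties broken by F1 then by the
    smaller learning rate.  Returns ``(best_config_dict, records)`` where
    ``records`` is the full evaluation table.
    """
    base = base or TrainConfig()
    lrs = grid.get("lr", [base.lr])
    wds = grid.get("weight_decay", [base.weight_decay])
    bss = grid.get("batch_size", [base.batch_size])
    cells = sorted({(float(a), float(b), int(c))
                    for a in lrs for b in wds for c in bss})
    if not cells:
        raise ValueError("empty hyperparameter grid")
    X_va, y_va = samples_to_arrays(splits[1])
    records = []
    for lr, wd, bs in cells:
        cfg = TrainConfig(**{**asdict(base), "lr": lr, "weight_decay": wd,
                             "batch_size": bs})
        result = train(model_config, splits, cfg)
        rep = compute_metrics(y_va, predict(result.params, model_config, X_va))
        records.append({"lr": lr, "weight_decay": wd, "batch_size": bs,
                        "val_auc": rep.auc, "val_f1": rep.f1 or 0.0})
    best = max(records, key=lambda r: (r["val_auc"], r["val_f1"], -r["lr"]))
    return {k: best[k] for k in ("lr", "weight_decay", "batch_size")}, records


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def run_baselines(splits, seed: int = 0) -> dict:
    """XGBoost and RBF-SVM on flattened window features, same splits/metrics.

    Windows are flattened to fixed-length vectors (wave features
    concatenated); each model reports train- and test-set metrics computed by
    :func:`compute_metrics`.
    """
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    tr, _, te = splits
    X_tr, y_tr = samples_to_arrays(tr)
    X_te, y_te = samples_to_arrays(te)
    X_tr = X_tr.reshape(len(X_tr), -1)
    X_te = X_te.reshape(len(X_te), -1)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("degenerate split: a baseline split lacks a class")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        models = {
            "xgboost": XGBClassifier(
                n_estimators=200, max_depth=3, learning_rate=0.1,
                subsample=0.9, random_state=seed, n_jobs=1,
                eval_metric="logloss",
            ),
            "svm": SVC(kernel="rbf", probability=True, random_state=seed),
        }
    out = {}
    for name, clf in models.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X_tr, y_tr)
        out[name] = {
            "train": compute_metrics(y_tr, clf.predict_proba(X_tr)[:, 1]),
            "test": compute_metrics(y_te, clf.predict_proba(X_te)[:, 1]),
        }
    return out


# ---------------------------------------------------------------------------
# interpretability
# ---------------------------------------------------------------------------

def export_attention_heatmap(params: dict, config: ModelConfig,
                             samples, feature_names: list[str],
                             out_csv=None, out_png=None,
                             trained: bool = True) -> pd.DataFrame:
    """Feature x embedding-dimension attribution matrix.

    Attribution A[f, d] = |W_in[f, d]| * s_f, where s_f averages, over
    samples, the attention mass received by each wave position (all blocks,
    heads and queries pooled) times the magnitude of feature f at that
    position.  This is a constructive interpretation of an attention heatmap
    over the input projection: a zero projection yields an all-zero matrix,
    and rows follow ``feature_names`` (the retained-feature manifest).
    """
    if not trained:
        warnings.warn("exporting a heatmap from an untrained checkpoint",
                      stacklevel=2)
    if isinstance(samples, list):
        X, _ = samples_to_arrays(samples)
    else:
        X = np.asarray(samples, dtype=float)
    collected: list = []
    forward_predict(params, config, X, collect_attention=collected)
    L = X.shape[1]
    mass = np.zeros(L)
    total = 0
    for w in collected:  # (B, H, Lq, Lk) with Lk == L
        mass += w.mean(axis=(0, 1, 2))
        total += 1
    mass /= max(total, 1)
    # s_f: attention-mass-weighted mean |feature value| per feature
    s = np.einsum("blf,l->f", np.abs(X), mass) / len(X)
    W = np.abs(params["input_proj.W"].data)  # (F, d_model)
    A = W * s[:, None]
    df = pd.DataFrame(A, index=feature_names,
                      columns=[f"dim_{j}" for j in range(config.d_model)])
    if out_csv is not None:
        df.to_csv(out_csv)
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, max(3, 0.25 * len(feature_names))))
        im = ax.imshow(A, aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(feature_names)), feature_names, fontsize=6)
        ax.set_xlabel("embedding dimension")
        ax.set_ylabel("feature")
        fig.colorbar(im, ax=ax, label="attention-weighted |projection|")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return df
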