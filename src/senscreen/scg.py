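"""Two-output multilayer perceptron trained by scaled conjugate gradient.

The classifier mirrors the screening design: one hidden layer (tanh) and
two logistic output neurons, one scoring "active" and one "inactive", so
asymmetric cutoffs can later be applied to each output independently.

Training minimizes E(w) = 1/2 * sum of squared output errors. The scaled
conjugate gradient (SCG) method estimates curvature along each conjugate
direction by a finite-difference gradient perturbation and regularizes it
with a Levenberg-Marquardt-style scale parameter, avoiding explicit line
searches. Accepted steps never increase the training error; reported
history entries are MSE normalized per compound and output, so the
per-compound pruning threshold lives on [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("senscreen")


@dataclass
class MLPParams:
    n_inputs: int
    hidden_layers: list[int] = field(default_factory=lambda: [20])
    n_outputs: int = 2
    max_epochs: int = 300
    grad_tol: float = 1e-6
    seed: int = 0
    trainer: str = "scg"  # "scg" or "gd" (plain gradient-descent comparator)
    learning_rate: float = 0.05  # gd only
    plateau_window: int = 30  # stop a run when this many iterations stall
    restarts: bool = True  # multi-start within the epoch budget (fit only)
    weight_decay: float = 0.0  # L2 coefficient on the weights, added to E

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or any(h < 1 for h in self.hidden_layers):
            raise ValueError("all layer sizes must be >= 1")
        if self.n_outputs != 2:
            raise ValueError("the classifier has exactly 2 output neurons")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.n_inputs, *self.hidden_layers, self.n_outputs]


@dataclass
class MLPModel:
    weights: list[np.ndarray]  # per layer, shape (fan_in, fan_out)
    biases: list[np.ndarray]  # per layer, shape (fan_out,)
    params: MLPParams
    training_history: list[float] = field(default_factory=list)

    @property
    def n_weights(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layer_sizes": self.params.layer_sizes,
            "seed": self.params.seed,
            "trainer": self.params.trainer,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "training_history": self.training_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        payload = json.loads(Path(path).read_text())
        sizes = payload["layer_sizes"]
        params = MLPParams(
            n_inputs=sizes[0],
            hidden_layers=sizes[1:-1],
            seed=payload.get("seed", 0),
            trainer=payload.get("trainer", "scg"),
        )
        return cls(
            weights=[np.array(w) for w in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
            params=params,
            training_history=list(payload.get("training_history", [])),
        )


@dataclass
class CVReport:
    fold_of: np.ndarray  # fold index per row
    fold_confusions: list  # list of ensemble.ConfusionMatrix
    accuracy: float
    kappa: float
    per_compound_mse: np.ndarray
    row_ids: list[str] | None = None


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_mlp(params: MLPParams) -> MLPModel:
    """Symmetric uniform initialization scaled by 1/sqrt(fan_in)."""
    rng = np.random.default_rng(params.seed)
    weights, biases = [], []
    sizes = params.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return MLPModel(weights=weights, biases=biases, params=params)


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Network outputs, shape (n, 2); column 0 = active, 1 = inactive."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.params.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.params.n_inputs}"
        )
    a = X
    last = len(model.weights) - 1
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        a = _logistic(z) if i == last else np.tanh(z)
    return a


# ---------------------------------------------------------------------------
# Flat-vector plumbing for the SCG loop


def _get_flat(model: MLPModel) -> np.ndarray:
    return np.concatenate([w.ravel() for w in model.weights] + [b for b in model.biases])


def _set_flat(model: MLPModel, flat: np.ndarray) -> None:
    i = 0
    for w in model.weights:
        w[...] = flat[i : i + w.size].reshape(w.shape)
        i += w.size
    for b in model.biases:
        b[...] = flat[i : i + b.size]
        i += b.size


def _loss_and_grad(
    model: MLPModel, X: np.ndarray, Y: np.ndarray
) -> tuple[float, np.ndarray]:
    """E = 1/2 sum (out - target)^2 [+ 1/2 wd ||w||^2] and its gradient."""
    activations = [X]
    zs = []
    a = X
    last = len(model.weights) - 1
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        zs.append(z)
        a = _logistic(z) if i == last else np.tanh(z)
        activations.append(a)
    out = activations[-1]
    err = out - Y
    loss = 0.5 * float(np.sum(err**2))
    grads_w = [np.empty_like(w) for w in model.weights]
    grads_b = [np.empty_like(b) for b in model.biases]
    delta = err * out * (1.0 - out)  # logistic derivative
    for i in range(last, -1, -1):
        grads_w[i] = activations[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (1.0 - activations[i] ** 2)
    flat = np.concatenate([g.ravel() for g in grads_w] + [g for g in grads_b])
    wd = model.params.weight_decay
    if wd:
        w = _get_flat(model)
        loss += 0.5 * wd * float(w @ w)
        flat = flat + wd * w
    return loss, flat


def loss_and_grad(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Public wrapper (flat gradient in the model's weight ordering)."""
    return _loss_and_grad(model, np.asarray(X, float), np.asarray(Y, float))


def normalized_mse(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> float:
    out = forward(model, X)
    return float(np.mean((out - Y) ** 2))


# ---------------------------------------------------------------------------
# Scaled conjugate gradient

SCG_SIGMA = 1e-5
SCG_LAMBDA_INIT = 1e-6
SCG_DELTA_LO = 0.25  # raise lambda below this comparison value
SCG_DELTA_HI = 0.75  # reduce lambda above it


def train_scg(
    model: MLPModel, X: np.ndarray, Y: np.ndarray, params: MLPParams | None = None
) -> tuple[MLPModel, list[float]]:
    """Train in place by scaled conjugate gradient; returns (model, history).

    One epoch is one SCG iteration (two full-batch gradient evaluations at
    most). The conjugate direction is restarted to steepest descent every W
    iterations, W = number of weights. History records the normalized
    training MSE after every iteration, starting with the initial value.
    """
    params = params or model.params
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    n_out = Y.shape[1]
    W_count = model.n_weights

    w = _get_flat(model)
    E, grad = _loss_and_grad(model, X, Y)
    r = -grad
    p = r.copy()
    lam = SCG_LAMBDA_INIT
    lam_bar = 0.0
    success = True
    delta_k = 0.0
    history = [2.0 * E / (n * n_out)]

    for k in range(1, params.max_epochs + 1):
        norm_p2 = float(p @ p)
        norm_p = np.sqrt(norm_p2)
        if norm_p < 1e-300:
            break
        if success:
            sigma_k = SCG_SIGMA / norm_p
            _set_flat(model, w + sigma_k * p)
            _, grad_plus = _loss_and_grad(model, X, Y)
            s = (grad_plus - grad) / sigma_k
            delta_k = float(p @ s)
        # scale curvature for positive definiteness
        delta_scaled = delta_k + (lam - lam_bar) * norm_p2
        if delta_scaled <= 0:
            lam_bar = 2.0 * (lam - delta_scaled / norm_p2)
            delta_scaled = -delta_scaled + lam * norm_p2
            lam = lam_bar
        mu = float(p @ r)
        if mu <= 0:  # direction lost descent property: restart
            p = r.copy()
            success = True
            history.append(2.0 * E / (n * n_out))
            continue
        alpha = mu / delta_scaled
        _set_flat(model, w + alpha * p)
        E_new, grad_new = _loss_and_grad(model, X, Y)
        if not np.isfinite(E_new):
            raise FloatingPointError("non-finite training loss; aborting SCG")
        Delta = 2.0 * delta_scaled * (E - E_new) / (mu * mu) if mu != 0 else 0.0
        if Delta >= 0:  # accept: error did not increase
            w = w + alpha * p
            E = E_new
            r_new = -grad_new
            grad = grad_new
            lam_bar = 0.0
            success = True
            if k % W_count == 0:
                p = r_new.copy()  # periodic restart to steepest descent
            else:
                beta = float((r_new @ r_new) - (r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= SCG_DELTA_HI:
                lam *= 0.25
        else:  # reject the step
            _set_flat(model, w)
            lam_bar = lam
            success = False
        if Delta < SCG_DELTA_LO:
            lam += delta_scaled * (1.0 - Delta) / norm_p2
        lam = min(lam, 1e100)
        history.append(2.0 * E / (n * n_out))
        if np.linalg.norm(r) < params.grad_tol:
            break
        # plateau: no meaningful error decrease over the trailing window
        win = params.plateau_window
        if win and len(history) > win:
            then, now = history[-win - 1], history[-1]
            if then - now <= 1e-9 * max(then, 1e-30):
                break

    _set_flat(model, w)
    model.training_history = history
    return model, history


def train_gd(
    model: MLPModel, X: np.ndarray, Y: np.ndarray, params: MLPParams | None = None
) -> tuple[MLPModel, list[float]]:
    """Plain full-batch gradient descent, the scan's baseline learning rule."""
    params = params or model.params
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, n_out = X.shape[0], Y.shape[1]
    lr = params.learning_rate / n
    w = _get_flat(model)
    E, grad = _loss_and_grad(model, X, Y)
    history = [2.0 * E / (n * n_out)]
    for _ in range(params.max_epochs):
        w = w - lr * grad
        _set_flat(model, w)
        E, grad = _loss_and_grad(model, X, Y)
        if not np.isfinite(E):
            raise FloatingPointError("non-finite training loss; aborting GD")
        history.append(2.0 * E / (n * n_out))
        if np.linalg.norm(grad) < params.grad_tol:
            break
    model.training_history = history
    return model, history


TRAINERS: dict[str, Callable] = {"scg": train_scg, "gd": train_gd}


def fit(X: np.ndarray, Y: np.ndarray, params: MLPParams) -> MLPModel:
    """Initialize and train a network with the configured learning rule.

    When a run converges or stalls before the epoch budget is spent and
    ``restarts`` is on, remaining epochs go to fresh seeded
    initializations (multi-start); the best weights over all starts are
    returned. Small nets escape poor local minima this way; runs that use
    their full budget behave exactly like a single training run.
    """
    import dataclasses

    budget = params.max_epochs
    best_model: MLPModel | None = None
    best_err = np.inf
    attempt = 0
    while budget > 0:
        attempt_params = dataclasses.replace(
            params, seed=params.seed + 90001 * attempt, max_epochs=budget
        )
        model = init_mlp(attempt_params)
        _, history = TRAINERS[params.trainer](model, X, Y, attempt_params)
        if history[-1] < best_err:
            best_err = history[-1]
            best_model = model
        budget -= max(len(history) - 1, 1)
        attempt += 1
        if not params.restarts:
            break
    assert best_model is not None
    return best_model


# ---------------------------------------------------------------------------
# Cross-validation and pruning


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold index per row; each class dealt round-robin after a shuffle."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        rng.shuffle(idx)
        for j, row in enumerate(idx):
            fold_of[row] = (j + offset) % k
        offset += len(idx) % k  # stagger so small classes spread evenly
    return fold_of


def kfold_cv(
    X: np.ndarray,
    Y: np.ndarray,
    params: MLPParams,
    k: int = 10,
    seed: int = 0,
    row_ids: Sequence[str] | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation.

    Every compound is validated exactly once; its squared prediction error
    (mean over the two outputs) from that single validation prediction is
    the per-compound MSE used by pruning.
    """
    from .ensemble import confusion  # deferred: ensemble imports this module

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and at least k rows")
    labels = (Y[:, 0] >= Y[:, 1]).astype(int)  # 1 = active
    fold_of = stratified_folds(labels, k, seed)
    per_mse = np.empty(n)
    preds = np.empty(n, dtype=int)
    fold_confusions = []
    for fold in range(k):
        val = fold_of == fold
        train = ~val
        if len(np.unique(labels[train])) < 2:
            raise ValueError(f"fold {fold}: training split has a single class")
        import dataclasses

        fold_params = dataclasses.replace(params, seed=params.seed + fold)
        model = fit(X[train], Y[train], fold_params)
        out = forward(model, X[val])
        per_mse[val] = np.mean((out - Y[val]) ** 2, axis=1)
        fold_pred = (out[:, 0] >= out[:, 1]).astype(int)
        preds[val] = fold_pred
        fold_confusions.append(confusion(fold_pred, labels[val]))
    total = confusion(preds, labels)
    return CVReport(
        fold_of=fold_of,
        fold_confusions=fold_confusions,
        accuracy=total.accuracy,
        kappa=total.kappa,
        per_compound_mse=per_mse,
        row_ids=list(row_ids) if row_ids is not None else None,
    )


def prune_by_mse(cv_report: CVReport, threshold: float = 0.4) -> np.ndarray:
    """Indices of compounds whose cross-validated MSE is <= threshold.

    Compounds above the threshold were consistently misclassified and are
    treated as label noise.
    """
    retained = np.where(cv_report.per_compound_mse <= threshold)[0]
    logger.info(
        "MSE pruning at %.2f: retained %d / %d compounds",
        threshold, len(retained), len(cv_report.per_compound_mse),
    )
    return retained


def parameter_scan(
    X: np.ndarray,
    Y: np.ndarray,
    grid: Sequence[dict],
    k: int = 10,
    seed: int = 0,
) -> list[dict]:
    """10-fold CV over a grid of hidden sizes and learning rules.

    Each grid entry is a dict of MLPParams overrides (e.g.
    ``{"hidden_layers": [20], "trainer": "scg"}``). Returns one row per
    config with accuracy and kappa; the best row (by kappa, then accuracy)
    carries ``best=True``.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for cfg in grid:
        params = MLPParams(n_inputs=X.shape[1], seed=seed, **cfg)
        report = kfold_cv(X, Y, params, k=k, seed=seed)
        rows.append(
            {
                "config": dict(cfg),
                "accuracy": report.accuracy,
                "kappa": report.kappa,
                "best": False,
            }
        )
    best = max(range(len(rows)), key=lambda i: (rows[i]["kappa"], rows[i]["accuracy"]))
    rows[best]["best"] = True
    return rows
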