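"""Shallow neural network with a TP/FP trade-off loss.

One hidden ReLU layer, sigmoid output, trained full-batch with Adam on

    loss = 1 - (TP - lambda1 * FP) + lambda2 * ||w_out||^2

where TP and FP are *soft* counts: the summed predicted probabilities over
true cases and true controls respectively. The soft counts coincide with
hard counts when predictions saturate to {0, 1}, keeping the objective
differentiable. The loss is left unnormalized, so lambda1's scale depends
on cohort size; training is full-batch by default to keep that semantics
exact.

Hyperparameters are selected by stratified k-fold cross-validation
maximizing the fraction of validation cases scored strictly above the
maximum validation-control score (TPR at FPR = 0 on the fold).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ValidationError
from .io_features import FeatureMatrix, align_features

_MODEL_FORMAT = "dnvrisk-snn"
_MODEL_VERSION = 1
_PROB_EPS = 1e-12  # keeps predictions in the open interval (0, 1)


@dataclass(frozen=True)
class SNNHyperparams:
    """Training hyperparameters; ``lambda1`` weights false positives."""

    lambda1: float = 1.0
    hidden_units: int = 16
    lambda2: float = 0.0
    learning_rate: float = 1e-2
    epochs: int = 200
    seed: int = 0
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ValidationError("lambda1 must be > 0")
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be a positive integer")
        if self.lambda2 < 0:
            raise ValidationError("lambda2 must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be a positive integer")
        if self.restarts < 1:
            raise ValidationError("restarts must be a positive integer")


def default_grid(
    lambda1: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 10.0),
    hidden_units: Sequence[int] = (8, 16, 32, 64),
    lambda2: Sequence[float] = (0.0, 1e-4, 1e-3, 1e-2),
    learning_rate: Sequence[float] = (1e-3, 1e-2),
    epochs: int = 200,
    seed: int = 0,
) -> list[SNNHyperparams]:
    """Cartesian search grid over the documented default ranges."""
    grid = []
    for l1, h, l2, lr in itertools.product(lambda1, hidden_units, lambda2, learning_rate):
        grid.append(
            SNNHyperparams(
                lambda1=l1,
                hidden_units=h,
                lambda2=l2,
                learning_rate=lr,
                epochs=epochs,
                seed=seed,
            )
        )
    return grid


def custom_loss(
    labels: Sequence[float] | np.ndarray,
    predicted: Sequence[float] | np.ndarray,
    lambda1: float,
) -> float:
    """``1 - (TP - lambda1 * FP)`` with soft TP/FP counts; lower is better."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape:
        raise ValidationError(
            f"labels and predictions differ in length ({y.shape} vs {p.shape})"
        )
    if y.size == 0:
        raise ValidationError("empty label/prediction vectors")
    tp = float(p[y == 1].sum())
    fp = float(p[y == 0].sum())
    return 1.0 - (tp - lambda1 * fp)


@dataclass
class SNNModel:
    """Trained network; ``feature_schema`` fixes the input column order."""

    feature_schema: list[str]
    hyperparams: SNNHyperparams
    w_hidden: np.ndarray  # (input_dim, hidden_units)
    b_hidden: np.ndarray  # (hidden_units,)
    w_out: np.ndarray  # (hidden_units,)
    b_out: float
    activation: str = "relu"  # "identity" is a diagnostic mode

    @property
    def input_dim(self) -> int:
        return len(self.feature_schema)

    def forward(self, x: np.ndarray) -> np.ndarray:
        z1 = x @ self.w_hidden + self.b_hidden
        hidden = np.maximum(z1, 0.0) if self.activation == "relu" else z1
        z2 = hidden @ self.w_out + self.b_out
        return np.clip(expit(z2), _PROB_EPS, 1.0 - _PROB_EPS)


def _check_two_classes(labels: np.ndarray) -> None:
    if not (labels == 1).any():
        raise ValidationError("training set contains no cases")
    if not (labels == 0).any():
        raise ValidationError("training set contains no controls")


def snn_fit(
    train: FeatureMatrix,
    hp: SNNHyperparams,
    activation: str = "relu",
) -> SNNModel:
    """Fit the network with full-batch Adam; deterministic under ``hp.seed``.

    With ``hp.restarts > 1`` the network is trained from that many seeded
    initializations (seeds ``hp.seed + r``) and the restart maximizing the
    training-set fraction of cases above the maximum control score is kept
    (ties: lower training loss, then earlier restart). The custom objective
    is non-convex and occasionally lands in a poor basin from a single
    init; the selection criterion matches the one used for CV.
    """
    if hp.restarts > 1:
        best_model = None
        best_key: tuple[float, float] | None = None
        for r in range(hp.restarts):
            candidate = snn_fit(
                train, replace(hp, seed=hp.seed + r, restarts=1), activation
            )
            p = candidate.forward(train.values)
            controls = p[train.labels == 0]
            criterion = (
                float(np.mean(p[train.labels == 1] > controls.max()))
                if controls.size
                else 0.0
            )
            loss = custom_loss(train.labels, p, hp.lambda1)
            key = (criterion, -loss)
            if best_key is None or key > best_key:
                best_model, best_key = candidate, key
        assert best_model is not None
        best_model.hyperparams = hp
        return best_model

    x = train.values
    y = train.labels.astype(float)
    _check_two_classes(train.labels)

    rng = np.random.default_rng(hp.seed)
    d, h = x.shape[1], hp.hidden_units
    lim1, lim2 = 1.0 / np.sqrt(d), 1.0 / np.sqrt(h)
    w1 = rng.uniform(-lim1, lim1, size=(d, h))
    b1 = np.zeros(h)
    w2 = rng.uniform(-lim2, lim2, size=h)
    b2 = 0.0

    # dLoss/dp_i = -c_i with c_i = +1 for cases, -lambda1 for controls
    coeff = np.where(y == 1.0, 1.0, -hp.lambda1)

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]
    v = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]

    relu = activation == "relu"
    for t in range(1, hp.epochs + 1):
        z1 = x @ w1 + b1
        hidden = np.maximum(z1, 0.0) if relu else z1
        z2 = hidden @ w2 + b2
        p = expit(z2)

        dz2 = -coeff * p * (1.0 - p)
        g_w2 = hidden.T @ dz2 + 2.0 * hp.lambda2 * w2
        g_b2 = float(dz2.sum())
        d_hidden = np.outer(dz2, w2)
        dz1 = d_hidden * (z1 > 0.0) if relu else d_hidden
        g_w1 = x.T @ dz1
        g_b1 = dz1.sum(axis=0)

        grads = [g_w1, g_b1, g_w2, g_b2]
        params = [w1, b1, w2, b2]
        bc1 = 1.0 - beta1**t
        bc2 = 1.0 - beta2**t
        for i, (param, grad) in enumerate(zip(params, grads)):
            m[i] = beta1 * m[i] + (1.0 - beta1) * grad
            v[i] = beta2 * v[i] + (1.0 - beta2) * np.square(grad)
            step = hp.learning_rate * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)
            params[i] = param - step
        w1, b1, w2, b2 = params

    return SNNModel(
        feature_schema=list(train.feature_names),
        hyperparams=hp,
        w_hidden=w1,
        b_hidden=b1,
        w_out=w2,
        b_out=float(b2),
        activation=activation,
    )


def snn_predict(model: SNNModel, data: FeatureMatrix) -> np.ndarray:
    """Per-sample case probabilities in (0, 1), aligned to the model schema."""
    x = align_features(data, model.feature_schema)
    return model.forward(x)


def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Seeded label-stratified fold index sets (round-robin after shuffle)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for value in (1, 0):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        for offset, i in enumerate(idx):
            folds[offset % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cases_above_max_control(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> float:
    """Fraction of cases scored strictly above every control."""
    if control_scores.size == 0:
        raise ValidationError(
            "validation fold has zero controls; use stratified folding"
        )
    threshold = float(np.max(control_scores))
    return float(np.mean(case_scores > threshold))


def optimize_hyperparams(
    train: FeatureMatrix,
    grid: Sequence[SNNHyperparams],
    k: int = 3,
    seed: int = 0,
) -> SNNHyperparams:
    """Pick the grid point maximizing mean fold TPR-above-max-control.

    Ties are broken by grid order (first wins).
    """
    if not grid:
        raise ValidationError("hyperparameter grid is empty")
    _check_two_classes(train.labels)
    folds = stratified_folds(train.labels, k, seed)
    all_idx = np.arange(train.n_samples)

    best_hp, best_score = None, -np.inf
    for hp in grid:
        fold_scores = []
        for fold in folds:
            val_mask = np.zeros(train.n_samples, dtype=bool)
            val_mask[fold] = True
            fit_ids = [train.sample_ids[i] for i in all_idx[~val_mask]]
            val_ids = [train.sample_ids[i] for i in all_idx[val_mask]]
            fit_fm = train.subset(fit_ids)
            val_fm = train.subset(val_ids)
            model = snn_fit(fit_fm, hp)
            scores = snn_predict(model, val_fm)
            fold_scores.append(
                cases_above_max_control(
                    scores[val_fm.labels == 1], scores[val_fm.labels == 0]
                )
            )
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:
            best_hp, best_score = hp, mean_score
    assert best_hp is not None
    return best_hp


def save_model(model: SNNModel, path: str | Path) -> None:
    """Serialize to JSON; floats round-trip exactly via repr."""
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "feature_schema": model.feature_schema,
        "hyperparams": asdict(model.hyperparams),
        "activation": model.activation,
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SNNModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValidationError(f"{path}: not a {_MODEL_FORMAT} file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValidationError(
            f"{path}: unsupported model version {payload.get('version')}"
        )
    return SNNModel(
        feature_schema=list(payload["feature_schema"]),
        hyperparams=SNNHyperparams(**payload["hyperparams"]),
        w_hidden=np.array(payload["w_hidden"], dtype=float),
        b_hidden=np.array(payload["b_hidden"], dtype=float),
        w_out=np.array(payload["w_out"], dtype=float),
        b_out=float(payload["b_out"]),
        activation=payload.get("activation", "relu"),
    )
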