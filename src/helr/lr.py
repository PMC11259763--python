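"""Plaintext logistic regression built from first principles.

This is the arithmetic mirror of the encrypted trainer: minibatch Nesterov
accelerated gradient on the binary cross-entropy with an optional ridge
penalty, a polynomial sigmoid mode for ciphertext-evaluable arithmetic, and
a deterministic batch schedule shared operation-for-operation with the
encrypted loop so the two regimes can be compared on equal footing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainConfig",
    "ModelWeights",
    "PolySigmoid",
    "LossTrace",
    "sigmoid",
    "fit_poly_sigmoid",
    "bce",
    "gradient",
    "nag_step",
    "train_plaintext",
    "predict_proba",
    "classify",
    "odds_ratios",
    "linear_shap",
    "batch_blocks",
    "epoch_block_order",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 64
    momentum: float = 0.9
    epochs: int = 20
    l2_lambda: float = 0.01
    sigmoid_mode: str = "exact"          # "exact" | "poly"
    poly_degree: int = 3
    seed: int = 0
    early_stopping: bool = False
    patience: int = 3

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if self.sigmoid_mode not in ("exact", "poly"):
            raise ValueError(f"unknown sigmoid_mode {self.sigmoid_mode!r}")


@dataclass
class ModelWeights:
    beta: np.ndarray
    intercept: float
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not (np.isfinite(self.beta).all() and np.isfinite(self.intercept)):
            raise ValueError("model weights must be finite")

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "columns": self.columns,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelWeights":
        d = json.loads(text)
        return cls(np.asarray(d["beta"], dtype=float), d["intercept"],
                   d.get("columns"))


@dataclass
class LossTrace:
    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_bce", "val_bce"])
            for i, t in enumerate(self.train):
                v = self.val[i] if i < len(self.val) else ""
                w.writerow([i, t, v])


def sigmoid(z):
    """Numerically stable logistic function 1/(1+exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class PolySigmoid:
    """Least-squares polynomial approximation of the logistic function on a
    symmetric interval; the encrypted trainer evaluates this polynomial where
    the plaintext trainer would call the exact sigmoid."""

    degree: int
    coeffs: tuple[float, ...]          # low-to-high order
    interval: tuple[float, float]
    max_abs_error: float

    def __call__(self, z):
        return np.polynomial.polynomial.polyval(
            np.asarray(z, dtype=float), np.asarray(self.coeffs)
        )


def fit_poly_sigmoid(degree: int = 3,
                     interval: tuple[float, float] = (-8.0, 8.0),
                     grid_size: int = 4001) -> PolySigmoid:
    """Fit sigmoid by least squares on a dense uniform grid over ``interval``.

    The achieved max abs error on the grid is recorded on the result and
    frozen in tests as a regression bound.
    """
    if degree < 1 or degree % 2 == 0:
        raise ValueError("degree must be odd and >= 1")
    lo, hi = interval
    if not (lo < 0.0 < hi):
        raise ValueError("interval must straddle zero")
    grid = np.linspace(lo, hi, grid_size)
    target = sigmoid(grid)
    coeffs = np.polynomial.polynomial.polyfit(grid, target, degree)
    approx = np.polynomial.polynomial.polyval(grid, coeffs)
    err = float(np.max(np.abs(approx - target)))
    return PolySigmoid(degree, tuple(coeffs.tolist()), (lo, hi), err)


def bce(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy with probabilities clipped to
    [eps, 1 - eps]."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _sigmoid_fn(config: TrainConfig):
    if config.sigmoid_mode == "poly":
        return fit_poly_sigmoid(config.poly_degree)
    return sigmoid


def gradient(weights: ModelWeights, X: np.ndarray, y: np.ndarray,
             l2_lambda: float = 0.0,
             sigmoid_fn=sigmoid) -> tuple[np.ndarray, float]:
    """Minibatch BCE gradient with ridge penalty on the coefficients only
    (the intercept is unpenalized): (X'(p - y)/m + lambda*beta, mean(p - y))."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = X.shape[0]
    p = sigmoid_fn(X @ weights.beta + weights.intercept)
    resid = p - y
    g_beta = X.T @ resid / m + l2_lambda * weights.beta
    g_int = float(np.mean(resid))
    return g_beta, g_int


def nag_step(w: np.ndarray, b: float, vw: np.ndarray, vb: float,
             X_batch: np.ndarray, y_batch: np.ndarray, config: TrainConfig,
             sigmoid_fn=sigmoid):
    """One Nesterov accelerated gradient step (lookahead formulation):

        g  = grad at (w + mu*v)
        v <- mu*v - lr*g
        w <- w + v
    """
    mu, lr = config.momentum, config.learning_rate
    look = ModelWeights(w + mu * vw, b + mu * vb)
    gw, gb = gradient(look, X_batch, y_batch, config.l2_lambda, sigmoid_fn)
    vw_new = mu * vw - lr * gw
    vb_new = mu * vb - lr * gb
    return w + vw_new, b + vb_new, vw_new, vb_new


def batch_blocks(n: int, batch_size: int) -> list[np.ndarray]:
    """Rows partitioned into consecutive blocks of ``batch_size`` (last block
    may be short).  Shared verbatim by the encrypted trainer, whose ciphertext
    packing fixes row-to-block assignment at encryption time."""
    return [np.arange(s, min(s + batch_size, n))
            for s in range(0, n, batch_size)]


def epoch_block_order(n_blocks: int, epoch: int, seed: int) -> np.ndarray:
    """Seeded per-epoch permutation of block visit order."""
    rng = np.random.default_rng([seed, epoch, 0x5EC])
    return rng.permutation(n_blocks)


def train_plaintext(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    columns: list[str] | None = None,
    block_indices: list[np.ndarray] | None = None,
) -> tuple[ModelWeights, LossTrace]:
    """Minibatch NAG training from zero-initialized weights.

    Deterministic given the config seed: rows stay in their consecutive
    blocks and only the block visit order is reshuffled each epoch, so an
    encrypted run with the same seed consumes batches in the same order.
    Early stopping (patience on validation BCE) applies only when a
    validation set is provided and the flag is set.

    ``block_indices`` overrides the default consecutive blocks — used to
    mirror a merged ciphertext dataset whose per-site block boundaries are
    fixed at encryption time.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    n, p = X.shape
    sig = _sigmoid_fn(config)
    w = np.zeros(p)
    b = 0.0
    vw = np.zeros(p)
    vb = 0.0
    blocks = (block_indices if block_indices is not None
              else batch_blocks(n, config.batch_size))
    trace = LossTrace()
    best_val = np.inf
    bad_epochs = 0
    for epoch in range(config.epochs):
        for bi in epoch_block_order(len(blocks), epoch, config.seed):
            idx = blocks[bi]
            w, b, vw, vb = nag_step(w, b, vw, vb, X[idx], y[idx], config, sig)
        train_loss = bce(y, np.clip(sig(X @ w + b), 0.0, 1.0))
        if not np.isfinite(train_loss) or not np.isfinite(w).all():
            raise FloatingPointError(
                f"non-finite loss/weights at epoch {epoch}; "
                f"lr={config.learning_rate}, mode={config.sigmoid_mode}"
            )
        trace.train.append(train_loss)
        if validation is not None:
            Xv, yv = validation
            val_loss = bce(np.asarray(yv, float),
                           np.clip(sig(np.asarray(Xv, float) @ w + b),
                                   0.0, 1.0))
            trace.val.append(val_loss)
            if config.early_stopping:
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= config.patience:
                        break
    return ModelWeights(w, b, columns), trace


def predict_proba(weights: ModelWeights, X: np.ndarray,
                  sigmoid_fn=sigmoid, columns: list[str] | None = None):
    """Predicted probabilities sigmoid(X.beta + intercept)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(weights.beta):
        raise ValueError("column count does not match model")
    if columns is not None and weights.columns is not None \
            and list(columns) != list(weights.columns):
        raise ValueError("column schema does not match the trained model")
    return sigmoid_fn(X @ weights.beta + weights.intercept)


def classify(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels at the given probability threshold (ties classified 1)."""
    return (np.asarray(p, dtype=float) >= threshold).astype(int)


def odds_ratios(weights: ModelWeights) -> np.ndarray:
    """exp(beta), one odds ratio per coefficient."""
    return np.exp(weights.beta)


def linear_shap(weights: ModelWeights, X: np.ndarray,
                background_means: np.ndarray) -> np.ndarray:
    """Exact Shapley attributions for a linear model on the log-odds scale:
    phi_ij = beta_j * (x_ij - background_mean_j)."""
    X = np.asarray(X, dtype=float)
    mu = np.asarray(background_means, dtype=float)
    if mu.shape[0] != len(weights.beta):
        raise ValueError("background_means length does not match model")
    return (X - mu) * weights.beta
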