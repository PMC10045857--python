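"""Extreme Learning Machine: random frozen sigmoid hidden layer, analytic output weights.

The model is a single-hidden-layer feedforward network

    f(x) = sum_j  beta_j * sigmoid(w_j . x + b_j)

whose input weights ``W`` and biases ``b`` are drawn once, uniformly at
random (W in [-1, 1], b in [0, 1] by default), and *never trained*.  The only
learned parameters are the output weights ``beta``, obtained in closed form
as the minimum-norm least-squares solution

    beta = H+ Y,

where H is the n x L hidden-layer output matrix and H+ its Moore–Penrose
pseudoinverse (computed by SVD with a relative singular-value cutoff).
Binary problems train a single output column on {0,1} targets and threshold
the score at 0.5; K-class problems use one-hot targets with arg-max decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "ELMConfig",
    "ELMModel",
    "NotTrainedError",
    "init_hidden",
    "hidden_activations",
    "fit",
    "solve_output_weights",
    "default_sweep_grid",
    "decision_scores",
    "predict",
    "sweep_hidden_neurons",
    "SweepResult",
    "default_hidden_neurons",
    "derive_seed",
    "save_model",
    "load_model",
]


class NotTrainedError(RuntimeError):
    """The operation requires a fitted model (beta is only defined after fit)."""


@dataclass(frozen=True)
class ELMConfig:
    """Hyperparameters of the random hidden layer.

    ``pinv_rtol`` is the relative singular-value cutoff of the pseudoinverse;
    ``None`` uses max(n, L) * machine epsilon, the conventional default.
    """

    n_hidden: int
    activation: str = "sigmoid"
    input_weight_range: tuple[float, float] = (-1.0, 1.0)
    bias_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    pinv_rtol: float | None = None

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError(f"n_hidden must be >= 1, got {self.n_hidden}")
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")
        for name in ("input_weight_range", "bias_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered low < high")
        if self.pinv_rtol is not None and self.pinv_rtol < 0:
            raise ValueError("pinv_rtol must be >= 0")


@dataclass(frozen=True)
class ELMModel:
    """A (possibly trained) ELM.  W: L x m input weights; b: length-L biases;
    beta: L x K output weights, defined only after :func:`fit`."""

    W: np.ndarray
    b: np.ndarray
    config: ELMConfig
    n_features: int
    beta: np.ndarray | None = None
    encoding: str = "binary"            # "binary" | "onehot"
    classes_: np.ndarray | None = None  # class order for onehot decoding

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_outputs(self) -> int:
        if self.beta is None:
            raise NotTrainedError("model has no output weights yet")
        return self.beta.shape[1]

    @property
    def is_trained(self) -> bool:
        return self.beta is not None


def init_hidden(cfg: ELMConfig, m: int) -> ELMModel:
    """Draw the random hidden layer: W ~ U(input range), b ~ U(bias range)."""
    if m < 1:
        raise ValueError(f"need at least one input feature, got {m}")
    rng = np.random.default_rng(cfg.seed)
    W = rng.uniform(*cfg.input_weight_range, size=(cfg.n_hidden, m))
    b = rng.uniform(*cfg.bias_range, size=cfg.n_hidden)
    return ELMModel(W=W, b=b, config=cfg, n_features=m)


def hidden_activations(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """H[r, j] = sigmoid(w_j . x_r + b_j), computed overflow-free."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    return expit(X @ model.W.T + model.b)


def _encode_targets(y: np.ndarray, encoding: str):
    y = np.asarray(y)
    if encoding == "binary":
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binary encoding requires labels in {0, 1}")
        return y.reshape(-1, 1).astype(float), None
    if encoding == "onehot":
        classes = np.unique(y)
        Y = (y[:, None] == classes[None, :]).astype(float)
        return Y, classes
    raise ValueError(f"unknown target encoding {encoding!r}")


def fit(model: ELMModel, X: np.ndarray, y: np.ndarray, encoding: str = "binary") -> ELMModel:
    """Solve beta = H+ Y (minimum-norm least squares, SVD with relative cutoff)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != len(y):
        raise ValueError("X and y row counts differ")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    Y, classes = _encode_targets(y, encoding)
    H = hidden_activations(model, X)
    beta = solve_output_weights(H, Y, rtol=model.config.pinv_rtol)
    return replace(model, beta=beta, encoding=encoding, classes_=classes)


def solve_output_weights(H: np.ndarray, Y: np.ndarray, rtol: float | None = None) -> np.ndarray:
    """Minimum-norm least-squares solution of H beta = Y (beta = H+ Y).

    SVD-based; singular values below ``rtol * sigma_max`` are treated as zero.
    ``rtol=None`` uses max(n, L) * machine epsilon.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    if rtol is None:
        rtol = max(H.shape) * np.finfo(H.dtype).eps
    beta, *_ = np.linalg.lstsq(H, Y, rcond=rtol)
    return beta


def decision_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs H . beta, shape n x K.

    In binary mode the single column is the real-valued score used directly
    for ROC analysis and thresholding.
    """
    if not model.is_trained:
        raise NotTrainedError("call fit() before decision_scores()")
    H = hidden_activations(model, X)
    return H @ model.beta


def predict(model: ELMModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decode scores to labels.

    Binary: label 1 iff score >= threshold (the boundary score maps to 1).
    One-hot: arg-max over output columns, ties broken by the lowest class index.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be a finite real")
    S = decision_scores(model, X)
    if model.encoding == "binary":
        return (S[:, 0] >= threshold).astype(int)
    return model.classes_[np.argmax(S, axis=1)]


def default_hidden_neurons(n_train: int) -> int:
    """The one-tenth heuristic: L = round(0.1 * n_train) (e.g. 9200 -> 920)."""
    return max(1, int(round(0.1 * n_train)))


def default_sweep_grid(n_train: int) -> tuple[int, ...]:
    """Grid around the one-tenth anchor L0 = round(0.1 * n_train): quarter
    multiples of L0 from L0/4 to 2*L0 (for 9200 training rows: 230, 460,
    ..., 1840, always containing 920)."""
    L0 = default_hidden_neurons(n_train)
    return tuple(sorted({max(1, round(L0 * f / 4)) for f in range(1, 9)}))


def derive_seed(*parts: int) -> int:
    """Deterministic sub-seed from integer parts, kept below 2**31."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepResult:
    grid: tuple[int, ...]
    accuracies: tuple[float, ...]
    best_L: int


def sweep_hidden_neurons(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid,
    seed: int = 0,
    encoding: str = "binary",
    base_config: ELMConfig | None = None,
) -> SweepResult:
    """Hidden-layer size selection by validation accuracy.

    One fresh random hidden layer per grid point (sub-seeded from (seed, L) so
    the sweep is reproducible yet layers are independent); returns the full
    accuracy curve and the smallest L attaining the maximum.
    """
    grid = tuple(int(L) for L in grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    n_train = len(np.asarray(y_train))
    accs = []
    for L in grid:
        if L >= 10 * n_train:
            warnings.warn(
                f"L={L} is >= 10x the training size {n_train} (overparameterized)",
                UserWarning,
                stacklevel=2,
            )
        cfg = ELMConfig(n_hidden=L, seed=derive_seed(seed, L)) if base_config is None \
            else replace(base_config, n_hidden=L, seed=derive_seed(seed, L))
        model = fit(init_hidden(cfg, np.atleast_2d(X_train).shape[1]), X_train, y_train, encoding)
        accs.append(float(np.mean(predict(model, X_val) == np.asarray(y_val))))
    best = int(np.argmax(accs))  # first (smallest-L) max
    return SweepResult(grid=grid, accuracies=tuple(accs), best_L=grid[best])


def save_model(model: ELMModel, path) -> None:
    """Serialize W, b, beta, config and encoding; round-trips bit-exactly."""
    cfg = model.config
    np.savez(
        path,
        W=model.W,
        b=model.b,
        beta=model.beta if model.beta is not None else np.empty((0, 0)),
        trained=np.array(model.is_trained),
        encoding=np.array(model.encoding),
        classes=model.classes_ if model.classes_ is not None else np.empty(0),
        has_classes=np.array(model.classes_ is not None),
        n_features=np.array(model.n_features),
        n_hidden=np.array(cfg.n_hidden),
        activation=np.array(cfg.activation),
        input_weight_range=np.array(cfg.input_weight_range),
        bias_range=np.array(cfg.bias_range),
        seed=np.array(cfg.seed),
        pinv_rtol=np.array(-1.0 if cfg.pinv_rtol is None else cfg.pinv_rtol),
    )


def load_model(path) -> ELMModel:
    d = np.load(path, allow_pickle=False)
    rtol = float(d["pinv_rtol"])
    cfg = ELMConfig(
        n_hidden=int(d["n_hidden"]),
        activation=str(d["activation"]),
        input_weight_range=tuple(d["input_weight_range"]),
        bias_range=tuple(d["bias_range"]),
        seed=int(d["seed"]),
        pinv_rtol=None if rtol < 0 else rtol,
    )
    return ELMModel(
        W=d["W"],
        b=d["b"],
        config=cfg,
        n_features=int(d["n_features"]),
        beta=d["beta"] if bool(d["trained"]) else None,
        encoding=str(d["encoding"]),
        classes_=d["classes"] if bool(d["has_classes"]) else None,
    )
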