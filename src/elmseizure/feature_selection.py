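"""Connection-weight feature selection from a trained ELM.

Feature importance is read off the trained network's weights in four steps:

1. significance coefficients  C[i,k] = sum_j beta[j,k] * g(W[j,i])
   where g(x) = (1 - e^{-x}) / (1 + e^{-x}) = tanh(x/2) — the contribution of
   input feature i to output node k, aggregated over the L hidden nodes;
2. index correlation          R[i,k] = |tanh(C[i,k] / 2)|   (a magnitude in [0,1));
3. absolute influence         S[i,k] = R[i,k] / sum_i' R[i',k]  (columns sum to 1);
4. feature weights            W_feat[i] = mean_k S[i,k].

High-weight features are retained; two policies are offered — keep features
with weight >= mean weight (parameter-free default), or keep the top k.
The tanh(x/2) form is used throughout because the literal exponential ratio
overflows for large negative x; the two agree to ~1e-12 on sane ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elm import ELMModel, NotTrainedError

__all__ = [
    "FSResult",
    "significance_matrix",
    "index_correlation",
    "absolute_influence",
    "feature_weights",
    "select_features",
    "run_feature_selection",
]


@dataclass(frozen=True)
class FSResult:
    C: np.ndarray          # m x K significance coefficients
    R: np.ndarray          # m x K index correlations
    S: np.ndarray          # m x K influence shares (columns sum to 1)
    W_feat: np.ndarray     # length-m feature weights
    selected: tuple[int, ...]  # retained feature indices, descending weight
    policy: str


def significance_matrix(model: ELMModel) -> np.ndarray:
    """C[i,k] = sum_j beta[j,k] * tanh(W[j,i] / 2) for a trained model."""
    if not model.is_trained:
        raise NotTrainedError("feature selection needs a trained model")
    return np.tanh(model.W / 2.0).T @ model.beta


def index_correlation(C: np.ndarray) -> np.ndarray:
    """R = |tanh(C/2)|: squashes significance to a magnitude in [0, 1)."""
    C = np.asarray(C, dtype=float)
    if not np.isfinite(C).all():
        raise ValueError("C must be finite")
    return np.abs(np.tanh(C / 2.0))


def absolute_influence(R: np.ndarray) -> np.ndarray:
    """Normalize each output's column of R to sum to 1 (influence shares)."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    col = R.sum(axis=0)
    if (col <= 0).any():
        bad = np.flatnonzero(col <= 0).tolist()
        raise ValueError(f"no informative features for output column(s) {bad}")
    return R / col


def feature_weights(S: np.ndarray, as_printed: bool = False) -> np.ndarray:
    """Per-feature mean influence over the K output nodes (sums to 1 over features).

    ``as_printed=True`` instead averages over *features*, returning the
    constant 1/m per output — kept only for auditability of the alternative
    reading; it carries no ranking information.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if as_printed:
        return S.sum(axis=0) / S.shape[0]
    return S.mean(axis=1)


def select_features(
    W_feat: np.ndarray,
    policy: str = "threshold-mean",
    k: int | None = None,
) -> tuple[int, ...]:
    """Retain high-weight features, returned in descending-weight order.

    threshold-mean: keep features with W_feat >= mean(W_feat).
    top-k: keep the k largest (ties broken by the lower feature index).
    """
    w = np.asarray(W_feat, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("W_feat must be finite")
    m = w.size
    order = np.lexsort((np.arange(m), -w))  # descending weight, ties by index
    if policy == "threshold-mean":
        keep = w[order] >= w.mean()
        return tuple(int(i) for i in order[keep])
    if policy == "top-k":
        if k is None or not 1 <= k <= m:
            raise ValueError(f"top-k needs 1 <= k <= {m}, got {k}")
        return tuple(int(i) for i in order[:k])
    raise ValueError(f"unknown policy {policy!r}")


def run_feature_selection(
    model: ELMModel,
    policy: str = "threshold-mean",
    k: int | None = None,
) -> FSResult:
    """The full four-step pipeline on a trained model."""
    C = significance_matrix(model)
    R = index_correlation(C)
    S = absolute_influence(R)
    w = feature_weights(S)
    sel = select_features(w, policy=policy, k=k)
    return FSResult(C=C, R=R, S=S, W_feat=w, selected=sel, policy=policy)
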