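"""Synthetic Bonn-like EEG chunk tables and simple separable fixtures.

The generator emulates the *shape* of the chunked Bonn/UCI table — five
classes x 100 subjects x 23 one-second chunks of 178 samples, amplitudes
clipped to the printed ADC range [-1415, 2047] — with a planted class
structure so the whole pipeline is testable offline:

* every class is AR(2)-filtered Gaussian noise (a crude stand-in for
  band-limited background EEG), at a distinct per-class amplitude scale;
* the ictal class (label 1) additionally carries high-amplitude ~3 Hz
  spike-and-wave bursts, giving it markedly higher per-row variance.

No physiological realism is attempted beyond scale and separability; see the
methods note for what that does and does not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .data_io import BinaryDataset, LabeledDataset

__all__ = ["SynthConfig", "generate_bonn_like", "generate_separable", "write_manifest"]

#: per-class innovation scale of the AR(2) background, in ADC units.
#: Class 1 (ictal) also receives bursts; classes 2..5 are graded non-seizure
#: conditions (pre-ictal, inter-ictal, eyes closed, eyes open).
DEFAULT_CLASS_SCALES = {1: 100.0, 2: 22.0, 3: 15.0, 4: 10.0, 5: 6.0}


@dataclass(frozen=True)
class SynthConfig:
    n_subjects_per_class: int = 100
    chunks_per_subject: int = 23
    chunk_len: int = 178
    seed: int = 0
    class_scales: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SCALES))
    ar_coeffs: tuple[float, float] = (1.35, -0.45)
    burst_amplitude: float = 800.0
    burst_freq_hz: float = 3.0
    burst_prob: float = 1.0
    sampling_hz: float = 178.0
    clip_range: tuple[float, float] = (-1415.0, 2047.0)

    def __post_init__(self):
        if min(self.n_subjects_per_class, self.chunks_per_subject, self.chunk_len) < 1:
            raise ValueError("all counts must be >= 1")
        if not self.clip_range[0] < self.clip_range[1]:
            raise ValueError("clip_range low must be < high")
        if set(self.class_scales) != {1, 2, 3, 4, 5}:
            raise ValueError("class_scales must cover classes 1..5")

    @property
    def n_rows(self) -> int:
        return 5 * self.n_subjects_per_class * self.chunks_per_subject


def _ar2(rng: np.random.Generator, n: int, coeffs, sigma: float) -> np.ndarray:
    a1, a2 = coeffs
    eps = rng.normal(0.0, sigma, size=n + 50)   # 50-sample burn-in
    x = lfilter([1.0], [1.0, -a1, -a2], eps)
    return x[50:]


def generate_bonn_like(cfg: SynthConfig = SynthConfig()) -> LabeledDataset:
    """Generate the five-class chunk table; fully determined by ``cfg.seed``.

    Returns n = 5 * n_subjects_per_class * chunks_per_subject rows of
    ``chunk_len`` values each, labels 1..5 in equal counts, row ids of the
    form ``S<class>.P<subject>.C<chunk>``.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.chunk_len
    t = np.arange(T) / cfg.sampling_hz
    rows, labels, ids = [], [], []
    for cls in (1, 2, 3, 4, 5):
        sigma = cfg.class_scales[cls]
        for subj in range(cfg.n_subjects_per_class):
            series = _ar2(rng, cfg.chunks_per_subject * T, cfg.ar_coeffs, sigma)
            for ch in range(cfg.chunks_per_subject):
                x = series[ch * T:(ch + 1) * T].copy()
                if cls == 1 and rng.random() < cfg.burst_prob:
                    # spike-and-wave: fundamental + strong odd harmonic,
                    # gated over a random subinterval of at least half a chunk
                    start = rng.integers(0, T // 2 + 1)
                    length = rng.integers(T // 2, T - start + 1)
                    phase = rng.uniform(0, 2 * np.pi)
                    seg = slice(start, start + length)
                    w = 2 * np.pi * cfg.burst_freq_hz * t[seg]
                    x[seg] += cfg.burst_amplitude * (
                        np.sin(w + phase) + 0.6 * np.sin(3 * w + phase) ** 3
                    )
                rows.append(np.clip(x, *cfg.clip_range))
                labels.append(cls)
                ids.append(f"S{cls}.P{subj}.C{ch}")
    X = np.asarray(rows)
    return LabeledDataset(
        X,
        np.asarray(labels),
        row_ids=tuple(ids),
        feature_names=tuple(f"X{i + 1}" for i in range(T)),
    )


def generate_separable(
    n: int,
    m: int,
    margin: float,
    seed: int = 0,
    n_informative: int | None = None,
) -> BinaryDataset:
    """Two Gaussian clouds separated by ``margin`` along a random direction.

    A plain oracle fixture: rows are N(0, I) in m dimensions; the positive
    class is shifted by ``margin`` along a random unit vector.  With
    ``n_informative`` the shift is supported on the first ``n_informative``
    coordinates with equal magnitude and random signs, so each planted
    feature carries the same signal (a planted-feature setup for
    feature-selection recovery tests).  Labels are balanced.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n % 2:
        raise ValueError("n must be even for balanced classes")
    if m < 1:
        raise ValueError("m must be >= 1")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    k = m if n_informative is None else n_informative
    if not 1 <= k <= m:
        raise ValueError("n_informative must be in [1, m]")
    rng = np.random.default_rng(seed)
    u = np.zeros(m)
    if n_informative is None:
        v = rng.normal(size=k)
        u[:k] = v / np.linalg.norm(v)
    else:
        u[:k] = rng.choice([-1.0, 1.0], size=k) / np.sqrt(k)
    X = rng.normal(size=(n, m))
    y = np.zeros(n, dtype=int)
    pos = rng.permutation(n)[: n // 2]
    y[pos] = 1
    X[y == 1] += margin * u
    return BinaryDataset(X, y, feature_names=tuple(f"X{i + 1}" for i in range(m)))


def write_manifest(cfg: SynthConfig, path) -> None:
    """Record the generator config and seed next to a written table."""
    lines = [f"{k}\t{getattr(cfg, k)!r}" for k in (
        "n_subjects_per_class", "chunks_per_subject", "chunk_len", "seed",
        "class_scales", "ar_coeffs", "burst_amplitude", "burst_freq_hz",
        "burst_prob", "sampling_hz", "clip_range")]
    Path(path).write_text("\n".join(lines) + "\n")
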