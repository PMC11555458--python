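"""Drift detection: five chunk-comparison metrics, signal
normalization and threshold-based flagging.

Every metric compares each temporal chunk against a reference slice
(the first chunk by default; a consecutive-chunk mode is available) and
yields a :class:`DriftSignal` holding the raw per-chunk series, its
min-max normalized form and the flag decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from disdrift.data_model import (
    ChunkedDataset,
    FrequencyDistribution,
    chunk_frequencies,
    one_hot_matrix,
)

__all__ = [
    "DriftSignal",
    "jensen_shannon_divergence",
    "centroid",
    "cosine_distance",
    "normalize_signal",
    "detect_drift",
    "jsd_signal",
    "centroid_cosine_signal",
    "pca_reconstruction_signal",
    "autoencoder_reconstruction_signal",
    "classifier_error_signal",
    "compute_signal",
]


# ---------------------------------------------------------------------------
# primitive metrics
# ---------------------------------------------------------------------------


def jensen_shannon_divergence(
    p: FrequencyDistribution | np.ndarray,
    q: FrequencyDistribution | np.ndarray,
    log_base: float = 2.0,
) -> float:
    """Jensen-Shannon divergence ``1/2 KL(P||M) + 1/2 KL(Q||M)`` with
    the mixture ``M = (P + Q) / 2``.

    Symmetric in its arguments and bounded by 1 when ``log_base`` is 2.
    Zero probability cells contribute zero (the ``0 log 0`` convention).
    """
    if isinstance(p, FrequencyDistribution) and isinstance(q, FrequencyDistribution):
        if p.vocabulary != q.vocabulary:
            raise ValueError("distributions have mismatched vocabularies")
        pv, qv = p.probabilities, q.probabilities
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise ValueError("distributions have mismatched shapes")
    for name, v in (("p", pv), ("q", qv)):
        if np.any(v < 0) or abs(float(v.sum()) - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a probability distribution")

    m = 0.5 * (pv + qv)
    log = np.log(log_base)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * (np.log(a[mask]) - np.log(b[mask])))) / log

    return 0.5 * _kl(pv, m) + 0.5 * _kl(qv, m)


def centroid(vectors) -> np.ndarray:
    """Elementwise arithmetic mean of a nonempty vector collection."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0 or arr.shape[0] == 0:
        raise ValueError("centroid of an empty collection is undefined")
    return arr.mean(axis=0)


def cosine_distance(u, v) -> float:
    """``1 - cos(u, v)``; raises on zero-norm input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - (u @ v) / (nu * nv))


def normalize_signal(raw) -> np.ndarray:
    """Min-max rescale ``(X - min X) / (max X - min X)``; a constant
    series maps to all zeros (documented degenerate-case convention)."""
    x = np.asarray(raw, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty series")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# DriftSignal + flagging
# ---------------------------------------------------------------------------


@dataclass
class DriftSignal:
    """Per-chunk metric series against the reference chunk."""

    metric_name: str
    chunk_labels: tuple[str, ...]
    raw_values: np.ndarray
    normalized_values: np.ndarray = field(init=False)
    flags: np.ndarray | None = None
    threshold_policy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chunk_labels = tuple(self.chunk_labels)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if len(self.chunk_labels) != self.raw_values.shape[0]:
            raise ValueError("labels and values length mismatch")
        self.normalized_values = normalize_signal(self.raw_values)

    def to_rows(self) -> list[dict]:
        rows = []
        for i, lab in enumerate(self.chunk_labels):
            rows.append(
                {
                    "metric": self.metric_name,
                    "chunk": lab,
                    "raw": float(self.raw_values[i]),
                    "normalized": float(self.normalized_values[i]),
                    "flagged": bool(self.flags[i]) if self.flags is not None else None,
                }
            )
        return rows


def detect_drift(
    signal: DriftSignal | np.ndarray,
    k_sd: float = 2.0,
    reference_window: int = 3,
    fixed_threshold: float | None = None,
) -> list[int]:
    """Flag indices whose raw value exceeds ``mean + k_sd * SD`` of the
    first ``reference_window`` values.

    If the reference window has zero variance the k-SD rule is
    degenerate; the detector falls back (with a warning) to a fixed
    threshold — ``fixed_threshold`` if given, else the window mean plus
    a tiny absolute tolerance.
    """
    if isinstance(signal, DriftSignal):
        raw = signal.raw_values
    else:
        raw = np.asarray(signal, dtype=float)
    if raw.size < reference_window + 1:
        raise ValueError(
            f"signal has {raw.size} values; need at least reference_window + 1 "
            f"= {reference_window + 1}"
        )
    window = raw[:reference_window]
    mean = float(window.mean())
    sd = float(window.std(ddof=1)) if window.size > 1 else 0.0
    if sd == 0.0 and fixed_threshold is None:
        warnings.warn(
            "zero-variance reference window: falling back to fixed-threshold policy",
            stacklevel=2,
        )
        threshold = mean + 1e-8
        policy = {"policy": "fixed", "threshold": threshold, "fallback": True}
    elif fixed_threshold is not None and sd == 0.0:
        threshold = fixed_threshold
        policy = {"policy": "fixed", "threshold": threshold, "fallback": True}
    else:
        threshold = mean + k_sd * sd
        policy = {
            "policy": "k_sd",
            "k_sd": k_sd,
            "reference_window": reference_window,
            "threshold": threshold,
        }
    flags = raw > threshold
    if isinstance(signal, DriftSignal):
        signal.flags = flags
        signal.threshold_policy = policy
    return [int(i) for i in np.nonzero(flags)[0]]


# ---------------------------------------------------------------------------
# chunk pairing
# ---------------------------------------------------------------------------


def _chunk_pairs(dataset: ChunkedDataset, comparison: str) -> list[tuple[str, str]]:
    """(reference, target) label pairs, one per non-reference chunk."""
    if comparison == "first":
        ref = dataset.reference_chunk
        return [(ref, c) for c in dataset.chunks if c != ref]
    if comparison == "consecutive":
        return list(zip(dataset.chunks[:-1], dataset.chunks[1:]))
    raise ValueError(f"unknown comparison mode {comparison!r}")


# ---------------------------------------------------------------------------
# signal builders
# ---------------------------------------------------------------------------


def jsd_signal(
    dataset: ChunkedDataset,
    smoothing_epsilon: float = 0.5,
    log_base: float = 2.0,
    comparison: str = "first",
    per_patient: bool = False,
) -> DriftSignal:
    """JSD between each chunk's token distribution and the reference's."""
    freqs = chunk_frequencies(
        dataset, smoothing_epsilon=smoothing_epsilon, per_patient=per_patient
    )
    pairs = _chunk_pairs(dataset, comparison)
    values = [jensen_shannon_divergence(freqs[a], freqs[b], log_base) for a, b in pairs]
    return DriftSignal("jsd", tuple(b for _, b in pairs), np.asarray(values))


def _chunk_matrices(dataset: ChunkedDataset) -> dict[str, np.ndarray]:
    mat, cols, records = one_hot_matrix(dataset)
    out: dict[str, np.ndarray] = {}
    for chunk in dataset.chunks:
        rows = [i for i, r in enumerate(records) if r.chunk_label == chunk]
        out[chunk] = mat[rows]
    return out


def centroid_cosine_signal(
    dataset: ChunkedDataset, comparison: str = "first"
) -> DriftSignal:
    """Cosine distance between each chunk's centroid and the reference
    chunk's centroid, on the one-hot bag-of-events representation."""
    mats = _chunk_matrices(dataset)
    cents = {c: centroid(m) for c, m in mats.items() if m.shape[0] > 0}
    pairs = _chunk_pairs(dataset, comparison)
    values = [cosine_distance(cents[a], cents[b]) for a, b in pairs]
    return DriftSignal("centroid", tuple(b for _, b in pairs), np.asarray(values))


def pca_reconstruction_signal(
    dataset: ChunkedDataset,
    n_components: int | float = 0.9,
    comparison: str = "first",
    scale: bool = True,
) -> DriftSignal:
    """Mean squared residual of projecting each chunk onto the principal
    subspace fitted on the reference chunk only (centering/scaling also
    learned on the reference)."""
    mats = _chunk_matrices(dataset)
    ref = mats[dataset.reference_chunk]
    if scale:
        scaler = StandardScaler()
        # constant columns get unit scale to avoid divide-by-zero
        scaler.fit(ref)
        scaler.scale_[scaler.scale_ == 0] = 1.0
        transform = scaler.transform
    else:
        mean = ref.mean(axis=0)
        transform = lambda X: X - mean  # noqa: E731
    ref_t = transform(ref)
    max_rank = min(ref_t.shape)
    if isinstance(n_components, int) and n_components > max_rank:
        raise ValueError(
            f"n_components {n_components} exceeds reference rank bound {max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(ref_t)

    def residual(X: np.ndarray) -> float:
        Z = transform(X)
        rec = pca.inverse_transform(pca.transform(Z))
        return float(np.mean((Z - rec) ** 2))

    pairs = _chunk_pairs(dataset, comparison)
    values = [residual(mats[b]) for _, b in pairs]
    return DriftSignal("pca", tuple(b for _, b in pairs), np.asarray(values))


class _Autoencoder:
    """Single-hidden-layer autoencoder trained with full-batch Adam.

    Deliberately tiny and dependency-free: deterministic under a fixed
    seed and fast enough for per-chunk drift scoring.
    """

    def __init__(
        self,
        n_features: int,
        bottleneck: int,
        activation: str = "relu",
        seed: int = 0,
        learning_rate: float = 0.01,
        epochs: int = 300,
    ) -> None:
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / n_features)
        s2 = np.sqrt(2.0 / bottleneck)
        self.W1 = rng.normal(0, s1, size=(n_features, bottleneck))
        self.b1 = np.zeros(bottleneck)
        self.W2 = rng.normal(0, s2, size=(bottleneck, n_features))
        self.b2 = np.zeros(n_features)
        self.activation = activation
        self.lr = learning_rate
        self.epochs = epochs
        self.loss_history: list[float] = []

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        return (z > 0).astype(float) if self.activation == "relu" else np.ones_like(z)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._act(X @ self.W1 + self.b1) @ self.W2 + self.b2

    def fit(self, X: np.ndarray) -> "_Autoencoder":
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]
        for t in range(1, self.epochs + 1):
            Z1 = X @ self.W1 + self.b1
            H = self._act(Z1)
            R = H @ self.W2 + self.b2
            err = R - X
            self.loss_history.append(float(np.mean(err**2)))
            dR = 2.0 * err / (n * X.shape[1])
            gW2 = H.T @ dR
            gb2 = dR.sum(axis=0)
            dH = dR @ self.W2.T * self._act_grad(Z1)
            gW1 = X.T @ dH
            gb1 = dH.sum(axis=0)
            for p, g, mi, vi in zip(params, [gW1, gb1, gW2, gb2], m, v):
                mi[:] = beta1 * mi + (1 - beta1) * g
                vi[:] = beta2 * vi + (1 - beta2) * g**2
                mhat = mi / (1 - beta1**t)
                vhat = vi / (1 - beta2**t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        if len(self.loss_history) > 10 and self.loss_history[-1] > self.loss_history[0]:
            warnings.warn("autoencoder loss did not decrease during training", stacklevel=2)
        return self


def autoencoder_reconstruction_signal(
    dataset: ChunkedDataset,
    bottleneck: int = 4,
    epochs: int = 300,
    learning_rate: float = 0.01,
    activation: str = "relu",
    seed: int = 0,
    comparison: str = "first",
    scale: bool = True,
) -> DriftSignal:
    """Mean squared reconstruction error of a single-hidden-layer
    autoencoder trained on the reference chunk only."""
    mats = _chunk_matrices(dataset)
    ref = mats[dataset.reference_chunk]
    if scale:
        scaler = StandardScaler()
        scaler.fit(ref)
        scaler.scale_[scaler.scale_ == 0] = 1.0
        transform = scaler.transform
    else:
        transform = lambda X: X  # noqa: E731
    ref_t = transform(ref)
    ae = _Autoencoder(
        n_features=ref_t.shape[1],
        bottleneck=bottleneck,
        activation=activation,
        seed=seed,
        learning_rate=learning_rate,
        epochs=epochs,
    ).fit(ref_t)
    pairs = _chunk_pairs(dataset, comparison)
    values = [
        float(np.mean((transform(mats[b]) - ae.reconstruct(transform(mats[b]))) ** 2))
        for _, b in pairs
    ]
    return DriftSignal("autoencoder", tuple(b for _, b in pairs), np.asarray(values))


def classifier_error_signal(
    dataset: ChunkedDataset,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    comparison: str = "first",
) -> DriftSignal:
    """Cross-validated balanced accuracy of a regularized linear
    classifier separating the reference chunk (label 0) from each target
    chunk (label 1); 0.5 ~ exchangeable, 1.0 = fully separable."""
    mats = _chunk_matrices(dataset)
    pairs = _chunk_pairs(dataset, comparison)
    values = []
    for ref_label, target in pairs:
        Xr, Xt = mats[ref_label], mats[target]
        X = np.vstack([Xr, Xt])
        y = np.concatenate([np.zeros(Xr.shape[0]), np.ones(Xt.shape[0])])
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = []
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[train_idx])) < 2:
                warnings.warn("degenerate single-class fold skipped", stacklevel=2)
                continue
            clf = LogisticRegression(C=C, max_iter=2000)
            clf.fit(X[train_idx], y[train_idx])
            scores.append(balanced_accuracy_score(y[test_idx], clf.predict(X[test_idx])))
        values.append(float(np.mean(scores)))
    return DriftSignal("classifier", tuple(b for _, b in pairs), np.asarray(values))


_SIGNAL_BUILDERS = {
    "jsd": jsd_signal,
    "centroid": centroid_cosine_signal,
    "pca": pca_reconstruction_signal,
    "autoencoder": autoencoder_reconstruction_signal,
    "classifier": classifier_error_signal,
}


def compute_signal(dataset: ChunkedDataset, metric: str, **kwargs) -> DriftSignal:
    """Dispatch a metric name to its signal builder."""
    try:
        builder = _SIGNAL_BUILDERS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(_SIGNAL_BUILDERS)}"
        ) from None
    return builder(dataset, **kwargs)


def available_metrics() -> list[str]:
    return sorted(_SIGNAL_BUILDERS)
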