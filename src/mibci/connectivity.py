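"""Phase-based functional connectivity features per epoch.

For each channel the analytic signal ``z(t) = x(t) + i*H[x](t)`` is built
with the discrete (frequency-domain) Hilbert transform, giving the
instantaneous amplitude ``A(t) = |z(t)|`` and phase ``phi(t) = arg z(t)``.
Three pairwise metrics are supported:

* **PLI** (phase lag index): ``|mean(sign(wrap(phi_i - phi_j)))|`` with
  ``sign(0) = 0`` and the difference wrapped to (-pi, pi]. Insensitive to
  zero-lag (volume-conduction) coupling; ranges over [0, 1].
* **PC** (phase correlation): the Pearson product-moment correlation of
  the two wrapped instantaneous-phase series; ranges over [-1, 1].
* **Pearson**: plain Pearson correlation of the band-passed signals.

Per-epoch metrics fill a symmetric channels-by-channels adjacency matrix
whose strict upper triangle vectorizes into a brain-connectivity feature
(BCF) vector of length ``nc(nc-1)/2``.

The phase is taken from the four-quadrant arctangent of ``(H[x], x)``: a
two-quadrant ratio form loses the sign of the signal and breaks phase
continuity, so the four-quadrant form is the one used throughout.
Phases are used wrapped; an ``unwrap`` switch exists on
``phase_correlation`` because unwrapping genuinely changes the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

METRICS = ("pc", "pearson", "pli")


class DegenerateSignalError(ValueError):
    """Raised when a metric is undefined (zero-variance or zero signal)."""


@dataclass
class AnalyticDecomposition:
    """Instantaneous amplitude and phase of one or more channels."""

    amplitude: np.ndarray  # >= 0, same shape as the input
    phase: np.ndarray  # wrapped to (-pi, pi]


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi] (four-quadrant arctangent construction).

    The arctan2 form keeps the sign of arbitrarily small angles exact,
    which a modulo-based wrap destroys near the branch cut.
    """
    dphi = np.asarray(dphi, dtype=float)
    return np.arctan2(np.sin(dphi), np.cos(dphi))


def analytic_signal(x: np.ndarray, axis: int = -1) -> AnalyticDecomposition:
    """Discrete analytic-signal decomposition along ``axis``.

    Uses the frequency-domain construction (one-sided spectrum doubling)
    on the raw epoch, without padding; edge effects over a few cycles at
    each end are accepted for the 625-sample epochs this package targets.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise DegenerateSignalError("input must be non-empty and finite")
    if np.all(np.ptp(x, axis=axis) == 0) and np.all(x == 0):
        raise DegenerateSignalError(
            "all-zero signal: instantaneous phase is undefined (0/0)"
        )
    z = hilbert(x, axis=axis)
    return AnalyticDecomposition(amplitude=np.abs(z), phase=np.angle(z))


def pli(phi_i: np.ndarray, phi_j: np.ndarray) -> float:
    """Phase lag index of two equal-length phase series."""
    phi_i = np.asarray(phi_i, dtype=float)
    phi_j = np.asarray(phi_j, dtype=float)
    if phi_i.shape != phi_j.shape:
        raise ValueError("phase series must have equal length")
    dphi = wrap_phase(phi_i - phi_j)
    return float(np.abs(np.mean(np.sign(dphi))))


def phase_correlation(phi_i: np.ndarray, phi_j: np.ndarray, unwrap: bool = False) -> float:
    """Pearson correlation of two instantaneous-phase series.

    Population (divide-by-N) moments are used consistently in the
    covariance and the variances; the ratio is invariant to that choice.
    """
    phi_i = np.asarray(phi_i, dtype=float)
    phi_j = np.asarray(phi_j, dtype=float)
    if phi_i.shape != phi_j.shape:
        raise ValueError("phase series must have equal length")
    if unwrap:
        phi_i = np.unwrap(phi_i)
        phi_j = np.unwrap(phi_j)
    return _pearson(phi_i, phi_j, what="phase")


def pearson(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Pearson correlation of two signal series."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("series must have equal length")
    return _pearson(x_i, x_j, what="signal")


def _pearson(a: np.ndarray, b: np.ndarray, what: str) -> float:
    da = a - a.mean()
    db = b - b.mean()
    va = np.mean(da * da)
    vb = np.mean(db * db)
    if va == 0 or vb == 0:
        raise DegenerateSignalError(f"zero-variance {what} series")
    return float(np.mean(da * db) / np.sqrt(va * vb))


@dataclass
class ConnectivityMatrix:
    """Symmetric per-epoch adjacency over channels for one metric."""

    values: np.ndarray  # (nc, nc)
    metric: str
    montage: tuple[str, ...] = ()

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def adjacency(epoch: np.ndarray, metric: str, montage=None) -> ConnectivityMatrix:
    """Fill the symmetric adjacency matrix of one (channels, samples) epoch.

    Each unordered pair is computed once; the diagonal is 1 for the
    correlation metrics and 0 for the PLI.
    """
    metric = metric.lower()
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    epoch = np.asarray(epoch, dtype=float)
    nc = epoch.shape[0]
    montage = tuple(montage) if montage is not None else tuple(
        f"CH{i:02d}" for i in range(1, nc + 1)
    )
    variances = epoch.var(axis=1)
    for c in np.flatnonzero(variances == 0):
        raise DegenerateSignalError(
            f"channel {montage[c]!r} has zero variance; metric undefined"
        )

    if metric in ("pc", "pli"):
        series = analytic_signal(epoch, axis=1).phase
    else:
        series = epoch

    out = np.zeros((nc, nc))
    for i in range(nc):
        for j in range(i + 1, nc):
            if metric == "pli":
                v = pli(series[i], series[j])
            elif metric == "pc":
                v = phase_correlation(series[i], series[j])
            else:
                v = pearson(series[i], series[j])
            out[i, j] = out[j, i] = v
    if metric in ("pc", "pearson"):
        np.fill_diagonal(out, 1.0)
    return ConnectivityMatrix(values=out, metric=metric, montage=montage)


@dataclass
class BCFVector:
    """Vectorized strict upper triangle of a connectivity matrix."""

    values: np.ndarray  # length nc(nc-1)/2
    pairs: tuple[tuple[int, int], ...]  # (i, j) with i < j, row-major
    metric: str
    montage: tuple[str, ...] = ()

    @property
    def pair_labels(self) -> tuple[tuple[str, str], ...]:
        return tuple((self.montage[i], self.montage[j]) for i, j in self.pairs)


def vectorize_upper(matrix: ConnectivityMatrix) -> BCFVector:
    """Strict upper triangle in row-major order; the pair map is recorded."""
    m = matrix.values
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectivity matrix must be square")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return BCFVector(
        values=m[iu, ju].copy(),
        pairs=tuple(zip(iu.tolist(), ju.tolist())),
        metric=matrix.metric,
        montage=matrix.montage,
    )


def fold_upper(vec: BCFVector, diagonal: float = 0.0) -> np.ndarray:
    """Re-fold a BCF vector into the symmetric matrix it came from."""
    n = int(round((1 + np.sqrt(1 + 8 * len(vec.values))) / 2))
    out = np.full((n, n), diagonal, dtype=float)
    for (i, j), v in zip(vec.pairs, vec.values):
        out[i, j] = out[j, i] = v
    return out


def bcf_features(epoch_set, metric: str):
    """Per-epoch BCF vectors for an :class:`~mibci.preprocess.EpochSet`.

    Returns a :class:`~mibci.features.FeatureMatrix` whose columns are
    tagged ``bcf:<metric>:<ch_i>-<ch_j>``.
    """
    from .features import FeatureMatrix

    rows = []
    pairs = None
    for k in range(epoch_set.n_epochs):
        vec = vectorize_upper(adjacency(epoch_set.epoch(k), metric, epoch_set.montage))
        rows.append(vec.values)
        pairs = vec.pair_labels
    tags = [f"bcf:{metric}:{a}-{b}" for a, b in pairs]
    return FeatureMatrix(
        values=np.asarray(rows), tags=tags, labels=np.asarray(epoch_set.labels)
    )


def zscore_matrix(matrix: np.ndarray) -> np.ndarray:
    """Standardize the off-diagonal entries of one adjacency matrix.

    The mean and (population) standard deviation are taken over the
    off-diagonal values only; the diagonal is set to 0.
    """
    m = np.asarray(matrix, dtype=float)
    mask = ~np.eye(m.shape[0], dtype=bool)
    vals = m[mask]
    sd = vals.std()
    if sd == 0:
        raise DegenerateSignalError("zero variance within connectivity matrix")
    out = np.zeros_like(m)
    out[mask] = (vals - vals.mean()) / sd
    return out


def zscore_grand_average(matrices_by_class: dict[str, list]) -> dict[str, np.ndarray]:
    """Per-class grand averages of per-epoch Z-scored adjacency matrices.

    Each epoch's matrix is standardized over its off-diagonal entries,
    then the standardized matrices are averaged across epochs within the
    class. Class differences are plain elementwise subtractions of the
    returned averages (see :func:`class_difference`).
    """
    out = {}
    for cls, mats in matrices_by_class.items():
        if len(mats) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 epochs")
        arrs = [
            zscore_matrix(m.values if isinstance(m, ConnectivityMatrix) else m)
            for m in mats
        ]
        out[cls] = np.mean(arrs, axis=0)
    return out


def class_difference(averages: dict[str, np.ndarray], a: str, b: str) -> np.ndarray:
    """Elementwise difference of two class-average connectivity matrices."""
    return averages[a] - averages[b]


def edge_list(matrix: ConnectivityMatrix) -> list[tuple[str, str, float]]:
    """Plain-text-friendly (channel_i, channel_j, value) edge list."""
    vec = vectorize_upper(matrix)
    return [
        (a, b, float(v)) for (a, b), v in zip(vec.pair_labels, vec.values)
    ]
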