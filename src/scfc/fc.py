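"""Functional connectivity measures.

Four families of measures over region-level BOLD time series:

- cFC: Pearson correlation per region pair,
- mFC: mutual information per pair, estimated with the Kraskov
  k-nearest-neighbor estimator (nats),
- CT3: 3-way total correlation per region triplet, same estimator family,
- dynamic FC: Pearson correlation over non-overlapping windows,
  concatenated in temporal order.

Under a multivariate Gaussian process the information measures have closed
forms in the correlations: ``I(X_i, X_j) = -1/2 ln(1 - rho_ij^2)`` and, for
triplets, ``-1/2 ln det R`` of the 3x3 correlation matrix.  These closed
forms serve both as fast approximations and as oracles for the kNN
estimators on Gaussian data.

All vectorizations use the canonical lexicographic order over pairs
``(i, j), i < j`` or triplets ``(i, j, k), i < j < k``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from ._ksg import ksg_counts
from .atlas import RegionAtlas
from .errors import DomainError

#: documented tolerance for small negative kNN information estimates
NEGATIVE_MI_TOLERANCE = 0.1

#: triplet count above which ct3() requires an explicit opt-in
CT3_GATE_TRIPLETS = 100_000


@dataclass
class BOLDRun:
    """Regions x timepoints BOLD signal with its sampling interval.

    ``tr`` is the sampling interval in seconds (default 3.29 s);
    ``gsr_applied`` records whether the global mean signal has been
    regressed out.
    """

    values: np.ndarray
    tr: float = 3.29
    gsr_applied: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("values must be 2-D with at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityVector:
    """A flattened connectivity pattern with a canonical index order.

    ``index`` lists the region pairs (or triplets) in lexicographic order;
    for dynamic FC the pair index repeats per window and ``window_size``
    records the window length in samples.
    """

    values: np.ndarray
    index: np.ndarray
    measure: str
    n_regions: int
    window_size: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.index):
            raise ValueError("values and index must have equal length")

    @property
    def n_windows(self) -> int:
        base = len(pair_index(self.n_regions)) if self.index.shape[1] == 2 else len(self.index)
        return len(self.values) // base if self.measure == "dynFC" else 1


def pair_index(n: int) -> np.ndarray:
    """Lexicographic (i, j), i < j pairs as an (C(n,2), 2) array."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def triplet_index(n: int) -> np.ndarray:
    """Lexicographic (i, j, k), i < j < k triplets as an (C(n,3), 3) array."""
    return np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 3)),
        dtype=np.int64,
    ).reshape(-1, 3)


def vectorize_upper(
    matrix: np.ndarray,
    atlas: RegionAtlas | None = None,
    subset: str = "all",
    measure: str = "cFC",
) -> ConnectivityVector:
    """Flatten the strict upper triangle in lexicographic pair order.

    ``subset="intrahemispheric"`` keeps only pairs within one hemisphere
    (requires an atlas).
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("matrix must be square")
    idx = pair_index(n)
    vals = m[idx[:, 0], idx[:, 1]]
    if subset == "intrahemispheric":
        if atlas is None:
            raise ValueError("intrahemispheric subset requires an atlas")
        codes = atlas.hemisphere_codes()
        keep = codes[idx[:, 0]] == codes[idx[:, 1]]
        idx, vals = idx[keep], vals[keep]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    return ConnectivityVector(values=vals, index=idx, measure=measure, n_regions=n)


def unvectorize(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from a pair vectorization."""
    out = np.zeros((n, n))
    out[index[:, 0], index[:, 1]] = values
    out[index[:, 1], index[:, 0]] = values
    return out


def global_signal_regression(bold: BOLDRun) -> BOLDRun:
    """Regress the across-region mean series out of every region.

    Each region's series is replaced by the residual of its least-squares
    regression on (intercept, global mean).  Idempotent up to numerical
    tolerance; residuals are exactly uncorrelated with the global mean.  A
    constant global signal degrades to intercept-only removal with a
    warning.
    """
    x = bold.values
    g = x.mean(axis=0)
    if np.ptp(g) == 0.0:
        warnings.warn("global signal is constant; removing region means only")
        resid = x - x.mean(axis=1, keepdims=True)
    else:
        design = np.column_stack([np.ones_like(g), g])
        beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        resid = x - (design @ beta).T
    return BOLDRun(values=resid, tr=bold.tr, gsr_applied=True)


def pearson_fc(bold: BOLDRun, on_constant: str = "raise") -> np.ndarray:
    """Pairwise Pearson correlation matrix of the region time courses.

    A zero-variance region makes the coefficient undefined; by default this
    raises.  ``on_constant="zero"`` instead sets the affected entries to 0
    (the documented drop-region alternative).
    """
    x = bold.values
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        if on_constant == "raise":
            raise ValueError(f"zero-variance region(s) {bad.tolist()}; correlation undefined")
        if on_constant != "zero":
            raise ValueError(f"unknown on_constant {on_constant!r}")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x)
    if np.any(sd == 0):
        r[np.isnan(r)] = 0.0
        np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def gaussian_mi(rho):
    """Closed-form mutual information of a bivariate Gaussian, in nats."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise DomainError("|rho| must be < 1")
    out = -0.5 * np.log1p(-(r**2))
    return float(out) if np.isscalar(rho) else out


def gaussian_ct3(rho_ij: float, rho_jk: float, rho_ik: float) -> float:
    """Closed-form 3-way total correlation of a trivariate Gaussian, in nats.

    ``-1/2 ln det R`` via the expanded determinant
    ``1 + 2 r_ij r_jk r_ik - (r_ij^2 + r_jk^2 + r_ik^2)``.
    """
    det = 1.0 + 2.0 * rho_ij * rho_jk * rho_ik - (rho_ij**2 + rho_jk**2 + rho_ik**2)
    if det <= 0:
        raise DomainError("correlation triple is not positive definite")
    return -0.5 * float(np.log(det))


def _ksg_multiinfo(data: np.ndarray, k: int) -> float:
    d, n = data.shape
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples, got k={k}, n={n}")
    counts = ksg_counts(np.ascontiguousarray(data, dtype=np.float64), k)
    return float(digamma(k) + (d - 1) * digamma(n) - np.mean(np.sum(digamma(counts + 1), axis=1)))


def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 4) -> float:
    """Kraskov kNN mutual information estimate (algorithm 1), in nats.

    Deterministic given the inputs; small negative values are a known
    artifact of the estimator and are not clipped.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    return _ksg_multiinfo(np.vstack([x, y]), k)


def knn_total_correlation(columns: np.ndarray, k: int = 4) -> float:
    """Kraskov-type total correlation of d jointly sampled variables."""
    return _ksg_multiinfo(np.asarray(columns, dtype=float), k)


def mi_fc(bold: BOLDRun, k: int = 4) -> ConnectivityVector:
    """Mutual-information FC: kNN MI for every region pair."""
    x = bold.values
    idx = pair_index(bold.n_regions)
    vals = np.empty(len(idx))
    for p, (i, j) in enumerate(idx):
        vals[p] = _ksg_multiinfo(x[[i, j]], k)
    return ConnectivityVector(values=vals, index=idx, measure="mFC", n_regions=bold.n_regions)


def ct3(bold: BOLDRun, k: int = 4, allow_large: bool = False) -> ConnectivityVector:
    """3-way total correlation for every region triplet.

    The triplet count grows as C(n, 3); above 100 000 triplets the kNN sweep
    is the pipeline's cost hotspot and requires ``allow_large=True``.
    """
    n = bold.n_regions
    n_triplets = n * (n - 1) * (n - 2) // 6
    if n_triplets > CT3_GATE_TRIPLETS and not allow_large:
        raise ValueError(
            f"{n_triplets} triplets at n={n}; pass allow_large=True to run the full sweep"
        )
    x = bold.values
    idx = triplet_index(n)
    vals = np.empty(len(idx))
    for p, (i, j, kk) in enumerate(idx):
        vals[p] = _ksg_multiinfo(x[[i, j, kk]], k)
    return ConnectivityVector(values=vals, index=idx, measure="CT3", n_regions=n)


def dynamic_fc(bold: BOLDRun, window_size: int, truncate: bool = False) -> ConnectivityVector:
    """Windowed Pearson FC over non-overlapping windows, concatenated.

    ``window_size`` must divide the run length unless ``truncate=True``, in
    which case the tail remainder is dropped.
    """
    T = bold.n_timepoints
    if window_size < 2:
        raise ValueError("window_size must be at least 2 samples")
    if T % window_size != 0 and not truncate:
        raise ValueError(
            f"window_size {window_size} does not divide run length {T}; "
            "pass truncate=True to drop the tail"
        )
    n_windows = T // window_size
    if n_windows < 1:
        raise ValueError("run shorter than one window")
    idx = pair_index(bold.n_regions)
    chunks = []
    for w in range(n_windows):
        seg = BOLDRun(
            values=bold.values[:, w * window_size : (w + 1) * window_size],
            tr=bold.tr,
            gsr_applied=bold.gsr_applied,
        )
        chunks.append(vectorize_upper(pearson_fc(seg)).values)
    return ConnectivityVector(
        values=np.concatenate(chunks),
        index=np.tile(idx, (n_windows, 1)),
        measure="dynFC",
        n_regions=bold.n_regions,
        window_size=window_size,
    )
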