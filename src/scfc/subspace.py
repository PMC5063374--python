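"""Bootstrap SVD subspace analysis.

The statistical engine of the package: uncentered SVD of feature-by-subject
data matrices, bootstrap-over-subjects confidence intervals on the singular
values, a reproducible-dimension rule based on CI separation, average
projections that characterize each reproducible dimension, permutation
controls that destroy anatomical label structure, and helpers for pooling
empirical with model-generated connectivity patterns.

The SVD is deliberately uncentered: the dominant structure of interest is a
common positive core whose subject-to-subject variation is a global
multiplicative constant, and centering would subtract it.  Variance
fractions are therefore shares of the raw (uncentered) sum of squares,
``s_i^2 / sum_j s_j^2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import OP_BOOTSTRAP, OP_PERMUTE, substream
from .atlas import RegionAtlas

logger = logging.getLogger(__name__)


@dataclass
class DataMatrix:
    """Feature-by-observation matrix with per-column subject and source tags.

    Columns are subjects (or subject-condition combinations); features are
    connectivity coefficients or flattened BOLD samples.  ``subject_ids``
    drive bootstrap resampling: all columns sharing a subject id move
    together in a replicate.
    """

    X: np.ndarray
    subject_ids: list[str]
    source_tags: list[str]
    feature_meta: object = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (features x observations)")
        m = self.X.shape[1]
        if len(self.subject_ids) != m or len(self.source_tags) != m:
            raise ValueError("subject_ids and source_tags must have one entry per column")
        if any(not s for s in self.subject_ids):
            raise ValueError("subject ids must be non-empty")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_observations(self) -> int:
        return self.X.shape[1]

    def subjects(self) -> list[str]:
        """Distinct subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s)
        return list(seen)


@dataclass
class BootstrapSVDResult:
    """Full-data SVD plus bootstrap summaries.

    ``reproducible_dim`` counts the leading singular values whose bootstrap
    confidence intervals are separated from the next one; ``avg_projections``
    holds, per reproducible dimension, the feature-space pattern
    ``(mean_j u_i^T x_j) u_i``.
    """

    singular_values: np.ndarray
    variance_fractions: np.ndarray
    left_vectors: np.ndarray  # n x m, sign-aligned (mean entry of each >= 0)
    right_vectors: np.ndarray  # m x m
    ci_low: np.ndarray
    ci_high: np.ndarray
    reproducible_dim: int
    B: int
    alpha: float
    avg_projections: list[np.ndarray]
    boot_fraction_mean: np.ndarray
    boot_fraction_sd: np.ndarray
    boot_sv_mean: np.ndarray
    boot_sv_sd: np.ndarray
    n_redrawn: int = 0

    def summary(self) -> dict:
        d = self.reproducible_dim
        return {
            "reproducible_dim": int(d),
            "variance_fraction": [float(f) for f in self.variance_fractions[: max(d, 3)]],
            "boot_fraction_mean": [float(f) for f in self.boot_fraction_mean[: max(d, 3)]],
            "boot_fraction_sd": [float(f) for f in self.boot_fraction_sd[: max(d, 3)]],
        }


def _orient(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign ambiguity: orient each component so that the average
    projection of the data onto it is nonnegative.

    The mean coefficient of ``u_i`` over columns is ``s_i * mean(v_i)``, so
    the sign of ``mean(v_i)`` decides; ties fall back to the mean entry of
    ``u_i``.  This keeps ``u_1`` pointing toward the data's common core even
    when that core has negative mean in feature space (as it does after
    global-signal regression)."""
    vmean = v.mean(axis=0)
    umean = u.mean(axis=0)
    signs = np.where(vmean != 0, np.sign(vmean), np.where(umean >= 0, 1.0, -1.0))
    return u * signs, v * signs


def svd_variance(X: np.ndarray | DataMatrix):
    """Uncentered SVD with variance fractions.

    Returns ``(singular_values, variance_fractions, left_vectors,
    right_vectors)``; fractions are ``s_i^2 / sum_j s_j^2`` and sum to 1.
    """
    A = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("data matrix contains non-finite values")
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    u, v = _orient(u, vt.T)
    total = np.sum(s**2)
    fracs = s**2 / total if total > 0 else np.zeros_like(s)
    return s, fracs, u, v


def reproducible_dimension(ci_low, ci_high, rule: str = "contiguous") -> int:
    """Number of leading dimensions with separated singular-value CIs.

    Two consecutive intervals are separated when they do not overlap.  Under
    the default ``contiguous`` rule, ``d`` is the largest index such that the
    separation holds for every ``i <= d``; under ``last`` it is the last
    index at which separation holds, regardless of earlier overlaps.
    """
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    if lo.shape != hi.shape or lo.ndim != 1:
        raise ValueError("ci_low and ci_high must be 1-D of equal length")
    m = len(lo)
    separated = [
        (lo[i] > hi[i + 1]) or (lo[i + 1] > hi[i])  # disjoint intervals
        for i in range(m - 1)
    ]
    if rule == "contiguous":
        d = 0
        for sep in separated:
            if not sep:
                break
            d += 1
        return d
    if rule == "last":
        idx = [i + 1 for i, sep in enumerate(separated) if sep]
        return idx[-1] if idx else 0
    raise ValueError(f"unknown rule {rule!r}")


def average_projection(
    dm: DataMatrix, u: np.ndarray, source_filter: str | None = None
) -> np.ndarray:
    """Feature-space pattern ``(mean_j u^T x_j) u`` over selected columns.

    ``source_filter`` restricts the averaged columns to one source tag (used
    to characterize the second pooled dimension from empirical data only).
    Averaging and projection commute, so this equals the projection of the
    column mean.
    """
    if source_filter is None:
        cols = np.ones(dm.n_observations, dtype=bool)
    else:
        cols = np.array([t == source_filter for t in dm.source_tags])
        if not cols.any():
            raise ValueError(f"no columns with source tag {source_filter!r}")
    coeff = float(np.mean(u @ dm.X[:, cols]))
    return coeff * u


def bootstrap_svd(
    dm: DataMatrix,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    rule: str = "contiguous",
) -> BootstrapSVDResult:
    """Bootstrap-over-subjects SVD with percentile CIs on singular values.

    Each replicate resamples the distinct subject ids with replacement and
    keeps all columns of every sampled subject (a subject drawn twice
    contributes its columns twice).  Replicates collapsing onto a single
    subject are redrawn.  Singular values are ranked within each replicate;
    percentile intervals at level ``1 - alpha`` feed the reproducible-
    dimension rule.
    """
    subjects = dm.subjects()
    if len(subjects) < 3:
        raise ValueError("bootstrap requires at least 3 distinct subjects")
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; CIs will be noisy")
    cols_of = {s: np.where(np.array(dm.subject_ids) == s)[0] for s in subjects}
    counts = {len(c) for c in cols_of.values()}
    if len(counts) != 1:
        raise ValueError("all subjects must contribute the same number of columns")

    s_full, fracs_full, u_full, v_full = svd_variance(dm)
    m = len(s_full)

    rng = substream(seed, OP_BOOTSTRAP)
    n_subj = len(subjects)
    boot_s = np.empty((B, m))
    boot_f = np.empty((B, m))
    n_redrawn = 0
    for b in range(B):
        while True:
            draw = rng.integers(0, n_subj, n_subj)
            if len(np.unique(draw)) > 1:
                break
            n_redrawn += 1
        cols = np.concatenate([cols_of[subjects[i]] for i in draw])
        sb = np.linalg.svd(dm.X[:, cols], compute_uv=False)[:m]
        boot_s[b] = sb
        boot_f[b] = sb**2 / np.sum(sb**2)
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)

    lo = np.percentile(boot_s, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_s, 100 * (1 - alpha / 2), axis=0)
    d = reproducible_dimension(lo, hi, rule=rule)
    projections = [average_projection(dm, u_full[:, i]) for i in range(d)]

    return BootstrapSVDResult(
        singular_values=s_full,
        variance_fractions=fracs_full,
        left_vectors=u_full,
        right_vectors=v_full,
        ci_low=lo,
        ci_high=hi,
        reproducible_dim=d,
        B=B,
        alpha=alpha,
        avg_projections=projections,
        boot_fraction_mean=boot_f.mean(axis=0),
        boot_fraction_sd=boot_f.std(axis=0, ddof=1),
        boot_sv_mean=boot_s.mean(axis=0),
        boot_sv_sd=boot_s.std(axis=0, ddof=1),
        n_redrawn=n_redrawn,
    )


def permute_dataset(
    matrices: Sequence[np.ndarray],
    atlas: RegionAtlas,
    mode: str,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
    permutations: Sequence[np.ndarray] | None = None,
) -> DataMatrix:
    """Destroy label structure in per-subject connectivity matrices.

    ``mode``:

    - ``links``: permute the vectorized link entries of each subject,
    - ``regions``: permute region labels, then re-vectorize,
    - ``within_hemisphere``: one permutation of the n/2 left-hemisphere
      labels applied simultaneously to both hemispheres, so homotopic
      pairing is preserved.

    Permutations are drawn independently per subject unless ``permutations``
    supplies them explicitly (a single array is broadcast to all subjects, a
    common permutation, which leaves singular values unchanged).
    """
    from .fc import vectorize_upper  # local import to avoid a cycle

    rng = substream(seed, OP_PERMUTE)
    n = atlas.n_regions
    h = n // 2
    n_links = n * (n - 1) // 2
    if subject_ids is None:
        subject_ids = [f"s{j:02d}" for j in range(len(matrices))]

    def perm_for(j: int) -> np.ndarray:
        if permutations is not None:
            p = permutations if isinstance(permutations, np.ndarray) else permutations[j]
            return np.asarray(p)
        size = {"links": n_links, "regions": n, "within_hemisphere": h}[mode]
        return rng.permutation(size)

    cols = []
    for j, mat in enumerate(matrices):
        p = perm_for(j)
        if mode == "links":
            vec = vectorize_upper(mat, atlas).values
            cols.append(vec[p])
        elif mode in ("regions", "within_hemisphere"):
            if mode == "within_hemisphere":
                full = np.concatenate([p, p + h])
            else:
                full = p
            permuted = np.asarray(mat)[np.ix_(full, full)]
            cols.append(vectorize_upper(permuted, atlas).values)
        else:
            raise ValueError(f"unknown permutation mode {mode!r}")
    return DataMatrix(
        X=np.column_stack(cols),
        subject_ids=list(subject_ids),
        source_tags=[f"permuted_{mode}"] * len(matrices),
        extra={"mode": mode},
    )


def pool_datasets(sources: Sequence[tuple[str, Mapping[str, np.ndarray]]]) -> DataMatrix:
    """Pool per-subject vectors from several sources into one DataMatrix.

    ``sources`` is a list of ``(tag, {subject_id: vector})``.  Columns are
    ordered subject-major (all sources of subject 1, then subject 2, ...),
    preserving subject ids so bootstrap resampling moves a subject's columns
    together.  All sources must cover the same subjects with equal-length
    vectors.
    """
    if not sources:
        raise ValueError("no sources to pool")
    subjects = list(sources[0][1].keys())
    lengths = {len(np.asarray(v)) for _, data in sources for v in data.values()}
    if len(lengths) != 1:
        raise ValueError(f"mismatched feature lengths across sources: {sorted(lengths)}")
    cols, sids, tags = [], [], []
    for subj in subjects:
        for tag, data in sources:
            if subj not in data:
                raise ValueError(f"source {tag!r} missing subject {subj!r}")
            cols.append(np.asarray(data[subj], dtype=float))
            sids.append(subj)
            tags.append(tag)
    return DataMatrix(X=np.column_stack(cols), subject_ids=sids, source_tags=tags)


def residual_fc(
    empirical: Mapping[str, np.ndarray],
    simulated: Mapping[str, Mapping[str, np.ndarray]],
) -> DataMatrix:
    """Empirical minus simulated FC, one column per (subject, model)."""
    cols, sids, tags = [], [], []
    for subj, emp in empirical.items():
        emp = np.asarray(emp, dtype=float)
        for model, data in simulated.items():
            if subj not in data:
                raise ValueError(f"model {model!r} missing subject {subj!r}")
            sim = np.asarray(data[subj], dtype=float)
            if sim.shape != emp.shape:
                raise ValueError("mismatched feature lengths")
            cols.append(emp - sim)
            sids.append(subj)
            tags.append(f"residual_{model}")
    return DataMatrix(X=np.column_stack(cols), subject_ids=sids, source_tags=tags)


def bold_to_datamatrix(runs: Mapping[str, "object"]) -> DataMatrix:
    """Flatten per-subject BOLD runs (regions x timepoints) into columns.

    Flattening is region-major (row-major, C order): the first ``timepoints``
    features are region 0's series.  Use :func:`unflatten_bold` to invert.
    """
    cols, sids = [], []
    shape = None
    for subj, run in runs.items():
        vals = np.asarray(run.values, dtype=float)
        if shape is None:
            shape = vals.shape
        elif vals.shape != shape:
            raise ValueError("all BOLD runs must share the same shape")
        cols.append(vals.ravel(order="C"))
        sids.append(subj)
    dm = DataMatrix(
        X=np.column_stack(cols),
        subject_ids=sids,
        source_tags=["bold"] * len(cols),
        feature_meta=("bold", shape),
    )
    return dm


def unflatten_bold(column: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of the region-major BOLD flattening."""
    return np.asarray(column).reshape(shape, order="C")
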