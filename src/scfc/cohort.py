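"""Synthetic multi-subject connectome cohorts.

The empirical finding this generator emulates is that individual structural
connectomes differ from a shared core mostly by a global multiplicative
constant: each subject's SC is the common ground-truth matrix times a
lognormal gain, plus symmetric entrywise noise, thresholded at 0.001.
Diffusion-imaging false negatives are emulated by independently deleting
interhemispheric links.  A separate helper plants exact low-rank structure
in a feature-by-subject matrix for validating the subspace analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from ._rng import OP_DEGRADE, OP_GROUND_TRUTH, OP_PLANTED, OP_SUBJECT, substream
from .atlas import RegionAtlas, generate_atlas
from .subspace import DataMatrix

#: default threshold applied to subject-level SC, mirroring tractography practice
SC_THRESHOLD = 0.001


@dataclass
class SCMatrix:
    """Symmetric nonnegative weighted connectome with zero diagonal.

    ``weights[r, s]`` is the structural connectivity index between regions
    ``r`` and ``s``; there are no self-connections.  When
    ``threshold_applied > 0`` every surviving nonzero entry is at least that
    threshold.
    """

    weights: np.ndarray
    atlas: RegionAtlas
    threshold_applied: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        n = self.atlas.n_regions
        if w.shape != (n, n):
            raise ValueError(f"weights must be {n}x{n} to match the atlas")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if self.threshold_applied > 0:
            nz = w[w > 0]
            if nz.size and nz.min() < self.threshold_applied - 1e-15:
                raise ValueError("nonzero entries below the applied threshold")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.atlas.n_regions


@dataclass
class CohortSpec:
    """Parameters of a synthetic subject cohort.

    ``gain_sd`` is the log-sd of the per-subject multiplicative gain,
    ``noise_sd`` the sd of the symmetric additive entry noise, and
    ``interhemispheric_miss_rate`` the probability that a true
    interhemispheric link goes undetected.
    """

    n_subjects: int = 21
    gain_sd: float = 0.2
    noise_sd: float = 5e-4
    interhemispheric_miss_rate: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.gain_sd <= 0 or self.noise_sd < 0:
            raise ValueError("gain_sd must be > 0 and noise_sd >= 0")
        if not 0.0 <= self.interhemispheric_miss_rate <= 1.0:
            raise ValueError("interhemispheric_miss_rate must be in [0, 1]")


def _symmetrize_upper(n: int, upper_values: np.ndarray, iu) -> np.ndarray:
    m = np.zeros((n, n))
    m[iu] = upper_values
    return m + m.T


def generate_ground_truth_sc(
    atlas: RegionAtlas,
    density_intra: float = 0.35,
    density_inter: float = 0.02,
    homotopic_weight: float = 0.02,
    weight_log_sd: float = 0.8,
    weight_scale: float = 0.01,
    seed: int = 0,
    max_tries: int = 200,
) -> SCMatrix:
    """Sample a shared ground-truth SC matrix.

    Within-hemisphere pairs are connected with probability ``density_intra``
    and across hemispheres with ``density_inter``; nonzero weights are
    lognormal with median ``weight_scale`` and log-sd ``weight_log_sd``.
    Every homotopic pair receives exactly ``homotopic_weight`` (possibly 0).
    The two intra-hemispheric subgraphs are resampled until connected.
    """
    for p, name in ((density_intra, "density_intra"), (density_inter, "density_inter")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
    if homotopic_weight < 0:
        raise ValueError("homotopic_weight must be nonnegative")
    if weight_log_sd <= 0:
        raise ValueError("weight_log_sd must be positive")
    rng = substream(seed, OP_GROUND_TRUTH)
    n = atlas.n_regions
    codes = atlas.hemisphere_codes()
    iu = np.triu_indices(n, k=1)
    intra_pair = codes[iu[0]] == codes[iu[1]]
    pair_of = np.asarray(atlas.homotopic_pair)
    homotopic = pair_of[iu[0]] == iu[1]

    for _ in range(max_tries):
        dens = np.where(intra_pair, density_intra, density_inter)
        present = rng.random(len(dens)) < dens
        logw = rng.normal(np.log(weight_scale), weight_log_sd, len(dens))
        vals = np.where(present, np.exp(logw), 0.0)
        vals[homotopic] = homotopic_weight
        w = _symmetrize_upper(n, vals, iu)
        if _hemispheres_connected(w, codes):
            return SCMatrix(weights=w, atlas=atlas, threshold_applied=0.0)
    raise RuntimeError(
        f"could not sample connected intra-hemispheric subgraphs in {max_tries} tries; "
        "increase density_intra"
    )


def _hemispheres_connected(w: np.ndarray, codes: np.ndarray) -> bool:
    for side in (0, 1):
        idx = np.where(codes == side)[0]
        block = w[np.ix_(idx, idx)]
        n_comp, _ = connected_components(block > 0, directed=False)
        if n_comp != 1:
            return False
    return True


def generate_subject_sc(gt: SCMatrix, spec: CohortSpec, subject_index: int) -> SCMatrix:
    """One subject's SC: global gain times the core, plus noise, thresholded.

    The gain is ``exp(N(0, gain_sd^2))`` drawn reproducibly from
    ``(spec.seed, subject_index)``; symmetric zero-diagonal Gaussian noise of
    sd ``noise_sd`` is added, negatives are clipped to 0, and entries below
    0.001 are zeroed (measure first, then threshold).
    """
    rng = substream(spec.seed, OP_SUBJECT, subject_index)
    gain = float(np.exp(rng.normal(0.0, spec.gain_sd)))
    n = gt.n_regions
    iu = np.triu_indices(n, k=1)
    noise = rng.normal(0.0, spec.noise_sd, len(iu[0])) if spec.noise_sd > 0 else np.zeros(len(iu[0]))
    w = gain * gt.weights + _symmetrize_upper(n, noise, iu)
    w = np.clip(w, 0.0, None)
    w[w < SC_THRESHOLD] = 0.0
    return SCMatrix(weights=w, atlas=gt.atlas, threshold_applied=SC_THRESHOLD)


def degrade_sc(sc: SCMatrix, interhemispheric_miss_rate: float, seed: int = 0) -> SCMatrix:
    """Emulate tractography false negatives on interhemispheric links.

    Each nonzero interhemispheric entry is independently zeroed with the
    given probability; the decision is made per unordered pair so symmetry
    is preserved.  Intrahemispheric entries are untouched.
    """
    if not 0.0 <= interhemispheric_miss_rate <= 1.0:
        raise ValueError("interhemispheric_miss_rate must be in [0, 1]")
    rng = substream(seed, OP_DEGRADE)
    w = sc.weights.copy()
    codes = sc.atlas.hemisphere_codes()
    iu = np.triu_indices(sc.n_regions, k=1)
    inter = codes[iu[0]] != codes[iu[1]]
    drop = (rng.random(len(iu[0])) < interhemispheric_miss_rate) & inter
    w[iu[0][drop], iu[1][drop]] = 0.0
    w[iu[1][drop], iu[0][drop]] = 0.0
    return SCMatrix(weights=w, atlas=sc.atlas, threshold_applied=sc.threshold_applied)


def generate_cohort(
    atlas_or_n: RegionAtlas | int,
    spec: CohortSpec,
    gt: SCMatrix | None = None,
    **gt_kwargs,
) -> tuple[SCMatrix, list[SCMatrix]]:
    """Convenience wrapper: ground truth plus ``n_subjects`` subject SCs."""
    atlas = atlas_or_n if isinstance(atlas_or_n, RegionAtlas) else generate_atlas(atlas_or_n)
    if gt is None:
        gt = generate_ground_truth_sc(atlas, seed=spec.seed, **gt_kwargs)
    subjects = [generate_subject_sc(gt, spec, i) for i in range(spec.n_subjects)]
    return gt, subjects


def _spread_loadings(m: int, rank: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal subject loadings with near-uniform magnitude.

    The first component loads every subject equally (the shared-core
    structure the cohort model emulates); later components start from random
    sign patterns and are Gram-Schmidt orthogonalized.  Even loadings are
    what make subject-bootstrap singular values tight: resampling subjects
    then barely changes a component's captured energy.
    """
    v = np.empty((m, rank))
    v[:, 0] = 1.0 / np.sqrt(m)
    for i in range(1, rank):
        while True:
            x = rng.choice([-1.0, 1.0], m) / np.sqrt(m)
            for j in range(i):
                x = x - (x @ v[:, j]) * v[:, j]
            norm = np.linalg.norm(x)
            if norm > 1e-6:
                v[:, i] = x / norm
                break
    return v


def planted_lowrank_dataset(
    n_features: int,
    n_observations: int,
    rank: int,
    variance_fractions,
    noise_sd: float,
    seed: int = 0,
) -> DataMatrix:
    """Plant exact low-rank structure plus i.i.d. Gaussian noise.

    ``X = sum_i s_i u_i v_i^T + E`` with orthonormal ``u_i``, ``v_i``.  The
    singular values are sized so that, counting the expected noise energy
    ``noise_sd^2 * n_features * n_observations`` in the total sum of squares,
    component ``i`` is expected to capture ``variance_fractions[i]`` of it.
    With zero noise the fractions are renormalized to sum to 1.
    Ground truth is recorded in ``extra``.
    """
    fracs = np.asarray(variance_fractions, dtype=float)
    if rank < 1 or len(fracs) != rank:
        raise ValueError("variance_fractions must have one entry per planted component")
    if np.any(fracs <= 0):
        raise ValueError("variance fractions must be positive")
    if fracs.sum() > 1.0 + 1e-12:
        raise ValueError(f"variance fractions must sum to <= 1, got {fracs.sum():.4f}")
    if rank > min(n_features, n_observations):
        raise ValueError("rank exceeds matrix dimensions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = substream(seed, OP_PLANTED)
    u, _ = np.linalg.qr(rng.normal(size=(n_features, rank)))
    v = _spread_loadings(n_observations, rank, rng)
    noise_energy = noise_sd**2 * n_features * n_observations
    leftover = 1.0 - fracs.sum()
    if noise_sd > 0 and leftover > 1e-12:
        total = noise_energy / leftover
    else:
        # scale is arbitrary; fractions are renormalized over the signal
        total = float(n_features * n_observations)
        fracs = fracs / fracs.sum()
    s = np.sqrt(fracs * total)
    X = (u * s) @ v.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    subjects = [f"s{j:02d}" for j in range(n_observations)]
    return DataMatrix(
        X=X,
        subject_ids=subjects,
        source_tags=["planted"] * n_observations,
        extra={
            "planted_rank": rank,
            "planted_fractions": fracs.copy(),
            "planted_singular_values": s.copy(),
            "noise_sd": noise_sd,
        },
    )
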