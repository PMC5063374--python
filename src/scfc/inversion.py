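"""Estimating structural connectivity from functional connectivity.

Proof-of-concept inversion of the SC-FC relationship: the first reproducible
dimension of the SC cohort is log-transformed (``SC' = ln(SC / 0.0001)``
after flooring at 1e-6), its relationship with the first reproducible
dimension of the pooled FC data is fitted by a 4th-order least-squares
polynomial ``FC ~ P4(SC')``, and the fit is inverted numerically on its
dominant monotone branch to map an empirical FC pattern back to
``SC_hat = 0.001 * exp(P4^-1(FC))``.

The printed reference constants differ by a factor of 10 between the
forward transform (0.0001) and the inversion (0.001); both are kept exactly
as given and are independently configurable, so estimates carry that x10
scale unless the caller reconciles the constants deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import SCMatrix
from .errors import MultiBranchError
from .fc import unvectorize, vectorize_upper
from .subspace import DataMatrix, average_projection, bootstrap_svd, pool_datasets

#: defaults exactly as printed in the source method
SC_FLOOR = 1e-6
SC_REF = 1e-4
SC_REF_OUT = 1e-3


def transform_sc(sc_pattern: np.ndarray, floor: float = SC_FLOOR, ref: float = SC_REF):
    """Log-transform an SC pattern, masking sub-floor entries.

    Returns ``(sc_prime, mask)`` where ``mask`` flags the retained entries
    (``value >= floor``) and ``sc_prime = ln(value / ref)`` on those.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if ref <= 0:
        raise ValueError("ref must be positive")
    vals = np.asarray(sc_pattern, dtype=float)
    mask = vals >= floor
    sc_prime = np.log(vals[mask] / ref)
    return sc_prime, mask


@dataclass
class PolynomialMap:
    """Least-squares polynomial map from SC' to FC with inversion metadata."""

    coefficients: np.ndarray  # ascending order, length = order + 1
    fit_domain: tuple[float, float]
    central_interval: tuple[float, float]  # 5th-95th percentile of fitted SC'
    inverse_grid: int = 4096
    residual_rms: float = 0.0
    branch: tuple[float, float] | None = field(default=None)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        a, b = self.fit_domain
        if not a < b:
            raise ValueError("fit_domain must be nondegenerate")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coefficients)

    def derivative_roots_in_domain(self) -> np.ndarray:
        dcoef = np.polynomial.polynomial.polyder(self.coefficients)
        if len(dcoef) <= 1 or np.allclose(dcoef, 0):
            return np.array([])
        roots = np.polynomial.polynomial.polyroots(dcoef)
        real = roots[np.abs(roots.imag) < 1e-10].real
        a, b = self.fit_domain
        return np.sort(real[(real > a) & (real < b)])

    def monotone_branch(self) -> tuple[float, float]:
        """Largest monotone interval covering the central fitted SC' mass.

        Splits the fit domain at the derivative's real roots and picks the
        piece with the largest overlap with the central interval; if no
        piece covers at least half of it, the map has no dominant branch.
        """
        if self.branch is not None:
            return self.branch
        a, b = self.fit_domain
        cuts = self.derivative_roots_in_domain()
        edges = np.concatenate([[a], cuts, [b]])
        lo, hi = self.central_interval
        best, best_cov = None, -1.0
        for left, right in zip(edges[:-1], edges[1:]):
            cov = max(0.0, min(right, hi) - max(left, lo))
            if cov > best_cov:
                best, best_cov = (float(left), float(right)), cov
        central_span = max(hi - lo, 1e-12)
        if best is None or best_cov < 0.5 * central_span:
            raise MultiBranchError(
                "fitted polynomial has no dominant monotone branch over the fit domain; "
                f"turning points at {np.round(cuts, 4).tolist()}",
                turning_points=cuts,
            )
        self.branch = best
        return best


def fit_sc_fc_map(
    sc_prime: np.ndarray, fc_proj: np.ndarray, order: int = 4, inverse_grid: int = 4096
) -> PolynomialMap:
    """Least-squares polynomial fit of the SC' -> FC relationship."""
    x = np.asarray(sc_prime, dtype=float)
    y = np.asarray(fc_proj, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sc_prime and fc_proj must be matched 1-D arrays")
    if len(x) < order + 1:
        raise ValueError(f"need at least {order + 1} points for an order-{order} fit")
    if order == 0:
        coef = np.array([float(y.mean())])
    else:
        # fit in the scaled Polynomial basis for conditioning, convert back
        poly = np.polynomial.Polynomial.fit(x, y, deg=order)
        coef = poly.convert().coef
        if len(coef) < order + 1:
            coef = np.pad(coef, (0, order + 1 - len(coef)))
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    return PolynomialMap(
        coefficients=coef,
        fit_domain=(float(x.min()), float(x.max())),
        central_interval=(float(np.percentile(x, 5)), float(np.percentile(x, 95))),
        inverse_grid=inverse_grid,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def invert_fc(
    fc_pattern: np.ndarray, poly_map: PolynomialMap, ref_out: float = SC_REF_OUT
):
    """Numerically invert the fitted map and exponentiate back to SC scale.

    Each FC value is inverted on the dominant monotone branch by bisection
    (to 1e-10 in SC'); values outside the polynomial's range over the branch
    are clamped to the boundary and flagged.  Returns
    ``(sc_hat, clamped_mask)`` with ``sc_hat = ref_out * exp(SC')``.
    """
    if ref_out <= 0:
        raise ValueError("ref_out must be positive")
    y = np.asarray(fc_pattern, dtype=float)
    a, b = poly_map.monotone_branch()
    fa, fb = float(poly_map(a)), float(poly_map(b))
    increasing = fb >= fa
    ylo, yhi = (fa, fb) if increasing else (fb, fa)
    clamped = (y < ylo) | (y > yhi)
    yc = np.clip(y, ylo, yhi)

    lo = np.full_like(yc, a)
    hi = np.full_like(yc, b)
    # vectorized bisection; 60 halvings reach well below the 1e-10 target
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = poly_map(mid)
        go_right = (fm < yc) if increasing else (fm > yc)
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    sc_prime = 0.5 * (lo + hi)
    return ref_out * np.exp(sc_prime), clamped


@dataclass
class SCEstimate:
    """Result of the FC-inversion pipeline."""

    weights: np.ndarray  # symmetric estimated SC matrix
    pattern: np.ndarray  # vectorized estimate in pair order
    poly_map: PolynomialMap
    extrapolated: np.ndarray  # entries absent from the forward fit
    clamped: np.ndarray  # entries clamped to the map's range
    sc_projection: np.ndarray
    fc_projection: np.ndarray
    empirical_fc_pattern: np.ndarray
    refs: dict


def estimate_sc_pipeline(
    empirical_fc: Mapping[str, np.ndarray],
    simulated_fc: Mapping[str, Mapping[str, np.ndarray]],
    sc_cohort: Mapping[str, SCMatrix],
    floor: float = SC_FLOOR,
    ref: float = SC_REF,
    ref_out: float = SC_REF_OUT,
    order: int = 4,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> SCEstimate:
    """Estimate SC from FC on a subject cohort.

    Bootstrap SVD of the vectorized SC cohort and of the pooled
    (empirical + simulated) FC give first-dimension average-projection
    patterns; the SC pattern is log-transformed (entries below ``floor``
    dropped from the fit, not from the inversion), the SC'-FC relation is
    fitted at the given polynomial order, and the inverse is applied to the
    empirical FC first-dimension pattern.  Entries masked from the fit still
    receive estimates - recovering links missed upstream is the point - and
    are flagged as extrapolated.
    """
    if not empirical_fc:
        raise ValueError("empirical FC set is empty")
    if not sc_cohort:
        raise ValueError("SC cohort is empty")

    subjects = list(sc_cohort)
    atlas = sc_cohort[subjects[0]].atlas
    sc_vectors = {s: vectorize_upper(sc_cohort[s].weights, atlas).values for s in subjects}
    sc_dm = DataMatrix(
        X=np.column_stack([sc_vectors[s] for s in subjects]),
        subject_ids=subjects,
        source_tags=["sc"] * len(subjects),
    )
    sc_res = bootstrap_svd(sc_dm, B=B, alpha=alpha, seed=seed)
    sc_proj = average_projection(sc_dm, sc_res.left_vectors[:, 0])

    pooled = pool_datasets(
        [("empirical", dict(empirical_fc))]
        + [(model, dict(data)) for model, data in simulated_fc.items()]
    )
    fc_res = bootstrap_svd(pooled, B=B, alpha=alpha, seed=seed + 1)
    u1 = fc_res.left_vectors[:, 0]
    fc_proj = average_projection(pooled, u1)
    empirical_pattern = average_projection(pooled, u1, source_filter="empirical")

    sc_prime, mask = transform_sc(sc_proj, floor=floor, ref=ref)
    poly_map = fit_sc_fc_map(sc_prime, fc_proj[mask], order=order)
    sc_hat, clamped = invert_fc(empirical_pattern, poly_map, ref_out=ref_out)

    idx = vectorize_upper(sc_cohort[subjects[0]].weights, atlas).index
    return SCEstimate(
        weights=unvectorize(sc_hat, idx, atlas.n_regions),
        pattern=sc_hat,
        poly_map=poly_map,
        extrapolated=~mask,
        clamped=clamped,
        sc_projection=sc_proj,
        fc_projection=fc_proj,
        empirical_fc_pattern=empirical_pattern,
        refs={"floor": floor, "ref": ref, "ref_out": ref_out},
    )
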