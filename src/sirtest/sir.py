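"""Sliced inverse regression of multivariate phenotypes on genotype slices.

The reduction runs in five steps: (1) standardize the traits to z-scale with
the inverse square root of their sample covariance, (2) partition individuals
into slices by genotype — one slice per observed genotype vector when the
3^k pattern space is small, otherwise contiguous blocks along the leading
eigenvector of the genetic relatedness matrix with small blocks merged —
(3) compute within-slice means and centered covariances of z, (4) pool the
within-slice covariances with slice-proportion weights into Ê, and (5) take
the eigenvectors of Ê for its smallest eigenvalues and map them back to the
original trait scale.  Because z is standardized, the law of total covariance
gives Ê = I − Σ_h p̂_h z̄_h z̄_hᵀ exactly: the smallest eigenvectors of the
pooled *within* covariance are the leading eigenvectors of the *between*
covariance, i.e. the effective dimension-reduction (e.d.r.) directions.

All sample covariances in this pipeline use the maximum-likelihood divisor
(n, and n_h within slices) so the identity above, which the test suite
asserts to 1e-8, holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_io import GenotypeMatrix, PhenotypeMatrix, RunConfig, ValidationError

_EIG_FLOOR = 1e-10  # relative eigenvalue floor for the inverse square root


@dataclass(frozen=True)
class StandardizationTransform:
    """Affine map y -> Σ̂_yy^{-1/2}(y − ȳ) and its ingredients."""

    mean: np.ndarray      # (q,)
    cov: np.ndarray       # (q, q), MLE divisor n
    inv_sqrt: np.ndarray  # (q, q), symmetric


@dataclass(frozen=True)
class SlicingPlan:
    """Partition of the n individuals into H nonempty slices."""

    assignment: np.ndarray  # (n,) integer labels in 0..H-1
    H: int
    proportions: np.ndarray  # (H,) = n_h / n
    strategy: Literal["exhaustive", "relatedness"]


@dataclass(frozen=True)
class GRM:
    """Genetic relatedness matrix: Pearson correlation of genotype rows."""

    values: np.ndarray  # (n, n), symmetric, unit diagonal


@dataclass(frozen=True)
class SIREstimate:
    pooled_cov: np.ndarray      # Ê, (q, q)
    slice_means: np.ndarray     # (H, q) within-slice means of z
    proportions: np.ndarray     # (H,)
    eigenvalues: np.ndarray     # (q,) ascending eigenvalues of Ê
    directions: np.ndarray      # (d0, q) rows Ŝ_m on the original trait scale
    reduced_trait: np.ndarray   # (n,) ỹ for d0 = 1, else (n, d0)
    transform: StandardizationTransform
    plan: SlicingPlan


# ---------------------------------------------------------------------------
# step 1: standardization
# ---------------------------------------------------------------------------


def standardize(Y: PhenotypeMatrix | np.ndarray) -> tuple[np.ndarray, StandardizationTransform]:
    """Whiten the traits: Z = (Y − ȳ) Σ̂_yy^{-1/2} with (1/n)ZᵀZ = I exactly."""
    values = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, dtype=float)
    n, q = values.shape
    if n <= q:
        raise ValidationError(f"standardization needs n > q (got n={n}, q={q})")
    mean = values.mean(axis=0)
    centered = values - mean
    cov = centered.T @ centered / n
    w, V = np.linalg.eigh(cov)
    if w[-1] <= 0 or w[0] <= _EIG_FLOOR * w[-1]:
        raise ValidationError(
            "phenotype covariance is singular or near-singular "
            f"(eigenvalue ratio {w[0] / w[-1] if w[-1] > 0 else 0:.2e}); "
            "remove collinear traits or reduce q before testing"
        )
    inv_sqrt = (V / np.sqrt(w)) @ V.T
    Z = centered @ inv_sqrt
    return Z, StandardizationTransform(mean=mean, cov=cov, inv_sqrt=inv_sqrt)


# ---------------------------------------------------------------------------
# step 2: slicing
# ---------------------------------------------------------------------------


def slice_exhaustive(G: GenotypeMatrix, cap: int = 3**10) -> SlicingPlan:
    """One slice per observed genotype vector (the natural H = 3^k slicing)."""
    if 3 ** G.k > cap:
        raise ValidationError(
            f"3^{G.k} possible genotype patterns exceed the cap {cap}; "
            "use the relatedness slicing strategy"
        )
    _, assignment = np.unique(G.values, axis=0, return_inverse=True)
    assignment = assignment.ravel()
    H = int(assignment.max()) + 1
    counts = np.bincount(assignment, minlength=H)
    return SlicingPlan(assignment, H, counts / G.n, "exhaustive")


def compute_grm(G: GenotypeMatrix) -> GRM:
    """Empirical correlation between individuals' genotype vectors."""
    if G.k < 2:
        raise ValidationError("GRM needs k >= 2 SNPs")
    values = G.values.astype(float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        i = int(np.argmax(sd == 0))
        raise ValidationError(
            f"individual {G.sample_ids[i]!r} has a constant genotype vector; "
            "correlation with other individuals is undefined"
        )
    grm = np.corrcoef(values)
    np.fill_diagonal(grm, 1.0)
    return GRM(np.clip(grm, -1.0, 1.0))


def _leading_grm_eigvec(G: GenotypeMatrix) -> np.ndarray:
    """Leading eigenvector of the GRM via its rank-k factor (O(n k^2)).

    Individuals with a constant genotype vector have no defined correlation
    with anyone; they contribute a zero row (zero loading) and end up grouped
    by input order among the eigenvector ties.
    """
    values = G.values.astype(float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        import logging

        logging.getLogger("sirtest").info(
            "%d individuals with constant genotype vectors get zero GRM loading",
            int((sd == 0).sum()),
        )
        sd = np.where(sd == 0, np.inf, sd)
    R = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    M = R.T @ R  # k x k; GRM = R Rᵀ / k shares eigenvectors with R Rᵀ
    w, V = np.linalg.eigh(M)
    u = R @ V[:, -1]
    norm = np.linalg.norm(u)
    if norm == 0:  # all rows constant: keep input order
        return np.zeros(G.n)
    u = u / norm
    # deterministic sign: largest-magnitude entry positive
    if u[int(np.argmax(np.abs(u)))] < 0:
        u = -u
    return u


def slice_by_relatedness(
    G: GenotypeMatrix, target_slice_size: int = 10, min_slice_size: int = 5
) -> SlicingPlan:
    """Slice along the leading GRM eigenvector; merge blocks below min size.

    Individuals are ordered by their loading on the leading eigenvector of
    the GRM (ties broken by input order), cut into contiguous blocks of
    ``target_slice_size``, and adjacent blocks are merged left-to-right until
    every slice holds at least ``min_slice_size`` individuals.
    """
    n = G.n
    if n < 2 * min_slice_size:
        raise ValidationError(
            f"need n >= {2 * min_slice_size} for relatedness slicing, got {n}"
        )
    u = _leading_grm_eigvec(G)
    order = np.argsort(u, kind="stable")
    sizes = [min(target_slice_size, n - s) for s in range(0, n, target_slice_size)]
    while len(sizes) > 1 and min(sizes) < min_slice_size:
        i = next(j for j, s in enumerate(sizes) if s < min_slice_size)
        if i > 0:
            sizes[i - 1] += sizes.pop(i)
        else:
            sizes[0] += sizes.pop(1)
    assignment = np.empty(n, dtype=np.int64)
    pos = 0
    for label, size in enumerate(sizes):
        assignment[order[pos:pos + size]] = label
        pos += size
    counts = np.bincount(assignment)
    return SlicingPlan(assignment, len(sizes), counts / n, "relatedness")


def make_plan(G: GenotypeMatrix, cfg: RunConfig) -> SlicingPlan:
    if cfg.slicing == "exhaustive":
        return slice_exhaustive(G, cap=cfg.exhaustive_cap)
    return slice_by_relatedness(G, cfg.target_slice_size, cfg.min_slice_size)


# ---------------------------------------------------------------------------
# steps 3-4: within-slice moments and the pooled covariance
# ---------------------------------------------------------------------------


def slice_moments(Z: np.ndarray, plan: SlicingPlan) -> tuple[np.ndarray, list[np.ndarray]]:
    """Within-slice means z̄_h and centered covariances v̂_h (divisor n_h)."""
    if Z.shape[0] != plan.assignment.shape[0]:
        raise ValidationError("slicing plan does not cover the data")
    q = Z.shape[1]
    means = np.zeros((plan.H, q))
    covs: list[np.ndarray] = []
    for h in range(plan.H):
        Zh = Z[plan.assignment == h]
        means[h] = Zh.mean(axis=0)
        C = Zh - means[h]
        covs.append(C.T @ C / Zh.shape[0])
    return means, covs


def pooled_within_cov(slice_covs: list[np.ndarray], proportions: np.ndarray) -> np.ndarray:
    """Ê = Σ_h p̂_h v̂_h, the slice-weighted mean of within-slice covariances."""
    if len(slice_covs) != len(proportions):
        raise ValidationError("slice_covs and proportions lengths differ")
    E = np.zeros_like(slice_covs[0])
    for p, v in zip(proportions, slice_covs):
        E += p * v
    return (E + E.T) / 2


# ---------------------------------------------------------------------------
# step 5: e.d.r. directions
# ---------------------------------------------------------------------------


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    return -vec if vec[int(np.argmax(np.abs(vec)))] < 0 else vec


def estimate_directions(
    E_hat: np.ndarray,
    transform: StandardizationTransform,
    d0: int = 1,
    *,
    slice_means: np.ndarray | None = None,
    proportions: np.ndarray | None = None,
    plan: SlicingPlan | None = None,
    Z: np.ndarray | None = None,
) -> SIREstimate:
    """Eigendecompose Ê; the d0 smallest eigenvectors span the reduced space.

    Directions are returned on the original trait scale, Ŝ_m = η̂_mᵀ Σ̂_yy^{-1/2},
    with a deterministic sign (largest-magnitude z-scale coordinate positive).
    """
    q = E_hat.shape[0]
    if d0 > q:
        raise ValidationError(f"d0={d0} exceeds the number of traits q={q}")
    w, V = np.linalg.eigh((E_hat + E_hat.T) / 2)
    etas = np.column_stack([_fix_sign(V[:, m]) for m in range(d0)])  # (q, d0)
    directions = etas.T @ transform.inv_sqrt  # (d0, q)
    reduced = Z @ etas if Z is not None else np.zeros((0, d0))
    if d0 == 1:
        reduced = reduced.ravel()
    H = 0 if slice_means is None else slice_means.shape[0]
    return SIREstimate(
        pooled_cov=E_hat,
        slice_means=slice_means if slice_means is not None else np.zeros((0, q)),
        proportions=proportions if proportions is not None else np.zeros(0),
        eigenvalues=w,
        directions=directions,
        reduced_trait=reduced,
        transform=transform,
        plan=plan if plan is not None else SlicingPlan(np.zeros(0, np.int64), H, np.zeros(0), "exhaustive"),
    )


def reduce(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig) -> SIREstimate:
    """Full pipeline: standardize -> slice -> moments -> pool -> directions."""
    if isinstance(Y, PhenotypeMatrix) and isinstance(G, GenotypeMatrix):
        if Y.sample_ids != G.sample_ids:
            raise ValidationError("phenotype and genotype samples are not aligned")
    Z, transform = standardize(Y)
    plan = make_plan(G, cfg)
    means, covs = slice_moments(Z, plan)
    E_hat = pooled_within_cov(covs, plan.proportions)
    return estimate_directions(
        E_hat, transform, cfg.d0,
        slice_means=means, proportions=plan.proportions, plan=plan, Z=Z,
    )
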