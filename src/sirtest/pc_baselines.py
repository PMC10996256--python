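"""PC-based competitor tests: PCA1, PCFisher and PCMinp.

Each test first replaces the q traits by their principal-component scores,
then tests every SNP against the scores with simple-regression slope tests
and combines the q per-PC p-values: PCA1 keeps only the first component's
p-value, PCFisher refers X = -2 Σ_m ln p_m to chi-square with 2q degrees of
freedom, and PCMinp applies a Šidák correction to the smallest per-PC
p-value.  Family-wise control across the k SNPs is Bonferroni throughout.
These are standard single-marker forms matching the usual sketches of the
PC-combination literature; the harness accepts further plug-in callables for
variants not implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import TestResult
from .data_io import GenotypeMatrix, PhenotypeMatrix, RunConfig, ValidationError
from .sir import _fix_sign


@dataclass(frozen=True)
class PCDecomposition:
    """Principal-component scores of the traits and their eigenvalues."""

    scores: np.ndarray       # (n, q), mutually uncorrelated columns
    eigenvalues: np.ndarray  # (q,), descending, nonnegative
    components: np.ndarray   # (q, q), rows are loading vectors


def pc_decompose(Y: PhenotypeMatrix | np.ndarray) -> PCDecomposition:
    """Centered PCA of the traits via eigendecomposition of Σ̂_yy (n-1)."""
    values = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, dtype=float)
    n, q = values.shape
    if n <= q:
        raise ValidationError(f"PCA needs n > q (got n={n}, q={q})")
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    w, V = np.linalg.eigh(cov)
    w, V = w[::-1], V[:, ::-1]
    V = np.column_stack([_fix_sign(V[:, m]) for m in range(q)])
    return PCDecomposition(scores=centered @ V, eigenvalues=np.maximum(w, 0.0),
                           components=V.T)


def pc_single_snp_pvalues(scores: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Two-sided slope-test p-values of each PC score on one SNP."""
    g = np.asarray(g, dtype=float)
    n, q = scores.shape
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0:
        warnings.warn("constant SNP: all per-PC p-values set to 1")
        return np.ones(q)
    yc = scores - scores.mean(axis=0)
    sxy = gc @ yc                       # (q,)
    b = sxy / sxx
    rss = (yc**2).sum(axis=0) - b * sxy
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = b**2 * sxx * dof / rss
    t2 = np.where(rss <= 0, np.inf, t2)
    return stats.f.sf(t2, 1, dof)       # t² with dof df is F(1, dof)


def _combined_test(Y, G, cfg, combine, label) -> TestResult:
    pcs = pc_decompose(Y)
    k = G.k
    per_snp = []
    for j in range(k):
        p_pc = pc_single_snp_pvalues(pcs.scores, G.values[:, j])
        stat, p = combine(p_pc)
        per_snp.append((G.snp_ids[j], float(stat), float(p), min(1.0, k * float(p))))
    best = min(per_snp, key=lambda t: t[2])
    return TestResult(label, best[1], best[3], per_snp=per_snp)


def pca1_test(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig | None = None) -> TestResult:
    """Per-SNP test using only the first principal component."""
    def combine(p_pc):
        return stats.chi2.isf(max(p_pc[0], np.finfo(float).tiny), 1), p_pc[0]
    return _combined_test(Y, G, cfg, combine, "PCA1")


def pcfisher_test(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig | None = None) -> TestResult:
    """Fisher combination of the q per-PC p-values, chi-square(2q) reference."""
    def combine(p_pc):
        X = -2.0 * np.sum(np.log(np.maximum(p_pc, np.finfo(float).tiny)))
        return X, stats.chi2.sf(X, 2 * len(p_pc))
    return _combined_test(Y, G, cfg, combine, "PCFisher")


def pcminp_test(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig | None = None) -> TestResult:
    """Minimum per-PC p-value with Šidák correction across the q PCs."""
    def combine(p_pc):
        pmin = float(np.min(p_pc))
        return pmin, 1.0 - (1.0 - pmin) ** len(p_pc)
    return _combined_test(Y, G, cfg, combine, "PCMinp")
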