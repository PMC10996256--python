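"""Association tests on the SIR-reduced trait, plus classical Wald baselines.

The global test (label "SIR") regresses the reduced trait ỹ on all k SNPs and
forms the Wald quadratic T̃ = β̂ᵀ Cov(β̂)⁻¹ β̂.  The per-SNP variant ("SIR-S")
regresses ỹ on each SNP separately, T̃_j² = β̂_j² / Var(β̂_j), and controls the
family-wise error with Bonferroni across the k SNPs.  Because ỹ is itself
estimated from the genotypes, neither statistic is chi-square under the null;
p-values come from a permutation scheme that re-runs the *entire* pipeline —
slicing, reduction, regression — on each genotype-row permutation.

For speed the permutation loop uses an algebraically identical shortcut:
permuting rows of G permutes the slice assignment and leaves the trait
standardization, XᵀX and the per-SNP sums of squares unchanged, so each
permutation only needs regrouped slice means, a q×q eigendecomposition and
two matrix-vector products.  ``test_association.py`` verifies this engine
against a naive full re-fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .data_io import GenotypeMatrix, PhenotypeMatrix, RunConfig, ValidationError
from .sir import SlicingPlan, _fix_sign, make_plan, reduce, standardize

logger = logging.getLogger("sirtest")


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    df: int | None = None
    per_snp: list[tuple[str, float, float, float]] | None = None
    # per_snp rows: (snp_id, statistic, raw p, Bonferroni-adjusted p)


# ---------------------------------------------------------------------------
# OLS pieces
# ---------------------------------------------------------------------------


def fit_reduced_global(
    y_tilde: np.ndarray, G: GenotypeMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS of ỹ on all SNPs with an intercept; returns slopes and their cov."""
    Gv = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    n, k = Gv.shape
    if n <= k + 1:
        raise ValidationError(f"need n > k+1 (got n={n}, k={k})")
    X = np.column_stack([np.ones(n), Gv])
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < k + 1:
        sd = Gv.std(axis=0)
        names = (G.snp_ids if isinstance(G, GenotypeMatrix)
                 else [f"snp{j}" for j in range(k)])
        const = [names[j] for j in range(k) if sd[j] == 0]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {k + 1}); "
            f"constant/collinear SNPs: {const or 'linear dependence among SNPs'}"
        )
    A = np.linalg.inv(XtX)
    beta = A @ (X.T @ y_tilde)
    resid = y_tilde - X @ beta
    sigma2 = float(resid @ resid) / (n - k - 1)
    cov = sigma2 * A[1:, 1:]
    return beta[1:], cov


def wald_statistic(beta: np.ndarray, cov: np.ndarray) -> float:
    """T = βᵀ cov⁻¹ β for a symmetric positive-definite covariance."""
    cov = np.asarray(cov, dtype=float)
    try:
        L = np.linalg.cholesky((cov + cov.T) / 2)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("coefficient covariance is singular") from exc
    x = np.linalg.solve(L, np.asarray(beta, dtype=float))
    return float(x @ x)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


class _SirPermutationEngine:
    """Re-estimates the full SIR pipeline under genotype-row permutations.

    Precomputes everything permutation-invariant once: the standardized
    traits Z, the slice assignment of the observed G (a permutation of G's
    rows only permutes that assignment), XᵀX and its inverse, and the per-SNP
    centered sums of squares.

    Under relatedness slicing, individuals with identical genotype vectors
    have identical GRM eigenvector loadings; the engine breaks those ties by
    the rows' pre-permutation order, whereas a literal re-fit breaks them by
    post-permutation order.  The tied individuals are exchangeable given the
    data, so both conventions yield statistics with the same permutation-null
    distribution; on tie-free data the two agree exactly.
    """

    def __init__(self, Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig):
        self.cfg = cfg
        self.Z, self.transform = standardize(Y)
        self.n, self.q = self.Z.shape
        plan = make_plan(G, cfg)
        self.plan = plan
        self.order = np.argsort(plan.assignment, kind="stable")
        counts = np.bincount(plan.assignment, minlength=plan.H)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.counts = counts.astype(float)
        self.props = plan.proportions

        Gv = G.values.astype(float)
        self.Gv = Gv
        self.snp_ids = G.snp_ids
        self.k = Gv.shape[1]
        X = np.column_stack([np.ones(self.n), Gv])
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < self.k + 1:
            # reuse the detailed diagnostic
            fit_reduced_global(np.zeros(self.n), G)
        self.A = np.linalg.inv(XtX)
        self.C = np.linalg.inv(self.A[1:, 1:])  # = centered GᵀG
        self.g_mean = Gv.mean(axis=0)
        self.S_xx = ((Gv - self.g_mean) ** 2).sum(axis=0)

    def _reduced_trait(self, perm: np.ndarray | None) -> np.ndarray:
        """ỹ after re-estimating the reduction on G[perm]."""
        if perm is None:
            Zg = self.Z[self.order]
        else:
            inv = np.empty(self.n, dtype=np.int64)
            inv[perm] = np.arange(self.n)
            Zg = self.Z[inv[self.order]]
        sums = np.add.reduceat(Zg, self.starts, axis=0)
        means = sums / self.counts[:, None]
        M = (means * self.props[:, None]).T @ means  # between-slice cov
        E_hat = np.eye(self.q) - M  # exact: (1/n) ZᵀZ = I
        _, V = np.linalg.eigh(E_hat)
        eta = _fix_sign(V[:, 0])
        return self.Z @ eta

    def statistics(self, perm: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        """(global T̃, per-SNP T̃_j²) for genotype rows permuted by ``perm``."""
        y = self._reduced_trait(perm)
        if perm is None:
            Gty = self.Gv.T @ y
        else:
            u = np.empty(self.n)
            u[perm] = y  # (G[perm]ᵀ y)_j = Σ_m G[m,j] u[m]
            Gty = self.Gv.T @ u
        y_sum = y.sum()
        Xty = np.concatenate([[y_sum], Gty])
        beta = self.A @ Xty
        S_yy_tot = float(y @ y)
        rss = S_yy_tot - float(beta @ Xty)
        sigma2 = rss / (self.n - self.k - 1)
        slopes = beta[1:]
        T_global = float(slopes @ self.C @ slopes) / sigma2

        # per-SNP simple regressions (ỹ has exact zero mean)
        S_xy = Gty - self.g_mean * y_sum
        S_yy = S_yy_tot - y_sum**2 / self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            b = S_xy / self.S_xx
            rss_j = S_yy - b * S_xy
            T_snp = b**2 * self.S_xx * (self.n - 2) / rss_j
        T_snp = np.where(self.S_xx > 0, T_snp, np.nan)
        return T_global, T_snp


def _permutation_count_pvalue(T_obs: float, T_perm: np.ndarray) -> float:
    B = len(T_perm)
    return (1 + int(np.sum(T_perm >= T_obs))) / (1 + B)


def permutation_pvalue(
    Y: PhenotypeMatrix,
    G: GenotypeMatrix,
    cfg: RunConfig,
    statistic: Callable[[PhenotypeMatrix, GenotypeMatrix], float],
    method: str = "custom",
) -> TestResult:
    """Generic permutation test: the statistic is recomputed from scratch on
    each uniform row-permutation of G.  p = (1 + #{T_b >= T_obs}) / (1 + B).
    """
    rng = np.random.default_rng(cfg.seed)
    logger.info("permutation test %s: seed=%d B=%d", method, cfg.seed, cfg.n_permutations)
    T_obs = statistic(Y, G)
    T_perm = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        perm = rng.permutation(G.n)
        Gp = GenotypeMatrix(G.values[perm], G.sample_ids, G.snp_ids)
        T_perm[b] = statistic(Y, Gp)
    return TestResult(method, float(T_obs), _permutation_count_pvalue(T_obs, T_perm),
                      n_permutations=cfg.n_permutations)


def _sir_permutation_run(Y, G, cfg) -> tuple[TestResult, TestResult]:
    """One shared permutation pass producing both SIR and SIR-S results."""
    engine = _SirPermutationEngine(Y, G, cfg)
    rng = np.random.default_rng(cfg.seed)
    logger.info("SIR permutation run: seed=%d B=%d slicing=%s",
                cfg.seed, cfg.n_permutations, cfg.slicing)
    T_obs, T_snp_obs = engine.statistics(None)
    B = cfg.n_permutations
    T_perm = np.empty(B)
    T_snp_perm = np.empty((B, engine.k))
    for b in range(B):
        T_perm[b], T_snp_perm[b] = engine.statistics(rng.permutation(engine.n))

    p_global = _permutation_count_pvalue(T_obs, T_perm)
    global_res = TestResult("SIR", float(T_obs), p_global, n_permutations=B)

    per_snp = []
    raw_ps = np.empty(engine.k)
    for j in range(engine.k):
        if not np.isfinite(T_snp_obs[j]):
            warnings.warn(f"constant SNP column {engine.snp_ids[j]!r}; p set to 1")
            raw_ps[j] = 1.0
            per_snp.append((engine.snp_ids[j], float("nan"), 1.0, 1.0))
            continue
        pj = _permutation_count_pvalue(T_snp_obs[j], T_snp_perm[:, j][np.isfinite(T_snp_perm[:, j])])
        raw_ps[j] = pj
        per_snp.append((engine.snp_ids[j], float(T_snp_obs[j]), pj,
                        min(1.0, engine.k * pj)))
    jbest = int(np.argmin(raw_ps))
    sirs_res = TestResult(
        "SIR-S",
        float(T_snp_obs[jbest]) if np.isfinite(T_snp_obs[jbest]) else float("nan"),
        min(1.0, engine.k * float(raw_ps[jbest])),
        n_permutations=B,
        per_snp=per_snp,
    )
    return global_res, sirs_res


def sir_global_test(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig) -> TestResult:
    """Global SIR test of H0: no SNP is associated with any trait."""
    return _sir_permutation_run(Y, G, cfg)[0]


def sirs_test(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig) -> TestResult:
    """Per-SNP SIR test with Bonferroni control across the k SNPs."""
    return _sir_permutation_run(Y, G, cfg)[1]


def sir_both_tests(Y, G, cfg) -> tuple[TestResult, TestResult]:
    """SIR and SIR-S from a single permutation pass (identical to running
    each separately with the same config/seed)."""
    return _sir_permutation_run(Y, G, cfg)


def naive_sir_statistics(Y: PhenotypeMatrix, G: GenotypeMatrix, cfg: RunConfig
                         ) -> tuple[float, np.ndarray]:
    """Reference implementation: full pipeline via reduce() + explicit OLS.

    Used by the tests as the slow, independent route the permutation engine
    must reproduce.
    """
    est = reduce(Y, G, cfg)
    y = est.reduced_trait
    beta, cov = fit_reduced_global(y, G)
    T_global = wald_statistic(beta, cov)
    n = G.n
    Gv = G.values.astype(float)
    T_snp = np.empty(G.k)
    for j in range(G.k):
        g = Gv[:, j]
        gc = g - g.mean()
        sxx = float(gc @ gc)
        if sxx == 0:
            T_snp[j] = np.nan
            continue
        yc = y - y.mean()
        b = float(gc @ yc) / sxx
        rss = float(yc @ yc) - b * float(gc @ yc)
        T_snp[j] = b**2 * sxx * (n - 2) / rss
    return T_global, T_snp


# ---------------------------------------------------------------------------
# classical multivariate Wald baselines
# ---------------------------------------------------------------------------


def _multivariate_ols(Y: np.ndarray, X: np.ndarray):
    """Multivariate OLS: returns (B_hat, resid_cov (divisor n-p), (XᵀX)⁻¹)."""
    n, p = X.shape
    A = np.linalg.inv(X.T @ X)
    B_hat = A @ (X.T @ Y)
    resid = Y - X @ B_hat
    Sigma = resid.T @ resid / (n - p)
    return B_hat, Sigma, A


def wald_T1(Y: PhenotypeMatrix, G: GenotypeMatrix, j: int) -> TestResult:
    """Wald test of SNP j against all q traits; chi-square with q df.

    T1 = β̂_j [Cov(β̂_j)]⁻¹ β̂_jᵀ from the multivariate regression of Y on
    SNP j with an intercept.
    """
    Yv = Y.values
    n, q = Yv.shape
    if n <= q + 1:
        raise ValidationError(f"need n > q+1 (got n={n}, q={q})")
    g = G.values[:, j].astype(float)
    X = np.column_stack([np.ones(n), g])
    if g.std() == 0:
        raise ValidationError(f"SNP {G.snp_ids[j]!r} is constant")
    B_hat, Sigma, A = _multivariate_ols(Yv, X)
    beta_j = B_hat[1]  # (q,)
    # Cov(β̂_j) = A[1,1] * Sigma
    T1 = float(beta_j @ np.linalg.solve(Sigma, beta_j)) / A[1, 1]
    p = float(stats.chi2.sf(T1, df=q))
    return TestResult("T1", T1, max(p, np.finfo(float).tiny), df=q,
                      per_snp=[(G.snp_ids[j], T1, p, min(1.0, G.k * p))])


def wald_T2(Y: PhenotypeMatrix, G: GenotypeMatrix) -> TestResult:
    """Joint Wald test of all k×q coefficients; chi-square with kq df."""
    Yv, Gv = Y.values, G.values.astype(float)
    n, q = Yv.shape
    k = Gv.shape[1]
    if n <= k * q + k + 1:
        raise ValidationError(f"n={n} too small for a joint test of {k * q} coefficients")
    X = np.column_stack([np.ones(n), Gv])
    B_hat, Sigma, A = _multivariate_ols(Yv, X)
    Bs = B_hat[1:]  # (k, q) slopes
    C = np.linalg.inv(A[1:, 1:])  # centered GᵀG
    # vec(B̂)ᵀ [Σ ⊗ A_ss]⁻¹ vec(B̂) = tr(Σ⁻¹ B̂ᵀ C B̂)
    T2 = float(np.trace(np.linalg.solve(Sigma, Bs.T @ C @ Bs)))
    p = float(stats.chi2.sf(T2, df=k * q))
    return TestResult("T2", T2, max(p, np.finfo(float).tiny), df=k * q)


def wald_snp_bonferroni(Y: PhenotypeMatrix, G: GenotypeMatrix,
                        cfg: RunConfig | None = None) -> TestResult:
    """Per-SNP T1 tests with Bonferroni across SNPs (the 'Wald' baseline)."""
    per_snp = []
    for j in range(G.k):
        r = wald_T1(Y, G, j)
        per_snp.append((G.snp_ids[j], r.statistic, r.p_value,
                        min(1.0, G.k * r.p_value)))
    best = min(per_snp, key=lambda t: t[2])
    return TestResult("Wald", best[1], best[3], df=Y.q, per_snp=per_snp)


# ---------------------------------------------------------------------------
# tidy output
# ---------------------------------------------------------------------------


def results_table(results: Sequence[TestResult], seed: int | None = None):
    """Long-format table: one row per (method, SNP-or-global)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(dict(method=r.method, snp_id="global", statistic=r.statistic,
                         p=r.p_value, p_adjusted=r.p_value,
                         n_permutations=r.n_permutations, seed=seed))
        for snp_id, stat, raw, adj in (r.per_snp or []):
            rows.append(dict(method=r.method, snp_id=snp_id, statistic=stat,
                             p=raw, p_adjusted=adj,
                             n_permutations=r.n_permutations, seed=seed))
    return pd.DataFrame(rows)
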