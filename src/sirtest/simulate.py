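"""Generative models and the type-I-error / power experiment harness.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium with a minor
allele frequency sampled uniformly from (0.3, 0.5); phenotypes follow the
multivariate linear model Y = G B + E with rows of E i.i.d. N(0, Σ) where
Σ_lm = ρ^{|l-m|} (AR(1) correlation across traits).  The preset effect
matrices place the signal on SNP 3 (five entries of ±1.10 on the first five
traits) and a weak single-trait effect 0.02 of SNP 4 on trait 2; all other
rows are zero.  Three scenario families cover low/high-dimensional traits
and genotypes; the harness runs any registered test method over fresh
replicates and reports rejection proportions with binomial standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .association import (
    TestResult,
    sir_both_tests,
    sir_global_test,
    sirs_test,
    wald_T2,
    wald_snp_bonferroni,
)
from .data_io import GenotypeMatrix, PhenotypeMatrix, RunConfig, ValidationError
from .pc_baselines import pca1_test, pcfisher_test, pcminp_test

logger = logging.getLogger("sirtest")


@dataclass(frozen=True)
class EffectMatrix:
    """k x q matrix B of genetic effects; row j is SNP j's effect vector."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def nonzero_rows(self) -> list[int]:
        return [int(j) for j in np.flatnonzero(np.any(self.values != 0, axis=1))]


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: int
    case: int
    n: int
    k: int
    q: int
    rho: float
    B: EffectMatrix
    maf_range: tuple[float, float] = (0.3, 0.5)
    null_model: bool = False

    def effects(self) -> np.ndarray:
        if self.null_model:
            return np.zeros((self.k, self.q))
        return self.B.values


@dataclass(frozen=True)
class ExperimentResult:
    methods: list[str]
    rejection: dict[str, float]
    std_error: dict[str, float]
    replicates: int
    n_permutations: int
    alpha: float
    seed: int
    spec: ScenarioSpec

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                method=self.methods,
                rejection=[self.rejection[m] for m in self.methods],
                std_error=[self.std_error[m] for m in self.methods],
                replicates=self.replicates,
                n_permutations=self.n_permutations,
                alpha=self.alpha,
                seed=self.seed,
                scenario=self.spec.scenario,
                case=self.spec.case,
                n=self.spec.n,
                k=self.spec.k,
                q=self.spec.q,
                rho=self.spec.rho,
                null_model=self.spec.null_model,
            )
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    k: int,
    maf_range: tuple[float, float] = (0.3, 0.5),
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: per SNP, p ~ U(maf_range) and counts ~ Binomial(2, p)."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError(f"invalid MAF range {maf_range}; need 0 < lo <= hi <= 0.5")
    if n < 2 or k < 1:
        raise ValidationError("need n >= 2 and k >= 1")
    rng = np.random.default_rng(rng)
    p = rng.uniform(lo, hi, size=k)
    values = rng.binomial(2, p, size=(n, k))
    return GenotypeMatrix(values, [f"s{i}" for i in range(n)], [f"snp{j + 1}" for j in range(k)])


def ar1_covariance(q: int, rho: float) -> np.ndarray:
    """Σ with Σ_lm = ρ^{|l-m|}; identity at ρ = 0."""
    if abs(rho) >= 1:
        raise ValidationError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(q)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_phenotypes(
    G: GenotypeMatrix,
    B: EffectMatrix | np.ndarray,
    rho: float,
    rng: np.random.Generator | int | None = None,
) -> PhenotypeMatrix:
    """Y = G B + E with AR(1)-correlated Gaussian errors across traits."""
    Bv = B.values if isinstance(B, EffectMatrix) else np.asarray(B, dtype=float)
    if Bv.shape[0] != G.k:
        raise ValidationError(f"effect matrix has {Bv.shape[0]} rows but k={G.k}")
    q = Bv.shape[1]
    rng = np.random.default_rng(rng)
    L = np.linalg.cholesky(ar1_covariance(q, rho))
    E = rng.standard_normal((G.n, q)) @ L.T
    values = G.values @ Bv + E
    return PhenotypeMatrix(values, list(G.sample_ids), [f"trait{m + 1}" for m in range(q)])


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_POS5 = [1.10, 1.10, 1.10, 1.10, 1.10]
_MIX5 = [1.10, -1.10, 1.10, -1.10, 1.10]

# (k, q, beta3-pattern): beta3 acts on the first five traits, beta4 = 0.02 on
# trait 2 only; every other row of B is zero.
_SCENARIOS: dict[tuple[int, int], tuple[int, int, list[float]]] = {
    (1, 1): (5, 5, _POS5),
    (1, 2): (5, 10, _POS5),
    (1, 3): (10, 5, _POS5),
    (1, 4): (10, 10, _MIX5),
    (2, 1): (10, 50, _POS5),
    (2, 2): (10, 50, _MIX5),
    (2, 3): (10, 100, _POS5),
    (3, 1): (40, 50, _MIX5),
    (3, 2): (40, 100, _MIX5),
    (3, 3): (100, 50, _MIX5),
    (3, 4): (100, 100, _MIX5),
}


def scenario_effects(scenario: int, case: int) -> EffectMatrix:
    """Preset effect matrix B for a (scenario, case) pair."""
    key = (scenario, case)
    if key not in _SCENARIOS:
        valid = sorted(_SCENARIOS)
        raise ValidationError(f"unknown (scenario, case) {key}; valid: {valid}")
    k, q, beta3 = _SCENARIOS[key]
    B = np.zeros((k, q))
    B[2, : len(beta3)] = beta3       # SNP 3
    B[3, 1] = 0.02                   # SNP 4 acts on trait 2 only
    return EffectMatrix(B)


def scenario_spec(
    scenario: int,
    case: int,
    n: int = 1000,
    rho: float = 0.0,
    null_model: bool = False,
) -> ScenarioSpec:
    """Build a full ScenarioSpec from a preset (scenario, case)."""
    B = scenario_effects(scenario, case)
    k, q = B.values.shape
    return ScenarioSpec(scenario, case, n, k, q, rho, B, null_model=null_model)


def default_slicing(k: int) -> str:
    """Exhaustive genotype-pattern slices for small k, relatedness for k >= 10."""
    return "exhaustive" if k < 10 else "relatedness"


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

METHODS = {
    "SIR": sir_global_test,
    "SIR-S": sirs_test,
    "PCA1": pca1_test,
    "PCFisher": pcfisher_test,
    "PCMinp": pcminp_test,
    "Wald": wald_snp_bonferroni,
    "T2": lambda Y, G, cfg: wald_T2(Y, G),
}


def _one_replicate(spec: ScenarioSpec, methods: list[str], cfg: RunConfig,
                   seed_seq: np.random.SeedSequence) -> dict[str, bool]:
    rng = np.random.default_rng(seed_seq)
    G = simulate_genotypes(spec.n, spec.k, spec.maf_range, rng)
    Y = simulate_phenotypes(G, spec.effects(), spec.rho, rng)
    perm_seed = int(rng.integers(0, 2**31 - 1))
    rep_cfg = replace(cfg, seed=perm_seed)
    rejected: dict[str, bool] = {}
    results: dict[str, TestResult] = {}
    if "SIR" in methods and "SIR-S" in methods:
        results["SIR"], results["SIR-S"] = sir_both_tests(Y, G, rep_cfg)
    for m in methods:
        if m not in results:
            results[m] = METHODS[m](Y, G, rep_cfg)
        rejected[m] = results[m].p_value <= cfg.alpha
    return rejected


def run_experiment(
    spec: ScenarioSpec,
    methods: list[str],
    replicates: int,
    cfg: RunConfig,
    n_jobs: int = 1,
) -> ExperimentResult:
    """Rejection proportions of each method over fresh simulated replicates.

    Each replicate gets its own seed spawned from ``cfg.seed``, so results do
    not depend on the worker count.
    """
    for m in methods:
        if m not in METHODS:
            raise ValidationError(f"unknown method {m!r}; registered: {sorted(METHODS)}")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if cfg.slicing == "exhaustive" and 3**spec.k > cfg.exhaustive_cap:
        cfg = replace(cfg, slicing="relatedness")
        logger.info("switched to relatedness slicing for k=%d", spec.k)
    children = np.random.SeedSequence(cfg.seed).spawn(replicates)
    logger.info("experiment: scenario=%d case=%d null=%s reps=%d B=%d seed=%d",
                spec.scenario, spec.case, spec.null_model, replicates,
                cfg.n_permutations, cfg.seed)
    if n_jobs == 1:
        rows = [_one_replicate(spec, methods, cfg, ss) for ss in children]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(spec, methods, cfg, ss) for ss in children
        )
    rejection = {m: float(np.mean([r[m] for r in rows])) for m in methods}
    std_error = {
        m: float(np.sqrt(rejection[m] * (1 - rejection[m]) / replicates)) for m in methods
    }
    return ExperimentResult(
        methods=list(methods),
        rejection=rejection,
        std_error=std_error,
        replicates=replicates,
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        seed=cfg.seed,
        spec=spec,
    )
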