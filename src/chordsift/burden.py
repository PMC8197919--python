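"""Gene- and pathway-level rare-variant association tests.

The unit test statistic is the optimal linear combination of a burden score
test and a variance-component (kernel) score test. With genotype matrix G
(n samples × m rare variants), case/control indicator y, per-variant weights
w and null-model residuals r = y − mu:

    s_j      = w_j · g_j' r                    (weighted per-variant score)
    Q_skat   = Σ_j s_j²                        (variance-component statistic)
    Q_burden = (Σ_j s_j)²                      (burden statistic)
    Q_rho    = (1 − rho) Q_skat + rho Q_burden,  rho ∈ [0, 1]

The burden component is powerful when variant effects share a direction;
the kernel component when effects are mixed. Under the null each Q_rho is
asymptotically a positive mixture of chi-squared(1) variables whose weights
are the eigenvalues of the mixing-transformed null covariance of the score
vector; the optimal test takes the minimum p-value over a grid of rho and
evaluates its null distribution by a one-dimensional integral. A
phenotype-permutation fallback (which is also the testing oracle) is
available for every statistic.

The null model is an intercept-only logistic regression by default;
covariates are adjusted through a logistic GLM fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from ._quadform import chi2mix_sf, clean_spectrum, liu_quantile, liu_sf
from .errors import InputError
from .model import CohortGenotypes, GenePanel
from .pathogenicity import ClassificationResult

__all__ = [
    "DEFAULT_RHO_GRID",
    "BurdenInput",
    "BurdenResult",
    "variant_weights",
    "score_statistics",
    "analytic_pvalue",
    "skato_test",
    "run_burden_suite",
    "results_table",
]

logger = logging.getLogger(__name__)

#: Default rho grid of the optimal test (dense near the kernel end, where
#: the optimum usually lies for mixed-direction effects).
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class BurdenInput:
    """One testing unit: genotypes, phenotype, weights, optional covariates."""

    G: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.G.ndim != 2:
            raise InputError("G must be a samples × variants matrix")
        n, m = self.G.shape
        if m < 1:
            raise InputError("at least one variant is required")
        if self.y.shape != (n,):
            raise InputError("phenotype length must match the number of samples")
        classes = np.unique(self.y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
            raise InputError("phenotype must contain both cases (1) and controls (0)")
        if self.weights.shape != (m,) or np.any(self.weights < 0):
            raise InputError("weights must be per-variant and non-negative")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
                raise InputError("covariates must be an n × k matrix")


@dataclass
class BurdenResult:
    unit_id: str
    mode: str
    m_variants: int
    q_burden: float
    q_skat: float
    rho_grid: tuple[float, ...]
    p_per_rho: tuple[float, ...]
    p_skato: float
    p_burden: float
    p_permutation: float | None = None
    n_permutations: int = 0
    adj_p: float | None = None


def variant_weights(
    mafs: np.ndarray, scheme: str = "beta_1_25", n_samples: int | None = None
) -> np.ndarray:
    """Per-variant weights from minor allele frequencies.

    ``beta_1_25`` evaluates the Beta(1, 25) density at each frequency, which
    up-weights the rarest variants; ``flat`` weights every variant equally.
    A zero frequency is replaced by the pseudo-count estimate 0.5/(2n + 1)
    when the sample size is supplied.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs > 0.5):
        raise InputError("minor allele frequencies must not exceed 0.5")
    if np.any(mafs < 0):
        raise InputError("minor allele frequencies must be non-negative")
    if np.any(mafs == 0):
        if n_samples is None:
            raise InputError("zero MAF requires n_samples for the pseudo-count estimate")
        mafs = np.where(mafs == 0, 0.5 / (2 * n_samples + 1), mafs)
    if scheme == "flat":
        return np.ones_like(mafs)
    if scheme == "beta_1_25":
        return beta_dist.pdf(mafs, 1, 25)
    raise InputError(f"unknown weighting scheme {scheme!r}")


def _fit_null(y: np.ndarray, covariates: np.ndarray | None):
    """Null logistic model: fitted means mu and variances v = mu(1-mu)."""
    n = y.shape[0]
    if covariates is None:
        mu = np.full(n, y.mean())
    else:
        import statsmodels.api as sm

        X = sm.add_constant(covariates)
        mu = sm.GLM(y, X, family=sm.families.Binomial()).fit().fittedvalues
        mu = np.asarray(mu, dtype=float)
    v = mu * (1.0 - mu)
    if np.all(v == 0):
        raise InputError("phenotype is constant under the null model")
    return mu, v


def _prepare(inp: BurdenInput) -> dict:
    """Shared pieces: weighted genotypes, scores, and the projected matrix Z1
    whose Gram matrix is the null covariance of the score vector."""
    G = np.where(inp.G < 0, 0.0, inp.G)  # missing dosages contribute nothing
    A = G * inp.weights[None, :]
    mu, v = _fit_null(inp.y, inp.covariates)
    r = inp.y - mu
    S = A.T @ r

    sv = np.sqrt(v)
    B = A * sv[:, None]
    if inp.covariates is None:
        X1 = sv[:, None]
    else:
        import statsmodels.api as sm

        X1 = sm.add_constant(inp.covariates) * sv[:, None]
    # project out the null design in the sqrt(v)-weighted space
    coef, *_ = np.linalg.lstsq(X1, B, rcond=None)
    Z1 = B - X1 @ coef
    return {"A": A, "S": S, "Z1": Z1, "mu": mu, "v": v, "r": r}


def score_statistics(inp: BurdenInput, rho: float) -> float:
    """Q_rho = (1 − rho)·Q_skat + rho·Q_burden for one mixing value."""
    if not (0.0 <= rho <= 1.0):
        raise InputError("rho must lie in [0, 1]")
    S = _prepare(inp)["S"]
    return float((1.0 - rho) * (S @ S) + rho * S.sum() ** 2)


def analytic_pvalue(Q: float, null_spectrum: np.ndarray, method: str = "saddlepoint") -> float:
    """Tail probability of the chi-squared(1) mixture with the given spectrum at Q."""
    lam = np.asarray(null_spectrum, dtype=float)
    if lam.size == 0 or np.all(lam == 0):
        raise InputError("null spectrum must contain a positive eigenvalue")
    if np.any(lam < 0):
        raise InputError("eigenvalues must be non-negative")
    if Q <= 0:
        return 1.0
    return chi2mix_sf(float(Q), clean_spectrum(lam), method=method)


def _rho_sqrt(rho: float, m: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt((1.0 - rho) + m * rho) - a) / m
    return a * np.eye(m) + b * np.ones((m, m))


def _spectra_by_rho(Phi: np.ndarray, rho_grid: Sequence[float]) -> list[np.ndarray]:
    m = Phi.shape[0]
    spectra = []
    for rho in rho_grid:
        Rh = _rho_sqrt(rho, m)
        lam = np.linalg.eigvalsh(Rh @ Phi @ Rh)
        spectra.append(clean_spectrum(lam))
    return spectra


def _optimal_pvalue(
    Z1: np.ndarray,
    rho_grid: Sequence[float],
    spectra: Sequence[np.ndarray],
    t_min: float,
) -> float:
    """Null probability that the minimum p over the rho grid falls below t_min.

    One-dimensional integration over the shared burden-direction chi-squared
    component; the remainder is moment-matched per evaluation point.
    """
    n_grid = len(rho_grid)
    bonf = min(1.0, t_min * n_grid)
    m = Z1.shape[1]
    z_mean = Z1.mean(axis=1)
    denom = float(z_mean @ z_mean)
    if denom <= 0 or m == 1:
        return bonf
    cof1 = (Z1.T @ z_mean) / denom
    Zi2 = Z1 - np.outer(z_mean, cof1)
    M2 = Zi2.T @ Zi2
    lam = clean_spectrum(np.linalg.eigvalsh(M2))
    if lam.size == 0:
        return bonf
    M1 = np.outer(cof1, cof1) * denom
    mu_q = lam.sum()
    var_zeta = 4.0 * float(np.sum(M1 * M2))
    var_q = 2.0 * float(np.sum(lam**2)) + var_zeta
    df = float(np.sum(lam**2) ** 2 / np.sum(lam**4))
    shrink = np.sqrt(max(var_q - var_zeta, 0.0) / var_q) if var_q > 0 else 1.0

    rho_cap = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)
    tau = (m**2 * rho_cap + (1.0 - rho_cap) * float(np.sum(cof1**2))) * denom
    qmin = np.array([liu_quantile(t_min, spec) for spec in spectra])

    def integrand(x: float) -> float:
        vals = (qmin - tau * x) / (1.0 - rho_cap)
        q = vals.min()
        if q <= 0:
            F = 0.0
        else:
            q_std = (q - mu_q) * shrink + mu_q
            F = 1.0 - float(liu_sf(q_std, lam))
        return F * chi2.pdf(x, df=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, 40.0, limit=200)
    p = 1.0 - val
    # the exact combination probability is bracketed by the single best rho
    # and its Bonferroni bound over the grid
    return float(min(max(p, t_min), bonf, 1.0))


def skato_test(
    inp: BurdenInput,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    n_permutations: int = 0,
    seed: int | None = None,
    unit_id: str = "",
    mode: str = "",
) -> BurdenResult:
    """Optimal burden/variance-component test for one unit.

    Analytic p-values per rho and for the grid minimum; optionally a
    phenotype-label permutation p-value for the same min-p statistic
    (``seed`` is then required for reproducibility).
    """
    rho_grid = tuple(float(r) for r in rho_grid)
    if any(not (0.0 <= r <= 1.0) for r in rho_grid) or not rho_grid:
        raise InputError("rho grid must be a non-empty subset of [0, 1]")
    if n_permutations > 0 and seed is None:
        raise InputError("permutation p-values require an explicit seed")

    parts = _prepare(inp)
    S, Z1, A = parts["S"], parts["Z1"], parts["A"]
    q_skat = float(S @ S)
    q_burden = float(S.sum() ** 2)
    m = inp.G.shape[1]

    Phi = Z1.T @ Z1
    if not np.any(np.abs(Phi) > 1e-12):
        warnings.warn(f"unit {unit_id or '<anonymous>'}: no genotype variance; p = 1")
        ones = (1.0,) * len(rho_grid)
        return BurdenResult(unit_id, mode, m, q_burden, q_skat, rho_grid, ones, 1.0, 1.0)

    spectra = _spectra_by_rho(Phi, rho_grid)
    q_rho = tuple((1.0 - r) * q_skat + r * q_burden for r in rho_grid)
    p_per_rho = tuple(analytic_pvalue(q, spec) for q, spec in zip(q_rho, spectra))
    t_min = min(p_per_rho)
    p_skato = _optimal_pvalue(Z1, rho_grid, spectra, t_min) if len(rho_grid) > 1 else t_min

    if 1.0 in rho_grid:
        p_burden = p_per_rho[rho_grid.index(1.0)]
    else:
        lam_b = clean_spectrum(np.array([float(np.ones(m) @ Phi @ np.ones(m))]))
        p_burden = analytic_pvalue(q_burden, lam_b)

    result = BurdenResult(
        unit_id, mode, m, q_burden, q_skat, rho_grid, p_per_rho, p_skato, p_burden
    )

    if n_permutations > 0:
        result.p_permutation = _permutation_pvalue(
            A, inp.y, parts["mu"], q_rho, rho_grid, spectra, n_permutations, seed
        )
        result.n_permutations = n_permutations
    return result


def _permutation_pvalue(
    A: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    q_rho_obs: Sequence[float],
    rho_grid: Sequence[float],
    spectra: Sequence[np.ndarray],
    n_permutations: int,
    seed: int,
) -> float:
    """Permutation p for the min-p statistic over the rho grid.

    Residuals are permuted (equivalent to permuting phenotype labels under
    the intercept-only null); per-permutation p's use the moment-matched
    tail with the spectra held fixed, so observed and permuted statistics
    are mapped through the same monotone transform per rho.
    """
    rng = np.random.default_rng(seed)
    r = y - mu
    B = n_permutations
    R = rng.permuted(np.broadcast_to(r, (B, r.shape[0])), axis=1).T  # n × B
    S_all = A.T @ R  # m × B
    qs = np.sum(S_all**2, axis=0)
    qb = S_all.sum(axis=0) ** 2

    p_obs = np.empty(len(rho_grid))
    P = np.empty((len(rho_grid), B))
    for i, (rho, spec) in enumerate(zip(rho_grid, spectra)):
        P[i] = liu_sf((1.0 - rho) * qs + rho * qb, spec)
        p_obs[i] = liu_sf(q_rho_obs[i], spec)
    t_perm = P.min(axis=0)
    t_obs = p_obs.min()
    return float((1 + np.sum(t_perm <= t_obs + 1e-12)) / (B + 1))


def run_burden_suite(
    cohort: CohortGenotypes,
    panel: GenePanel | None,
    classifications: Sequence[ClassificationResult] | None = None,
    mode: str = "all_rare",
    correction: str = "bonferroni",
    weight_scheme: str = "beta_1_25",
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    n_permutations: int = 0,
    seed: int | None = None,
) -> list[BurdenResult]:
    """One optimal test per gene (modes ``all_rare``/``pathogenic_only``) or
    per functional category (mode ``pathway``), with multiplicity adjustment
    over the units actually tested.

    ``pathogenic_only`` restricts each gene's columns to classifier-retained
    variants and therefore tests a subset of the ``all_rare`` columns;
    ``pathway`` pools all rare variants of every panel gene in the category.
    Without a panel, the gene-level modes test every gene present in the
    cohort; pathway mode requires one.
    """
    if mode not in {"all_rare", "pathogenic_only", "pathway"}:
        raise InputError(f"unknown analysis mode {mode!r}")
    if correction not in {"bonferroni", "none"}:
        raise InputError(f"unknown correction {correction!r}")
    if mode == "pathogenic_only" and classifications is None:
        raise InputError("pathogenic_only mode requires per-variant classifications")
    if classifications is not None and len(classifications) != cohort.n_variants:
        raise InputError("classifications must align with the cohort variant index")

    genes = np.array([rec.gene for rec in cohort.variant_index])
    keep = np.ones(cohort.n_variants, dtype=bool)
    if mode == "pathogenic_only":
        keep = np.array([c.retained for c in classifications], dtype=bool)

    if mode == "pathway":
        if panel is None:
            raise InputError("pathway mode requires a gene panel")
        units = [
            (cat, np.isin(genes, sorted(panel.genes_in_category(cat))))
            for cat in sorted({c for cats in panel.categories.values() for c in cats})
        ]
    else:
        unit_genes = set(genes) if panel is None else set(genes) & set(panel.genes)
        units = [(g, (genes == g) & keep) for g in sorted(unit_genes)]

    n = cohort.n_samples
    y = cohort.phenotype.astype(float)
    results: list[BurdenResult] = []
    for i, (unit_id, cols) in enumerate(units):
        if not cols.any():
            logger.info("unit %s has no qualifying variants; skipped", unit_id)
            continue
        G = cohort.dosage[:, cols].astype(float)
        G[G < 0] = 0.0
        alt_freq = G.sum(axis=0) / (2.0 * n)
        mafs = np.minimum(alt_freq, 1.0 - alt_freq)
        w = variant_weights(mafs, scheme=weight_scheme, n_samples=n)
        inp = BurdenInput(G=G, y=y, weights=w)
        unit_seed = None if seed is None else (seed + 9973 * i) % 2**31
        results.append(
            skato_test(
                inp, rho_grid=rho_grid, n_permutations=n_permutations,
                seed=unit_seed, unit_id=unit_id, mode=mode,
            )
        )

    k = len(results)
    for res in results:
        res.adj_p = min(1.0, res.p_skato * k) if correction == "bonferroni" else res.p_skato
    return results


def results_table(results: Sequence[BurdenResult]):
    """Results as a DataFrame ready for tab-separated export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "unit": r.unit_id,
                "mode": r.mode,
                "m_variants": r.m_variants,
                "q_burden": r.q_burden,
                "q_skat": r.q_skat,
                "p_burden": r.p_burden,
                "p_skato": r.p_skato,
                "p_permutation": r.p_permutation,
                "adj_p": r.adj_p,
            }
            for r in results
        ]
    )
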