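"""Bayesian phylogenetic mixed model (the "animal model") for Gaussian
responses at measurement-record level.

Model, for record r of species s:

    y_r = x_r' beta + u_phylo[s] + u_species[s] + e_r
    u_phylo   ~ N(0, sigma2_phylo * A)     A = BM relatedness (unit diagonal)
    u_species ~ N(0, sigma2_species * I)   residual between-species effects
    e_r       ~ N(0, sigma2_residual)      within-species variability

Priors: diffuse normal on fixed effects (mean 0, variance 1e10) and
univariate inverse-Wishart(V = 1, nu = 0.02) on each variance component,
implemented as inverse-gamma(nu/2, nu*V/2).  Sampling is a conjugate
Gibbs scheme: all location effects are drawn jointly from their
multivariate-normal full conditional via the mixed-model equations; each
variance component from its inverse-gamma full conditional.

Phylogenetic uncertainty is handled by running the sampler per tree over
a sample of topologies and pooling chain-1 draws (additional chains per
tree are only used for the Gelman-Rubin diagnostic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .errors import ConvergenceError, DesignError, TraitError
from .phylo import bm_covariance, tip_labels

__all__ = [
    "ModelSpec", "PriorSpec", "MCMCSettings", "Design", "PosteriorSample",
    "ModelSummary", "RepeatabilityResult", "build_design", "gibbs_run",
    "multi_tree_run", "pmcmc", "hpd_interval", "conditional_r2", "psrf",
    "ess_and_autocorr", "repeatability", "vif", "summarize",
    "apply_transform",
]

Transform = Literal["log", "sqrt", "signed_sqrt", "none"]


# ---------------------------------------------------------------------------
# specification types

@dataclass
class ModelSpec:
    """What to fit: response, fixed effects and their types, transforms."""

    response: str
    fixed_terms: dict[str, Literal["continuous", "binary"]]
    #: {"phylogeny", "species"}; drop "species" for one-row-per-species data
    random_terms: frozenset = frozenset({"phylogeny", "species"})
    transform_map: dict[str, Transform] = field(default_factory=dict)
    standardize: bool = True
    #: population (n) vs sample (n-1) SD for standardization
    std_ddof: int = 0

    def __post_init__(self) -> None:
        if self.response in self.fixed_terms:
            raise DesignError("response cannot also be a fixed term")


@dataclass(frozen=True)
class PriorSpec:
    variance_prior_V: float = 1.0
    variance_prior_nu: float = 0.02
    fixed_effect_mean: float = 0.0
    fixed_effect_variance: float = 1e10

    def __post_init__(self) -> None:
        if self.variance_prior_V <= 0 or self.variance_prior_nu <= 0:
            raise DesignError("variance prior V and nu must be positive")


@dataclass
class MCMCSettings:
    """Desk-scale defaults; the published schedule (2400 iterations,
    400 burn-in, thin 1000, 3 chains, 1000 trees) is reproducible by
    setting the corresponding fields."""

    n_iterations: int = 5000
    burn_in: int = 1000
    thin: int = 20
    n_chains: int = 2
    seed: int = 0
    trees_per_run: int = 100

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise DesignError("burn_in must be below n_iterations")
        if self.thin < 1:
            raise DesignError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


def paper_schedule(seed: int = 0) -> MCMCSettings:
    """The published protocol: 2 retained draws per tree, 2000 pooled over
    1000 trees, 3 chains."""
    return MCMCSettings(n_iterations=2400, burn_in=400, thin=1000,
                        n_chains=3, seed=seed, trees_per_run=1000)


# ---------------------------------------------------------------------------
# transforms and design assembly

def apply_transform(values: np.ndarray, transform: Transform, name: str = "") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if transform in (None, "none"):
        return values
    if transform == "log":
        if np.any(values <= 0):
            bad = np.nonzero(values <= 0)[0][:5]
            raise DesignError(f"log transform of non-positive values in {name!r} "
                              f"at rows {bad.tolist()}")
        return np.log(values)
    if transform == "sqrt":
        if np.any(values < 0):
            raise DesignError(f"sqrt transform of negative values in {name!r}")
        return np.sqrt(values)
    if transform == "signed_sqrt":
        return np.sign(values) * np.sqrt(np.abs(values))
    raise DesignError(f"unknown transform {transform!r}")


@dataclass
class Design:
    """Assembled arrays for one model on one tree."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    Z: np.ndarray
    species: list[str]
    A: np.ndarray
    has_species_term: bool
    record_species: list[str]


def build_design(data: pd.DataFrame, spec: ModelSpec, tree: dendropy.Tree) -> Design:
    """Response vector, fixed design matrix (intercept first), record-to-
    species incidence and the unit-diagonal phylogenetic relatedness matrix.

    Continuous predictors (and the response) are transformed per
    ``transform_map`` and continuous predictors are then mean-centred and
    scaled to unit SD.
    """
    tips = set(tip_labels(tree))
    species = sorted(set(data["species_id"]))
    missing = sorted(set(species) - tips)
    if missing:
        raise DesignError(f"species absent from tree: {missing}")
    for col in [spec.response, *spec.fixed_terms]:
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from data")
        if data[col].isna().any():
            raise DesignError(f"missing values in column {col!r}")

    y = apply_transform(data[spec.response].to_numpy(),
                        spec.transform_map.get(spec.response, "none"), spec.response)

    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for name, kind in spec.fixed_terms.items():
        v = apply_transform(data[name].to_numpy(),
                            spec.transform_map.get(name, "none"), name)
        if kind == "continuous" and spec.standardize:
            sd = v.std(ddof=spec.std_ddof)
            if sd == 0 or not np.isfinite(sd):
                raise DesignError(f"constant predictor {name!r}: SD undefined")
            v = (v - v.mean()) / sd
        elif kind == "continuous":
            if v.std() == 0:
                raise DesignError(f"constant predictor {name!r}")
        cols.append(v)
        names.append(name)
    X = np.column_stack(cols)

    sp_index = {sp: i for i, sp in enumerate(species)}
    Z = np.zeros((len(data), len(species)))
    rec_sp = data["species_id"].tolist()
    for r, sp in enumerate(rec_sp):
        Z[r, sp_index[sp]] = 1.0

    C, order = bm_covariance(tree, order=species)
    d = np.sqrt(np.diag(C))
    A = C / np.outer(d, d)
    return Design(y=y, X=X, fixed_names=names, Z=Z, species=species, A=A,
                  has_species_term="species" in spec.random_terms,
                  record_species=rec_sp)


# ---------------------------------------------------------------------------
# posterior containers

@dataclass
class PosteriorSample:
    """Draws of fixed effects and variance components, possibly pooled
    across trees."""

    beta_draws: np.ndarray                 # (n_draws, n_fixed)
    var_phylo_draws: np.ndarray
    var_species_draws: Optional[np.ndarray]
    var_residual_draws: np.ndarray
    fixed_names: list[str]
    tree_index: np.ndarray
    #: per-parameter Gelman-Rubin statistic when >= 2 chains were run
    psrf: Optional[dict[str, float]] = None

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def parameter(self, name: str) -> np.ndarray:
        if name in self.fixed_names:
            return self.beta_draws[:, self.fixed_names.index(name)]
        comp = {"var_phylo": self.var_phylo_draws,
                "var_species": self.var_species_draws,
                "var_residual": self.var_residual_draws}.get(name)
        if comp is None:
            raise KeyError(name)
        return comp

    @property
    def parameter_names(self) -> list[str]:
        names = list(self.fixed_names) + ["var_phylo"]
        if self.var_species_draws is not None:
            names.append("var_species")
        names.append("var_residual")
        return names

    def to_tidy(self) -> pd.DataFrame:
        """Long-format draw table: draw, tree_index, parameter, value."""
        rows = []
        for name in self.parameter_names:
            vals = self.parameter(name)
            rows.append(pd.DataFrame({
                "draw": np.arange(len(vals)), "tree_index": self.tree_index,
                "parameter": name, "value": vals}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def pool(cls, samples: Sequence["PosteriorSample"]) -> "PosteriorSample":
        has_sp = samples[0].var_species_draws is not None
        return cls(
            beta_draws=np.vstack([s.beta_draws for s in samples]),
            var_phylo_draws=np.concatenate([s.var_phylo_draws for s in samples]),
            var_species_draws=(np.concatenate([s.var_species_draws for s in samples])
                               if has_sp else None),
            var_residual_draws=np.concatenate([s.var_residual_draws for s in samples]),
            fixed_names=samples[0].fixed_names,
            tree_index=np.concatenate([s.tree_index for s in samples]),
        )


# ---------------------------------------------------------------------------
# the Gibbs sampler

def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape, 1.0))


def gibbs_run(
    design: Design,
    priors: PriorSpec,
    settings: MCMCSettings,
    seed: int | None = None,
    tree_index: int = 0,
) -> PosteriorSample:
    """One MCMC chain on one tree; identical seeds give identical draws.

    Location effects (fixed + phylogenetic + species) are drawn jointly
    from their multivariate-normal full conditional via the mixed-model
    equations; variance components from inverse-gamma full conditionals
    with shape (nu + dim)/2 and rate (nu*V + S)/2.
    """
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    y, X, Z, A = design.y, design.X, design.Z, design.A
    n, p = X.shape
    q = Z.shape[1]
    has_sp = design.has_species_term

    blocks = [X, Z] + ([Z] if has_sp else [])
    W = np.hstack(blocks)
    dim = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y
    try:
        Acf = cho_factor(A + 1e-10 * np.eye(q), lower=True)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("phylogenetic relatedness matrix is not positive "
                               "definite") from exc
    Ainv = cho_solve(Acf, np.eye(q))
    beta_prec = 1.0 / priors.fixed_effect_variance
    nu, V = priors.variance_prior_nu, priors.variance_prior_V

    var_y = float(np.var(y)) or 1.0
    s2p = s2s = s2e = var_y / (3.0 if has_sp else 2.0)

    keep = settings.retained_per_chain
    if keep < 1:
        raise ConvergenceError("settings retain zero draws per chain "
                               "(n_iterations - burn_in < thin)")
    betas = np.empty((keep, p))
    vps = np.empty(keep)
    vss = np.empty(keep) if has_sp else None
    ves = np.empty(keep)
    k = 0

    idx_p = slice(p, p + q)
    idx_s = slice(p + q, p + 2 * q)
    eye_q = np.eye(q)
    for it in range(1, settings.n_iterations + 1):
        M = WtW / s2e
        M[np.arange(p), np.arange(p)] += beta_prec
        M[idx_p, idx_p] += Ainv / s2p
        if has_sp:
            M[idx_s, idx_s] += eye_q / s2s
        try:
            L = cholesky(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "mixed-model equations not positive definite (variance "
                "component collapsed)") from exc
        rhs = Wty / s2e
        mean = cho_solve((L, True), rhs, check_finite=False)
        z = rng.standard_normal(dim)
        theta = mean + solve_triangular(L, z, lower=True, trans="T", check_finite=False)

        up = theta[idx_p]
        Sp = float(up @ (Ainv @ up))
        s2p = max(_inv_gamma(rng, (nu + q) / 2.0, (nu * V + Sp) / 2.0), 1e-12)
        if has_sp:
            us = theta[idx_s]
            s2s = max(_inv_gamma(rng, (nu + q) / 2.0, (nu * V + float(us @ us)) / 2.0), 1e-12)
        resid = y - W @ theta
        s2e = max(_inv_gamma(rng, (nu + n) / 2.0,
                             (nu * V + float(resid @ resid)) / 2.0), 1e-12)

        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            betas[k] = theta[:p]
            vps[k] = s2p
            if has_sp:
                vss[k] = s2s
            ves[k] = s2e
            k += 1

    return PosteriorSample(
        beta_draws=betas[:k], var_phylo_draws=vps[:k],
        var_species_draws=vss[:k] if has_sp else None,
        var_residual_draws=ves[:k], fixed_names=design.fixed_names,
        tree_index=np.full(k, tree_index, dtype=int),
    )


def multi_tree_run(
    data: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec,
    settings: MCMCSettings,
    trees: Sequence[dendropy.Tree],
) -> PosteriorSample:
    """Pool chain-1 draws over a sample of trees.

    Each tree contributes ``retained_per_chain`` draws to the pooled
    posterior (the published schedule retains 2, giving 2000 over 1000
    trees).  When ``settings.n_chains`` >= 2 the extra chains are run per
    tree solely to compute the Gelman-Rubin statistic, reported as the
    maximum over trees per parameter.
    """
    if len(trees) == 0:
        raise DesignError("need at least one tree")
    use = list(trees)[: settings.trees_per_run]
    pooled: list[PosteriorSample] = []
    worst_psrf: dict[str, float] = {}
    ss = np.random.SeedSequence(settings.seed)
    for ti, tree in enumerate(use):
        design = build_design(data, spec, tree)
        chain_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                       for s in ss.spawn(settings.n_chains)]
        chains = [gibbs_run(design, priors, settings, seed=cs, tree_index=ti)
                  for cs in chain_seeds]
        pooled.append(chains[0])
        if settings.n_chains >= 2 and chains[0].n_draws >= 10:
            for name in chains[0].parameter_names:
                r = psrf([c.parameter(name) for c in chains])
                worst_psrf[name] = max(worst_psrf.get(name, 0.0), r)
    out = PosteriorSample.pool(pooled)
    if worst_psrf:
        out.psrf = worst_psrf
    return out


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics

def pmcmc(draws: np.ndarray) -> float:
    """Two-sided MCMC sign probability 2*min(P(>0), P(<0)), floored at 2/N."""
    draws = np.asarray(draws)
    n = len(draws)
    if n < 2:
        raise TraitError("pmcmc needs at least 2 draws")
    pos = int(np.sum(draws > 0))
    neg = int(np.sum(draws < 0))
    return max(2.0 * min(pos, neg) / n, 2.0 / n)


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws))
    n = len(x)
    k = max(int(math.ceil(prob * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def conditional_r2(sample: PosteriorSample, X: np.ndarray) -> float:
    """Posterior mean of (V_fix + phylo + species) / (V_fix + phylo +
    species + residual), V_fix the variance of the fixed-effect linear
    predictor over records."""
    fit = X @ sample.beta_draws.T
    v_fix = fit.var(axis=0)
    v_sp = sample.var_species_draws if sample.var_species_draws is not None else 0.0
    num = v_fix + sample.var_phylo_draws + v_sp
    r2 = num / (num + sample.var_residual_draws)
    return float(np.mean(r2))


def psrf(chains: Sequence[np.ndarray]) -> float:
    """Gelman-Rubin potential scale reduction over aligned chains:
    sqrt(((n-1)/n * W + B/n) / W)."""
    if len(chains) < 2:
        raise TraitError("PSRF needs at least 2 chains")
    arr = np.asarray(chains, dtype=float)
    m, n = arr.shape
    if n < 10:
        raise TraitError("PSRF needs chains of length >= 10")
    W = float(np.mean(arr.var(axis=1, ddof=1)))
    B = n * float(arr.mean(axis=1).var(ddof=1))
    if W <= 0:
        return 1.0
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def ess_and_autocorr(draws: np.ndarray) -> tuple[float, np.ndarray]:
    """Effective sample size N / (1 + 2*sum rho_k), with the sum truncated
    at the first non-positive autocorrelation; returns (ESS, rho[1:K])."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10:
        raise TraitError("ESS needs at least 10 draws")
    v = x.var()
    if v == 0:
        raise TraitError("zero-variance draws: ESS undefined")
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (v * n)
    rhos = []
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        rhos.append(acf[k])
        s += acf[k]
    ess = n / (1.0 + 2.0 * s)
    return float(ess), np.asarray(rhos if rhos else [0.0])


@dataclass
class ModelSummary:
    """Per-model report in the style of an MCMCglmm solution table."""

    fixed: pd.DataFrame          # posterior_mean, hpd_lower, hpd_upper, pmcmc
    variance: pd.DataFrame       # posterior_mean, hpd_lower, hpd_upper
    conditional_r2: float
    psrf: dict[str, float]
    ess: dict[str, float]
    max_autocorrelation: float
    n_draws: int
    converged: bool


def summarize(sample: PosteriorSample, X: np.ndarray,
              psrf_limit: float = 1.1, ess_floor: float = 0.0) -> ModelSummary:
    """Posterior means, 95% HPD intervals, pMCMC values, conditional R^2
    and the diagnostic suite for a (pooled) posterior sample."""
    fixed_rows = {}
    for j, name in enumerate(sample.fixed_names):
        d = sample.beta_draws[:, j]
        lo, hi = hpd_interval(d)
        fixed_rows[name] = {"posterior_mean": float(d.mean()), "hpd_lower": lo,
                            "hpd_upper": hi, "pmcmc": pmcmc(d)}
    var_rows = {}
    for name in ["var_phylo", "var_species", "var_residual"]:
        try:
            d = sample.parameter(name)
        except KeyError:
            continue
        if d is None:
            continue
        lo, hi = hpd_interval(d)
        var_rows[name] = {"posterior_mean": float(d.mean()),
                          "hpd_lower": lo, "hpd_upper": hi}
    ess = {}
    max_rho = 0.0
    for name in sample.parameter_names:
        d = sample.parameter(name)
        if np.var(d) == 0:
            continue
        e, rhos = ess_and_autocorr(d)
        ess[name] = e
        if len(rhos):
            max_rho = max(max_rho, float(rhos[0]))
    psrf_d = sample.psrf or {}
    converged = all(v < psrf_limit for v in psrf_d.values()) and \
        all(v >= ess_floor for v in ess.values())
    return ModelSummary(
        fixed=pd.DataFrame(fixed_rows).T,
        variance=pd.DataFrame(var_rows).T,
        conditional_r2=conditional_r2(sample, X),
        psrf=psrf_d, ess=ess, max_autocorrelation=max_rho,
        n_draws=sample.n_draws, converged=converged,
    )


# ---------------------------------------------------------------------------
# repeatability and collinearity

@dataclass(frozen=True)
class RepeatabilityResult:
    repeatability: float
    trait: str
    n_records: int
    n_species: int
    var_species: float
    var_residual: float


def repeatability(records: pd.DataFrame, trait: str,
                  species_col: str = "species_id") -> RepeatabilityResult:
    """Between-species share of total phenotypic variance from replicated
    records: a one-way random-effects variance-components fit (ANOVA
    estimator, clipped at zero), R = s2_species / (s2_species + s2_res)."""
    df = records[[species_col, trait]].dropna()
    groups = df.groupby(species_col)[trait]
    sizes = groups.size()
    reps = sizes[sizes >= 2]
    if len(reps) < 2:
        raise TraitError("repeatability needs >= 2 species with >= 2 records")
    N = int(sizes.sum())
    a = len(sizes)
    grand = df[trait].mean()
    means = groups.mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((df[trait] - df[species_col].map(means)) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a) if N > a else 0.0
    n0 = (N - float((sizes ** 2).sum()) / N) / (a - 1)
    s2_sp = max((ms_between - ms_within) / n0, 0.0)
    s2_res = ms_within
    total = s2_sp + s2_res
    r = s2_sp / total if total > 0 else 1.0
    return RepeatabilityResult(repeatability=float(r), trait=trait,
                               n_records=N, n_species=a,
                               var_species=s2_sp, var_residual=s2_res)


def vif(X: pd.DataFrame | np.ndarray, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per predictor, from
    regressing each column on the others plus an intercept."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise DesignError("VIF needs at least 2 predictors")
    out = {}
    for j in range(p):
        if np.var(M[:, j]) == 0:
            raise DesignError(f"constant column {names[j]!r}")
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, M[:, j], rcond=None)
        resid = M[:, j] - others @ coef
        r2 = 1.0 - resid.var() / M[:, j].var()
        if r2 > 1.0 - 1e-10:
            raise DesignError(f"predictor {names[j]!r} is perfectly collinear "
                              "with the others (infinite VIF)")
        out[names[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
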