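"""Bayesian two-level logistic regression for intersectional strata.

The model for child i in stratum j is

    logit P(y_ij = 1) = beta0 + x_ij' beta + u_j,     u_j ~ Normal(0, sigma2_u)

fitted twice: the null model ("Model 1") with no covariates, whose stratum
variance captures all between-strata differences, and the main-effects model
("Model 2") which adds treatment-coded indicators of the strata-defining
variables, so that the remaining stratum variance reflects interaction
(multiplicative) effects only.

Inference is by seeded MCMC: a gradient-free Metropolis-within-Gibbs sampler
with proposal scales adapted during burn-in only (Robbins-Monro toward 0.44
acceptance) and frozen afterwards, so the post-burn-in chain satisfies
detailed balance. Stratum effects are updated as an independent block — each
u_j touches only its own stratum's likelihood, so all J proposals are
accepted or rejected element-wise in one vectorised step. The stratum
standard deviation is updated on the log scale with the Jacobian term.

Priors are weakly informative and configurable: Normal(0, scale) on the
intercept and fixed effects (default scale 10 on the log-odds scale) and a
half-Student-t (default 3 degrees of freedom, scale 2.5) on the stratum
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strata import StrataIndex
from .survey_io import SurveyDataset

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "SamplerConfig",
    "ModelFit",
    "build_design",
    "log_posterior",
    "fit",
    "odds_ratios",
    "diagnostics",
    "split_rhat",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: the outcome, the strata index, and the fixed effects.

    ``fixed_vars`` is empty for the null model; for the main-effects model it
    must be a subset of (conventionally, exactly) the strata-defining
    variables. Reference levels come from the codebook.
    """

    outcome: str
    strata: StrataIndex
    fixed_vars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_vars", tuple(self.fixed_vars))
        extra = set(self.fixed_vars) - set(self.strata.variables)
        if extra:
            raise ValueError(
                f"fixed_vars {sorted(extra)} are not strata-defining variables"
            )


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the log-odds scale."""

    fixed_effect_scale: float = 10.0
    stratum_sd_df: float = 3.0
    stratum_sd_scale: float = 2.5

    def __post_init__(self) -> None:
        if self.fixed_effect_scale <= 0 or self.stratum_sd_scale <= 0:
            raise ValueError("prior scales must be strictly positive")
        if self.stratum_sd_df <= 0:
            raise ValueError("stratum_sd_df must be strictly positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run lengths. ``iterations`` is the total per chain including
    ``burn_in`` discarded iterations."""

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def desk(cls, seed: int = 0, chains: int = 4) -> "SamplerConfig":
        """Desk-scale default: 4 chains x 5,000 iterations, 1,000 burn-in."""
        return cls(chains=chains, iterations=5000, burn_in=1000, seed=seed)

    @classmethod
    def paper(cls, seed: int = 0, chains: int = 4) -> "SamplerConfig":
        """Long-run profile: 50,000 iterations with 5,000 burn-in."""
        return cls(chains=chains, iterations=50_000, burn_in=5000, seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "SamplerConfig":
        """Short screening-quality runs for simulation studies."""
        return cls(chains=2, iterations=1000, burn_in=400, seed=seed)


@dataclass
class ModelFit:
    """Posterior draws and pre-computed data bindings for one fitted model.

    Draw arrays are shaped ``(chains, draws)`` for scalars, ``(chains,
    draws, p)`` for the fixed effects and ``(chains, draws, J)`` for the
    stratum effects, where draws counts post-burn-in retained iterations.
    """

    spec: ModelSpec
    priors: PriorSpec
    config: SamplerConfig
    design_columns: list[str]
    beta0: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    u: np.ndarray
    y: np.ndarray
    X: np.ndarray
    s: np.ndarray  # zero-based stratum index per record

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_strata(self) -> int:
        return self.u.shape[2]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: 1-D for scalars, 2-D otherwise."""
        arr = getattr(self, name)
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def summaries(self) -> pd.DataFrame:
        """Posterior mean / median / 95% equal-tailed interval per parameter
        (intercept, fixed effects, stratum variance)."""
        rows = []
        params = [("beta0", self.pooled("beta0"))]
        params += [
            (f"beta[{c}]", self.pooled("beta")[:, k])
            for k, c in enumerate(self.design_columns)
        ]
        params.append(("sigma2_u", self.pooled("sigma2")))
        for name, d in params:
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
            rows.append(
                {"parameter": name, "mean": d.mean(), "median": med,
                 "ci_lower": lo, "ci_upper": hi}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    dataset: SurveyDataset, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicator matrix for the fixed effects.

    One column per non-reference level of each fixed variable, named
    ``"var:level"`` in codebook order; reference levels contribute no column.
    A reference level unobserved in the data is fatal — the contrasts would
    not be interpretable.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    # codebook order of variables and of levels within variable
    ordered = [n for n in dataset.codebook.names if n in set(spec.fixed_vars)]
    for var in ordered:
        vspec = dataset.codebook[var]
        values = dataset.records[var]
        if not (values == vspec.reference).any():
            raise ValueError(
                f"reference level {vspec.reference!r} of {var!r} unobserved in data"
            )
        for level in vspec.levels:
            if level == vspec.reference:
                continue
            cols.append((values == level).to_numpy(dtype=np.float64))
            names.append(f"{var}:{level}")
    if cols:
        X = np.column_stack(cols)
    else:
        X = np.empty((dataset.n_records, 0))
    return X, names


# ---------------------------------------------------------------------------
# log posterior (also the test surface for likelihood correctness)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _half_t_logpdf_unnorm(sd: float, df: float, scale: float) -> float:
    # density of |T| with T ~ Student-t(df) scaled by `scale`, up to a constant
    return -0.5 * (df + 1.0) * np.log1p((sd / scale) ** 2 / df)


def log_posterior(
    y: np.ndarray,
    X: np.ndarray,
    s: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    u: np.ndarray,
    sigma2: float,
    priors: PriorSpec = PriorSpec(),
) -> float:
    """Log posterior density of the two-level logistic model (unnormalised
    only by the marginal likelihood; every prior term carries its constants).

    Evaluated over (beta0, beta, u, sigma_u) with sigma_u = sqrt(sigma2):
    the Bernoulli log-likelihood, Normal(0, sigma2) stratum-effect terms,
    Normal(0, scale^2) priors on the intercept and fixed effects, and the
    half-Student-t prior density on sigma_u.
    """
    from scipy import stats

    if sigma2 <= 0:
        return -np.inf
    sd = float(np.sqrt(sigma2))
    eta = beta0 + X @ beta + u[s]
    ll = float(np.sum(y * eta - _softplus(eta)))
    lp_u = float(stats.norm.logpdf(u, 0.0, sd).sum())
    lp_beta = float(
        stats.norm.logpdf(beta0, 0.0, priors.fixed_effect_scale)
        + stats.norm.logpdf(beta, 0.0, priors.fixed_effect_scale).sum()
    )
    lp_sd = float(
        np.log(2.0)
        + stats.t.logpdf(sd, priors.stratum_sd_df,
                         scale=priors.stratum_sd_scale)
    )
    return ll + lp_u + lp_beta + lp_sd


# ---------------------------------------------------------------------------
# sampler


def _run_chain(
    y: np.ndarray,
    X: np.ndarray,
    s: np.ndarray,
    J: int,
    priors: PriorSpec,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    col_idx = [np.flatnonzero(X[:, k]) for k in range(p)]
    y_col = [y[idx] for idx in col_idx]
    y_sum = float(y.sum())
    sc2 = priors.fixed_effect_scale**2

    # stratum-level design: covariates are constant within stratum, so each
    # design column corresponds to a subset of strata — the basis for the
    # likelihood-invariant translation moves below
    Z = np.zeros((J, p))
    Z[s] = X
    col_strata = [np.flatnonzero(Z[:, k]) for k in range(p)]

    # initial state: empirical-logit intercept plus seeded jitter for
    # overdispersed starts
    p_hat = (y_sum + 0.5) / (n + 1.0)
    beta0 = float(np.log(p_hat / (1 - p_hat)) + 0.2 * rng.normal())
    beta = 0.05 * rng.normal(size=p)
    u = np.zeros(J)
    log_sd = float(np.log(0.5) + 0.2 * rng.normal())

    eta = beta0 + X @ beta + u[s]

    # adaptive proposal scales (log-scale random-walk step sizes)
    ls_b0 = np.log(0.1)
    ls_beta = np.full(p, np.log(0.1))
    ls_u = np.full(J, np.log(0.8))
    ls_sd = np.log(0.3)
    ls_grp = np.log(0.2)
    ls_tr0 = np.log(0.1)
    ls_tr = np.full(p, np.log(0.1))
    target = 0.44

    n_keep = (config.iterations - config.burn_in + config.thin - 1) // config.thin
    out_b0 = np.empty(n_keep)
    out_beta = np.empty((n_keep, p))
    out_s2 = np.empty(n_keep)
    out_u = np.empty((n_keep, J))
    kept = 0

    for t in range(config.iterations):
        adapting = t < config.burn_in
        gamma = (t + 1.0) ** -0.6 if adapting else 0.0

        # --- intercept ---
        delta = rng.normal() * np.exp(ls_b0)
        d_ll = delta * y_sum - float(
            (_softplus(eta + delta) - _softplus(eta)).sum()
        )
        d_lp = (beta0**2 - (beta0 + delta) ** 2) / (2.0 * sc2)
        acc = np.log(rng.uniform()) < d_ll + d_lp
        if acc:
            beta0 += delta
            eta += delta
        if adapting:
            ls_b0 += gamma * (float(acc) - target)

        # --- fixed effects, one coordinate at a time on their support ---
        for k in range(p):
            idx = col_idx[k]
            delta = rng.normal() * np.exp(ls_beta[k])
            eta_k = eta[idx]
            d_ll = delta * float(y_col[k].sum()) - float(
                (_softplus(eta_k + delta) - _softplus(eta_k)).sum()
            )
            d_lp = (beta[k] ** 2 - (beta[k] + delta) ** 2) / (2.0 * sc2)
            acc = np.log(rng.uniform()) < d_ll + d_lp
            if acc:
                beta[k] += delta
                eta[idx] += delta
            if adapting:
                ls_beta[k] += gamma * (float(acc) - target)

        # --- translation moves: shift a fixed effect against the stratum
        # effects of its strata; eta (hence the likelihood) is unchanged and
        # only the normal priors enter the acceptance ratio. These moves
        # break the strong posterior coupling between beta and u. ---
        sigma2 = np.exp(2.0 * log_sd)
        delta = rng.normal() * np.exp(ls_tr0)
        d_lp = (beta0**2 - (beta0 + delta) ** 2) / (2.0 * sc2) + float(
            ((u**2 - (u - delta) ** 2).sum())
        ) / (2.0 * sigma2)
        acc = np.log(rng.uniform()) < d_lp
        if acc:
            beta0 += delta
            u -= delta
        if adapting:
            ls_tr0 += gamma * (float(acc) - target)

        for k in range(p):
            sk = col_strata[k]
            delta = rng.normal() * np.exp(ls_tr[k])
            u_k = u[sk]
            d_lp = (beta[k] ** 2 - (beta[k] + delta) ** 2) / (2.0 * sc2) + float(
                (u_k**2 - (u_k - delta) ** 2).sum()
            ) / (2.0 * sigma2)
            acc = np.log(rng.uniform()) < d_lp
            if acc:
                beta[k] += delta
                u[sk] = u_k - delta
            if adapting:
                ls_tr[k] += gamma * (float(acc) - target)

        # --- stratum effects: independent element-wise block ---
        eps = rng.normal(size=J) * np.exp(ls_u)
        eps_rec = eps[s]
        contrib = y * eps_rec - (_softplus(eta + eps_rec) - _softplus(eta))
        d_ll_j = np.bincount(s, weights=contrib, minlength=J)
        sigma2 = np.exp(2.0 * log_sd)
        d_lp_j = (u**2 - (u + eps) ** 2) / (2.0 * sigma2)
        acc_j = np.log(rng.uniform(size=J)) < d_ll_j + d_lp_j
        step = np.where(acc_j, eps, 0.0)
        u += step
        eta += step[s]
        if adapting:
            ls_u += gamma * (acc_j.astype(float) - target)

        # --- stratum sd on the log scale (likelihood-free given u) ---
        delta = rng.normal() * np.exp(ls_sd)
        new_log_sd = log_sd + delta
        ssu = float(np.sum(u**2))
        sd_old, sd_new = np.exp(log_sd), np.exp(new_log_sd)

        def _lp_sd(sd: float) -> float:
            return (
                -J * np.log(sd)
                - ssu / (2.0 * sd**2)
                + _half_t_logpdf_unnorm(sd, priors.stratum_sd_df,
                                        priors.stratum_sd_scale)
                + np.log(sd)  # Jacobian of the log transform
            )

        acc = np.log(rng.uniform()) < _lp_sd(sd_new) - _lp_sd(sd_old)
        if acc:
            log_sd = new_log_sd
        if adapting:
            ls_sd += gamma * (float(acc) - target)

        # --- joint (u, sigma) rescale: breaks the strong u-sd coupling ---
        delta = rng.normal() * np.exp(ls_grp)
        c = np.exp(delta)
        shift = (c - 1.0) * u[s]
        d_ll = float((y * shift - (_softplus(eta + shift) - _softplus(eta))).sum())
        # normal terms cancel exactly under joint scaling; what remains is
        # the half-t prior difference plus the log-scale Jacobian
        sd_old = np.exp(log_sd)
        d_lp = (
            _half_t_logpdf_unnorm(sd_old * c, priors.stratum_sd_df,
                                  priors.stratum_sd_scale)
            - _half_t_logpdf_unnorm(sd_old, priors.stratum_sd_df,
                                    priors.stratum_sd_scale)
            + delta
        )
        acc = np.log(rng.uniform()) < d_ll + d_lp
        if acc:
            u *= c
            eta += shift
            log_sd += delta
        if adapting:
            ls_grp += gamma * (float(acc) - target)

        if not np.isfinite(eta).all() or not np.isfinite(beta0):
            raise FloatingPointError(
                "non-finite model state at iteration "
                f"{t}: beta0={beta0}, beta={beta}, sigma2={np.exp(2 * log_sd)}"
            )

        if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
            out_b0[kept] = beta0
            out_beta[kept] = beta
            out_s2[kept] = np.exp(2.0 * log_sd)
            out_u[kept] = u
            kept += 1

    return out_b0[:kept], out_beta[:kept], out_s2[:kept], out_u[:kept]


def fit(
    dataset: SurveyDataset,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> ModelFit:
    """Fit the two-level logistic model by seeded MCMC.

    Deterministic given data, spec, priors, config and seed: chains run
    sequentially with per-chain generators spawned from the config seed.
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig.desk()

    if not spec.strata.assignment.index.equals(dataset.records.index):
        raise ValueError(
            "strata index does not match dataset records; rebuild strata "
            "after complete-case filtering"
        )
    if spec.strata.observed_count < 2:
        raise ValueError("need at least 2 observed strata")
    y = dataset.outcome01(spec.outcome).to_numpy(dtype=np.float64)
    if y.min() == y.max():
        raise ValueError(
            f"outcome {spec.outcome!r} has a single class; model unidentifiable"
        )
    X, names = build_design(dataset, spec)
    s = spec.strata.zero_based()
    J = spec.strata.observed_count

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains_b0, chains_beta, chains_s2, chains_u = [], [], [], []
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        b0, b, s2, u = _run_chain(y, X, s, J, priors, config, rng)
        chains_b0.append(b0)
        chains_beta.append(b)
        chains_s2.append(s2)
        chains_u.append(u)

    return ModelFit(
        spec=spec,
        priors=priors,
        config=config,
        design_columns=names,
        beta0=np.stack(chains_b0),
        beta=np.stack(chains_beta),
        sigma2=np.stack(chains_s2),
        u=np.stack(chains_u),
        y=y,
        X=X,
        s=s,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def odds_ratios(
    fit: ModelFit, *, point: str = "median", force: bool = False
) -> pd.DataFrame:
    """Odds ratios with 95% equal-tailed credible intervals.

    ``point`` selects the posterior summary exponentiated for the OR column
    ("median", the default, or "mean"). ``significant`` flags intervals
    excluding 1. Refuses to summarise an unconverged fit (any split R-hat
    >= 1.05) unless ``force=True``.
    """
    if point not in ("median", "mean"):
        raise ValueError("point must be 'median' or 'mean'")
    if not force:
        diag = diagnostics(fit)
        if not diag.attrs["converged"]:
            raise RuntimeError(
                "fit has not converged (split R-hat >= 1.05); "
                "pass force=True to summarise anyway"
            )
    rows = []
    params = [("Intercept", fit.pooled("beta0"))]
    params += [
        (c, fit.pooled("beta")[:, k]) for k, c in enumerate(fit.design_columns)
    ]
    for name, draws in params:
        center = np.median(draws) if point == "median" else draws.mean()
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "odds_ratio": float(np.exp(center)),
                "ci_lower": float(np.exp(lo)),
                "ci_upper": float(np.exp(hi)),
                "significant": bool(np.exp(lo) > 1.0 or np.exp(hi) < 1.0),
            }
        )
    return pd.DataFrame(rows)


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``draws`` has shape (chains, iterations). Each chain is split in half,
    then the classic between/within variance ratio is formed. Degenerate
    constant chains (zero within- and between-chain variance) return exactly
    1.0; zero within-chain variance with distinct chains returns inf.
    """
    draws = np.asarray(draws, dtype=np.float64)
    c, d = draws.shape
    half = d // 2
    if half < 2:
        return float("nan")
    parts = draws[:, : 2 * half].reshape(c * 2, half)
    W = float(parts.var(axis=1, ddof=1).mean())
    B = float(half * parts.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def diagnostics(fit: ModelFit, *, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat and bulk effective sample size for every parameter.

    Returns a DataFrame (parameter, rhat, ess_bulk) whose ``attrs`` carry
    ``converged`` (all R-hat below threshold) and ``note``. With a single
    chain R-hat is undefined and the report is flagged accordingly.
    """
    names: list[str] = ["beta0"]
    arrays: list[np.ndarray] = [fit.beta0]
    for k, c in enumerate(fit.design_columns):
        names.append(f"beta[{c}]")
        arrays.append(fit.beta[:, :, k])
    names.append("sigma2_u")
    arrays.append(fit.sigma2)
    for j in range(fit.n_strata):
        names.append(f"u[{j + 1}]")
        arrays.append(fit.u[:, :, j])

    single_chain = fit.beta0.shape[0] < 2
    if single_chain:
        rhats = [float("nan")] * len(names)
    else:
        rhats = [split_rhat(a) for a in arrays]

    import arviz as az  # deferred: slow import

    ess = []
    for a in arrays:
        val = az.ess(np.ascontiguousarray(a))
        if hasattr(val, "data_vars"):  # xarray Dataset from ndarray input
            val = float(next(iter(val.data_vars.values())).values)
        ess.append(float(val))

    frame = pd.DataFrame({"parameter": names, "rhat": rhats, "ess_bulk": ess})
    if single_chain:
        frame.attrs["converged"] = False
        frame.attrs["note"] = "insufficient chains: R-hat undefined"
    else:
        finite = np.asarray(rhats)
        frame.attrs["converged"] = bool(np.all(finite < rhat_threshold))
        frame.attrs["note"] = ""
    frame.attrs["rhat_threshold"] = rhat_threshold
    return frame


def trace_data(fit: ModelFit) -> pd.DataFrame:
    """Long-format draws (parameter, chain, iteration, value) for the
    intercept, fixed effects and stratum variance — trace-plot ready."""
    frames = []
    scalars = {"beta0": fit.beta0, "sigma2_u": fit.sigma2}
    for k, c in enumerate(fit.design_columns):
        scalars[f"beta[{c}]"] = fit.beta[:, :, k]
    for name, arr in scalars.items():
        c, d = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": name,
                    "chain": np.repeat(np.arange(c), d),
                    "iteration": np.tile(np.arange(d), c),
                    "value": arr.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
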