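"""Synthetic categorical survey data with known ground truth.

Generates microdata shaped like a child-health household survey — one row
per child, a binary outcome, and a handful of categorical social
determinants — from a fully known data-generating process:

    logit P(y_i = 1) = beta0 + x_i' beta + u_{j(i)} + interaction bonus

with covariates drawn independently from declared marginals (or from a
mixture over profiles when correlated determinants are wanted), stratum
effects u_j ~ Normal(0, sigma2_u) per observed covariate combination, and
optional interaction terms: an extra log-odds bonus applied to every
stratum satisfying a predicate — the concrete mechanism behind
"multiplicative" intersectional effects, and the thing the main-effects
model cannot explain away.

Everything realised (stratum effects, per-record linear predictor, true
VPC) is returned as :class:`SyntheticTruth` so that recovery can be tested
end to end. Missingness is completely at random only.

The ``uhs_like_preset`` configurations mirror the structure of the 2013
Bangladesh urban health survey analysis: 3,183 children, outcome
prevalences near 19% (cough), 28% (fever) and 5% (ARI), and the per-outcome
determinant sets whose category counts give 192 / 1,536 / 576 potential
strata. Marginals are uniform (the survey's true marginals live outside
this package) and the true main effects are set to the odds ratios reported
for the survey, so generated data are on a realistic effect scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .survey_io import Codebook, SurveyDataset, VariableSpec

__all__ = [
    "SyntheticVariable",
    "Interaction",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "uhs_like_preset",
    "PRESET_PREVALENCE",
]


@dataclass(frozen=True)
class SyntheticVariable:
    """One categorical determinant: ordered levels and their marginals."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...] | None = None  # None = uniform

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.probs is not None:
            probs = tuple(float(p) for p in self.probs)
            object.__setattr__(self, "probs", probs)
            if len(probs) != len(self.levels):
                raise ValueError(f"{self.name}: probs/levels length mismatch")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: marginal probabilities must sum to 1")
        if len(self.levels) < 2:
            raise ValueError(f"{self.name}: needs >= 2 levels")

    @property
    def marginals(self) -> np.ndarray:
        if self.probs is None:
            return np.full(len(self.levels), 1.0 / len(self.levels))
        return np.asarray(self.probs)


@dataclass(frozen=True)
class Interaction:
    """Extra log-odds applied to strata whose profile satisfies ``when``.

    ``when`` receives a mapping variable -> level for one stratum and
    returns True where the bonus applies.
    """

    when: Callable[[Mapping[str, str]], bool]
    bonus: float
    description: str = ""


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of the data-generating process.

    ``betas`` maps (variable, level) to a true log-odds effect for
    non-reference levels (reference = first declared level, effect 0).
    ``balanced`` replaces marginal sampling by a deterministic equal
    allocation over the covariate cross-product, handy for simulation
    studies that want strata of identical size. ``profile_mixture`` makes
    determinants correlated: a list of (weight, {variable: level-probs})
    profiles; each record first draws a profile, then its covariates from
    that profile's marginals (falling back to the variable's own marginals).
    """

    n_records: int
    variables: tuple[SyntheticVariable, ...]
    beta0: float = 0.0
    betas: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sigma2_u: float = 0.0
    interactions: tuple[Interaction, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0
    outcome_name: str = "outcome"
    outcome_levels: tuple[str, str] = ("No", "Yes")
    balanced: bool = False
    profile_mixture: tuple[tuple[float, Mapping[str, Sequence[float]]], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        object.__setattr__(self, "betas", dict(self.betas))
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if self.sigma2_u < 0:
            raise ValueError("sigma2_u must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        known = {(v.name, l) for v in self.variables for l in v.levels[1:]}
        bad = set(self.betas) - known
        if bad:
            raise ValueError(f"betas refer to unknown non-reference levels: {sorted(bad)}")
        if self.profile_mixture:
            w = [float(t[0]) for t in self.profile_mixture]
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("profile_mixture weights must sum to 1")

    def codebook(self) -> Codebook:
        specs = [
            VariableSpec(
                name=self.outcome_name,
                role="outcome",
                levels=self.outcome_levels,
                reference=self.outcome_levels[0],
            )
        ]
        for v in self.variables:
            specs.append(
                VariableSpec(
                    name=v.name,
                    role="determinant",
                    levels=v.levels,
                    reference=v.levels[0],
                )
            )
        return Codebook(tuple(specs))


@dataclass
class SyntheticTruth:
    """Realised ground truth for one generated dataset.

    The linear predictor decomposes exactly as
    ``eta = beta0 + x_effect + interaction_effect + u_effect`` per record;
    :meth:`recompute_eta` reproduces ``eta`` from the stored components.
    """

    beta0: float
    betas: dict[tuple[str, str], float]
    sigma2_u: float
    stratum_keys: list[tuple[tuple[str, str], ...]]
    u: np.ndarray  # realised stratum effects, aligned with stratum_keys
    interaction_bonus: np.ndarray  # per-stratum bonus, same alignment
    stratum_of_record: np.ndarray  # zero-based, record order
    x_effect: np.ndarray
    u_effect: np.ndarray
    interaction_effect: np.ndarray
    eta: np.ndarray
    y: np.ndarray  # outcome before missingness, 0/1
    true_vpc: float
    prevalence: float

    def recompute_eta(self) -> np.ndarray:
        return self.beta0 + self.x_effect + self.interaction_effect + self.u_effect


def _draw_covariates(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_records
    cols: dict[str, np.ndarray] = {}
    if config.balanced:
        grids = np.meshgrid(
            *[np.arange(len(v.levels)) for v in config.variables], indexing="ij"
        )
        combos = np.column_stack([g.ravel() for g in grids])
        reps = -(-n // len(combos))  # ceil
        alloc = np.tile(combos, (reps, 1))[:n]
        for i, v in enumerate(config.variables):
            cols[v.name] = np.asarray(v.levels)[alloc[:, i]]
        return pd.DataFrame(cols)
    if config.profile_mixture:
        weights = np.array([t[0] for t in config.profile_mixture])
        which = rng.choice(len(weights), size=n, p=weights)
        for v in config.variables:
            out = np.empty(n, dtype=object)
            for m, (_, overrides) in enumerate(config.profile_mixture):
                mask = which == m
                probs = np.asarray(overrides.get(v.name, v.marginals), dtype=float)
                out[mask] = rng.choice(v.levels, size=int(mask.sum()), p=probs)
            cols[v.name] = out.astype(str)
        return pd.DataFrame(cols)
    for v in config.variables:
        cols[v.name] = rng.choice(v.levels, size=n, p=v.marginals)
    return pd.DataFrame(cols)


def generate(config: SyntheticConfig) -> tuple[SurveyDataset, SyntheticTruth]:
    """Generate one dataset and its ground truth. Same seed, same output."""
    rng = np.random.default_rng(config.seed)
    covs = _draw_covariates(config, rng)
    n = config.n_records
    var_names = [v.name for v in config.variables]

    # per-record main-effect contribution
    x_effect = np.zeros(n)
    for v in config.variables:
        col = covs[v.name].to_numpy()
        for level in v.levels[1:]:
            b = config.betas.get((v.name, level), 0.0)
            if b:
                x_effect += b * (col == level)

    # observed strata, sorted by level order for deterministic alignment
    level_idx = np.column_stack(
        [covs[v.name].map({l: i for i, l in enumerate(v.levels)}).to_numpy()
         for v in config.variables]
    )
    ordered = sorted({tuple(row) for row in level_idx})
    key_of = {combo: j for j, combo in enumerate(ordered)}
    s = np.array([key_of[tuple(row)] for row in level_idx])
    keys = [
        tuple((v.name, v.levels[i]) for v, i in zip(config.variables, combo))
        for combo in ordered
    ]

    u = rng.normal(0.0, np.sqrt(config.sigma2_u), size=len(keys))
    if config.sigma2_u == 0.0:
        u = np.zeros(len(keys))

    bonus = np.zeros(len(keys))
    for inter in config.interactions:
        for j, key in enumerate(keys):
            if inter.when(dict(key)):
                bonus[j] += inter.bonus

    u_effect = u[s]
    interaction_effect = bonus[s]
    eta = config.beta0 + x_effect + interaction_effect + u_effect
    y = (rng.uniform(size=n) < expit(eta)).astype(int)

    records = covs.copy()
    records.insert(0, config.outcome_name,
                   np.asarray(config.outcome_levels)[y])
    records.index = pd.RangeIndex(n, name="record_id")

    if config.missing_rate > 0.0:
        mask = rng.uniform(size=records.shape) < config.missing_rate
        records = records.mask(mask)

    dataset = SurveyDataset(
        records=records,
        codebook=config.codebook(),
        provenance=f"synthetic(seed={config.seed})",
    )
    truth = SyntheticTruth(
        beta0=config.beta0,
        betas=dict(config.betas),
        sigma2_u=config.sigma2_u,
        stratum_keys=keys,
        u=u,
        interaction_bonus=bonus,
        stratum_of_record=s,
        x_effect=x_effect,
        u_effect=u_effect,
        interaction_effect=interaction_effect,
        eta=eta,
        y=y,
        true_vpc=float(100.0 * config.sigma2_u
                       / (config.sigma2_u + np.pi**2 / 3.0)),
        prevalence=float(y.mean()),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# survey-like presets


PRESET_PREVALENCE = {"cough": 0.19, "fever": 0.28, "ari": 0.05}

_CHILD_AGE = SyntheticVariable("child_age", ("1 year and less", "2 to 5"))
_DIVISION = SyntheticVariable(
    "division", ("Dhaka", "Khulna", "Rajshahi", "Other divisions")
)
_HH_HEAD_AGE = SyntheticVariable(
    "hh_head_age", ("13 to 29 years", "30 to 44 years", "45 years and above")
)
_GARBAGE = SyntheticVariable(
    "garbage_disposal",
    (
        "Disposed within premises",
        "Collected from home",
        "Disposed in bin outside",
        "Disposed in open spaces",
    ),
)
_EMPLOYED = SyntheticVariable("mother_employed", ("No", "Yes"))
_MOTHER_AGE = SyntheticVariable("mother_age", ("Below 18 years", "18 years and above"))
_SCHOOL = SyntheticVariable("mother_school", ("No", "Yes"))
_KITCHEN = SyntheticVariable("separate_kitchen", ("No", "Yes"))
_WEALTH = SyntheticVariable("wealth_index", ("Rich", "Middle", "Poor"))
_FUEL = SyntheticVariable(
    "cooking_fuel",
    ("Charcoal, dung cakes", "Kerosene or liquid gas", "Natural gas", "Wood fuel"),
)

_PRESET_VARIABLES: dict[str, tuple[SyntheticVariable, ...]] = {
    "cough": (_CHILD_AGE, _DIVISION, _HH_HEAD_AGE, _GARBAGE, _EMPLOYED),
    "fever": (_CHILD_AGE, _DIVISION, _HH_HEAD_AGE, _MOTHER_AGE, _GARBAGE,
              _SCHOOL, _EMPLOYED, _KITCHEN),
    "ari": (_CHILD_AGE, _DIVISION, _WEALTH, _HH_HEAD_AGE, _FUEL, _EMPLOYED),
}

# true main effects on the odds-ratio scale, per outcome
_PRESET_ORS: dict[str, dict[tuple[str, str], float]] = {
    "cough": {
        ("child_age", "2 to 5"): 0.76,
        ("division", "Khulna"): 1.41,
        ("division", "Rajshahi"): 1.94,
        ("division", "Other divisions"): 1.76,
        ("hh_head_age", "30 to 44 years"): 0.62,
        ("hh_head_age", "45 years and above"): 0.81,
        ("garbage_disposal", "Collected from home"): 0.55,
        ("garbage_disposal", "Disposed in bin outside"): 0.54,
        ("garbage_disposal", "Disposed in open spaces"): 0.51,
        ("mother_employed", "Yes"): 0.75,
    },
    "fever": {
        ("child_age", "2 to 5"): 0.89,
        ("division", "Khulna"): 1.10,
        ("division", "Rajshahi"): 1.52,
        ("division", "Other divisions"): 1.50,
        ("hh_head_age", "30 to 44 years"): 0.66,
        ("hh_head_age", "45 years and above"): 0.81,
        ("mother_age", "18 years and above"): 0.72,
        ("garbage_disposal", "Collected from home"): 0.65,
        ("garbage_disposal", "Disposed in bin outside"): 0.63,
        ("garbage_disposal", "Disposed in open spaces"): 0.74,
        ("mother_school", "Yes"): 0.84,
        ("mother_employed", "Yes"): 1.15,
        ("separate_kitchen", "Yes"): 1.15,
    },
    "ari": {
        ("child_age", "2 to 5"): 0.78,
        ("division", "Khulna"): 2.46,
        ("division", "Rajshahi"): 1.66,
        ("division", "Other divisions"): 2.06,
        ("wealth_index", "Middle"): 0.74,
        ("wealth_index", "Poor"): 0.93,
        ("hh_head_age", "30 to 44 years"): 0.48,
        ("hh_head_age", "45 years and above"): 0.88,
        ("cooking_fuel", "Kerosene or liquid gas"): 0.82,
        ("cooking_fuel", "Natural gas"): 0.67,
        ("cooking_fuel", "Wood fuel"): 0.48,
        ("mother_employed", "Yes"): 0.67,
    },
}

# residual (beyond-main-effects) stratum variance per outcome
_PRESET_SIGMA2 = {"cough": 0.05, "fever": 0.02, "ari": 0.04}


def _calibrate_beta0(
    variables: Sequence[SyntheticVariable],
    betas: Mapping[tuple[str, str], float],
    sigma2_u: float,
    target: float,
) -> float:
    """Intercept giving marginal prevalence ``target`` under the preset DGP.

    The main-effect contribution distributes as an independent sum over
    variables; its exact distribution is enumerated per variable and
    convolved, and the Gaussian stratum effect is integrated by
    Gauss-Hermite quadrature, leaving a monotone scalar equation for beta0.
    """
    values = np.array([0.0])
    probs = np.array([1.0])
    for v in variables:
        effs = np.array(
            [0.0] + [betas.get((v.name, l), 0.0) for l in v.levels[1:]]
        )
        values = (values[:, None] + effs[None, :]).ravel()
        probs = (probs[:, None] * v.marginals[None, :]).ravel()
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    u_nodes = nodes * np.sqrt(sigma2_u) if sigma2_u > 0 else np.zeros_like(nodes)
    w = weights / weights.sum()

    def prevalence(b0: float) -> float:
        grid = b0 + values[:, None] + u_nodes[None, :]
        return float((probs[:, None] * w[None, :] * expit(grid)).sum())

    return float(brentq(lambda b: prevalence(b) - target, -20.0, 20.0, xtol=1e-10))


def uhs_like_preset(outcome: str, *, seed: int = 0) -> SyntheticConfig:
    """Survey-like configuration for one of ``cough``, ``fever``, ``ari``.

    3,183 records; the outcome's strata-defining variable set with uniform
    marginals; true odds ratios at the reported survey effect sizes; the
    intercept calibrated so marginal prevalence hits 19% / 28% / 5%.
    """
    if outcome not in _PRESET_VARIABLES:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of "
                       f"{sorted(_PRESET_VARIABLES)}")
    variables = _PRESET_VARIABLES[outcome]
    betas = {k: float(np.log(v)) for k, v in _PRESET_ORS[outcome].items()}
    sigma2 = _PRESET_SIGMA2[outcome]
    beta0 = _calibrate_beta0(variables, betas, sigma2, PRESET_PREVALENCE[outcome])
    return SyntheticConfig(
        n_records=3183,
        variables=variables,
        beta0=beta0,
        betas=betas,
        sigma2_u=sigma2,
        seed=seed,
        outcome_name=outcome,
        outcome_levels=("No", "Yes"),
    )
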