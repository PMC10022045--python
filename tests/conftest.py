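"""Shared fixtures: toy codebooks, small synthetic datasets, cheap fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import maihda as m
from maihda.synthetic_data import SyntheticConfig, SyntheticVariable, generate


@pytest.fixture
def toy_codebook() -> m.Codebook:
    return m.Codebook(
        (
            m.VariableSpec("sick", "outcome", ("No", "Yes"), "No"),
            m.VariableSpec(
                "age", "determinant", ("young", "old"), "young",
                missing_codes=("99",),
            ),
            m.VariableSpec(
                "division", "determinant",
                ("Dhaka", "Khulna", "Other divisions"), "Dhaka",
                recode_map={
                    "Barisal": "Other divisions",
                    "Chittagong": "Other divisions",
                    "Rangpur": "Other divisions",
                    "Sylhet": "Other divisions",
                },
            ),
        )
    )


def write_toy_table(path, rows, header="sick,age,division"):
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


@pytest.fixture(scope="session")
def cough_dataset():
    cfg = m.uhs_like_preset("cough", seed=1)
    dataset, truth = generate(cfg)
    return dataset, truth


def _small_config(seed=5):
    variables = (
        SyntheticVariable("g1", ("a", "b")),
        SyntheticVariable("g2", ("a", "b")),
        SyntheticVariable("g3", ("a", "b", "c")),
    )
    betas = {("g1", "b"): 0.7, ("g2", "b"): -0.5,
             ("g3", "b"): 0.4, ("g3", "c"): -0.6}
    return SyntheticConfig(
        n_records=1500, variables=variables, beta0=-0.8, betas=betas,
        sigma2_u=0.3, seed=seed,
    )


@pytest.fixture(scope="session")
def small_fit_pair():
    """A 12-stratum dataset with both models fitted at screening quality."""
    dataset, truth = generate(_small_config())
    index = m.build_strata(dataset, dataset.codebook.determinant_names)
    sampler = m.SamplerConfig(chains=2, iterations=900, burn_in=300, seed=42)
    fit1 = m.fit(dataset, m.ModelSpec("outcome", index), config=sampler)
    fit2 = m.fit(
        dataset,
        m.ModelSpec("outcome", index, fixed_vars=index.variables),
        config=sampler,
    )
    return dataset, truth, index, fit1, fit2


@pytest.fixture
def fake_fit_factory():
    """Build a ModelFit with prescribed posterior draws on a tiny dataset.

    Used to unit-test posterior summarisation (odds ratios, stratum
    effects, predicted probabilities) against closed-form oracles.
    """

    def make(
        beta0_draws: np.ndarray,
        beta_draws: np.ndarray | None = None,
        sigma2_draws: np.ndarray | None = None,
        u_draws: np.ndarray | None = None,
        n_strata: int = 2,
        y: np.ndarray | None = None,
        X: np.ndarray | None = None,
        s: np.ndarray | None = None,
        design_columns: list[str] | None = None,
    ) -> m.ModelFit:
        variables = (SyntheticVariable("g", tuple("abcdefgh"[:n_strata])),)
        n = 2 * n_strata if y is None else len(y)
        cfg = SyntheticConfig(
            n_records=n, variables=variables, seed=0, balanced=True
        )
        dataset, _ = generate(cfg)
        index = m.build_strata(dataset, ["g"])
        beta0_draws = np.atleast_2d(beta0_draws)
        c, d = beta0_draws.shape
        p = 0 if beta_draws is None else beta_draws.shape[-1]
        if beta_draws is None:
            beta_draws = np.zeros((c, d, 0))
        if sigma2_draws is None:
            sigma2_draws = np.ones((c, d))
        if u_draws is None:
            u_draws = np.zeros((c, d, index.observed_count))
        if y is None:
            y = np.tile([0.0, 1.0], n // 2)
        if X is None:
            X = np.zeros((n, p))
        if s is None:
            s = np.repeat(np.arange(index.observed_count), n // index.observed_count)
        spec = m.ModelSpec("outcome", index)
        return m.ModelFit(
            spec=spec,
            priors=m.PriorSpec(),
            config=m.SamplerConfig(chains=max(c, 1), iterations=d + 1, burn_in=0, seed=0),
            design_columns=design_columns or [f"x{k}" for k in range(p)],
            beta0=beta0_draws,
            beta=np.asarray(beta_draws, dtype=float),
            sigma2=np.asarray(sigma2_draws, dtype=float),
            u=np.asarray(u_draws, dtype=float),
            y=np.asarray(y, dtype=float),
            X=np.asarray(X, dtype=float),
            s=np.asarray(s),
        )

    return make
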