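"""Construction of intersectional strata.

A stratum is one combination of categories across the selected social
determinants (e.g. child age x division x mother's employment); it is the
level-2 unit of the multilevel model. Only combinations actually observed in
the data become model units — empty cells of the cross-product contribute
nothing to the likelihood — and strata of size 1 are deliberately retained,
since the multilevel model pools information across strata.

Ordinals are 1-based and assigned in lexicographic codebook-level order, so
rankings and caterpillar plots are reproducible across runs and record
orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_io import SurveyDataset

__all__ = [
    "StratumKey",
    "StrataIndex",
    "build_strata",
    "stratum_label",
    "roster_frame",
    "PRESET_VARIABLES",
]

# Strata-defining variable sets used for each outcome (child-health survey
# presets); see synthetic_data.uhs_like_preset for the matching generators.
PRESET_VARIABLES: dict[str, list[str]] = {
    "cough": [
        "child_age", "division", "hh_head_age", "garbage_disposal",
        "mother_employed",
    ],
    "fever": [
        "child_age", "division", "hh_head_age", "mother_age",
        "garbage_disposal", "mother_school", "mother_employed",
        "separate_kitchen",
    ],
    "ari": [
        "child_age", "division", "wealth_index", "hh_head_age",
        "cooking_fuel", "mother_employed",
    ],
}

StratumKey = tuple[tuple[str, str], ...]  # ((variable, level), ...) in codebook order


def stratum_label(key: StratumKey) -> str:
    """Deterministic human-readable label: ``var=level`` pairs joined by ``|``."""
    return "|".join(f"{var}={level}" for var, level in key)


@dataclass
class StrataIndex:
    """Mapping from records to observed intersectional strata.

    ``assignment`` maps record id -> 1-based stratum ordinal; ``keys[j-1]``
    is the :data:`StratumKey` of ordinal ``j``; ``sizes[j-1]`` its record
    count. ``potential_count`` is the full cross-product size, of which
    ``observed_count`` combinations actually occur.
    """

    variables: tuple[str, ...]
    keys: list[StratumKey]
    assignment: pd.Series  # record_id -> ordinal (1-based)
    sizes: np.ndarray
    potential_count: int

    @property
    def observed_count(self) -> int:
        return len(self.keys)

    @property
    def labels(self) -> list[str]:
        return [stratum_label(k) for k in self.keys]

    def zero_based(self) -> np.ndarray:
        """Per-record stratum indices 0..J-1 in assignment (record) order."""
        return self.assignment.to_numpy() - 1


def build_strata(dataset: SurveyDataset, vars: Sequence[str]) -> StrataIndex:
    """Index each record into its intersectional stratum.

    Requires a dataset complete on ``vars`` (run
    :func:`maihda.survey_io.complete_cases` first). Strata are enumerated for
    observed combinations only and sorted lexicographically by codebook level
    order, which fixes the 1-based ordinals.
    """
    vars = list(vars)
    if not vars:
        raise ValueError("vars must be non-empty")
    unknown = [v for v in vars if v not in dataset.codebook]
    if unknown:
        raise KeyError(f"variables not in codebook: {unknown}")
    # canonical codebook order of the strata-defining variables
    vars = [n for n in dataset.codebook.names if n in set(vars)]
    sub = dataset.records[vars]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(
            f"missing values in {bad}; apply complete_cases before build_strata"
        )

    specs = [dataset.codebook[v] for v in vars]
    # per-record level indices in codebook level order -> lexicographic sort key
    level_idx = np.column_stack(
        [sub[v].map({l: i for i, l in enumerate(s.levels)}).to_numpy()
         for v, s in zip(vars, specs)]
    )
    observed = {tuple(row) for row in level_idx}
    ordered = sorted(observed)
    keys: list[StratumKey] = [
        tuple((v, s.levels[i]) for v, s, i in zip(vars, specs, combo))
        for combo in ordered
    ]
    ordinal_of = {combo: j + 1 for j, combo in enumerate(ordered)}
    assignment = pd.Series(
        [ordinal_of[tuple(row)] for row in level_idx],
        index=sub.index,
        name="stratum",
    )
    sizes = np.bincount(assignment.to_numpy(), minlength=len(keys) + 1)[1:]
    return StrataIndex(
        variables=tuple(vars),
        keys=keys,
        assignment=assignment,
        sizes=sizes,
        potential_count=prod(len(s.levels) for s in specs),
    )


def roster_frame(index: StrataIndex) -> pd.DataFrame:
    """Strata roster (ordinal, label, size) — the stratum-calculation sheet."""
    return pd.DataFrame(
        {
            "ordinal": np.arange(1, index.observed_count + 1),
            "label": index.labels,
            "size": index.sizes,
        }
    )
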