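"""Codebook-driven reading, validation and export of categorical survey microdata.

The analysis operates on purely categorical tables: one row per child, one
column per variable, every cell either a declared category label or missing.
A :class:`Codebook` declares each variable's role (outcome / determinant /
id), its levels, its reference level, its missing codes, and an optional
recoding (e.g. merging several administrative divisions into one "Other
divisions" category). Loading validates every cell against the codebook and
applies recodes and missing codes; downstream modules can then assume clean,
fully-declared categories.

Missing data are handled by complete-case analysis only (no imputation):
:func:`complete_cases` drops records with any missing value among a chosen
variable set, mirroring standard practice for surveys whose missingness is
assumed completely at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "VariableSpec",
    "Codebook",
    "SurveyDataset",
    "CodebookError",
    "SurveyValidationError",
    "load_survey",
    "complete_cases",
    "write_survey",
    "load_codebook",
    "write_codebook",
]


class CodebookError(ValueError):
    """Raised when a codebook violates its own invariants."""


class SurveyValidationError(ValueError):
    """Raised when a data table does not conform to its codebook."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one categorical survey variable.

    Parameters
    ----------
    name
        Column name in the data table.
    role
        One of ``"outcome"``, ``"determinant"``, ``"id"``. Outcomes must be
        binary with levels interpreted as ``{absent=0, present=1}`` in level
        order.
    levels
        Ordered category labels (after recoding). Order is canonical: it
        drives stratum ordering and design-matrix column order.
    reference
        The reference level, one of ``levels``.
    missing_codes
        Tokens (e.g. ``"99"``, ``"NA"``) treated as missing on load; empty
        cells are always missing.
    recode_map
        Optional ``old-label -> new-label`` mapping applied on load. Targets
        must be declared levels.
    """

    name: str
    role: str
    levels: tuple[str, ...]
    reference: str
    missing_codes: tuple[str, ...] = ()
    recode_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "missing_codes", tuple(self.missing_codes))
        if self.role not in ("outcome", "determinant", "id"):
            raise CodebookError(f"{self.name}: unknown role {self.role!r}")
        if len(self.levels) < 2:
            raise CodebookError(f"{self.name}: needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise CodebookError(f"{self.name}: duplicate levels")
        if self.reference not in self.levels:
            raise CodebookError(
                f"{self.name}: reference {self.reference!r} not among levels"
            )
        if self.role == "outcome" and len(self.levels) != 2:
            raise CodebookError(f"{self.name}: outcomes must have exactly 2 levels")
        if self.recode_map:
            bad = set(self.recode_map.values()) - set(self.levels)
            if bad:
                raise CodebookError(
                    f"{self.name}: recode targets {sorted(bad)} are not declared levels"
                )

    def level_index(self, label: str) -> int:
        return self.levels.index(label)


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of :class:`VariableSpec` describing one survey table."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CodebookError("duplicate variable names in codebook")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def outcome_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "outcome"]

    @property
    def determinant_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "determinant"]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)


@dataclass
class SurveyDataset:
    """A validated categorical survey table plus its codebook.

    ``records`` is a DataFrame indexed by record id with one string column
    per non-id codebook variable; missing values are ``NaN``.
    """

    records: pd.DataFrame
    codebook: Codebook
    provenance: str = ""

    @property
    def n_records(self) -> int:
        return len(self.records)

    def outcome01(self, outcome: str) -> pd.Series:
        """The outcome recoded to 0/1 in declared level order (absent, present)."""
        spec = self.codebook[outcome]
        if spec.role != "outcome":
            raise ValueError(f"{outcome!r} is not declared as an outcome")
        col = self.records[outcome]
        if col.isna().any():
            raise ValueError(f"outcome {outcome!r} has missing values; "
                             "run complete_cases first")
        return col.map({spec.levels[0]: 0, spec.levels[1]: 1}).astype(int)


# ---------------------------------------------------------------------------
# codebook JSON round-trip


def load_codebook(path: str | Path) -> Codebook:
    raw = json.loads(Path(path).read_text())
    variables = []
    for v in raw["variables"]:
        variables.append(
            VariableSpec(
                name=v["name"],
                role=v["role"],
                levels=tuple(v["levels"]),
                reference=v["reference"],
                missing_codes=tuple(v.get("missing_codes", ())),
                recode_map=v.get("recode_map") or None,
            )
        )
    return Codebook(tuple(variables))


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    doc = {
        "variables": [
            {
                "name": v.name,
                "role": v.role,
                "levels": list(v.levels),
                "reference": v.reference,
                "missing_codes": list(v.missing_codes),
                "recode_map": dict(v.recode_map) if v.recode_map else None,
            }
            for v in codebook.variables
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# loading and validation


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def load_survey(
    codebook: Codebook,
    table_path: str | Path,
    *,
    id_column: str | None = None,
    provenance: str | None = None,
) -> SurveyDataset:
    """Read a delimited text table and validate it against the codebook.

    The delimiter (comma or tab) is autodetected from the header line. Cells
    are whitespace-trimmed and matched case-sensitively. Recode maps are
    applied before validation; cells matching a variable's missing codes (or
    empty cells) become missing. Unknown columns in the codebook's variable
    set and undeclared category labels are fatal.
    """
    path = Path(table_path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    if id_column is None:
        id_candidates = [v.name for v in codebook.variables if v.role == "id"]
        id_column = id_candidates[0] if id_candidates else None

    needed = [v.name for v in codebook.variables if v.role != "id"]
    missing_cols = [n for n in needed if n not in raw.columns]
    if missing_cols:
        raise SurveyValidationError(
            f"table lacks codebook columns: {missing_cols}"
        )

    if id_column is not None and id_column in raw.columns:
        ids = raw[id_column].str.strip()
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5].tolist()
            raise SurveyValidationError(f"duplicate record ids: {dupes}")
        index = pd.Index(ids, name="record_id")
    else:
        index = pd.RangeIndex(len(raw), name="record_id")

    out = pd.DataFrame(index=index)
    for name in needed:
        spec = codebook[name]
        col = raw[name].str.strip()
        if spec.recode_map:
            col = col.replace(dict(spec.recode_map))
        col = col.mask(col.isin(spec.missing_codes) | (col == ""))
        bad = col.dropna()[~col.dropna().isin(spec.levels)]
        if len(bad):
            row, val = bad.index[0], bad.iloc[0]
            raise SurveyValidationError(
                f"undeclared label {val!r} in column {name!r} at row {row!r} "
                f"({len(bad)} offending cells)"
            )
        out[name] = col.values
    out.index = index
    return SurveyDataset(
        records=out,
        codebook=codebook,
        provenance=provenance or str(path),
    )


def complete_cases(
    dataset: SurveyDataset, vars: Sequence[str]
) -> tuple[SurveyDataset, int]:
    """Keep only records with no missing value among ``vars``.

    Returns the filtered dataset and the number of dropped records.
    Raises if no complete case remains.
    """
    unknown = [v for v in vars if v not in dataset.codebook]
    if unknown:
        raise KeyError(f"variables not in codebook: {unknown}")
    keep = dataset.records[list(vars)].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped == dataset.n_records:
        raise SurveyValidationError(
            f"no complete cases on {list(vars)}"
        )
    return (
        SurveyDataset(
            records=dataset.records.loc[keep].copy(),
            codebook=dataset.codebook,
            provenance=dataset.provenance,
        ),
        dropped,
    )


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Export the dataset as CSV in codebook column order (missing as empty)."""
    order = [n for n in dataset.codebook.names if n in dataset.records.columns]
    dataset.records[order].to_csv(path, index=True, na_rep="")
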