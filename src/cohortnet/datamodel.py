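"""Cohort tables and binary indicator recoding.

Case-control cohorts in cardiovascular epidemiology mix continuous risk
factors (lipids, blood pressure, BMI, ...), genotypes coded as the three
genotypic classes (common homozygote, heterozygote, rare homozygote) and
binary traits such as smoking, together with a binary outcome recording
whether the individual had an event during follow-up.

Downstream similarity learning operates on 0/1 vectors only, so every
variable is recoded into a *complete and mutually exclusive* set of binary
indicator columns:

* ``genotype3`` -> three columns, one per genotypic class;
* ``continuous`` -> empirical tertiles (chosen to mirror the three genotypic
  classes), then three columns, one per tertile;
* ``binary``    -> a yes/no pair.

No reference category is omitted: the feature-selection stage decides for
itself which of two complementary columns is redundant.  Categories are
1-based: tertile 1 is the lowest third, genotype class 1 the common
homozygote.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KINDS = ("continuous", "genotype3", "binary")

#: default category labels per variable kind
_DEFAULT_LABELS = {
    "continuous": ("t1", "t2", "t3"),
    "genotype3": ("1", "2", "3"),
    "binary": ("yes", "no"),
}

EVENT_LABEL = "Event"
NO_EVENT_LABEL = "No_Event"


class CohortError(ValueError):
    """Raised for malformed cohort input (unknown columns, domain violations)."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single cohort variable.

    Parameters
    ----------
    name
        Column name in the cohort table; must be unique.
    kind
        One of ``continuous``, ``genotype3``, ``binary``.  Determines how
        many indicator columns the variable expands into (3, 3 and 2).
    labels
        Category labels, lowest/common-homozygote first.  Defaults per kind.
    """

    name: str
    kind: str
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise CohortError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if not self.labels:
            object.__setattr__(self, "labels", _DEFAULT_LABELS[self.kind])
        expected = 2 if self.kind == "binary" else 3
        if len(self.labels) != expected:
            raise CohortError(
                f"{self.name!r}: kind {self.kind!r} needs {expected} labels, "
                f"got {len(self.labels)}"
            )

    @property
    def n_categories(self) -> int:
        return 2 if self.kind == "binary" else 3


@dataclass
class CohortTable:
    """Typed individuals x variables table with a binary outcome.

    ``values`` holds one column per :class:`VariableSpec`, in spec order;
    ``outcome`` is 1 for individuals with an event during follow-up.
    """

    individuals: list[str]
    variables: list[VariableSpec]
    values: pd.DataFrame
    outcome: np.ndarray

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=int)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortError("duplicate variable names in schema")
        if list(self.values.columns) != names:
            self.values = self.values.loc[:, names]
        if len(self.individuals) != len(self.values):
            raise CohortError("individuals and value rows differ in length")
        if len(self.outcome) != len(self.values):
            raise CohortError("outcome length does not match number of rows")
        if not np.isin(self.outcome, (0, 1)).all():
            raise CohortError("outcome must be binary 0/1")
        for spec in self.variables:
            col = self.values[spec.name]
            if spec.kind == "genotype3":
                bad = ~col.isin((0, 1, 2)) & col.notna()
                if bad.any():
                    row = self.individuals[int(np.flatnonzero(bad)[0])]
                    raise CohortError(
                        f"genotype column {spec.name!r} has value outside "
                        f"{{0,1,2}} at row {row!r}"
                    )
            elif spec.kind == "binary":
                bad = ~col.isin((0, 1)) & col.notna()
                if bad.any():
                    row = self.individuals[int(np.flatnonzero(bad)[0])]
                    raise CohortError(
                        f"binary column {spec.name!r} has non-0/1 value at row {row!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.outcome.sum())

    def variable(self, name: str) -> VariableSpec:
        for spec in self.variables:
            if spec.name == name:
                return spec
        raise KeyError(name)


@dataclass(frozen=True)
class IndicatorColumn:
    """Metadata tying one 0/1 column back to its parent variable."""

    parent: str
    category: int  # 1-based; 0 for outcome columns
    label: str


@dataclass
class IndicatorMatrix:
    """Individuals x binary indicator columns.

    For every parent variable the indicator columns partition each row:
    exactly one of them is 1 (exhaustive, mutually exclusive categories).
    When the outcome is included it appears as the complementary
    ``Event`` / ``No_Event`` pair.
    """

    columns: list[IndicatorColumn]
    data: pd.DataFrame
    has_outcome: bool = False

    def __post_init__(self):
        if list(self.data.columns) != [c.label for c in self.columns]:
            raise CohortError("indicator data columns do not match metadata labels")
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise CohortError("indicator entries must be 0/1")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.columns]

    @property
    def feature_columns(self) -> list[IndicatorColumn]:
        """Indicator columns excluding the outcome pair."""
        return [c for c in self.columns if c.category != 0]

    def feature_frame(self) -> pd.DataFrame:
        """0/1 feature matrix with outcome columns excluded."""
        return self.data.loc[:, [c.label for c in self.feature_columns]]

    def parent_of(self, label: str) -> tuple[str, int]:
        """Recover (parent variable, 1-based category) from a column label."""
        for c in self.columns:
            if c.label == label:
                return c.parent, c.category
        raise KeyError(label)


# ---------------------------------------------------------------------------
# recoding operations
# ---------------------------------------------------------------------------


def tertile_bin(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Assign each value to a tertile category in {1, 2, 3}.

    Categories are assigned by rank against the 1/3 and 2/3 empirical
    quantile positions, so the three bins are as equal in size as ``n``
    permits (sizes differ by at most one, larger bins first).  Ties are
    broken by stable rank order, i.e. original row order.

    Raises
    ------
    CohortError
        If fewer than 3 distinct values are present (no tertiles exist).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise CohortError("tertile_bin expects a 1-D vector")
    if np.isnan(v).any():
        raise CohortError("tertile_bin: missing values must be dropped first")
    n = v.size
    if np.unique(v).size < 3:
        raise CohortError("tertile_bin: need at least 3 distinct values")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    cut1 = int(np.ceil(n / 3))
    cut2 = int(np.ceil(2 * n / 3))
    return 1 + (ranks >= cut1).astype(int) + (ranks >= cut2).astype(int)


def _indicator_block(spec: VariableSpec, col: pd.Series) -> tuple[list[IndicatorColumn], np.ndarray]:
    """One-hot expansion of a single variable per its kind."""
    if spec.kind == "continuous":
        cats = tertile_bin(col.to_numpy())
    elif spec.kind == "genotype3":
        cats = col.to_numpy().astype(int) + 1  # classes 0/1/2 -> 1/2/3
    else:  # binary: value 1 -> first label ("yes"), 0 -> second ("no")
        cats = np.where(col.to_numpy().astype(int) == 1, 1, 2)
    k = spec.n_categories
    block = np.zeros((len(col), k), dtype=int)
    block[np.arange(len(col)), cats - 1] = 1
    meta = [
        IndicatorColumn(spec.name, i + 1, f"{spec.name}:{spec.labels[i]}")
        for i in range(k)
    ]
    return meta, block


def expand_indicators(cohort: CohortTable, include_outcome: bool = False) -> IndicatorMatrix:
    """Recode every cohort variable into binary indicator columns.

    genotype3 variables expand into their 3 genotypic classes, continuous
    variables into 3 tertile membership columns, binary variables into a
    yes/no pair.  With ``include_outcome`` the complementary ``Event`` /
    ``No_Event`` pair is appended so the outcome can participate as two
    nodes in the similarity graph.
    """
    meta: list[IndicatorColumn] = []
    blocks: list[np.ndarray] = []
    for spec in cohort.variables:
        m, b = _indicator_block(spec, cohort.values[spec.name])
        meta.extend(m)
        blocks.append(b)
    if include_outcome:
        event = cohort.outcome.reshape(-1, 1)
        blocks.append(np.hstack([event, 1 - event]))
        meta.extend(
            [IndicatorColumn("outcome", 0, EVENT_LABEL), IndicatorColumn("outcome", 0, NO_EVENT_LABEL)]
        )
    data = pd.DataFrame(
        np.hstack(blocks), columns=[c.label for c in meta], index=cohort.individuals
    )
    return IndicatorMatrix(columns=meta, data=data, has_outcome=include_outcome)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_schema(path: str | Path) -> tuple[list[VariableSpec], str]:
    """Load a YAML schema declaring variable kinds and the outcome column.

    Expected layout::

        outcome: chd
        variables:
          - {name: bmi, kind: continuous}
          - {name: LIPC, kind: genotype3}
          - {name: smoking, kind: binary}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [
        VariableSpec(v["name"], v["kind"], tuple(v.get("labels", ())))
        for v in raw["variables"]
    ]
    return specs, raw.get("outcome", "outcome")


def read_cohort(
    path: str | Path,
    schema: Iterable[VariableSpec],
    outcome_col: str = "outcome",
    id_col: str | None = None,
) -> CohortTable:
    """Read a delimited cohort table (comma or tab) against a schema.

    Rows with any missing value are dropped with a logged count; the study
    design restricts the analysis to participants with complete records.
    Unknown columns (not in the schema, not the outcome, not the id) and
    out-of-domain genotype values raise :class:`CohortError`.
    """
    schema = list(schema)
    path = Path(path)
    if path.stat().st_size == 0:
        raise CohortError(f"{path}: empty file")
    df = pd.read_csv(path, sep=None, engine="python")
    if id_col is None and df.columns[0].lower() in ("id", "individual", "sample"):
        id_col = df.columns[0]
    known = {s.name for s in schema} | {outcome_col} | ({id_col} if id_col else set())
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise CohortError(f"{path}: unknown columns {unknown}")
    missing = [s.name for s in schema if s.name not in df.columns]
    if outcome_col not in df.columns:
        missing.append(outcome_col)
    if missing:
        raise CohortError(f"{path}: schema columns absent from file: {missing}")

    individuals = (
        df[id_col].astype(str).tolist() if id_col else [str(i) for i in range(len(df))]
    )
    wanted = [s.name for s in schema] + [outcome_col]
    sub = df[wanted]
    complete = sub.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%d record(s) removed with incomplete data", n_dropped)
    sub = sub.loc[complete]
    individuals = [ind for ind, keep in zip(individuals, complete) if keep]
    if len(sub) == 0:
        raise CohortError(f"{path}: no complete records")
    return CohortTable(
        individuals=individuals,
        variables=schema,
        values=sub[[s.name for s in schema]].reset_index(drop=True),
        outcome=sub[outcome_col].to_numpy(dtype=int),
    )


def write_indicators(matrix: IndicatorMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write the indicator matrix as TSV plus a JSON sidecar mapping
    each column to its (parent variable, category)."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".columns.json")
    matrix.data.to_csv(data_path, sep="\t", index_label="individual")
    meta = [
        {"label": c.label, "parent": c.parent, "category": c.category}
        for c in matrix.columns
    ]
    meta_path.write_text(json.dumps(meta, indent=1))
    return data_path, meta_path
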