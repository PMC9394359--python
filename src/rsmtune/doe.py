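"""Face-centered central composite designs over mixed numeric/categorical factors.

A central composite design (CCD) for ``k`` numeric factors consists of the
``2**k`` factorial corners at coded levels ±1, ``2*k`` axial ("star") points at
coded ±alpha on one axis at a time, and ``n_center`` replicated center runs.
With ``alpha = 1`` (the face-centered variant) the axial points sit on the faces
of the factorial hypercube, so no factor ever leaves its stated range.
Categorical factors cannot be varied continuously; the whole numeric design is
replicated once per combination of categorical levels, which multiplies every
space-type count by the product of the level counts.

Coded levels map linearly onto actual factor ranges: the low end of a range is
coded −1 and the high end +1, so ``coded = (actual − center) / half_range``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignSpec",
    "DesignMatrix",
    "InvalidSpecError",
    "build_ccd",
    "code_value",
    "decode_value",
    "read_design",
    "write_design",
]

SPACE_TYPES = ("factorial", "axial", "center")


class InvalidSpecError(ValueError):
    """A factor or design specification violates its invariants."""


@dataclass(frozen=True)
class FactorSpec:
    """One design factor, either numeric (a range) or categorical (a level list).

    Numeric factors carry the actual values coded to −1 (``low``) and +1
    (``high``). Categorical factors carry an ordered list of level labels;
    for two-level categoricals the first label is coded −1 and the second +1
    when the factor enters a regression model.
    """

    name: str
    kind: str = "numeric"  # "numeric" | "categorical"
    low: float | None = None
    high: float | None = None
    levels: tuple[str, ...] | None = None
    integer: bool = False  # round decoded actual values to the nearest integer

    def __post_init__(self) -> None:
        if self.kind == "numeric":
            if self.low is None or self.high is None:
                raise InvalidSpecError(f"numeric factor {self.name!r} needs low and high")
            if self.levels is not None:
                raise InvalidSpecError(f"numeric factor {self.name!r} must not define levels")
            if not self.low < self.high:
                raise InvalidSpecError(
                    f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
                )
        elif self.kind == "categorical":
            if self.low is not None or self.high is not None:
                raise InvalidSpecError(f"categorical factor {self.name!r} must not define low/high")
            if self.levels is None or len(self.levels) < 2:
                raise InvalidSpecError(f"categorical factor {self.name!r} needs >=2 levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise InvalidSpecError(f"categorical factor {self.name!r} has duplicate levels")
        else:
            raise InvalidSpecError(f"unknown factor kind {self.kind!r}")

    @property
    def is_numeric(self) -> bool:
        return self.kind == "numeric"

    @property
    def center(self) -> float:
        if not self.is_numeric:
            raise InvalidSpecError(f"categorical factor {self.name!r} has no numeric center")
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        if not self.is_numeric:
            raise InvalidSpecError(f"categorical factor {self.name!r} has no numeric range")
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class DesignSpec:
    """A face-centered CCD specification: numeric factors, categorical factors,
    axial distance ``alpha`` (coded units) and center replicates per
    categorical combination."""

    numeric_factors: tuple[FactorSpec, ...]
    categorical_factors: tuple[FactorSpec, ...] = ()
    alpha: float = 1.0
    n_center: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "numeric_factors", tuple(self.numeric_factors))
        object.__setattr__(self, "categorical_factors", tuple(self.categorical_factors))
        if len(self.numeric_factors) == 0:
            raise InvalidSpecError("a CCD needs at least one numeric factor")
        for f in self.numeric_factors:
            if not f.is_numeric:
                raise InvalidSpecError(f"{f.name!r} listed as numeric but is {f.kind}")
        for f in self.categorical_factors:
            if f.is_numeric:
                raise InvalidSpecError(f"{f.name!r} listed as categorical but is numeric")
        if not self.alpha > 0:
            raise InvalidSpecError("alpha must be positive")
        if self.n_center < 1:
            raise InvalidSpecError("n_center must be >= 1")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise InvalidSpecError("factor names must be unique")

    @property
    def k(self) -> int:
        return len(self.numeric_factors)

    @property
    def factors(self) -> tuple[FactorSpec, ...]:
        return self.numeric_factors + self.categorical_factors

    @property
    def runs_per_block(self) -> int:
        """Runs per categorical combination: 2^k + 2k + n_center."""
        return 2 ** self.k + 2 * self.k + self.n_center

    @property
    def n_runs(self) -> int:
        n_cat = 1
        for f in self.categorical_factors:
            n_cat *= len(f.levels)
        return self.runs_per_block * n_cat


@dataclass
class DesignMatrix:
    """An ordered set of design runs with coded and actual factor levels.

    ``table`` holds one row per run with columns ``run``, ``space_type``, the
    actual level of each factor (labels for categorical factors), and
    optionally ``response``. Coded levels of the numeric factors are kept in
    ``coded`` (same row order).
    """

    spec: DesignSpec
    table: pd.DataFrame
    coded: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def has_responses(self) -> bool:
        return "response" in self.table.columns and self.table["response"].notna().all()

    @property
    def responses(self) -> np.ndarray:
        if "response" not in self.table.columns:
            raise ValueError("design has no responses attached")
        return self.table["response"].to_numpy(dtype=float)

    def with_responses(self, values) -> "DesignMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self),):
            raise ValueError(f"expected {len(self)} responses, got {values.shape}")
        table = self.table.copy()
        table["response"] = values
        return DesignMatrix(self.spec, table, self.coded.copy())

    def space_counts(self) -> dict[str, int]:
        counts = self.table["space_type"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in SPACE_TYPES}


def code_value(factor: FactorSpec, actual) -> float | np.ndarray:
    """Map an actual numeric value to its coded level in [−1, +1] over the range."""
    if not factor.is_numeric:
        raise InvalidSpecError(f"cannot code categorical factor {factor.name!r} numerically")
    return (np.asarray(actual, dtype=float) - factor.center) / factor.half_range


def decode_value(factor: FactorSpec, coded) -> float | np.ndarray:
    """Inverse of :func:`code_value`; integer factors round to the nearest whole value."""
    if not factor.is_numeric:
        raise InvalidSpecError(f"cannot decode categorical factor {factor.name!r} numerically")
    actual = factor.center + np.asarray(coded, dtype=float) * factor.half_range
    if factor.integer:
        actual = np.round(actual)
    if np.ndim(actual) == 0:
        return float(actual)
    return actual


def _block_rows(spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Coded rows and space types for one categorical combination, in canonical
    order: factorial corners (last factor fastest), axial pairs, centers."""
    k = spec.k
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -spec.alpha
        axial[2 * i + 1, i] = spec.alpha
    centers = np.zeros((spec.n_center, k))
    coded = np.vstack([corners, axial, centers])
    space = (
        ["factorial"] * len(corners) + ["axial"] * len(axial) + ["center"] * spec.n_center
    )
    return coded, space


def build_ccd(spec: DesignSpec, shuffle_seed: int | None = None) -> DesignMatrix:
    """Build the full face-centered CCD for ``spec``.

    The numeric block (factorial, axial, center — in that order) is replicated
    for every combination of categorical levels, categorical levels outermost.
    Row order is deterministic; pass ``shuffle_seed`` to randomize run order
    (the least-squares fit is order-invariant, so the canonical order is the
    default for reproducibility).
    """
    block_coded, block_space = _block_rows(spec)
    cat_combos = list(
        itertools.product(*[f.levels for f in spec.categorical_factors])
    ) or [()]

    records = []
    coded_records = []
    for combo in cat_combos:
        for coded_row, space in zip(block_coded, block_space):
            rec = {"space_type": space}
            for f, c in zip(spec.numeric_factors, coded_row):
                rec[f.name] = decode_value(f, c)
            for f, lev in zip(spec.categorical_factors, combo):
                rec[f.name] = lev
            records.append(rec)
            coded_records.append(dict(zip((f.name for f in spec.numeric_factors), coded_row)))

    table = pd.DataFrame.from_records(records)
    coded = pd.DataFrame.from_records(coded_records)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(table))
        table = table.iloc[order].reset_index(drop=True)
        coded = coded.iloc[order].reset_index(drop=True)
    table.insert(0, "run", np.arange(1, len(table) + 1))
    return DesignMatrix(spec, table, coded)


def write_design(design: DesignMatrix, path) -> None:
    """Write a design (and any attached responses) as a UTF-8 CSV."""
    design.table.to_csv(path, index=False)


def read_design(path, spec: DesignSpec, response_column: str = "response") -> DesignMatrix:
    """Read a design CSV back into a :class:`DesignMatrix` under ``spec``.

    The file must have ``run`` and ``space_type`` columns plus one column of
    actual levels per factor in ``spec``; a ``response_column`` is attached if
    present. Coded levels are reconstructed from the factor ranges.
    """
    raw = pd.read_csv(path)
    for col in ("run", "space_type"):
        if col not in raw.columns:
            raise ValueError(f"design file is missing required column {col!r}")
    bad = set(raw["space_type"]) - set(SPACE_TYPES)
    if bad:
        raise ValueError(f"unknown space_type values: {sorted(bad)}")

    table = raw[["run", "space_type"]].copy()
    coded = {}
    for f in spec.factors:
        if f.name not in raw.columns:
            raise ValueError(f"design file is missing factor column {f.name!r}")
        col = raw[f.name]
        if f.is_numeric:
            vals = pd.to_numeric(col, errors="coerce")
            if vals.isna().any():
                bad_runs = raw.loc[vals.isna(), "run"].tolist()
                raise ValueError(
                    f"non-numeric values for numeric factor {f.name!r} in runs {bad_runs}"
                )
            table[f.name] = vals.to_numpy(dtype=float)
            coded[f.name] = code_value(f, table[f.name].to_numpy())
        else:
            labels = col.astype(str)
            unknown = set(labels) - set(f.levels)
            if unknown:
                raise ValueError(
                    f"unknown level(s) {sorted(unknown)} for categorical factor {f.name!r}"
                )
            table[f.name] = labels.to_numpy()
    if response_column in raw.columns:
        table["response"] = pd.to_numeric(raw[response_column], errors="raise").to_numpy()
    return DesignMatrix(spec, table, pd.DataFrame(coded))
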