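"""Cohort I/O and preprocessing: survival-class binning, imputation,
oversampling, one-hot encoding, and the 70/10/20 split.

A :class:`Dataset` is a thin wrapper around a pandas DataFrame whose columns
follow a :class:`~fuzzsurv.schema.CohortSchema`: 15 categorical predictors
plus ``survival_months`` (non-negative integer, optional per record) and
``survival_class`` (ordinal 0..5, optional per record). Overall survival time
is discretized into six classes of twelve months each, with everything past
five years pooled into the terminal class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import (
    MISSING_SENTINELS,
    N_CLASSES,
    SURVIVAL_CLASS,
    SURVIVAL_MONTHS,
    CohortSchema,
    default_schema,
)

#: upper bounds (inclusive) of the five closed survival bins, in months;
#: months beyond the last bound fall in the terminal class 5
CLASS_UPPER_BOUNDS = (12, 24, 36, 48, 60)


class CohortValidationError(ValueError):
    """A record or file violates the cohort schema."""


def bin_survival_time(months: int, bounds: tuple[int, ...] = CLASS_UPPER_BOUNDS) -> int:
    """Map overall survival months to its ordinal class 0..5.

    Bin edges are inclusive on the upper end (12 months -> class 0,
    13 -> class 1, ..., 60 -> class 4, anything above -> class 5).
    """
    if isinstance(months, (bool, np.bool_)):
        raise CohortValidationError("months must be an integer, got bool")
    m = np.asarray(months)
    if m.shape != () or not np.issubdtype(m.dtype, np.number):
        raise CohortValidationError(f"months must be a scalar integer, got {months!r}")
    if float(m) != int(m):
        raise CohortValidationError(f"months must be an integer, got {months!r}")
    m = int(m)
    if m < 0:
        raise CohortValidationError(f"months must be non-negative, got {m}")
    for k, ub in enumerate(bounds):
        if m <= ub:
            return k
    return len(bounds)


def bin_survival_times(months: np.ndarray) -> np.ndarray:
    """Vectorized :func:`bin_survival_time` over an integer array."""
    m = np.asarray(months)
    if np.any(m < 0):
        raise CohortValidationError("months must be non-negative")
    return np.minimum(np.maximum((m - 1) // 12, 0), N_CLASSES - 1).astype(int)


@dataclass
class Dataset:
    """A cohort: records in a DataFrame sharing one schema."""

    df: pd.DataFrame
    schema: CohortSchema = field(default_factory=default_schema)
    provenance: str = ""

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.schema.columns if c not in self.df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing columns: {missing_cols}")
        self.df = self.df[self.schema.columns].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Dataset":
        return replace(self, df=self.df.copy())

    @property
    def y(self) -> np.ndarray:
        """Survival-class labels as an int array; raises if any are missing."""
        cls = self.df[SURVIVAL_CLASS]
        if cls.isna().any():
            raise CohortValidationError("survival_class missing for some records")
        return cls.to_numpy(dtype=int)

    def validate(self) -> None:
        """Check every value against the schema and the outcome invariants."""
        df = self.df
        for var in self.schema.variables:
            col = df[var.name]
            bad = ~(col.isna() | col.isin(var.levels))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"variable {var.name!r}: value {col.iloc[row]!r} at record {row} "
                    f"not in levels {var.levels}"
                )
        months = df[SURVIVAL_MONTHS]
        cls = df[SURVIVAL_CLASS]
        if ((months.isna()) & (cls.isna())).any():
            raise CohortValidationError(
                "each record needs survival_months or survival_class"
            )
        if months.notna().any():
            m = months.dropna()
            if (m < 0).any() or (m != m.astype(int)).any():
                raise CohortValidationError("survival_months must be non-negative integers")
        if cls.notna().any():
            c = cls.dropna()
            if (~c.isin(range(N_CLASSES))).any():
                raise CohortValidationError("survival_class must be in 0..5")
        both = months.notna() & cls.notna()
        if both.any():
            derived = bin_survival_times(months[both].to_numpy(dtype=int))
            if (derived != cls[both].to_numpy(dtype=int)).any():
                raise CohortValidationError(
                    "survival_class inconsistent with survival_months"
                )


def derive_classes(ds: Dataset) -> Dataset:
    """Fill missing ``survival_class`` from ``survival_months`` where possible."""
    out = ds.copy()
    df = out.df
    need = df[SURVIVAL_CLASS].isna() & df[SURVIVAL_MONTHS].notna()
    if need.any():
        df.loc[need, SURVIVAL_CLASS] = bin_survival_times(
            df.loc[need, SURVIVAL_MONTHS].to_numpy(dtype=int)
        )
    return out


# ---------------------------------------------------------------------------
# imputation

def impute_missing(ds: Dataset, reference: Dataset | None = None) -> Dataset:
    """Fill missing values deterministically.

    Categorical predictors are filled with the per-variable mode (ties broken
    lexicographically); ``survival_months`` with the median of the observed
    values, rounded half-up to an integer. Modes/medians are computed on
    ``reference`` when given (e.g. the training split) and on ``ds`` itself
    otherwise.
    """
    ref = (reference or ds).df
    out = ds.copy()
    df = out.df
    for var in ds.schema.variables:
        col = df[var.name]
        if not col.isna().any():
            continue
        observed = ref[var.name].dropna()
        if observed.empty:
            raise CohortValidationError(f"variable {var.name!r} is entirely missing")
        counts = observed.value_counts()
        top = counts[counts == counts.max()]
        mode = sorted(top.index)[0]
        df[var.name] = col.fillna(mode)
    months = df[SURVIVAL_MONTHS]
    if months.isna().any():
        observed = ref[SURVIVAL_MONTHS].dropna()
        if not observed.empty:
            med = int(np.floor(float(observed.median()) + 0.5))
            df[SURVIVAL_MONTHS] = months.fillna(med)
    return derive_classes(out)


# ---------------------------------------------------------------------------
# oversampling

def oversample(ds: Dataset, seed: int) -> Dataset:
    """Random oversampling with replacement up to the majority-class count.

    Every represented class ends with exactly the majority class's count; the
    originals are all retained and the added records are uniform resamples of
    existing same-class records. Intended for the training split only.
    """
    if len(ds) == 0:
        raise CohortValidationError("cannot oversample an empty dataset")
    y = ds.y
    rng = np.random.default_rng(seed)
    counts = np.bincount(y, minlength=N_CLASSES)
    target = counts.max()
    extra_idx: list[np.ndarray] = []
    for k in range(N_CLASSES):
        if counts[k] == 0 or counts[k] == target:
            continue
        pool = np.flatnonzero(y == k)
        extra_idx.append(rng.choice(pool, size=target - counts[k], replace=True))
    if not extra_idx:
        return ds.copy()
    extras = ds.df.iloc[np.concatenate(extra_idx)]
    out_df = pd.concat([ds.df, extras], ignore_index=True)
    return replace(ds, df=out_df)


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split: 70/10/20 with floor rounding."""

    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _part_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    a = int(np.floor(fractions[0] * n))
    b = int(np.floor(fractions[1] * n))
    return a, b, n - a - b


def split_dataset(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset, Dataset]:
    """Partition into disjoint train/val/test parts.

    Sizes are floor(0.70 n), floor(0.10 n), remainder. When stratified (the
    default), each class is first allocated by the same floor rule and the
    leftover records are then distributed — largest fractional remainder
    first — so global sizes are exact and per-class proportions are within
    one record of the fractions.
    """
    n = len(ds)
    if n < 10:
        raise CohortValidationError(f"need at least 10 records to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    sizes = _part_sizes(n, spec.fractions)

    if not spec.stratified:
        perm = rng.permutation(n)
        parts = (
            perm[: sizes[0]],
            perm[sizes[0] : sizes[0] + sizes[1]],
            perm[sizes[0] + sizes[1] :],
        )
    else:
        y = ds.y
        classes = np.unique(y)
        small = [int(k) for k in classes if (y == k).sum() < 3]
        if small:
            raise CohortValidationError(
                f"classes {small} have fewer than 3 records; "
                "use stratified=False for such strata"
            )
        assigned: list[list[np.ndarray]] = [[], [], []]
        remainders = []  # (class, shuffled leftover indices, fractional parts)
        for k in classes:
            idx = rng.permutation(np.flatnonzero(y == k))
            nk = len(idx)
            a = int(np.floor(spec.fractions[0] * nk))
            b = int(np.floor(spec.fractions[1] * nk))
            c = int(np.floor(spec.fractions[2] * nk))
            assigned[0].append(idx[:a])
            assigned[1].append(idx[a : a + b])
            assigned[2].append(idx[a + b : a + b + c])
            leftover = idx[a + b + c :]
            fracs = [spec.fractions[j] * nk % 1.0 for j in range(3)]
            remainders.append((int(k), leftover, fracs))
        # distribute leftover records to hit the exact global sizes, giving
        # each part the strata where its fractional entitlement is largest
        deficits = [sizes[j] - sum(len(a) for a in assigned[j]) for j in range(3)]
        for k, leftover, fracs in remainders:
            for i in range(len(leftover)):
                order = sorted(range(3), key=lambda j: (-fracs[j], j))
                for j in order:
                    if deficits[j] > 0:
                        assigned[j].append(leftover[i : i + 1])
                        deficits[j] -= 1
                        fracs[j] = -1.0  # a stratum feeds each part at most once first
                        break
        parts = tuple(
            np.sort(np.concatenate(a)) if a else np.array([], dtype=int) for a in assigned
        )

    out = []
    for idx in parts:
        out.append(replace(ds, df=ds.df.iloc[np.sort(idx)].reset_index(drop=True)))
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# encoding

@dataclass
class EncodedMatrix:
    """One-hot design matrix: one column per (variable, level), schema order."""

    X: np.ndarray
    y: np.ndarray | None
    column_names: list[str]


def encode(ds: Dataset) -> EncodedMatrix:
    """One-hot encode the predictors; requires no missing predictor values."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(ds)
    for var in ds.schema.variables:
        col = ds.df[var.name]
        if col.isna().any():
            raise CohortValidationError(f"variable {var.name!r} has missing values")
        bad = ~col.isin(var.levels)
        if bad.any():
            val = col[bad].iloc[0]
            raise CohortValidationError(f"variable {var.name!r}: unseen level {val!r}")
        for lev in var.levels:
            names.append(f"{var.name}={lev}")
            cols.append((col == lev).to_numpy(dtype=float))
    X = np.column_stack(cols) if n else np.empty((0, len(names)))
    cls = ds.df[SURVIVAL_CLASS]
    y = cls.to_numpy(dtype=int) if cls.notna().all() and n else None
    return EncodedMatrix(X=X, y=y, column_names=names)


def decode(enc: EncodedMatrix, schema: CohortSchema | None = None) -> Dataset:
    """Inverse of :func:`encode` on the categorical content.

    Survival months are not part of the encoding and come back missing.
    """
    schema = schema or default_schema()
    data: dict[str, list] = {}
    j = 0
    for var in schema.variables:
        block = enc.X[:, j : j + len(var.levels)]
        j += len(var.levels)
        if not np.allclose(block.sum(axis=1), 1.0):
            raise CohortValidationError(f"one-hot block for {var.name!r} does not sum to 1")
        data[var.name] = [var.levels[i] for i in block.argmax(axis=1)]
    df = pd.DataFrame(data)
    df[SURVIVAL_MONTHS] = pd.array([pd.NA] * len(df), dtype="Int64")
    df[SURVIVAL_CLASS] = (
        pd.array(enc.y, dtype="Int64")
        if enc.y is not None
        else pd.array([pd.NA] * len(df), dtype="Int64")
    )
    return Dataset(df=df, schema=schema)


# ---------------------------------------------------------------------------
# CSV I/O

def _empty_frame(schema: CohortSchema) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in schema.columns})
    df[SURVIVAL_MONTHS] = df[SURVIVAL_MONTHS].astype("Int64")
    df[SURVIVAL_CLASS] = df[SURVIVAL_CLASS].astype("Int64")
    return df


def read_cohort_csv(path, schema: CohortSchema | None = None) -> Dataset:
    """Read a cohort CSV, validating every cell; errors cite the file line.

    Header must match the schema's canonical column order; empty cells and
    "NA" are missing. Line numbers in error messages count the header as
    line 1.
    """
    schema = schema or default_schema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != schema.columns:
        raise CohortValidationError(
            f"header {list(raw.columns)} does not match schema columns {schema.columns}"
        )
    if len(raw) == 0:
        return Dataset(df=_empty_frame(schema), schema=schema, provenance=str(path))
    raw = raw.map(lambda v: pd.NA if v in MISSING_SENTINELS else v)
    for var in schema.variables:
        bad = ~(raw[var.name].isna() | raw[var.name].isin(var.levels))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"row {i + 2}: variable {var.name!r} has invalid level "
                f"{raw[var.name].iloc[i]!r}"
            )
    df = raw.copy()
    for col, lo, hi in ((SURVIVAL_MONTHS, 0, None), (SURVIVAL_CLASS, 0, N_CLASSES - 1)):
        vals = []
        for i, v in enumerate(raw[col]):
            if pd.isna(v):
                vals.append(pd.NA)
                continue
            try:
                iv = int(v)
            except ValueError:
                raise CohortValidationError(f"row {i + 2}: {col} {v!r} is not an integer")
            if iv < lo or (hi is not None and iv > hi):
                raise CohortValidationError(f"row {i + 2}: {col} {iv} out of range")
            vals.append(iv)
        df[col] = pd.array(vals, dtype="Int64")
    ds = Dataset(df=df, schema=schema, provenance=str(path))
    ds.validate()
    return ds


def write_cohort_csv(ds: Dataset, path) -> None:
    """Write the cohort as UTF-8 CSV with blank cells for missing values."""
    ds.df.to_csv(path, index=False, na_rep="")


def datasets_equal(a: Dataset, b: Dataset) -> bool:
    """Value equality of two cohorts over the canonical columns."""
    if a.schema.columns != b.schema.columns or len(a) != len(b):
        return False
    return a.df.fillna("␀").eq(b.df.fillna("␀")).all().all()
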