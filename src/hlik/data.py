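"""Long-format encounter tables and GLMM design construction.

The data model targets EHR-like repeated-measures data: one row per clinical
encounter, identified by a patient and a facility, carrying an event count
(or death indicator), an exposure duration, and covariates.  Fixed-effect
designs combine an intercept, dummy-coded categoricals, linear terms and
natural-spline blocks; random-effect designs are block-sparse indicator
matrices, one block per grouping factor (random intercepts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .splines import NaturalCubicSplineBasis, natural_cubic_spline_basis

__all__ = [
    "TableSchema",
    "LongTable",
    "GLMMData",
    "read_long_table",
    "write_long_table",
    "encode_survival_as_poisson",
    "build_design",
    "subsample_patients",
]

_NA_TOKENS = {"", "NA"}


@dataclass(frozen=True)
class TableSchema:
    """Column declaration for a long-format encounter table."""

    patient_col: str = "patient_id"
    facility_col: str = "facility_id"
    event_col: str = "event"
    duration_col: str | None = "duration_days"
    numeric_covariates: tuple = ()
    categorical_covariates: tuple = ()

    @property
    def required_columns(self) -> list:
        cols = [self.patient_col, self.facility_col, self.event_col]
        if self.duration_col is not None:
            cols.append(self.duration_col)
        return cols + list(self.numeric_covariates) + list(self.categorical_covariates)


@dataclass
class LongTable:
    """A validated long-format table plus its schema.

    Categorical level sets (including the id columns) are recorded in
    first-appearance order, so design construction is invariant to which
    subset of rows is later used.
    """

    frame: pd.DataFrame
    schema: TableSchema
    levels: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in (self.schema.patient_col, self.schema.facility_col, *self.schema.categorical_covariates):
            if col not in self.levels:
                self.levels[col] = list(dict.fromkeys(self.frame[col].astype(str)))

    def __len__(self):
        return len(self.frame)

    @property
    def n_patients(self):
        return len(self.levels[self.schema.patient_col])

    @property
    def n_facilities(self):
        return len(self.levels[self.schema.facility_col])


def read_long_table(path, schema: TableSchema) -> LongTable:
    """Read a CSV into a :class:`LongTable`, validating it against ``schema``.

    Raises
    ------
    ValueError
        If a declared column is missing, a numeric column contains a
        non-numeric or NA token (the row number is reported), or a duration
        is non-positive.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.required_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"schema error: missing column(s) {missing} in {path}")
    numeric_cols = [schema.event_col, *schema.numeric_covariates]
    if schema.duration_col is not None:
        numeric_cols.append(schema.duration_col)
    for col in numeric_cols:
        raw = frame[col]
        bad = raw.isin(_NA_TOKENS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"parse error: NA value in numeric column {col!r} at data row {row}")
        try:
            frame[col] = pd.to_numeric(raw)
        except (ValueError, TypeError):
            ok = pd.to_numeric(raw, errors="coerce").notna()
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ValueError(
                f"parse error: non-numeric value {raw.iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            ) from None
    if (frame[schema.event_col] < 0).any():
        raise ValueError("validation error: negative event count")
    if schema.duration_col is not None and (frame[schema.duration_col] <= 0).any():
        row = int(np.flatnonzero((frame[schema.duration_col] <= 0).to_numpy())[0])
        raise ValueError(
            f"validation error: non-positive {schema.duration_col} at data row {row}"
        )
    return LongTable(frame=frame, schema=schema)


def write_long_table(table: LongTable, path) -> None:
    """Write the table back to CSV (comma-separated, header, UTF-8)."""
    table.frame.to_csv(path, index=False)


def encode_survival_as_poisson(encounters):
    """Encode an ordered per-patient encounter history for a Poisson model.

    Each encounter is a ``(alive_at_end, duration_days)`` pair.  Survival
    through an encounter contributes event 0; a terminal death contributes
    event 1.  The log of the exposure duration becomes the offset, which
    turns the Poisson fit into a piecewise-exponential survival model.

    Returns ``(events, offsets)`` as float arrays.
    """
    alive = np.asarray([bool(a) for a, _ in encounters])
    durations = np.asarray([float(d) for _, d in encounters])
    if np.any(durations <= 0):
        raise ValueError("validation error: encounter duration must be > 0")
    deaths = ~alive
    if deaths.any() and (deaths[:-1].any() or deaths.sum() > 1):
        raise ValueError(
            "ordering error: death must terminate the encounter sequence"
        )
    return deaths.astype(float), np.log(durations)


@dataclass
class GLMMData:
    """Numeric arrays for GLMM fitting.

    ``Z`` is CSC block-sparse with one block of indicator columns per
    grouping factor; ``group_blocks`` maps factor name -> (start, stop)
    column slice and ``group_levels`` maps factor name -> level labels.
    """

    y: np.ndarray
    X: np.ndarray
    Z: sparse.csc_matrix
    offset: np.ndarray
    family_tag: str
    x_names: list
    group_blocks: dict
    group_levels: dict
    spline_bases: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.y)
        if not (self.X.shape[0] == self.Z.shape[0] == len(self.offset) == n):
            raise ValueError("dimension mismatch between y, X, Z, offset")
        total = sum(stop - start for start, stop in self.group_blocks.values())
        if total != self.Z.shape[1]:
            raise ValueError("group blocks do not partition the columns of Z")

    @property
    def n_obs(self):
        return len(self.y)

    @property
    def n_fixed(self):
        return self.X.shape[1]

    @property
    def n_random(self):
        return self.Z.shape[1]

    @property
    def group_names(self):
        return list(self.group_blocks)

    def block_sizes(self):
        return {k: stop - start for k, (start, stop) in self.group_blocks.items()}


def _spline_feature(table, term, prediction_bases):
    col = table.frame[term["name"]].to_numpy(dtype=float)
    if prediction_bases is not None and term["name"] in prediction_bases:
        basis = prediction_bases[term["name"]]
        return basis, basis(col)
    if len(np.unique(col)) < 2:
        raise ValueError(f"degenerate input: covariate {term['name']!r} is constant")
    knots = term.get("knots")
    if knots is not None:
        basis = NaturalCubicSplineBasis(
            df=term.get("df", 3),
            boundary_knots=(knots[0], knots[-1]),
            internal_knots=tuple(knots[1:-1]),
        )
        return basis, basis(col)
    return natural_cubic_spline_basis(col, df=term.get("df", 3), boundary=term.get("boundary"))


def build_design(table: LongTable, model_config: dict, prediction_bases=None) -> GLMMData:
    """Build a :class:`GLMMData` from a table and a model configuration.

    ``model_config`` keys::

        family: "poisson" | "bernoulli" | "gaussian"
        response: column name (defaults to the schema's event column)
        offset_from: duration column name, or None for a zero offset
        fixed: list of {name, type: "linear"|"categorical"|"spline",
                        df?, boundary?, knots?}
        groups: list of grouping-factor column names

    The fixed design starts with an intercept; categoricals are dummy-coded
    against their first-appearance level; spline terms contribute ``df``
    columns each.
    """
    frame, schema = table.frame, table.schema
    n = len(frame)
    response = model_config.get("response", schema.event_col)
    y = frame[response].to_numpy(dtype=float)

    offset_from = model_config.get("offset_from")
    if offset_from is None:
        offset = np.zeros(n)
    else:
        dur = frame[offset_from].to_numpy(dtype=float)
        if np.any(dur <= 0):
            raise ValueError("validation error: offset durations must be > 0")
        offset = np.log(dur)

    cols = [np.ones(n)]
    names = ["(intercept)"]
    spline_bases = {}
    for term in model_config.get("fixed", []):
        name, kind = term["name"], term["type"]
        if name not in frame.columns:
            raise ValueError(f"schema error: unknown column {name!r}")
        if kind == "linear":
            cols.append(frame[name].to_numpy(dtype=float))
            names.append(name)
        elif kind == "categorical":
            levels = table.levels.get(name)
            if levels is None:
                levels = list(dict.fromkeys(frame[name].astype(str)))
            vals = frame[name].astype(str)
            unseen = set(vals) - set(levels)
            if unseen:
                raise ValueError(f"level error: unseen level(s) {sorted(unseen)} in {name!r}")
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        elif kind == "spline":
            basis, block = _spline_feature(table, term, prediction_bases)
            spline_bases[name] = basis
            cols.append(block)
            names.extend(f"{name}.ns{j + 1}" for j in range(block.shape[1] if block.ndim > 1 else 1))
        else:
            raise ValueError(f"unknown fixed-effect type {kind!r}")
    X = np.column_stack(cols)

    groups = model_config.get("groups", [schema.patient_col, schema.facility_col])
    z_blocks, group_blocks, group_levels = [], {}, {}
    col0 = 0
    for g in groups:
        levels = table.levels.get(g) or list(dict.fromkeys(frame[g].astype(str)))
        if len(levels) < 1:
            raise ValueError(f"grouping factor {g!r} has no levels")
        index = pd.Categorical(frame[g].astype(str), categories=levels).codes
        if np.any(index < 0):
            raise ValueError(f"level error: unseen level in grouping factor {g!r}")
        block = sparse.csc_matrix(
            (np.ones(n), (np.arange(n), index)), shape=(n, len(levels))
        )
        z_blocks.append(block)
        group_blocks[g] = (col0, col0 + len(levels))
        group_levels[g] = list(levels)
        col0 += len(levels)
    Z = sparse.hstack(z_blocks, format="csc")

    return GLMMData(
        y=y, X=X, Z=Z, offset=offset, family_tag=model_config.get("family", "poisson"),
        x_names=names, group_blocks=group_blocks, group_levels=group_levels,
        spline_bases=spline_bases,
    )


def subsample_patients(table: LongTable, fraction: float, seed: int) -> LongTable:
    """Simple random sampling of patients without replacement.

    The sampling unit is the patient: all encounters of a sampled patient are
    retained.  Keeps ``floor(fraction * n_patients)`` patients (all of them
    when ``fraction == 1``); deterministic given ``seed``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return table
    patients = table.levels[table.schema.patient_col]
    k = int(np.floor(fraction * len(patients)))
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(np.asarray(patients, dtype=object), size=k, replace=False))
    mask = table.frame[table.schema.patient_col].astype(str).isin(kept)
    return LongTable(frame=table.frame.loc[mask].reset_index(drop=True), schema=table.schema)
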