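"""Longitudinal person–age–count panel and baseline-covariate containers.

The panel is the data model every other stage consumes: one row per person
per observed age, holding the arrest count at that age and (optionally)
per-charge-category counts.  Observation windows are inclusive integer age
ranges and may differ across persons — cohorts observed over different
calendar spans yield an unbalanced panel.

Charge categories are not mutually exclusive: a single arrest carrying both
a drug and a property charge increments both category counts, so category
counts need not sum to the total ``count`` at an age.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CHARGE_CATEGORIES",
    "CHARGE_COLUMNS",
    "Panel",
    "CovariateTable",
    "PanelValidationError",
    "SchemaError",
    "read_panel",
    "write_panel",
    "read_covariates",
    "restrict_ages",
]

logger = logging.getLogger(__name__)

CHARGE_CATEGORIES = ("drugs", "violence", "property", "other")
CHARGE_COLUMNS = tuple(f"n_{c}" for c in CHARGE_CATEGORIES)

#: canonical column order of the long-format CSV
_PANEL_COLUMNS = ("person_id", "cohort", "age", "count") + CHARGE_COLUMNS
_REQUIRED = ("person_id", "age", "count")


class PanelValidationError(ValueError):
    """Raised when panel data violate the data-model invariants."""


class SchemaError(ValueError):
    """Raised when a required column cannot be resolved in an input file."""


def _as_int(series: pd.Series, name: str) -> pd.Series:
    """Coerce to integer, rejecting fractional or non-numeric values."""
    num = pd.to_numeric(series, errors="coerce")
    if num.isna().any():
        row = int(num.index[num.isna()][0])
        raise PanelValidationError(f"non-numeric {name!r} at row {row}")
    if not np.allclose(num, np.round(num)):
        row = int(num.index[~np.isclose(num, np.round(num))][0])
        raise PanelValidationError(f"non-integer {name!r} at row {row}")
    return num.round().astype(np.int64)


class Panel:
    """Validated long-format panel of per-age arrest counts.

    Parameters
    ----------
    data : DataFrame
        Columns ``person_id, age, count`` required; ``cohort`` and the
        per-category columns ``n_drugs, n_violence, n_property, n_other``
        optional.
    windows : DataFrame, optional
        Explicit per-person observation windows with columns
        ``person_id, min_age, max_age`` (inclusive).  When omitted, each
        person's window is inferred as the observed age span.
    dense_windows : bool
        When True, in-window ages missing from ``data`` are filled with
        zero counts.  By default a missing in-window age is an error: the
        likelihood treats every in-window age as observed, so a gap means
        the file is incomplete rather than silently arrest-free.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        windows: pd.DataFrame | None = None,
        dense_windows: bool = False,
        validate: bool = True,
    ) -> None:
        df = data.copy()
        for col in _REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"panel data missing required column {col!r}")
        if "cohort" not in df.columns:
            df["cohort"] = "all"
        df["person_id"] = df["person_id"].astype(str)
        df["cohort"] = df["cohort"].astype(str)
        if len(df):
            df["age"] = _as_int(df["age"], "age")
            df["count"] = _as_int(df["count"], "count")
        else:
            df["age"] = df.get("age", pd.Series(dtype=np.int64)).astype(np.int64)
            df["count"] = df.get("count", pd.Series(dtype=np.int64)).astype(np.int64)
        for col in CHARGE_COLUMNS:
            if col in df.columns:
                df[col] = _as_int(df[col].fillna(0), col) if len(df) else df[col].astype(np.int64)
        keep = [c for c in _PANEL_COLUMNS if c in df.columns]
        df = df[keep].sort_values(["person_id", "age"], kind="mergesort").reset_index(drop=True)

        if windows is not None:
            w = windows.copy()
            w["person_id"] = w["person_id"].astype(str)
            w = w.set_index("person_id")[["min_age", "max_age"]].astype(np.int64)
        else:
            if len(df):
                g = df.groupby("person_id")["age"]
                w = pd.DataFrame({"min_age": g.min(), "max_age": g.max()})
            else:
                w = pd.DataFrame(columns=["min_age", "max_age"], dtype=np.int64)

        if dense_windows and len(df):
            df = self._densify(df, w)

        self._data = df
        self._windows = w
        if validate:
            self._validate()

    @staticmethod
    def _densify(df: pd.DataFrame, w: pd.DataFrame) -> pd.DataFrame:
        frames = []
        cohorts = df.drop_duplicates("person_id").set_index("person_id")["cohort"]
        for pid, row in w.iterrows():
            ages = np.arange(row["min_age"], row["max_age"] + 1)
            frames.append(pd.DataFrame({"person_id": pid, "cohort": cohorts.get(pid, "all"), "age": ages}))
        full = pd.concat(frames, ignore_index=True)
        merged = full.merge(df.drop(columns=["cohort"]), on=["person_id", "age"], how="left")
        for col in ("count",) + tuple(c for c in CHARGE_COLUMNS if c in df.columns):
            merged[col] = merged[col].fillna(0).astype(np.int64)
        keep = [c for c in _PANEL_COLUMNS if c in merged.columns]
        return merged[keep].sort_values(["person_id", "age"], kind="mergesort").reset_index(drop=True)

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        df = self._data
        if (df["count"] < 0).any():
            row = int(df.index[df["count"] < 0][0])
            raise PanelValidationError(f"negative count at row {row}")
        dup = df.duplicated(subset=["person_id", "age"])
        if dup.any():
            pid, age = df.loc[dup.idxmax(), ["person_id", "age"]]
            raise PanelValidationError(f"duplicate (person, age) pair: ({pid!r}, {age})")
        ncoh = df.groupby("person_id")["cohort"].nunique()
        if len(ncoh) and (ncoh > 1).any():
            raise PanelValidationError(f"person {ncoh.idxmax()!r} carries multiple cohort labels")
        for col in CHARGE_COLUMNS:
            if col in df.columns:
                if (df[col] < 0).any():
                    raise PanelValidationError(f"negative {col}")
                bad = df[col] > df["count"]
                if bad.any():
                    row = int(df.index[bad][0])
                    raise PanelValidationError(
                        f"{col} exceeds the recorded total count at row {row}"
                    )
        # every recorded age inside its person's window, and windows dense
        if len(df):
            w = self._windows
            merged = df.merge(w, left_on="person_id", right_index=True, how="left")
            if merged["min_age"].isna().any():
                pid = merged.loc[merged["min_age"].isna(), "person_id"].iloc[0]
                raise PanelValidationError(f"person {pid!r} has records but no window")
            out = (merged["age"] < merged["min_age"]) | (merged["age"] > merged["max_age"])
            if out.any():
                pid, age = merged.loc[out.idxmax(), ["person_id", "age"]]
                raise PanelValidationError(
                    f"age {age} outside the observation window of person {pid!r}"
                )
            n_obs = df.groupby("person_id")["age"].size()
            span = (w["max_age"] - w["min_age"] + 1).reindex(n_obs.index)
            sparse = n_obs < span
            if sparse.any():
                pid = sparse.idxmax()
                raise PanelValidationError(
                    f"person {pid!r} is missing rows for in-window ages; "
                    "pass dense_windows=True to fill them with zero counts"
                )

    # -- accessors ----------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """Long-format records (copy-on-write view; do not mutate)."""
        return self._data

    @property
    def windows(self) -> pd.DataFrame:
        return self._windows

    @property
    def persons(self) -> np.ndarray:
        return np.asarray(sorted(self._data["person_id"].unique()))

    @property
    def n_persons(self) -> int:
        return int(self._data["person_id"].nunique())

    @property
    def cohorts(self) -> pd.Series:
        """Per-person cohort label, indexed by person_id."""
        return self._data.drop_duplicates("person_id").set_index("person_id")["cohort"]

    @property
    def has_charges(self) -> bool:
        return all(c in self._data.columns for c in CHARGE_COLUMNS)

    @property
    def age_range(self) -> tuple[int, int]:
        if not len(self._data):
            raise ValueError("empty panel has no age range")
        return int(self._data["age"].min()), int(self._data["age"].max())

    def total_count(self) -> int:
        return int(self._data["count"].sum())

    def person_totals(self, window: tuple[int, int] | None = None) -> pd.Series:
        """Per-person total arrests, optionally restricted to an age window."""
        df = self._data
        if window is not None:
            lo, hi = window
            df = df[(df["age"] >= lo) & (df["age"] <= hi)]
        return df.groupby("person_id")["count"].sum().reindex(self.persons, fill_value=0)

    def map_cohorts(self, mapping: Mapping[str, str]) -> "Panel":
        """Relabel cohorts (e.g. collapse birth cohorts into younger/older)."""
        df = self._data.copy()
        df["cohort"] = df["cohort"].map(lambda c: mapping.get(c, c))
        return Panel(df, windows=self._windows.reset_index(), validate=False)

    def restrict_ages(self, min_age: int, max_age: int) -> "Panel":
        """Drop records outside ``[min_age, max_age]`` and clip windows.

        Persons left with no in-window records are dropped (their number is
        logged).  Applying the same restriction twice is a no-op.
        """
        if min_age > max_age:
            raise ValueError(f"inverted age bounds: [{min_age}, {max_age}]")
        df = self._data
        kept = df[(df["age"] >= min_age) & (df["age"] <= max_age)]
        dropped = self.n_persons - kept["person_id"].nunique()
        if dropped:
            logger.info("restrict_ages: dropped %d person(s) with no in-range records", dropped)
        w = self._windows.copy()
        w["min_age"] = w["min_age"].clip(lower=min_age)
        w["max_age"] = w["max_age"].clip(upper=max_age)
        w = w.loc[w.index.isin(kept["person_id"].unique())]
        return Panel(kept.reset_index(drop=True), windows=w.reset_index(), validate=False)

    # -- equality & I/O -----------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self._data.equals(other._data) and self._windows.equals(other._windows)

    def __repr__(self) -> str:
        return f"<Panel: {self.n_persons} persons, {len(self._data)} person-ages>"

    def to_csv(self, path) -> None:
        write_panel(self, path)

    @classmethod
    def read_csv(cls, path, schema: Mapping[str, str] | None = None, **kw) -> "Panel":
        return read_panel(path, schema=schema, **kw)


def read_panel(path, schema: Mapping[str, str] | None = None, dense_windows: bool = False) -> Panel:
    """Read a long-format panel CSV.

    ``schema`` maps canonical column names (person_id, cohort, age, count,
    n_drugs, ...) to the file's column names when they differ.
    """
    raw = pd.read_csv(path, dtype={0: str})
    if schema:
        rename = {v: k for k, v in schema.items()}
        raw = raw.rename(columns=rename)
    for col in _REQUIRED:
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} not found in {path} (schema: {schema})")
    return Panel(raw, dense_windows=dense_windows)


def write_panel(panel: Panel, path) -> None:
    """Write the panel as a long-format CSV with stable column order."""
    cols = [c for c in _PANEL_COLUMNS if c in panel.data.columns]
    panel.data.to_csv(path, index=False, columns=cols)


def restrict_ages(panel: Panel, max_age: int, min_age: int = 0) -> Panel:
    """Functional form of :meth:`Panel.restrict_ages`."""
    return panel.restrict_ages(min_age, max_age)


class CovariateTable:
    """Baseline covariates, one row per person (per imputation).

    Covariates are numeric: binaries coded 0/1, scales standardized.  An
    ``imputation_id`` column distinguishes multiply-imputed versions; a
    table without it is a single complete dataset (imputation 0).
    """

    def __init__(self, data: pd.DataFrame) -> None:
        df = data.copy()
        if "person_id" not in df.columns:
            raise SchemaError("covariate table missing 'person_id'")
        df["person_id"] = df["person_id"].astype(str)
        if "imputation_id" not in df.columns:
            df["imputation_id"] = 0
        df["imputation_id"] = df["imputation_id"].astype(np.int64)
        dup = df.duplicated(subset=["person_id", "imputation_id"])
        if dup.any():
            raise PanelValidationError("duplicate (person, imputation) covariate rows")
        self._data = df.sort_values(["imputation_id", "person_id"], kind="mergesort").reset_index(drop=True)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in self._data.columns if c not in ("person_id", "imputation_id"))

    @property
    def imputation_ids(self) -> np.ndarray:
        return np.sort(self._data["imputation_id"].unique())

    def for_imputation(self, imputation_id: int = 0) -> pd.DataFrame:
        sub = self._data[self._data["imputation_id"] == imputation_id]
        if not len(sub):
            raise KeyError(f"imputation {imputation_id} not present")
        return sub.set_index("person_id")[list(self.covariate_names)]

    def matrix(self, persons: Iterable[str], names: Iterable[str] | None = None,
               imputation_id: int = 0) -> np.ndarray:
        """Covariate matrix aligned to ``persons`` (no intercept column)."""
        names = list(names) if names is not None else list(self.covariate_names)
        table = self.for_imputation(imputation_id)
        missing = [n for n in names if n not in table.columns]
        if missing:
            raise SchemaError(f"unknown covariate(s): {missing}")
        aligned = table.reindex(list(persons))[names]
        if aligned.isna().any().any():
            pid = aligned.index[aligned.isna().any(axis=1)][0]
            raise PanelValidationError(f"person {pid!r} missing covariates")
        return aligned.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        cols = ["person_id", "imputation_id", *self.covariate_names]
        self._data.to_csv(path, index=False, columns=cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CovariateTable):
            return NotImplemented
        return self._data.equals(other._data)


def read_covariates(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, dtype={"person_id": str}))
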