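"""Per-participant trial data container and CSV input/output.

A trial records, for each participant, the randomized treatment assignment
``Z``, the received treatment ``X``, the randomized psychological
encouragement ``Q``, the measured emotion level ``M`` and the clinical
outcome ``Y``.  Optional columns hold the expectation ``E``, desire ``D``
and their interaction ``I = E*D``, an extra placebo mediator ``A`` with its
own binary instrument ``W``, and any number of observed-confounder
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialDataset", "read_trial_csv", "write_trial_csv"]

#: canonical column order used when writing CSV files
CANONICAL_COLUMNS = ("Z", "Q", "X", "E", "D", "I", "M", "Y", "A", "W")

_BINARY_COLUMNS = frozenset({"Z", "Q", "X", "E", "D", "I", "W"})
_REQUIRED_COLUMNS = ("Z", "Q", "X", "M", "Y")


class DatasetError(ValueError):
    """Raised when trial data violates a structural assumption."""


def _as_float_array(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DatasetError(f"column {name!r} must be one-dimensional")
    if np.isnan(arr).any():
        raise DatasetError(
            f"column {name!r} contains missing values; missingness is rejected, not imputed"
        )
    return arr


def _check_binary(name: str, arr: np.ndarray) -> np.ndarray:
    if not np.isin(arr, (0.0, 1.0)).all():
        raise DatasetError(f"column {name!r} must contain only 0/1 values")
    return arr


@dataclass
class TrialDataset:
    """Validated per-participant arrays for one randomized trial.

    Parameters
    ----------
    Z, Q, X : array-like of {0, 1}
        Assigned treatment, encouragement instrument, received treatment.
    M, Y : array-like of float
        Emotion level and outcome.
    E, D : array-like of {0, 1}, optional
        Expectation and desire; when both are given the interaction
        ``I`` is derived as their elementwise product (a supplied ``I``
        must match it).
    A, W : optional
        Extra real-valued placebo mediator and its binary instrument.
    covariates : dict of str -> array-like, optional
        Observed-confounder columns available for adjustment.
    """

    Z: np.ndarray
    Q: np.ndarray
    X: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    E: np.ndarray | None = None
    D: np.ndarray | None = None
    I: np.ndarray | None = None
    A: np.ndarray | None = None
    W: np.ndarray | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _REQUIRED_COLUMNS:
            setattr(self, name, _as_float_array(name, getattr(self, name)))
        for name in ("E", "D", "I", "A", "W"):
            if getattr(self, name) is not None:
                setattr(self, name, _as_float_array(name, getattr(self, name)))
        self.covariates = {
            k: _as_float_array(k, v) for k, v in self.covariates.items()
        }
        n = self.Z.shape[0]
        if n < 2:
            raise DatasetError("a trial needs at least 2 participants")
        for name, arr in self._columns():
            if arr.shape[0] != n:
                raise DatasetError(
                    f"column {name!r} has length {arr.shape[0]}, expected {n}"
                )
            if name in _BINARY_COLUMNS:
                _check_binary(name, arr)
        if (self.E is None) != (self.D is None):
            raise DatasetError("E and D must be supplied together")
        if self.E is not None:
            implied = self.E * self.D
            if self.I is None:
                self.I = implied
            elif not np.array_equal(self.I, implied):
                raise DatasetError("I must equal the elementwise product E*D")
        elif self.I is not None:
            raise DatasetError("I requires both E and D")
        if (self.A is None) != (self.W is None):
            raise DatasetError("extra mediator A requires its instrument W and vice versa")

    # -- container protocol ------------------------------------------------

    @property
    def n(self) -> int:
        """Number of participants."""
        return int(self.Z.shape[0])

    def _columns(self):
        for name in CANONICAL_COLUMNS:
            arr = getattr(self, name)
            if arr is not None:
                yield name, arr
        yield from self.covariates.items()

    def column(self, name: str) -> np.ndarray:
        """Return a column by canonical or covariate name."""
        if name in CANONICAL_COLUMNS:
            arr = getattr(self, name)
            if arr is None:
                raise KeyError(f"column {name!r} not present in this dataset")
            return arr
        try:
            return self.covariates[name]
        except KeyError:
            raise KeyError(f"column {name!r} not present in this dataset") from None

    def has(self, name: str) -> bool:
        if name in CANONICAL_COLUMNS:
            return getattr(self, name) is not None
        return name in self.covariates

    def replace_column(self, name: str, values: np.ndarray) -> "TrialDataset":
        """Return a copy with one column replaced (used by adjustments)."""
        cols = {k: v.copy() for k, v in self._as_dict().items()}
        if name not in cols:
            raise KeyError(f"column {name!r} not present in this dataset")
        cols[name] = np.asarray(values, dtype=float)
        return TrialDataset.from_columns(cols)

    def _as_dict(self) -> dict[str, np.ndarray]:
        return dict(self._columns())

    @classmethod
    def from_columns(cls, columns: dict[str, np.ndarray]) -> "TrialDataset":
        canonical = {k: v for k, v in columns.items() if k in CANONICAL_COLUMNS}
        covariates = {k: v for k, v in columns.items() if k not in CANONICAL_COLUMNS}
        missing = [c for c in _REQUIRED_COLUMNS if c not in canonical]
        if missing:
            raise DatasetError(f"missing required columns: {missing}")
        return cls(covariates=covariates, **canonical)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self._as_dict())
        for name in df.columns:
            if name in _BINARY_COLUMNS:
                df[name] = df[name].astype(int)
        return df


def read_trial_csv(
    path,
    column_map: dict[str, str] | None = None,
    covariates: list[str] | None = None,
) -> TrialDataset:
    """Read a trial dataset from a header-bearing CSV file.

    ``column_map`` renames file columns to canonical names
    (``{"file name": "canonical name"}``).  Columns named in
    ``covariates`` are loaded as observed-confounder covariates; any
    remaining non-canonical columns are ignored with neither error nor
    adjustment.  Binary columns are accepted only when coded exactly 0/1,
    and rows with missing values are rejected.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    cols: dict[str, np.ndarray] = {}
    for name in CANONICAL_COLUMNS:
        if name in df.columns:
            cols[name] = df[name].to_numpy()
    for name in covariates or []:
        if name not in df.columns:
            raise DatasetError(f"declared covariate {name!r} not found in file")
        cols[name] = df[name].to_numpy()
    return TrialDataset.from_columns(cols)


def write_trial_csv(data: TrialDataset, path) -> None:
    """Write a dataset as comma-separated UTF-8 text with a header row."""
    data.to_dataframe().to_csv(path, index=False)
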