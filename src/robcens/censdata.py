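"""Data model, validation, and delimited-file I/O for censored regression data.

An observation is either fully observed, left-censored (the response is only
known to be at or below a bound L), or right-censored (at or above a bound U).
Bounds are stored as +/-inf sentinels when inactive so that downstream
likelihood code can dispatch on status without branching on missingness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CensStatus",
    "CensoredDataset",
    "DatasetValidationError",
    "StatusParseError",
    "ConfigurationError",
    "read_dataset",
    "write_dataset",
    "lung_adapter",
]


class ConfigurationError(ValueError):
    """A named column or option is missing or inconsistent."""


class StatusParseError(ValueError):
    """A censoring-status value could not be interpreted."""


class DatasetValidationError(ValueError):
    """A dataset invariant is violated; the message names the first bad row."""


class CensStatus(enum.IntEnum):
    """Censoring status of one observation."""

    OBSERVED = 0
    LEFT = 1
    RIGHT = 2

    @classmethod
    def parse(cls, value) -> "CensStatus":
        """Accept the text codes 'observed'/'left'/'right' or integers 0/1/2."""
        if isinstance(value, str):
            key = value.strip().lower()
            aliases = {"observed": cls.OBSERVED, "left": cls.LEFT, "right": cls.RIGHT}
            if key in aliases:
                return aliases[key]
            try:
                value = int(key)
            except ValueError:
                raise StatusParseError(f"unparseable censoring status {value!r}") from None
        try:
            return cls(int(value))
        except ValueError:
            raise StatusParseError(f"unparseable censoring status {value!r}") from None


@dataclass
class CensoredDataset:
    """Responses with censoring status and bounds plus a covariate matrix.

    Attributes
    ----------
    y : (n,) float array
        Observed response; equals the bound for censored rows.
    status : (n,) int array
        Per-row :class:`CensStatus` codes.
    lower, upper : (n,) float arrays
        Observable interval (L_i, U_i); ``-inf`` / ``+inf`` where inactive.
    X : (n, p) float array
        Covariate matrix, including an intercept column when requested.
    names : list of str
        Covariate labels, one per column of ``X``.
    """

    y: np.ndarray
    status: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    X: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]
        self.validate()

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        n = self.y.shape[0]
        for name, arr in (("status", self.status), ("lower", self.lower), ("upper", self.upper)):
            if arr.shape[0] != n:
                raise DatasetValidationError(f"{name} has length {arr.shape[0]}, expected {n}")
        if self.X.shape[0] != n:
            raise DatasetValidationError(f"X has {self.X.shape[0]} rows, expected {n}")
        if len(self.names) != self.X.shape[1]:
            raise DatasetValidationError("names length does not match number of covariate columns")
        if not np.all(np.isfinite(self.X)):
            bad = int(np.where(~np.isfinite(self.X).all(axis=1))[0][0])
            raise DatasetValidationError(f"non-finite covariate value in row {bad}")
        if not np.all(np.isfinite(self.y)):
            bad = int(np.where(~np.isfinite(self.y))[0][0])
            raise DatasetValidationError(f"non-finite response in row {bad}")
        valid_codes = {int(s) for s in CensStatus}
        for i, s in enumerate(self.status):
            if int(s) not in valid_codes:
                raise DatasetValidationError(f"invalid status code {s} in row {i}")
        both = np.isfinite(self.lower) & np.isfinite(self.upper)
        bad = np.where(both & (self.lower >= self.upper))[0]
        if bad.size:
            raise DatasetValidationError(
                f"row {int(bad[0])}: lower bound {self.lower[bad[0]]} >= upper bound {self.upper[bad[0]]}"
            )
        obs = self.status == CensStatus.OBSERVED
        bad = np.where(obs & np.isfinite(self.lower) & (self.y <= self.lower))[0]
        if bad.size:
            raise DatasetValidationError(f"row {int(bad[0])}: observed response at or below lower bound")
        bad = np.where(obs & np.isfinite(self.upper) & (self.y >= self.upper))[0]
        if bad.size:
            raise DatasetValidationError(f"row {int(bad[0])}: observed response at or above upper bound")
        left = self.status == CensStatus.LEFT
        bad = np.where(left & (self.y != self.lower))[0]
        if bad.size:
            raise DatasetValidationError(f"row {int(bad[0])}: left-censored response must equal its lower bound")
        right = self.status == CensStatus.RIGHT
        bad = np.where(right & (self.y != self.upper))[0]
        if bad.size:
            raise DatasetValidationError(f"row {int(bad[0])}: right-censored response must equal its upper bound")

    def subset(self, idx) -> "CensoredDataset":
        """Row subset / permutation (keeps covariate labels)."""
        idx = np.asarray(idx)
        return CensoredDataset(
            y=self.y[idx], status=self.status[idx], lower=self.lower[idx],
            upper=self.upper[idx], X=self.X[idx], names=list(self.names),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with text status codes, suitable for CSV round-trips."""
        codes = np.array(["observed", "left", "right"])
        df = pd.DataFrame({"y": self.y, "status": codes[self.status]})
        for j, name in enumerate(self.names):
            df[name] = self.X[:, j]
        return df


def _from_columns(y, status, X, names, add_intercept: bool) -> CensoredDataset:
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    lower = np.full(n, -np.inf)
    upper = np.full(n, np.inf)
    status = np.asarray(status, dtype=int)
    lower[status == CensStatus.LEFT] = y[status == CensStatus.LEFT]
    upper[status == CensStatus.RIGHT] = y[status == CensStatus.RIGHT]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["Intercept"] + names
    return CensoredDataset(y=y, status=status, lower=lower, upper=upper, X=X, names=names)


def read_dataset(path, response: str, status_col: str, covariates,
                 add_intercept: bool = True) -> CensoredDataset:
    """Read a censored regression dataset from a headered CSV file.

    The status column accepts the text codes ``observed`` / ``left`` /
    ``right`` or the integer codes 0 / 1 / 2.  For right-censored rows the
    response value is stored as the upper bound U_i (and symmetrically for
    left censoring).

    Raises
    ------
    ConfigurationError
        If a named column is absent.
    StatusParseError
        If a status value cannot be interpreted (message gives the row).
    DatasetValidationError
        If a dataset invariant fails (message names the first offending row).
    """
    df = pd.read_csv(path)
    missing = [c for c in [response, status_col, *covariates] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"column(s) {missing} not found in {path}")
    if len(df) == 0:
        raise ConfigurationError(f"{path} contains no data rows")
    status = np.empty(len(df), dtype=int)
    for i, v in enumerate(df[status_col].to_numpy()):
        try:
            status[i] = CensStatus.parse(v)
        except StatusParseError as exc:
            raise StatusParseError(f"row {i}: {exc}") from None
    return _from_columns(
        y=df[response].to_numpy(dtype=float),
        status=status,
        X=df[list(covariates)].to_numpy(dtype=float),
        names=list(covariates),
        add_intercept=add_intercept,
    )


def write_dataset(data: CensoredDataset, path) -> None:
    """Write a dataset as CSV so that :func:`read_dataset` round-trips it."""
    data.to_frame().to_csv(path, index=False)


def lung_adapter(path, log_transform: bool = True, add_intercept: bool = True):
    """Adapt a CSV in the public NCCTG lung-cancer layout.

    Expects columns ``time`` (survival in days), ``status`` (1 = censored,
    2 = dead), ``age``, ``sex``, ``ph.ecog``.  Death maps to an observed
    response; status 1 maps to right censoring at the recorded time.  Rows
    with missing ``ph.ecog`` are dropped.  The response is log-transformed
    by default: on the day scale the intercept of a linear model would sit
    in the hundreds, while log-days keeps the symmetric-error assumption
    plausible for survival times.

    Returns
    -------
    (CensoredDataset, int)
        The dataset and the number of rows excluded for missing ph.ecog.
    """
    df = pd.read_csv(path)
    required = ["time", "status", "age", "sex", "ph.ecog"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"column(s) {missing} not found in {path}")
    n_before = len(df)
    df = df.dropna(subset=["ph.ecog", "time", "age", "sex"])
    n_dropped = n_before - len(df)
    status = np.empty(len(df), dtype=int)
    for i, s in enumerate(df["status"].to_numpy()):
        if int(s) == 2:
            status[i] = CensStatus.OBSERVED
        elif int(s) == 1:
            status[i] = CensStatus.RIGHT
        else:
            raise StatusParseError(f"row {i}: unknown lung status code {s} (expected 1 or 2)")
    y = df["time"].to_numpy(dtype=float)
    if log_transform:
        y = np.log(y)
    data = _from_columns(
        y=y, status=status,
        X=df[["age", "sex", "ph.ecog"]].to_numpy(dtype=float),
        names=["age", "sex", "ph.ecog"],
        add_intercept=add_intercept,
    )
    return data, n_dropped
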