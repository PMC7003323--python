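"""In-memory containers and TSV I/O for expression and clinical data.

Expression is a features × samples numeric matrix carrying a scale tag
(``raw`` FPKM or ``log2p1`` = log2(FPKM + 1)).  Clinical data is a plain
:class:`pandas.DataFrame` with the columns ``sample_id``, ``os_time``
(days), ``os_event`` (0/1), ``subtype`` and optional covariates
(``age``, ``gender``, ``stage``); :func:`validate_clinical` enforces the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Tokens treated as missing in any clinical column.
NA_TOKENS = ("", "NA", "NaN", "[Not Available]")

RAW = "raw"
LOG2P1 = "log2p1"


class CoxFilterError(Exception):
    """Base class for package errors."""


class ConfigError(CoxFilterError):
    """Invalid configuration (bad proportions, non-positive counts...)."""


class DataError(CoxFilterError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Features × samples expression matrix.

    Parameters
    ----------
    feature_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray, shape (n_features, n_samples)
        Expression values; finite, and non-negative in ``raw`` mode.
    scale_tag : {"raw", "log2p1"}
        Unit of ``values``: FPKM or log2(FPKM + 1).
    """

    feature_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    scale_tag: str = RAW

    def __post_init__(self):
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if self.scale_tag not in (RAW, LOG2P1):
            raise DataError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")
        if self.scale_tag == RAW and self.values.size and np.any(self.values < 0):
            raise DataError("raw FPKM values must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_features(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row subset by boolean mask or index array, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in keep],
            values=self.values[keep],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Column subset, reordered to ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return replace(
            self, sample_ids=list(sample_ids), values=self.values[:, idx]
        )

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def write_tsv(self, path) -> None:
        """TSV: first column ``feature_id``, header row of sample ids."""
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, scale_tag: str = RAW) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            feature_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            scale_tag=scale_tag,
        )


REQUIRED_CLINICAL = ("sample_id", "os_time", "os_event", "subtype")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table contract; returns the (unmodified) frame.

    Requires unique sample ids, os_time >= 0 and os_event in {0, 1} where
    present.  Missing values are permitted here; they are dropped by
    :func:`coxfilter.preprocess.align_samples` according to its ``require``
    list.
    """
    for col in REQUIRED_CLINICAL:
        if col not in clinical.columns:
            raise DataError(f"clinical table missing column {col!r}")
    if clinical["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in clinical table")
    t = pd.to_numeric(clinical["os_time"], errors="coerce")
    if (t.dropna() < 0).any():
        raise DataError("os_time must be non-negative")
    e = pd.to_numeric(clinical["os_event"], errors="coerce").dropna()
    if not e.isin([0, 1]).all():
        raise DataError("os_event must be 0 or 1")
    return clinical


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str},
        na_values=list(NA_TOKENS), keep_default_na=False,
    )
    return validate_clinical(df)


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.10g")
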