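"""Core containers: sample-by-feature matrices and connectivity edge indices.

Feature matrices are stored as a plain ``numpy`` array plus identifier lists
rather than a DataFrame: the CV protocols slice rows and columns millions of
times and array indexing keeps that cheap.  Round-tripping to tab-delimited
text (header of feature ids; ``sample_id`` and ``label`` columns first) goes
through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """A samples x features table with binary class labels.

    Parameters
    ----------
    values : (n_samples, n_features) float array, no missing values.
    labels : (n_samples,) int array with entries in {0, 1}; both classes must
        be present with at least two samples each.
    feature_ids : unique feature identifiers, one per column.
    sample_ids : unique sample identifiers, one per row.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        n, d = self.values.shape
        if len(self.labels) != n:
            raise ValueError(f"label count {len(self.labels)} != row count {n}")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length must equal column count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal row count")
        if len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        for c in (0, 1):
            if (self.labels == c).sum() < 2:
                raise ValueError(f"class {c} needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def column_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Integer column positions of the given feature ids (order preserved)."""
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([lookup[f] for f in feature_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from exc

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["sample_id", "label"]:
            raise ValueError("expected 'sample_id' and 'label' as the first two columns")
        return cls(
            values=df.iloc[:, 2:].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            feature_ids=list(df.columns[2:]),
            sample_ids=[str(s) for s in df["sample_id"]],
        )


#: Canonical frequency bands (Hz) for the synthetic connectivity features.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "low-beta": (12.0, 22.0),
    "high-beta": (22.0, 30.0),
    "gamma": (30.0, 55.0),
}


@dataclass
class ConnectivityIndex:
    """Maps each connectivity feature to a (channel pair, frequency band).

    Edges enumerate all unordered channel pairs (channel_a before channel_b in
    the canonical channel order, no self-pairs) crossed with the frequency
    bands, so a 45-channel montage and 6 bands yield C(45,2) * 6 = 5940
    entries.
    """

    table: pd.DataFrame = field(repr=False)
    channels: list[str] = field(default_factory=list)

    REQUIRED = ["feature_id", "channel_a", "channel_b", "band", "band_low_hz", "band_high_hz"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"index table missing columns: {missing}")
        order = {ch: i for i, ch in enumerate(self.channels)}
        a = self.table["channel_a"].map(order)
        b = self.table["channel_b"].map(order)
        if a.isna().any() or b.isna().any():
            raise ValueError("index references channels outside the canonical order")
        if not (a < b).all():
            raise ValueError("channel_a must precede channel_b in canonical order")
        if self.table["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids in index")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def lookup(self, feature_id: str) -> pd.Series:
        hit = self.table[self.table["feature_id"] == feature_id]
        if hit.empty:
            raise KeyError(f"unknown feature id {feature_id!r}")
        return hit.iloc[0]

    def feature_id_for(self, channel_a: str, channel_b: str, band: str) -> str:
        """Feature id of an edge; channel order is normalised to canonical."""
        order = {ch: i for i, ch in enumerate(self.channels)}
        if order[channel_a] > order[channel_b]:
            channel_a, channel_b = channel_b, channel_a
        hit = self.table[
            (self.table["channel_a"] == channel_a)
            & (self.table["channel_b"] == channel_b)
            & (self.table["band"] == band)
        ]
        if hit.empty:
            raise KeyError(f"no edge ({channel_a}, {channel_b}, {band})")
        return str(hit.iloc[0]["feature_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table[self.REQUIRED].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, channels: Sequence[str]) -> "ConnectivityIndex":
        return cls(table=pd.read_csv(path, sep="\t"), channels=list(channels))
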