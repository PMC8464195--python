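"""Modelling matrix construction: Rf windowing, grid alignment, scaling.

The modelling matrix concatenates, per sample, the organic band intensities
resampled onto a fixed Rf grid per imaging channel and the four sugar
quantities. Only bands inside the analytical Rf window (0.05-0.60 by
default, closed at both ends) are considered. Standardisation is per-column
min-max scaling to [0, 1]; the scaling parameters are retained so the
transform can be inverted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import SampleLabel, format_sample_label, parse_sample_label
from .profiles import (
    CHANNELS,
    SUGARS,
    ProfileTable,
    organic_column_name,
    parse_organic_column,
)

RF_WINDOW: tuple[float, float] = (0.05, 0.60)

FEATURE_SETS = ("sugars", "organics", "combined")


@dataclass(frozen=True)
class FeatureInfo:
    """Per-column metadata: a sugar, or a (channel, Rf) grid position."""

    kind: str  # "sugar" | "organic"
    name: str
    channel: str | None = None
    rf: float | None = None


@dataclass(frozen=True)
class GridSpec:
    """Shared Rf grid: closed interval [low, high] sampled every ``step``."""

    low: float = RF_WINDOW[0]
    high: float = RF_WINDOW[1]
    step: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError("grid bounds must satisfy 0 <= low < high <= 1")
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    def points(self) -> np.ndarray:
        n = int(np.floor((self.high - self.low) / self.step + 1e-9)) + 1
        if n < 1:
            raise ValueError("empty grid")
        return np.round(self.low + self.step * np.arange(n), 6)


@dataclass
class FeatureMatrix:
    """Samples x features real matrix with column metadata and labels."""

    values: np.ndarray
    features: list[FeatureInfo]
    labels: list[SampleLabel]
    standardised: bool = False
    scale_min: np.ndarray | None = None
    scale_range: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.features):
            raise ValueError("feature metadata length must equal column count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label count must equal row count")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def sugar_indices(self) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.features) if f.kind == "sugar"])

    def organic_indices(self, channel: str | None = None) -> np.ndarray:
        return np.array(
            [
                i
                for i, f in enumerate(self.features)
                if f.kind == "organic" and (channel is None or f.channel == channel)
            ],
            dtype=int,
        )

    def channels(self) -> list[str]:
        return [ch for ch in CHANNELS if self.organic_indices(ch).size]

    def channel_grid(self, channel: str) -> np.ndarray:
        idx = self.organic_indices(channel)
        return np.array([self.features[i].rf for i in idx])

    def select(self, feature_set: str) -> "FeatureMatrix":
        """Column subset by feature set: 'sugars', 'organics' or 'combined'."""
        if feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {feature_set!r}")
        if feature_set == "combined":
            return self
        idx = self.sugar_indices() if feature_set == "sugars" else self.organic_indices()
        return FeatureMatrix(
            self.values[:, idx],
            [self.features[i] for i in idx],
            list(self.labels),
            standardised=self.standardised,
            scale_min=None if self.scale_min is None else self.scale_min[idx],
            scale_range=None if self.scale_range is None else self.scale_range[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index([format_sample_label(l) for l in self.labels], name="sample"),
            columns=[f.name for f in self.features],
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write values as CSV and metadata/scaling as a JSON sidecar."""
        self.to_frame().to_csv(path)
        if sidecar:
            meta = {
                "standardised": self.standardised,
                "features": [
                    {"kind": f.kind, "name": f.name, "channel": f.channel, "rf": f.rf}
                    for f in self.features
                ],
                "scale_min": None if self.scale_min is None else self.scale_min.tolist(),
                "scale_range": None
                if self.scale_range is None
                else self.scale_range.tolist(),
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample")
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        features = [FeatureInfo(**f) for f in meta["features"]]
        return cls(
            df.to_numpy(dtype=float),
            features,
            [parse_sample_label(s) for s in df.index],
            standardised=meta["standardised"],
            scale_min=None if meta["scale_min"] is None else np.array(meta["scale_min"]),
            scale_range=None
            if meta["scale_range"] is None
            else np.array(meta["scale_range"]),
        )


def restrict_rf_window(
    table: ProfileTable, low: float = RF_WINDOW[0], high: float = RF_WINDOW[1]
) -> ProfileTable:
    """Drop organic columns with Rf outside the closed window [low, high].

    Sugar (and carried-through extra) columns are untouched.
    """
    if not low < high:
        raise ValueError("inverted Rf window bounds")
    drop = [name for name, _, rf in table.organic_columns() if not low <= rf <= high]
    return ProfileTable(
        table.data.drop(columns=drop),
        list(table.labels),
        provenance=table.provenance,
        extra_columns=list(table.extra_columns),
    )


def assemble_features(
    table: ProfileTable,
    grid: GridSpec | dict[str, GridSpec] | None = None,
) -> FeatureMatrix:
    """Resample organic bands onto the Rf grid and append the sugar columns.

    Each band's AU is assigned to the nearest grid point of its channel;
    bands mapping to the same grid point keep the maximum AU. The grid may
    be shared or given per channel; per-channel grids must only name
    channels present in the table. Column order is organics (channel-major,
    ascending Rf) followed by the four sugars, giving
    ``channels x grid length + 4`` columns.
    """
    if grid is None:
        grid = GridSpec()
    table_channels = {ch for _, ch, _ in table.organic_columns()}
    if isinstance(grid, GridSpec):
        grids = {ch: grid for ch in CHANNELS}
    else:
        if not grid:
            raise ValueError("empty grid specification")
        missing = set(grid) - table_channels
        if missing:
            raise ValueError(f"channels absent from table: {sorted(missing)}")
        grids = dict(grid)

    features: list[FeatureInfo] = []
    blocks: list[np.ndarray] = []
    n = table.n_samples
    for ch in CHANNELS:
        if ch not in grids:
            continue
        points = grids[ch].points()
        block = np.zeros((n, points.size))
        for name, _, rf in table.organic_columns():
            if parse_organic_column(name)[0] != ch:
                continue
            j = int(np.argmin(np.abs(points - rf)))
            block[:, j] = np.maximum(block[:, j], table.data[name].to_numpy(dtype=float))
        blocks.append(block)
        features += [
            FeatureInfo("organic", organic_column_name(ch, p), channel=ch, rf=float(p))
            for p in points
        ]
    sugar_block = table.data[list(SUGARS)].to_numpy(dtype=float)
    blocks.append(sugar_block)
    features += [FeatureInfo("sugar", s) for s in SUGARS]
    return FeatureMatrix(np.hstack(blocks), features, list(table.labels))


def standardise(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale every column to [0, 1]; constant columns map to 0.

    The original column minima and ranges are retained on the result for
    :func:`inverse_standardise`.
    """
    if matrix.standardised:
        raise ValueError("matrix is already standardised")
    if matrix.n_samples == 0 or matrix.n_features == 0:
        raise ValueError("empty matrix")
    lo = matrix.values.min(axis=0)
    rng = matrix.values.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    scaled = (matrix.values - lo) / safe
    scaled[:, rng == 0] = 0.0
    return FeatureMatrix(
        scaled,
        list(matrix.features),
        list(matrix.labels),
        standardised=True,
        scale_min=lo,
        scale_range=rng,
    )


def inverse_standardise(matrix: FeatureMatrix) -> FeatureMatrix:
    """Undo :func:`standardise` using the retained scaling parameters."""
    if not matrix.standardised or matrix.scale_min is None:
        raise ValueError("matrix carries no scaling parameters")
    values = matrix.values * np.where(matrix.scale_range > 0, matrix.scale_range, 0.0)
    values = values + matrix.scale_min
    return FeatureMatrix(values, list(matrix.features), list(matrix.labels))
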