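"""Profile tables: per-sample sugar quantities plus banded organic fingerprints.

A :class:`ProfileTable` holds one row per sample with

* four sugar columns (``fructose``, ``glucose``, ``maltose``, ``sucrose``) in
  quantification units, and
* organic band columns named ``<channel>@<Rf>`` with the Rf printed to four
  decimals, e.g. ``R366_D@0.4100``. Channels are the four imaging conditions:
  254 nm and 366 nm before derivatisation (``R254``, ``R366``) and
  transmittance white light / 366 nm after derivatisation (``TW_D``,
  ``R366_D``). Band intensities are absorbance peak heights (AU) in [0, 1];
  a value of 0 means "no band at this position".

Tables are serialised as plain delimited text (comma by default) with the
sample label in the first column, so that write -> read is a bit-exact
round trip.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import SampleLabel, format_sample_label, parse_sample_label

logger = logging.getLogger(__name__)

SUGARS: tuple[str, ...] = ("fructose", "glucose", "maltose", "sucrose")
CHANNELS: tuple[str, ...] = ("R254", "R366", "TW_D", "R366_D")

_ORGANIC_COL_RE = re.compile(r"^(?P<channel>R254|R366|TW_D|R366_D)@(?P<rf>0?\.\d+|[01](?:\.\d+)?)$")


class ProfileTableError(ValueError):
    """Raised when a table violates the profile-table contract."""


def organic_column_name(channel: str, rf: float) -> str:
    if channel not in CHANNELS:
        raise ProfileTableError(f"unknown channel {channel!r}")
    return f"{channel}@{rf:.4f}"


def parse_organic_column(name: str) -> tuple[str, float] | None:
    """Return (channel, rf) for an organic column name, else None."""
    m = _ORGANIC_COL_RE.match(name)
    if m is None:
        return None
    return m.group("channel"), float(m.group("rf"))


@dataclass
class SampleRecord:
    """One product or blend: identity, sugar profile and organic band set."""

    label: SampleLabel
    sugars: dict[str, float]
    bands: dict[tuple[str, float], float]  # (channel, rf) -> AU

    def __post_init__(self) -> None:
        for s in SUGARS:
            if s not in self.sugars:
                raise ProfileTableError(f"missing sugar {s!r}")
            if self.sugars[s] < 0:
                raise ProfileTableError(f"negative {s} quantity")
        for (channel, rf), au in self.bands.items():
            if channel not in CHANNELS:
                raise ProfileTableError(f"unknown channel {channel!r}")
            if not 0.0 <= rf <= 1.0:
                raise ProfileTableError(f"Rf {rf} outside [0, 1]")
            if au < 0:
                raise ProfileTableError("negative band intensity")


@dataclass
class ProfileTable:
    """Samples x (sugars + organic bands) table with label metadata.

    ``data`` is indexed by the canonical label string; sugar columns come
    first, then organic columns sorted by channel (in :data:`CHANNELS` order)
    and ascending Rf, then any carried-through extra columns (kept but not
    modelled).
    """

    data: pd.DataFrame
    labels: list[SampleLabel]
    provenance: str = ""
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.data):
            raise ProfileTableError("label count does not match row count")
        for s in SUGARS:
            if s not in self.data.columns:
                raise ProfileTableError(f"missing sugar column {s!r}")
        modelled = [c for c in self.data.columns if c not in self.extra_columns]
        block = self.data[modelled]
        if block.isna().any().any():
            raise ProfileTableError("missing values in table")
        if (block.to_numpy(dtype=float) < 0).any():
            raise ProfileTableError("negative quantities in table")
        for name in modelled:
            if name in SUGARS:
                continue
            parsed = parse_organic_column(name)
            if parsed is None:
                raise ProfileTableError(f"unrecognised column {name!r}")
            if not 0.0 <= parsed[1] <= 1.0:
                raise ProfileTableError(f"Rf outside [0, 1] in column {name!r}")
        self.data = self.data[_canonical_column_order(self.data.columns, self.extra_columns)]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def organic_columns(self) -> list[tuple[str, str, float]]:
        """All organic columns as (column name, channel, rf), in table order."""
        out = []
        for name in self.data.columns:
            parsed = parse_organic_column(name)
            if parsed is not None and name not in self.extra_columns:
                out.append((name, parsed[0], parsed[1]))
        return out

    def records(self) -> list[SampleRecord]:
        recs = []
        organics = self.organic_columns()
        for label, (_, row) in zip(self.labels, self.data.iterrows()):
            bands = {
                (ch, rf): float(row[name]) for name, ch, rf in organics if row[name] > 0
            }
            recs.append(
                SampleRecord(label, {s: float(row[s]) for s in SUGARS}, bands)
            )
        return recs

    def equals(self, other: "ProfileTable") -> bool:
        return self.labels == other.labels and self.data.equals(other.data)


def _canonical_column_order(columns, extra_columns) -> list[str]:
    organics = []
    extras = []
    for name in columns:
        if name in SUGARS or name in extra_columns:
            if name in extra_columns:
                extras.append(name)
            continue
        ch, rf = parse_organic_column(name)
        organics.append((CHANNELS.index(ch), rf, name))
    return list(SUGARS) + [name for _, _, name in sorted(organics)] + extras


def records_to_table(records: list[SampleRecord], provenance: str = "") -> ProfileTable:
    """Assemble records into a table over the union of band positions."""
    if not records:
        raise ProfileTableError("no records")
    positions = sorted(
        {pos for r in records for pos in r.bands},
        key=lambda p: (CHANNELS.index(p[0]), p[1]),
    )
    columns = list(SUGARS) + [organic_column_name(ch, rf) for ch, rf in positions]
    rows = np.zeros((len(records), len(columns)))
    for i, rec in enumerate(records):
        rows[i, : len(SUGARS)] = [rec.sugars[s] for s in SUGARS]
        for j, pos in enumerate(positions):
            rows[i, len(SUGARS) + j] = rec.bands.get(pos, 0.0)
    index = [format_sample_label(r.label) for r in records]
    df = pd.DataFrame(rows, index=pd.Index(index, name="sample"), columns=columns)
    return ProfileTable(df, [r.label for r in records], provenance=provenance)


def read_profile_table(
    path,
    schema: dict | None = None,
    delimiter: str = ",",
) -> ProfileTable:
    """Read a delimited profile table.

    ``schema`` optionally maps vendor column names onto the package's own:
    ``{"sample": <label column>, "sugars": {<col>: <sugar>},
    "organics": {<col>: (channel, rf)}}``. Without a schema the file must
    already use the canonical naming (``sample``, sugar names,
    ``<channel>@<Rf>``). Columns that are neither mapped nor recognised are
    carried through untouched but excluded from modelling.
    """
    df = pd.read_csv(path, sep=delimiter)
    if df.empty:
        raise ProfileTableError(f"{path}: table has no rows")
    schema = schema or {}
    sample_col = schema.get("sample", "sample")
    if sample_col not in df.columns:
        raise ProfileTableError(f"{path}: missing sample column {sample_col!r}")
    rename: dict[str, str] = {}
    for col, sugar in schema.get("sugars", {}).items():
        rename[col] = sugar
    for col, (channel, rf) in schema.get("organics", {}).items():
        rename[col] = organic_column_name(channel, float(rf))
    df = df.rename(columns=rename)
    labels = [parse_sample_label(str(v)) for v in df[sample_col]]
    if len(set(labels)) != len(labels):
        raise ProfileTableError(f"{path}: duplicate sample labels")
    df = df.drop(columns=[sample_col])
    df.index = pd.Index([format_sample_label(l) for l in labels], name="sample")

    extra = []
    for name in df.columns:
        if name in SUGARS or parse_organic_column(name) is not None:
            coerced = pd.to_numeric(df[name], errors="coerce")
            if coerced.isna().any():
                raise ProfileTableError(f"{path}: non-numeric cell in column {name!r}")
            df[name] = coerced
        else:
            extra.append(name)
    table = ProfileTable(df, labels, provenance=str(path), extra_columns=extra)
    logger.info("read %s: %d rows, %d columns", path, len(df), df.shape[1])
    return table


def write_profile_table(table: ProfileTable, path, delimiter: str = ",") -> None:
    """Write a profile table as delimited text (header + one row per sample).

    Column order is deterministic (sugars, then organics by channel and Rf),
    and floats are written with full repr precision so that
    :func:`read_profile_table` inverts the write bit-exactly.
    """
    if table.data.shape[1] == 0:
        raise ProfileTableError("refusing to write a table with no columns")
    table.data.to_csv(path, sep=delimiter)
    logger.info(
        "wrote %s: %d rows, %d columns", path, table.n_samples, table.data.shape[1]
    )
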