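"""Input/output tables for the surveillance pipeline.

Five CSV tables describe a camera season:

``frames.csv``
    Every image a camera recorded: ``camera_id, timestamp, regime``.
    ``regime`` is ``focused`` (1-min frames inside the 12.00-15.00 and
    01.00-03.00 windows) or ``continuous`` (5-min frames, always active).
``visits.csv``
    One row per image in which a forager is present on a focal
    inflorescence: ``camera_id, inflorescence_id, timestamp, taxon`` with
    taxon one of ``moth``, ``bumblebee``, ``other``.
``phenology.csv``
    Per inflorescence: ``inflorescence_id, camera_id,
    doy_last_floret_emerged, doy_first_floret_senesced, fully_recorded``.
``dissection.csv``
    Per floret of each dissected infructescence: ``inflorescence_id,
    floret_rank, n_florets, percentile, n_seeds`` with 1 = basal rank,
    percentile 0 (basal) to 100 (apical) and 0-2 seeds per floret.
``cover.csv``
    Midday floral-cover fraction per camera and day of year:
    ``camera_id, doy, cover``.

Timestamps are ISO 8601 local clock time without timezone; the diel
sampling windows are defined in local clock hours. Day-of-year values may
be fractional (date + clock/24) so visit times and floral peaks share one
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainValueError, ReferentialError, SchemaError

__all__ = [
    "TAXA",
    "REGIMES",
    "REGIME_INTERVAL_MIN",
    "FOCUSED_WINDOWS",
    "TableBundle",
    "read_tables",
    "write_tables",
    "validate_bundle",
    "validate_regime",
    "fractional_doy",
]

TAXA = ("moth", "bumblebee", "other")
REGIMES = ("focused", "continuous")

#: Nominal frame spacing per camera regime, minutes.
REGIME_INTERVAL_MIN = {"focused": 1, "continuous": 5}

#: Active clock windows of the focused regime, minutes-of-day [start, end).
FOCUSED_WINDOWS = ((12 * 60, 15 * 60), (1 * 60, 3 * 60))

_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "frames": ("camera_id", "timestamp", "regime"),
    "visits": ("camera_id", "inflorescence_id", "timestamp", "taxon"),
    "phenology": (
        "inflorescence_id",
        "camera_id",
        "doy_last_floret_emerged",
        "doy_first_floret_senesced",
        "fully_recorded",
    ),
    "dissection": ("inflorescence_id", "floret_rank", "n_florets", "percentile", "n_seeds"),
    "cover": ("camera_id", "doy", "cover"),
}


@dataclass
class TableBundle:
    """The five validated pipeline inputs as DataFrames."""

    frames: pd.DataFrame
    visits: pd.DataFrame
    phenology: pd.DataFrame
    dissection: pd.DataFrame
    cover: pd.DataFrame

    def copy(self) -> "TableBundle":
        return TableBundle(**{f.name: getattr(self, f.name).copy() for f in dc_fields(self)})


def fractional_doy(timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year with time-of-day as a fraction (12:00 -> .5)."""
    ts = pd.DatetimeIndex(timestamps)
    frac = (ts.hour * 3600 + ts.minute * 60 + ts.second) / 86400.0
    return ts.dayofyear.to_numpy(float) + frac.to_numpy(float)


def _require_columns(df: pd.DataFrame, name: str) -> None:
    for col in _SCHEMAS[name]:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column {col!r}")


def _coerce(name: str, df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, name)
    df = df.loc[:, list(_SCHEMAS[name])].copy()
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    if name == "phenology":
        df["fully_recorded"] = df["fully_recorded"].astype(bool)
        for col in ("doy_last_floret_emerged", "doy_first_floret_senesced"):
            df[col] = df[col].astype(float)
    if name == "dissection":
        for col in ("floret_rank", "n_florets", "n_seeds"):
            df[col] = df[col].astype(int)
        df["percentile"] = pd.to_numeric(df["percentile"], errors="coerce")
    if name == "cover":
        df["doy"] = df["doy"].astype(float)
        df["cover"] = df["cover"].astype(float)
    return df


def _fill_percentiles(dissection: pd.DataFrame) -> pd.DataFrame:
    """Fill missing percentile positions from floret rank.

    Evenly spaced so rank 1 maps to 0 (basal) and rank n to 100 (apical);
    a single-floret head sits at 50.
    """
    miss = dissection["percentile"].isna()
    if miss.any():
        rank = dissection.loc[miss, "floret_rank"].to_numpy(float)
        n = dissection.loc[miss, "n_florets"].to_numpy(float)
        pct = np.where(n > 1, 100.0 * (rank - 1) / np.maximum(n - 1, 1), 50.0)
        dissection = dissection.copy()
        dissection.loc[miss, "percentile"] = pct
    return dissection


def validate_bundle(bundle: TableBundle) -> TableBundle:
    """Coerce dtypes, fill derived fields, and enforce every invariant.

    Raises :class:`SchemaError`, :class:`DomainValueError` or
    :class:`ReferentialError`; returns a cleaned copy on success.
    """
    frames = _coerce("frames", bundle.frames)
    visits = _coerce("visits", bundle.visits)
    phen = _coerce("phenology", bundle.phenology)
    diss = _fill_percentiles(_coerce("dissection", bundle.dissection))
    cover = _coerce("cover", bundle.cover)

    bad_regime = set(frames["regime"]) - set(REGIMES)
    if bad_regime:
        raise DomainValueError(f"frames: unknown regime values {sorted(bad_regime)}")
    bad_taxa = set(visits["taxon"]) - set(TAXA)
    if bad_taxa:
        raise DomainValueError(
            f"visits: taxon must be one of {TAXA}, found {sorted(bad_taxa)}"
        )

    # every annotation must point at a recorded frame of its camera
    frame_keys = set(zip(frames["camera_id"], frames["timestamp"]))
    for cam, ts in zip(visits["camera_id"], visits["timestamp"]):
        if (cam, ts) not in frame_keys:
            raise ReferentialError(
                f"visits: no frame for camera {cam!r} at {ts} — annotation "
                "timestamps must match the frame log"
            )

    known = set(phen["inflorescence_id"])
    for name, df in (("visits", visits), ("dissection", diss)):
        unknown = set(df["inflorescence_id"]) - known
        if unknown:
            raise ReferentialError(
                f"{name}: inflorescence ids absent from phenology: {sorted(unknown)}"
            )

    if (phen["doy_last_floret_emerged"] > phen["doy_first_floret_senesced"]).any():
        raise DomainValueError(
            "phenology: last-floret emergence after first-floret senescence"
        )
    if (diss["floret_rank"] > diss["n_florets"]).any():
        raise DomainValueError("dissection: floret_rank exceeds n_florets")
    if ((diss["n_seeds"] < 0) | (diss["n_seeds"] > 2)).any():
        raise DomainValueError("dissection: n_seeds must be in {0, 1, 2}")
    if ((diss["percentile"] < 0) | (diss["percentile"] > 100)).any():
        raise DomainValueError("dissection: percentile outside [0, 100]")
    mono = diss.sort_values(["inflorescence_id", "floret_rank"]).groupby(
        "inflorescence_id"
    )["percentile"]
    if (mono.diff().dropna() < 0).any():
        raise DomainValueError(
            "dissection: percentile must be non-decreasing with floret_rank"
        )
    if ((cover["cover"] < 0) | (cover["cover"] > 1)).any():
        raise DomainValueError("cover: cover fraction outside [0, 1]")

    return TableBundle(frames=frames, visits=visits, phenology=phen,
                       dissection=diss, cover=cover)


def read_tables(directory: str | Path | None = None,
                paths: Mapping[str, str | Path] | None = None) -> TableBundle:
    """Read and validate the five CSV inputs.

    Parameters
    ----------
    directory
        A directory containing ``frames.csv``, ``visits.csv``,
        ``phenology.csv``, ``dissection.csv`` and ``cover.csv``.
    paths
        Alternatively, an explicit mapping from table name to file path;
        overrides ``directory`` per table.
    """
    resolved: dict[str, Path] = {}
    for name in _SCHEMAS:
        if paths and name in paths:
            resolved[name] = Path(paths[name])
        elif directory is not None:
            resolved[name] = Path(directory) / f"{name}.csv"
        else:
            raise SchemaError(f"no path given for table {name!r}")
        if not resolved[name].exists():
            raise SchemaError(f"{name}: file not found: {resolved[name]}")
    raw = TableBundle(**{name: pd.read_csv(p) for name, p in resolved.items()})
    return validate_bundle(raw)


def write_tables(bundle: TableBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle back to ``<directory>/<table>.csv``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name in _SCHEMAS:
        df = getattr(bundle, name).copy()
        if "timestamp" in df.columns:
            df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime(
                "%Y-%m-%dT%H:%M:%S"
            )
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        out[name] = path
    return out


def _minute_of_day(ts: pd.DatetimeIndex) -> np.ndarray:
    return (ts.hour * 60 + ts.minute).to_numpy()


def in_focused_window(timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """True where a clock time falls inside a focused-regime window."""
    mod = _minute_of_day(pd.DatetimeIndex(timestamps))
    ok = np.zeros(len(mod), dtype=bool)
    for lo, hi in FOCUSED_WINDOWS:
        ok |= (mod >= lo) & (mod <= hi)
    return ok


def validate_regime(frames: pd.DataFrame) -> pd.DataFrame:
    """Report frame-log violations of the declared sampling regimes.

    Returns a DataFrame with one row per violation and columns
    ``camera_id, timestamp, kind, detail`` where ``kind`` is
    ``window`` (a focused frame outside 12.00-15.00 / 01.00-03.00) or
    ``gap`` (spacing between consecutive frames differs from the nominal
    interval). An empty report means a compliant log. Report-only: never
    raises.
    """
    frames = _coerce("frames", frames).sort_values(["camera_id", "timestamp"])
    records: list[dict] = []
    focused = frames[frames["regime"] == "focused"]
    if len(focused):
        outside = ~in_focused_window(focused["timestamp"])
        for _, row in focused[outside].iterrows():
            records.append(
                dict(camera_id=row.camera_id, timestamp=row.timestamp,
                     kind="window", detail="focused frame outside active windows")
            )
    for (cam, regime), grp in frames.groupby(["camera_id", "regime"], sort=False):
        interval = REGIME_INTERVAL_MIN[regime]
        ts = pd.DatetimeIndex(grp["timestamp"])
        gaps = np.diff(ts.asi8) / 60e9  # minutes
        if regime == "focused":
            # window-boundary jumps are expected, not gaps
            starts = in_focused_window(ts[1:])
        for prev, cur, gap in zip(ts[:-1], ts[1:], gaps):
            if gap == interval:
                continue
            if regime == "focused":
                prev_mod, cur_mod = (prev.hour * 60 + prev.minute), (cur.hour * 60 + cur.minute)
                # jump from one window's end to the next window's start
                at_boundary = any(prev_mod == hi for _, hi in FOCUSED_WINDOWS) and any(
                    cur_mod == lo for lo, _ in FOCUSED_WINDOWS
                )
                if at_boundary:
                    continue
            records.append(
                dict(camera_id=cam, timestamp=cur, kind="gap",
                     detail=f"{gap:g} min after previous frame (nominal {interval})")
            )
    return pd.DataFrame(records, columns=["camera_id", "timestamp", "kind", "detail"])
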