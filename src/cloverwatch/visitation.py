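"""From image-level visit annotations to counts, events and association tests.

The unit of visitation counting is the annotated image (a frame in which a
forager is present on a focal inflorescence). Visit *events* are a derived
view: a maximal run of strictly consecutive frames of one camera in which
the same visitor class is present on the same inflorescence. Because
presence between frames is unobserved, an event's duration is reported as
the lower bound ``(n_frames - 1) * frame_interval`` — a 3-frame moth event
under the 1-min regime lasted "over 2 min".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, ReferentialError
from .tables import REGIME_INTERVAL_MIN, TAXA

__all__ = [
    "count_visit_images",
    "image_fraction_pct",
    "assemble_events",
    "DielHistogram",
    "diel_histogram",
    "visitation_flags",
    "CooccurrenceResult",
    "cooccurrence_test",
    "chi2_from_table",
]


def count_visit_images(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon visit-image counts and integer-percent shares of the total.

    Returns a DataFrame indexed by taxon with columns ``count``,
    ``share_pct`` (share of all visit images, rounded to the nearest
    integer percent) and ``share`` (the unrounded fraction). With zero
    annotations the counts are zero and the shares NaN.
    """
    counts = visits["taxon"].value_counts().reindex(TAXA, fill_value=0)
    total = int(counts.sum())
    share = counts / total if total else counts * np.nan
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "share": share,
            "share_pct": np.round(100 * share).astype("Int64") if total else pd.array([pd.NA] * len(TAXA), dtype="Int64"),
        }
    )


def image_fraction_pct(n_visit_images: int, n_frames: int, sig: int = 2) -> float:
    """Visit images as a percentage of all frames, to ``sig`` significant figures.

    44 visit images among 164,532 frames gives 0.027 (percent).
    """
    if n_frames <= 0:
        raise DegenerateDataError("image fraction undefined without frames")
    pct = 100.0 * n_visit_images / n_frames
    if pct == 0:
        return 0.0
    from math import floor, log10

    return round(pct, -int(floor(log10(abs(pct)))) + (sig - 1))


def _frame_positions(frames: pd.DataFrame) -> dict:
    """Per camera: sorted timestamps (ns), their ordinal positions, interval."""
    out = {}
    for cam, grp in frames.groupby("camera_id", sort=False):
        ts = np.sort(pd.DatetimeIndex(grp["timestamp"]).asi8)
        interval = REGIME_INTERVAL_MIN[grp["regime"].iloc[0]]
        out[cam] = (ts, interval)
    return out


def assemble_events(visits: pd.DataFrame, frames: pd.DataFrame) -> pd.DataFrame:
    """Group annotations into visit events.

    Two annotations of the same taxon on the same inflorescence merge into
    one event iff they sit on consecutive frames of the camera — adjacent
    in the frame log *and* spaced by the nominal regime interval (a jump
    across a focused-window boundary never merges). Returns one row per
    event: ``inflorescence_id, taxon, start_timestamp, n_frames,
    frame_interval_min, duration_lower_bound_min``.
    """
    cams = _frame_positions(frames)
    rows: list[dict] = []
    for (infl, taxon, cam), grp in visits.groupby(
        ["inflorescence_id", "taxon", "camera_id"], sort=False
    ):
        if cam not in cams:
            raise ReferentialError(f"visits: camera {cam!r} absent from frame log")
        ts_all, interval = cams[cam]
        t = np.sort(pd.DatetimeIndex(grp["timestamp"]).asi8)
        pos = np.searchsorted(ts_all, t)
        if not np.array_equal(ts_all[np.clip(pos, 0, len(ts_all) - 1)], t):
            raise ReferentialError(
                f"visits: annotation for {infl!r} not matching any frame of {cam!r}"
            )
        consecutive = (np.diff(pos) == 1) & (np.diff(t) == interval * 60_000_000_000)
        breaks = np.flatnonzero(~consecutive)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(t) - 1]))
        for s, e in zip(starts, ends):
            n = int(e - s + 1)
            rows.append(
                dict(
                    inflorescence_id=infl,
                    taxon=taxon,
                    start_timestamp=pd.Timestamp(t[s]),
                    n_frames=n,
                    frame_interval_min=interval,
                    duration_lower_bound_min=(n - 1) * interval,
                )
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "inflorescence_id",
            "taxon",
            "start_timestamp",
            "n_frames",
            "frame_interval_min",
            "duration_lower_bound_min",
        ],
    )
    return events.sort_values(
        ["start_timestamp", "inflorescence_id"], ignore_index=True
    )


@dataclass
class DielHistogram:
    """Visit images and sampling effort binned by clock time.

    ``rate`` corrects the raw counts for unequal effort: the focused
    cameras record only inside two diel windows, so a raw diel histogram
    of counts conflates insect activity with camera activity. ``rate`` is
    NaN (undefined, not zero) in bins where no frame was recorded.
    """

    bin_width_min: int
    table: pd.DataFrame  # bin_start_min, count, effort, rate


def diel_histogram(
    visits: pd.DataFrame,
    frames: pd.DataFrame,
    bin_width_min: int = 60,
    taxon: str | None = None,
) -> DielHistogram:
    """Bin visit images and recorded frames by clock time of day."""
    if 1440 % bin_width_min:
        raise ConfigurationError(
            f"bin_width_min must divide 1440, got {bin_width_min}"
        )
    nbins = 1440 // bin_width_min
    if taxon is not None:
        visits = visits[visits["taxon"] == taxon]

    def binned(ts) -> np.ndarray:
        idx = pd.DatetimeIndex(ts)
        mod = (idx.hour * 60 + idx.minute).to_numpy() // bin_width_min
        return np.bincount(mod, minlength=nbins)

    count = binned(visits["timestamp"])
    effort = binned(frames["timestamp"])
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(effort > 0, count / np.maximum(effort, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_start_min": np.arange(nbins) * bin_width_min,
            "count": count,
            "effort": effort,
            "rate": rate,
        }
    )
    return DielHistogram(bin_width_min=bin_width_min, table=table)


def visitation_flags(
    visits: pd.DataFrame,
    phenology: pd.DataFrame,
    fully_recorded_only: bool = False,
) -> pd.DataFrame:
    """Per-inflorescence visited-by flags and visit-image counts.

    Every inflorescence in the phenology table gets a row; those with no
    annotation get all-false flags. ``visited_any`` is the OR of the three
    class flags.
    """
    phen = phenology
    if fully_recorded_only:
        phen = phen[phen["fully_recorded"]]
    known = set(phenology["inflorescence_id"])
    unknown = set(visits["inflorescence_id"]) - known
    if unknown:
        raise ReferentialError(f"visits reference unknown inflorescences {sorted(unknown)}")
    idx = pd.Index(phen["inflorescence_id"], name="inflorescence_id")
    flags = pd.DataFrame(index=idx)
    for t in TAXA:
        seen = visits.loc[visits["taxon"] == t, "inflorescence_id"]
        flags[f"visited_{t}"] = idx.isin(set(seen))
    flags["visited_any"] = flags[[f"visited_{t}" for t in TAXA]].any(axis=1)
    n_img = visits.groupby("inflorescence_id").size()
    flags["n_visit_images"] = n_img.reindex(idx, fill_value=0).astype(int)
    return flags


def chi2_from_table(table: np.ndarray) -> float:
    """Pearson chi-squared statistic sum((O-E)^2 / E) on a contingency table."""
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


@dataclass
class CooccurrenceResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    yates: bool


def cooccurrence_test(flags: pd.DataFrame, yates: bool = False) -> CooccurrenceResult:
    """Association between moth and bumblebee visitation across inflorescences.

    Pearson chi-squared on the 2x2 table of moth-visited x bumblebee-
    visited (d.f. = 1). Yates continuity correction is off by default.
    """
    if len(flags) < 2:
        raise DegenerateDataError("co-occurrence test needs >= 2 inflorescences")
    tab = pd.crosstab(flags["visited_moth"], flags["visited_bumblebee"]).reindex(
        index=[False, True], columns=[False, True], fill_value=0
    )
    arr = tab.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateDataError(
            "degenerate 2x2 table: a zero margin (a class never/always present)"
        )
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    return CooccurrenceResult(statistic=float(chi2), df=int(dof), p_value=float(p),
                              table=tab, yates=yates)
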