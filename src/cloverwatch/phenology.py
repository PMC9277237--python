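"""Floral-peak dates, season cover curves, and the Visit Lateness Index.

An inflorescence's *floral peak* is the half-way point between the
day-of-year on which its last floret emerged and the day-of-year on which
its first floret senesced. The *Visit Lateness Index* (VLI) of an
inflorescence is the mean fractional day-of-year of its visit images minus
its floral-peak day-of-year: negative values mean visits concentrated
before peak flowering. The VLI is undefined (not zero) for inflorescences
never seen visited.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, DomainValueError
from .tables import fractional_doy

__all__ = ["floral_peak_doy", "floral_peaks", "compute_vli", "cover_series"]


def floral_peak_doy(doy_last_floret_emerged: float, doy_first_floret_senesced: float) -> float:
    """Midpoint of last-floret emergence and first-floret senescence."""
    if doy_last_floret_emerged > doy_first_floret_senesced:
        raise DomainValueError(
            "last-floret emergence must not be after first-floret senescence"
        )
    return 0.5 * (doy_last_floret_emerged + doy_first_floret_senesced)


def floral_peaks(phenology: pd.DataFrame) -> pd.Series:
    """Per-inflorescence peak day-of-year, indexed by inflorescence_id."""
    bad = phenology["doy_last_floret_emerged"] > phenology["doy_first_floret_senesced"]
    if bad.any():
        raise DomainValueError(
            "last-floret emergence after first-floret senescence for "
            f"{phenology.loc[bad, 'inflorescence_id'].tolist()}"
        )
    peak = 0.5 * (
        phenology["doy_last_floret_emerged"] + phenology["doy_first_floret_senesced"]
    )
    return pd.Series(
        peak.to_numpy(), index=pd.Index(phenology["inflorescence_id"]), name="peak_doy"
    )


def compute_vli(visits: pd.DataFrame, phenology: pd.DataFrame) -> pd.DataFrame:
    """Visit Lateness Index per inflorescence.

    Returns a DataFrame indexed by inflorescence_id with columns
    ``peak_doy``, ``vli`` (NaN where no visit was recorded) and
    ``n_visits`` (visit-image count). Visit times enter as fractional
    day-of-year, so a 23:50 and a 00:10 visit differ by 20 minutes, not a
    day.
    """
    peaks = floral_peaks(phenology)
    out = pd.DataFrame({"peak_doy": peaks})
    if len(visits):
        doys = pd.Series(
            fractional_doy(visits["timestamp"]),
            index=visits["inflorescence_id"].to_numpy(),
        )
        mean_doy = doys.groupby(level=0).mean()
        n = doys.groupby(level=0).size()
    else:
        mean_doy = pd.Series(dtype=float)
        n = pd.Series(dtype=int)
    out["mean_visit_doy"] = mean_doy.reindex(out.index)
    out["vli"] = out["mean_visit_doy"] - out["peak_doy"]
    out["n_visits"] = n.reindex(out.index, fill_value=0).astype(int)
    out.index.name = "inflorescence_id"
    return out


def cover_series(cover: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Season floral-cover curve and its peak day.

    Aggregates the midday cover observations to an unweighted per-day mean
    across cameras and reports the day of maximal mean cover (ties broken
    to the earliest day).
    """
    if not len(cover):
        raise DegenerateDataError("cover series needs >= 1 observation")
    curve = (
        cover.groupby("doy", sort=True)["cover"].mean().rename("mean_cover").reset_index()
    )
    peak_doy = float(curve.loc[curve["mean_cover"].idxmax(), "doy"])
    return curve, peak_doy
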