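"""Monte-Carlo experiments over simulated seasons.

Thin helpers that run many independent seasons and summarise how often the
downstream tests detect (or falsely detect) the visitation -> seed-set
signal. Used for power/type-I calibration and by the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .inference import sli_vli_regression, two_group_seedset_model
from .pipeline import build_index_table
from .simulate import SimulationConfig, simulate_season
from .tables import FOCUSED_WINDOWS
from .visitation import count_visit_images

__all__ = ["ReplicateSummary", "run_replicate", "replicate_study"]


@dataclass
class ReplicateSummary:
    """Key statistics of one simulated season."""

    seed: int
    n_inflorescences: int
    n_visit_images: int
    visited_fraction: float
    moth_share: float
    moth_images_in_window: int
    moth_images_total: int
    two_group_p: float | None
    two_group_diff_pct: float | None
    slope: float | None
    slope_p: float | None
    mean_seed_set: float | None


def _minute_of_day(ts: pd.Series) -> np.ndarray:
    idx = pd.DatetimeIndex(ts)
    return (idx.hour * 60 + idx.minute).to_numpy()


def _in_clock_window(minute_of_day: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window[0] * 60, window[1] * 60
    if lo <= hi:
        return (minute_of_day >= lo) & (minute_of_day <= hi)
    return (minute_of_day >= lo) | (minute_of_day <= hi)


def run_replicate(config: SimulationConfig, seed: int) -> ReplicateSummary:
    """Simulate one season and run the headline analyses on it."""
    bundle, truth = simulate_season(config, seed=seed)
    idx = build_index_table(bundle)
    counts = count_visit_images(bundle.visits)
    total = int(counts["count"].sum())
    moth_visits = bundle.visits[bundle.visits["taxon"] == "moth"]
    in_win = (
        _in_clock_window(_minute_of_day(moth_visits["timestamp"]), config.moth_window)
        if len(moth_visits)
        else np.zeros(0, bool)
    )

    two_p = two_diff = None
    try:
        fit = two_group_seedset_model(idx, "any_visit")
        two_p, two_diff = fit.p_value, fit.mean_difference_pct
    except DegenerateDataError:
        pass
    slope = slope_p = None
    try:
        reg = sli_vli_regression(idx, weighted=True)
        slope, slope_p = reg.slope, reg.p_value
    except DegenerateDataError:
        pass

    return ReplicateSummary(
        seed=seed,
        n_inflorescences=len(idx),
        n_visit_images=total,
        visited_fraction=float(idx["visited_any"].mean()),
        moth_share=float(counts.loc["moth", "count"] / total) if total else float("nan"),
        moth_images_in_window=int(in_win.sum()),
        moth_images_total=int(len(moth_visits)),
        two_group_p=two_p,
        two_group_diff_pct=two_diff,
        slope=slope,
        slope_p=slope_p,
        mean_seed_set=float(idx["s"].mean()) if idx["s"].notna().any() else None,
    )


def replicate_study(
    config: SimulationConfig, n_replicates: int, base_seed: int = 0
) -> pd.DataFrame:
    """Run ``n_replicates`` independent seasons; one summary row each.

    Per-replicate seeds are spawned deterministically from ``base_seed``
    so the whole study is reproducible from one integer.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    rows = [run_replicate(config, int(s)) for s in seeds]
    return pd.DataFrame([r.__dict__ for r in rows])
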