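"""Generative simulator of a camera-surveilled red-clover season.

The simulator produces the five pipeline input tables plus ground truth,
emulating the field design: a grid of time-lapse cameras (a *focused*
regime shooting 1-min frames inside the 12.00-15.00 and 01.00-03.00
windows, and a *continuous* regime shooting 5-min frames around the
clock) watching inflorescences that flower for about two weeks each,
their florets opening basally to apically.

Mechanism, per inflorescence:

* Bumblebee (and "other") visits arrive as an inhomogeneous Poisson
  process whose intensity is uniform over the daylight window and scaled
  by the fraction of florets currently open; moth visits likewise within
  the nocturnal window (default 22.00-03.00, wrapping midnight).
* A visit is instantaneous for pollination — at its start time it
  pollinates each currently open, receptive, not-yet-pollinated floret
  independently with probability ``p_pollinate`` — but extended for
  detection: its duration (exponential) governs how many camera frames
  capture it, and each captured frame becomes one visit annotation.
* A pollinated floret sets ``Binomial(2, q_seed)`` seeds (two ovules).

Early visits can only pollinate basal (early-opening) florets, so visit
timing causally determines the within-head seed pattern: the mechanism
behind the Visit Lateness Index -> Seed Lateness Index relationship.

A *null* switch decouples seeds from visits (each floret is pollinated
independently of any visit), for calibrating type-I error of the
downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainValueError
from .tables import FOCUSED_WINDOWS, REGIMES, REGIME_INTERVAL_MIN, TableBundle

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_season",
    "detection_probability",
    "paperlike_preset",
    "strong_effect_config",
    "null_config",
]

MIN_PER_DAY = 1440


@dataclass
class SimulationConfig:
    """All knobs of the season generator; defaults follow the field design.

    Rates are expected visits per inflorescence at full bloom — per day
    within the daylight window for ``bee_rate``/``other_rate``, per night
    within ``moth_window`` for ``moth_rate`` — and are scaled down by the
    fraction of florets currently open. Durations are exponential means
    in minutes. ``p_pollinate`` is the per-visit success probability for
    each open, receptive, unpollinated floret; ``q_seed`` the per-ovule
    seed probability given pollination. When ``null_pollination`` is set,
    visits still happen but every floret is instead pollinated
    independently with ``base_pollination_prob`` — seeds carry no signal
    about visitation.
    """

    n_cameras_focused: int = 9
    n_cameras_continuous: int = 6
    inflorescences_per_camera: float = 2.4
    season_start_doy: int = 174  # 23 June
    season_end_doy: int = 227  # 15 August
    year: int = 2021
    flowering_start_mean_doy: float = 188.0
    flowering_start_sd_days: float = 7.0
    florets_per_inflorescence_mean: float = 80.0
    florets_per_inflorescence_sd: float = 15.0
    opening_span_days: float = 6.0
    receptive_days: float = 8.0
    bee_rate: float = 0.9
    moth_rate: float = 0.055
    other_rate: float = 0.07
    moth_window: tuple[float, float] = (22.0, 3.0)  # clock hours, wraps midnight
    daylight_window: tuple[float, float] = (6.0, 21.0)
    bee_duration_mean: float = 0.5
    moth_duration_mean: float = 3.0
    cover_per_inflorescence: float = 0.05
    p_pollinate: float = 0.15
    q_seed: float = 0.45
    null_pollination: bool = False
    base_pollination_prob: float = 0.4
    #: shifts the visit-intensity envelope earlier by this many days
    #: (phenological mismatch between visitor activity and flowering)
    visit_shift_days: float = 0.0
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_cameras_focused + self.n_cameras_continuous < 1:
            raise ConfigurationError("need at least one camera")
        if self.season_end_doy < self.season_start_doy:
            raise ConfigurationError("season ends before it starts")
        for name in ("bee_rate", "moth_rate", "other_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("p_pollinate", "q_seed", "base_pollination_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.opening_span_days > self.receptive_days:
            raise ConfigurationError(
                "opening_span_days must not exceed receptive_days (the last "
                "floret must emerge before the first senesces)"
            )
        return self


@dataclass
class GroundTruth:
    """What really happened, for parameter-recovery tests.

    ``visits``: every true visit (detected or not) with its time,
    duration and detected frame count. ``florets``: per-floret opening
    time, pollination outcome and the pollinating visit. ``heads``:
    per-inflorescence true peak and true mean visit time.
    """

    visits: pd.DataFrame
    florets: pd.DataFrame
    heads: pd.DataFrame


@lru_cache(maxsize=8)
def _day_grids(season_days: int) -> dict:
    """Frame offsets (minutes from season start) per regime, cached."""
    grids = {}
    day0 = np.arange(0, season_days) * MIN_PER_DAY
    focused_day = np.sort(
        np.concatenate([np.arange(lo, hi + 1) for lo, hi in FOCUSED_WINDOWS])
    )
    grids["focused"] = (day0[:, None] + focused_day[None, :]).ravel().astype(np.int64)
    grids["continuous"] = np.arange(0, season_days * MIN_PER_DAY, 5, dtype=np.int64)
    return grids


def _window_minutes(window: tuple[float, float]) -> tuple[float, float]:
    """(start minute-of-day, length in minutes), handling midnight wrap."""
    lo, hi = (window[0] * 60.0, window[1] * 60.0)
    length = (hi - lo) % MIN_PER_DAY
    if length == 0:
        length = MIN_PER_DAY
    return lo, length


def _season_base_ns(cfg: SimulationConfig) -> int:
    base = pd.Timestamp(cfg.year, 1, 1) + pd.Timedelta(days=cfg.season_start_doy - 1)
    return base.value


def _minutes_to_timestamps(minutes: np.ndarray, cfg: SimulationConfig) -> pd.DatetimeIndex:
    ns = _season_base_ns(cfg) + (np.asarray(minutes, np.float64) * 60e9).astype(np.int64)
    # frames live on whole minutes; visit times are real-valued but frames
    # snap them, so flooring to the second keeps CSVs tidy
    ns -= ns % 1_000_000_000
    return pd.DatetimeIndex(ns.astype("datetime64[ns]"))


def simulate_season(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[TableBundle, GroundTruth]:
    """Generate one season: the five input tables plus ground truth.

    Reproducible: the same config and seed yield byte-identical tables.
    ``seed`` overrides ``config.rng_seed`` when given. The emitted bundle
    is valid by construction (it is not re-validated here; round-trip it
    through :func:`cloverwatch.tables.validate_bundle` to check).
    """
    cfg = (config or paperlike_preset()).validate()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    season_days = cfg.season_end_doy - cfg.season_start_doy + 1
    grids = _day_grids(season_days)

    cameras = [(f"F{i + 1:02d}", "focused") for i in range(cfg.n_cameras_focused)] + [
        (f"C{i + 1:02d}", "continuous") for i in range(cfg.n_cameras_continuous)
    ]

    # --- inflorescences -------------------------------------------------
    heads: list[dict] = []
    for cam_id, regime in cameras:
        for k in range(rng.poisson(cfg.inflorescences_per_camera)):
            start = rng.normal(cfg.flowering_start_mean_doy, cfg.flowering_start_sd_days)
            n_fl = max(10, int(round(rng.normal(
                cfg.florets_per_inflorescence_mean, cfg.florets_per_inflorescence_sd
            ))))
            heads.append(
                dict(inflorescence_id=f"{cam_id}-i{k + 1}", camera_id=cam_id,
                     regime=regime, flowering_start=start, n_florets=n_fl)
            )
    if not heads:
        # Poisson draw can empty a tiny design; keep the contract simple
        raise ConfigurationError("no inflorescences drawn; raise the camera count or density")

    day_lo, day_len = _window_minutes(cfg.daylight_window)
    moth_lo, moth_len = _window_minutes(cfg.moth_window)
    season_min = season_days * MIN_PER_DAY

    visit_rows: list[dict] = []
    floret_rows: list[dict] = []
    head_rows: list[dict] = []
    annot: list[dict] = []
    visit_id = 0

    for head in heads:
        start = head["flowering_start"]
        n_fl = head["n_florets"]
        open_doy = start + cfg.opening_span_days * np.arange(n_fl) / (n_fl - 1)
        senesce_doy = open_doy + cfg.receptive_days
        start_min = (start - cfg.season_start_doy) * MIN_PER_DAY

        def frac_open(t_min: np.ndarray) -> np.ndarray:
            t_doy = cfg.season_start_doy + np.asarray(t_min, float) / MIN_PER_DAY
            return (
                (open_doy[None, :] <= t_doy[:, None])
                & (t_doy[:, None] <= senesce_doy[None, :])
            ).mean(axis=1)

        # --- visits: thinned inhomogeneous Poisson ----------------------
        times, taxa, durs = [], [], []
        for taxon, rate, (wlo, wlen), dur_mean in (
            ("bumblebee", cfg.bee_rate, (day_lo, day_len), cfg.bee_duration_mean),
            ("other", cfg.other_rate, (day_lo, day_len), cfg.bee_duration_mean),
            ("moth", cfg.moth_rate, (moth_lo, moth_len), cfg.moth_duration_mean),
        ):
            n_cand = rng.poisson(rate * season_days)
            if n_cand == 0:
                continue
            day = rng.integers(0, season_days, n_cand)
            t = day * MIN_PER_DAY + wlo + rng.uniform(0, wlen, n_cand)
            # thinning against the (possibly time-shifted) bloom envelope
            keep = (
                rng.uniform(size=n_cand)
                < frac_open(t + cfg.visit_shift_days * MIN_PER_DAY)
            ) & (t < season_min)
            t = t[keep]
            times.append(t)
            taxa += [taxon] * len(t)
            durs.append(rng.exponential(dur_mean, len(t)))
        if times:
            t_all = np.concatenate(times)
            d_all = np.concatenate(durs)
            order = np.argsort(t_all)
            t_all, d_all = t_all[order], d_all[order]
            taxa = [taxa[i] for i in order]
        else:
            t_all = np.empty(0)
            d_all = np.empty(0)

        # --- pollination -------------------------------------------------
        pollinated = np.zeros(n_fl, bool)
        poll_doy = np.full(n_fl, np.nan)
        poll_visit = np.full(n_fl, -1)
        if cfg.null_pollination:
            pollinated = rng.uniform(size=n_fl) < cfg.base_pollination_prob
            poll_doy[pollinated] = open_doy[pollinated] + rng.uniform(
                0, cfg.receptive_days, int(pollinated.sum())
            )
        else:
            for vi, t in enumerate(t_all):
                t_doy = cfg.season_start_doy + t / MIN_PER_DAY
                eligible = (open_doy <= t_doy) & (t_doy <= senesce_doy) & ~pollinated
                hit = eligible & (rng.uniform(size=n_fl) < cfg.p_pollinate)
                pollinated |= hit
                poll_doy[hit] = t_doy
                poll_visit[hit] = visit_id + vi
        n_seeds = np.where(pollinated, rng.binomial(2, cfg.q_seed, n_fl), 0)

        # --- detection: frames inside [start, start + duration] ----------
        grid = grids[head["regime"]]
        lo = np.searchsorted(grid, t_all)
        hi = np.searchsorted(grid, t_all + d_all, side="right")
        for vi, t in enumerate(t_all):
            frames_in = grid[lo[vi]:hi[vi]]
            for fm in frames_in:
                annot.append(
                    dict(camera_id=head["camera_id"],
                         inflorescence_id=head["inflorescence_id"],
                         minute=int(fm), taxon=taxa[vi])
                )
            visit_rows.append(
                dict(visit_id=visit_id + vi,
                     inflorescence_id=head["inflorescence_id"], taxon=taxa[vi],
                     time_doy=cfg.season_start_doy + t / MIN_PER_DAY,
                     duration_min=d_all[vi], n_frames_detected=len(frames_in))
            )
        visit_id += len(t_all)

        for i in range(n_fl):
            floret_rows.append(
                dict(inflorescence_id=head["inflorescence_id"], floret_rank=i + 1,
                     open_doy=open_doy[i], pollinated=bool(pollinated[i]),
                     pollination_doy=poll_doy[i],
                     pollinating_visit_id=int(poll_visit[i]),
                     n_seeds=int(n_seeds[i]))
            )
        emerge_last = start + cfg.opening_span_days
        senesce_first = start + cfg.receptive_days
        flower_end = start + cfg.opening_span_days + cfg.receptive_days
        head_rows.append(
            dict(inflorescence_id=head["inflorescence_id"], camera_id=head["camera_id"],
                 flowering_start=start, n_florets=n_fl,
                 true_peak_doy=0.5 * (emerge_last + senesce_first),
                 true_mean_visit_doy=(
                     cfg.season_start_doy + t_all.mean() / MIN_PER_DAY
                     if len(t_all) else np.nan
                 ),
                 n_true_visits=len(t_all),
                 fully_recorded=bool(
                     start >= cfg.season_start_doy and flower_end <= cfg.season_end_doy + 1
                 ),
                 doy_last_floret_emerged=emerge_last,
                 doy_first_floret_senesced=senesce_first)
        )

    truth_heads = pd.DataFrame(head_rows)

    # --- emit the five tables -------------------------------------------
    frames = pd.concat(
        [
            pd.DataFrame(
                {"camera_id": cam, "timestamp": _minutes_to_timestamps(grids[reg], cfg),
                 "regime": reg}
            )
            for cam, reg in cameras
        ],
        ignore_index=True,
    )

    annot_df = pd.DataFrame(annot, columns=["camera_id", "inflorescence_id", "minute", "taxon"])
    annot_df = annot_df.sort_values(["minute", "inflorescence_id", "taxon"], ignore_index=True)
    visits = pd.DataFrame(
        {
            "camera_id": annot_df["camera_id"],
            "inflorescence_id": annot_df["inflorescence_id"],
            "timestamp": _minutes_to_timestamps(annot_df["minute"].to_numpy(np.int64), cfg)
            if len(annot_df)
            else pd.DatetimeIndex([]),
            "taxon": annot_df["taxon"],
        }
    )

    lo_doy, hi_doy = float(cfg.season_start_doy), float(cfg.season_end_doy)
    phenology = pd.DataFrame(
        {
            "inflorescence_id": truth_heads["inflorescence_id"],
            "camera_id": truth_heads["camera_id"],
            "doy_last_floret_emerged": truth_heads["doy_last_floret_emerged"].clip(lo_doy, hi_doy + 1),
            "doy_first_floret_senesced": truth_heads["doy_first_floret_senesced"].clip(lo_doy, hi_doy + 1),
            "fully_recorded": truth_heads["fully_recorded"],
        }
    )

    florets = pd.DataFrame(floret_rows)
    dissection = pd.DataFrame(
        {
            "inflorescence_id": florets["inflorescence_id"],
            "floret_rank": florets["floret_rank"],
            "n_florets": florets.groupby("inflorescence_id")["floret_rank"].transform("max"),
            "percentile": np.nan,  # filled from rank by table validation
            "n_seeds": florets["n_seeds"],
        }
    )
    nf = dissection["n_florets"].to_numpy(float)
    rk = dissection["floret_rank"].to_numpy(float)
    dissection["percentile"] = np.where(nf > 1, 100.0 * (rk - 1) / np.maximum(nf - 1, 1), 50.0)

    # midday floral cover per camera-day, proportional to open florets
    cover_rows = []
    open_by_cam: dict[str, list[tuple[float, float]]] = {}
    for head in heads:
        open_by_cam.setdefault(head["camera_id"], []).append(
            (head["flowering_start"], head["n_florets"])
        )
    for cam_id, regime in cameras:
        for d in range(season_days):
            doy = cfg.season_start_doy + d
            midday = doy + 0.5
            total = 0.0
            for start, n_fl in open_by_cam.get(cam_id, []):
                op = start + cfg.opening_span_days * np.arange(n_fl) / (n_fl - 1)
                total += ((op <= midday) & (midday <= op + cfg.receptive_days)).mean()
            cover_rows.append(
                dict(camera_id=cam_id, doy=float(doy),
                     cover=min(1.0, total * cfg.cover_per_inflorescence))
            )
    cover = pd.DataFrame(cover_rows)

    bundle = TableBundle(frames=frames, visits=visits, phenology=phenology,
                         dissection=dissection, cover=cover)
    truth = GroundTruth(
        visits=pd.DataFrame(
            visit_rows,
            columns=["visit_id", "inflorescence_id", "taxon", "time_doy",
                     "duration_min", "n_frames_detected"],
        ),
        florets=florets,
        heads=truth_heads,
    )
    return bundle, truth


def detection_probability(
    duration_min: float,
    regime: str,
    start_minute_of_day: float | None = None,
    within_windows: bool = False,
    grid_step: float = 0.01,
) -> float:
    """Probability that a visit of given duration is captured by >= 1 frame.

    A visit starting at clock time ``t`` (uniform over the day unless
    ``start_minute_of_day`` fixes it, or ``within_windows`` restricts it
    to the focused regime's active windows) is detected iff the closed
    interval [t, t + duration] contains a frame time. For the continuous
    regime this is min(1, duration/5); for the focused regime the frame
    grid exists only inside the two diel windows, so short visits outside
    them are never detected while visits straddling a window boundary
    pick up extra boundary mass.
    """
    if duration_min < 0:
        raise DomainValueError("duration must be >= 0")
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}")
    interval = REGIME_INTERVAL_MIN[regime]
    ndays = int(duration_min // MIN_PER_DAY) + 2
    if regime == "continuous":
        grid = np.arange(0, MIN_PER_DAY * ndays, interval, dtype=float)
    else:
        day_grid = np.sort(
            np.concatenate([np.arange(lo, hi + 1) for lo, hi in FOCUSED_WINDOWS])
        ).astype(float)
        grid = np.concatenate([day_grid + MIN_PER_DAY * k for k in range(ndays)])
    if start_minute_of_day is not None:
        s = np.asarray([float(start_minute_of_day) % MIN_PER_DAY])
    else:
        # midpoint sampling: no start coincides with a frame instant
        s = np.arange(0.0, MIN_PER_DAY, grid_step) + grid_step / 2
        if within_windows and regime == "focused":
            mask = np.zeros(len(s), bool)
            for lo, hi in FOCUSED_WINDOWS:
                mask |= (s >= lo) & (s <= hi)
            s = s[mask]
    nxt = np.searchsorted(grid, s)
    detected = grid[np.minimum(nxt, len(grid) - 1)] <= s + duration_min
    detected &= nxt < len(grid)
    return float(detected.mean())


def paperlike_preset() -> SimulationConfig:
    """Default season matching the field study's coarse magnitudes.

    15 cameras (9 focused, 6 continuous) at mean 2.4 inflorescences each
    (~36 heads), a 23 June - 15 August season, and visit rates and
    durations calibrated so that, in expectation, about two thirds of
    heads are seen visited, moths provide about a third of visit images,
    and mean seed set sits near 0.26.
    """
    return SimulationConfig()


def strong_effect_config() -> SimulationConfig:
    """A sparse-visit, high-efficiency season where visits dominate seed set.

    Visits are rare enough that heads differ sharply in true visit count,
    each visit pollinates over half the receptive florets, and durations
    are long enough for cameras to detect a good share of visits — the
    regime in which the downstream visitation tests have real power.
    """
    return replace(
        paperlike_preset(),
        bee_rate=0.10,
        other_rate=0.02,
        moth_rate=0.06,
        bee_duration_mean=4.0,
        moth_duration_mean=6.0,
        p_pollinate=0.8,
        q_seed=0.4,
    )


def null_config() -> SimulationConfig:
    """Strong-effect visitation, but seeds independent of visits."""
    return replace(strong_effect_config(), null_pollination=True,
                   base_pollination_prob=0.4)
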