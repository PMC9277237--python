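from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cloverwatch import (
    ConfigurationError,
    detection_probability,
    paperlike_preset,
    simulate_season,
    validate_bundle,
    write_tables,
)
from cloverwatch.errors import DomainValueError
from cloverwatch.pipeline import build_index_table
from conftest import small_config


class TestDeterminismAndValidity:
    def test_same_seed_gives_byte_identical_csvs(self, tmp_path):
        for run in ("a", "b"):
            bundle, _ = simulate_season(small_config(), seed=3)
            write_tables(bundle, tmp_path / run)
        for name in ("frames", "visits", "phenology", "dissection", "cover"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
                tmp_path / "b" / f"{name}.csv"
            ).read_bytes()

    def test_different_seeds_differ(self):
        b1, _ = simulate_season(small_config(), seed=1)
        b2, _ = simulate_season(small_config(), seed=2)
        assert not b1.visits.equals(b2.visits)

    def test_emitted_bundle_passes_full_validation(self, small_season):
        bundle, _ = small_season
        validate_bundle(bundle)  # must not raise

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(n_cameras_focused=0, n_cameras_continuous=0).validate()
        with pytest.raises(ConfigurationError):
            small_config(p_pollinate=1.5).validate()
        with pytest.raises(ConfigurationError):
            small_config(opening_span_days=10.0, receptive_days=5.0).validate()


class TestMechanism:
    def test_no_pollination_no_seeds(self):
        bundle, truth = simulate_season(small_config(p_pollinate=0.0), seed=4)
        assert (bundle.dissection["n_seeds"] == 0).all()
        assert not truth.florets["pollinated"].any()

    def test_no_moths_no_moth_annotations(self):
        bundle, _ = simulate_season(small_config(moth_rate=0.0), seed=4)
        assert not (bundle.visits["taxon"] == "moth").any()

    def test_seed_conservation(self, small_season):
        bundle, truth = small_season
        assert bundle.dissection["n_seeds"].sum() == truth.florets["n_seeds"].sum()

    def test_causal_ordering_pollination_inside_receptivity(self, small_season):
        _, truth = small_season
        poll = truth.florets[truth.florets["pollinated"]]
        cfg = small_config()
        assert (poll["pollination_doy"] >= poll["open_doy"] - 1e-9).all()
        assert (
            poll["pollination_doy"] <= poll["open_doy"] + cfg.receptive_days + 1e-9
        ).all()

    def test_pollinating_visit_time_matches_pollination_time(self, small_season):
        _, truth = small_season
        poll = truth.florets.query("pollinated and pollinating_visit_id >= 0")
        vtimes = truth.visits.set_index("visit_id")["time_doy"]
        linked = vtimes.reindex(poll["pollinating_visit_id"]).to_numpy()
        assert np.allclose(linked, poll["pollination_doy"].to_numpy())

    def test_moth_annotations_confined_to_nocturnal_window(self, small_season):
        bundle, _ = small_season
        moth = bundle.visits[bundle.visits["taxon"] == "moth"]
        mod = pd.DatetimeIndex(moth["timestamp"])
        minutes = mod.hour * 60 + mod.minute
        in_window = (minutes >= 22 * 60) | (minutes <= 3 * 60 + 10)
        assert in_window.mean() > 0.95

    def test_vli_recovers_true_visit_timing_under_dense_sampling(self):
        # all-continuous cameras, dense visitation, every visit captured:
        # emitted VLI is an unbiased reading of true visit lateness, so
        # regressing VLI on (true mean visit time - true peak) gives ~1.
        # (The reverse regression attenuates: VLI image-weights visits by
        # their frame counts, which adds error-in-variables noise.)
        cfg = small_config(
            n_cameras_focused=0, n_cameras_continuous=5,
            bee_rate=4.0, moth_rate=1.5,
            bee_duration_mean=12.0, moth_duration_mean=12.0,
        )
        rows = []
        for seed in range(6):
            bundle, truth = simulate_season(cfg, seed=seed)
            idx = build_index_table(bundle)
            truth_h = truth.heads.set_index("inflorescence_id")
            sub = idx[idx["vli"].notna()]
            true_lateness = (
                truth_h.loc[sub.index, "true_mean_visit_doy"]
                - truth_h.loc[sub.index, "true_peak_doy"]
            )
            rows.append(pd.DataFrame({"vli": sub["vli"], "true": true_lateness}))
        df = pd.concat(rows).dropna()
        slope = np.polyfit(df["true"], df["vli"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.2)

    def test_earlier_visits_lower_vli_and_sli(self):
        # shifting the visit-intensity envelope 2 days earlier must lower
        # both the mean VLI and the mean SLI across replicate seasons
        base_v, base_s, shift_v, shift_s = [], [], [], []
        for seed in range(12):
            for shift, accv, accs in (
                (0.0, base_v, base_s), (2.0, shift_v, shift_s)
            ):
                cfg = small_config(visit_shift_days=shift, p_pollinate=0.5)
                idx = build_index_table(simulate_season(cfg, seed=seed)[0])
                accv.append(idx["vli"].mean())
                accs.append(idx["sli"].mean())
        assert np.nanmean(shift_v) < np.nanmean(base_v)
        assert np.nanmean(shift_s) < np.nanmean(base_s)


class TestDetectionProbability:
    def test_duration_equal_to_interval_always_detected(self):
        assert detection_probability(5.0, "continuous") == pytest.approx(1.0, abs=1e-3)

    def test_continuous_short_visit_matches_duration_over_interval(self):
        assert detection_probability(2.0, "continuous") == pytest.approx(0.4, abs=1e-3)

    def test_focused_short_visit_within_windows(self):
        p = detection_probability(0.2, "focused", within_windows=True)
        assert p == pytest.approx(0.2, abs=0.01)

    def test_visit_outside_focused_windows_never_detected(self):
        assert detection_probability(10.0, "focused", start_minute_of_day=990.0) == 0.0

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        duration = 0.7
        starts = rng.uniform(0, 1440, 100_000)
        # oracle: frame grid of the continuous regime, one day padding
        grid = np.arange(0, 2 * 1440, 5.0)
        nxt = np.searchsorted(grid, starts)
        hit = grid[nxt] <= starts + duration
        assert detection_probability(duration, "continuous") == pytest.approx(
            hit.mean(), abs=0.01
        )

    def test_negative_duration_rejected(self):
        with pytest.raises(DomainValueError):
            detection_probability(-1.0, "continuous")


class TestPreset:
    def test_preset_magnitudes(self):
        cfg = paperlike_preset()
        assert cfg.n_cameras_focused + cfg.n_cameras_continuous == 15
        assert cfg.inflorescences_per_camera == pytest.approx(2.4)
        bundle, _ = simulate_season(cfg, seed=0)
        assert 20 <= len(bundle.phenology) <= 55

    def test_preset_without_moths_has_zero_moth_share(self):
        cfg = replace(paperlike_preset(), moth_rate=0.0)
        bundle, _ = simulate_season(cfg, seed=0)
        assert not (bundle.visits["taxon"] == "moth").any()
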