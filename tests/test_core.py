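"""The interleaved expanding-interval scan and its variants."""

import numpy as np
import pytest

import isodetect as iso
from isodetect.contrasts import InvalidIntervalError
from isodetect.core import Direction


class TestExpansionPoints:
    def test_full_interval_schedule(self):
        grid = iso.ExpansionGrid(100, 10)
        right, left = iso.expansion_points(1, 100, grid)
        assert right == [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        assert left == [91, 81, 71, 61, 51, 41, 31, 21, 11, 1]

    def test_shrunk_interval_keeps_global_anchors(self):
        # after a detection at start-point 71, anchors are NOT recomputed
        grid = iso.ExpansionGrid(100, 10)
        right, left = iso.expansion_points(1, 71, grid)
        assert right == [10, 20, 30, 40, 50, 60, 70, 71]
        assert left == [61, 51, 41, 31, 21, 11, 1]

    def test_large_step_gives_single_full_interval(self):
        grid = iso.ExpansionGrid(50, 200)
        assert iso.expansion_points(1, 50, grid) == ([50], [1])

    def test_invalid_interval_rejected(self):
        with pytest.raises(InvalidIntervalError):
            iso.expansion_points(10, 10, iso.ExpansionGrid(100, 10))


class TestIsolateDetect:
    def test_constant_series_yields_nothing(self):
        cfg = iso.DetectionConfig(model=iso.CONST, lam=5, threshold=1.0)
        assert iso.isolate_detect(np.full(200, 2.5), cfg=cfg) == []

    def test_two_step_example_detection_schedule(self, two_step_signal):
        """First detection in a left interval starting at 71, second in a
        right interval ending at 40, recovering {38, 77} exactly."""
        f, truth = two_step_signal
        stats = iso.ScanStats()
        cfg = iso.DetectionConfig(model=iso.CONST, lam=10, threshold=1.0)
        out = iso.isolate_detect(f, 1, 100, cfg, stats=stats)
        assert out == truth
        first, second = stats.detections
        assert first.direction is Direction.LEFT and first.interval == (71, 100)
        assert first.b == 77
        assert second.direction is Direction.RIGHT and second.interval == (1, 40)
        assert second.b == 38

    def test_wave_kinks_recovered_exactly(self, wave_signal):
        f, truth = wave_signal
        cfg = iso.DetectionConfig(model=iso.LINEAR, lam=3, threshold=1.0)
        assert iso.isolate_detect(f, cfg=cfg) == truth

    @pytest.mark.parametrize("restart", list(iso.RestartMode))
    def test_restart_modes_recover_noiseless_steps(self, two_step_signal, restart):
        f, truth = two_step_signal
        cfg = iso.DetectionConfig(model=iso.CONST, lam=10, threshold=1.0,
                                  restart_mode=restart)
        assert iso.isolate_detect(f, cfg=cfg) == truth

    def test_short_series_returns_empty(self):
        cfg = iso.DetectionConfig(model=iso.LINEAR, lam=3, threshold=1.0)
        assert iso.isolate_detect(np.array([1.0, 2.0, 1.0]), cfg=cfg) == []

    def test_raising_threshold_never_adds_detections(self, two_step_signal):
        f, _ = two_step_signal
        prev = None
        for zeta in (0.5, 1.0, 2.0, 4.0, 8.0):
            cfg = iso.DetectionConfig(model=iso.CONST, lam=10, threshold=zeta)
            got = set(iso.isolate_detect(f, cfg=cfg))
            if prev is not None:
                assert got <= prev
            prev = got

    def test_deterministic(self, rng):
        x = rng.normal(size=500) + np.r_[np.zeros(250), 3 * np.ones(250)]
        cfg = iso.DetectionConfig(model=iso.CONST, lam=3, threshold=3.0)
        assert iso.isolate_detect(x, cfg=cfg) == iso.isolate_detect(x, cfg=cfg)

    def test_isolation_of_detection_intervals(self, rng):
        """In endpoint mode every triggering interval excludes previously
        detected change-points at the moment of its detection."""
        f = np.repeat([0, 4, 0, 4, 0, 4.0], 60)
        x = f + 0.3 * rng.normal(size=f.size)
        stats = iso.ScanStats()
        cfg = iso.DetectionConfig(model=iso.CONST, lam=7, threshold=3.0)
        iso.isolate_detect(x, cfg=cfg, stats=stats)
        seen = []
        for d in stats.detections:
            lo, hi = d.interval
            assert not any(lo <= b < hi for b in seen)
            seen.append(d.b)

    def test_interval_budget_on_pure_noise(self, rng):
        for T, lam in [(300, 3), (1000, 10), (777, 7)]:
            x = rng.normal(size=T)
            stats = iso.ScanStats()
            cfg = iso.DetectionConfig(model=iso.CONST, lam=lam, threshold=50.0)
            iso.isolate_detect(x, cfg=cfg, stats=stats)
            assert stats.intervals_examined <= 2 * int(np.ceil(T / lam))


class TestWindowedVariant:
    def test_matches_plain_scan_below_length_cutoff(self, rng):
        f = np.repeat([0, 3, 0, 3, 0.0], 1000)
        x = f + rng.normal(size=5000)
        cfg = iso.DetectionConfig(model=iso.CONST, lam=3,
                                  threshold=iso.default_threshold(5000, iso.CONST))
        assert iso.id_windowed(x, cfg) == iso.isolate_detect(x, cfg=cfg)

    def test_default_window_parameters(self):
        cfg = iso.DetectionConfig()
        assert cfg.window_len == 3000
        assert cfg.window_threshold_T == 12000

    def test_long_teeth_signal_recovered_exactly(self):
        """Noiseless level change every 7 points over T=70000, scanned in
        windows, including changes falling exactly on window boundaries."""
        f, truth = iso.gen_signal(iso.preset("t1_j4"))
        cfg = iso.DetectionConfig(
            model=iso.CONST, lam=3,
            threshold=iso.default_threshold(70000, iso.CONST),
            restart_mode=iso.RestartMode.AT_ESTIMATE)
        found = iso.id_windowed(f / 0.5, cfg)
        assert found == truth
        assert {21000, 42000, 63000} <= set(found)  # exact window-edge changes


def test_scan_family_max_bounded_by_interval_maximum(rng):
    x = rng.normal(size=100)
    m = iso.scan_family_max(x, lam=5)
    # the family includes the full interval, so the max is at least that
    _, full = iso.argmax_contrast(x, 1, 100, iso.CONST)
    assert m >= full
    # and never exceeds the exhaustive maximum over all (s, e, b)
    best = max(iso.argmax_contrast(x, s, e, iso.CONST)[1]
               for s in range(1, 100) for e in range(s + 1, 101))
    assert m <= best + 1e-12
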