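"""Stopping rules: triplet pruning, solution path, sSIC, hybrid."""

import numpy as np
import pytest

import isodetect as iso
from isodetect.selection import (
    LOWERED_CONSTANT,
    THRESHOLD_CONSTANT,
    HYBRID_J_STAR,
    HYBRID_LAMBDA_SSIC,
    HYBRID_LAMBDA_THRESHOLD,
)


def test_calibrated_threshold_constants():
    assert THRESHOLD_CONSTANT[iso.ModelKind.CONST] == 1.05
    assert THRESHOLD_CONSTANT[iso.ModelKind.LINEAR] == 1.4
    assert LOWERED_CONSTANT[iso.ModelKind.CONST] == 0.9
    assert LOWERED_CONSTANT[iso.ModelKind.LINEAR] == 1.25
    for model in (iso.CONST, iso.LINEAR):
        assert iso.default_threshold(2000, model, lowered=True) < \
            iso.default_threshold(2000, model)
        assert iso.default_threshold(4000, model) > iso.default_threshold(2000, model)


class TestTripletScore:
    def test_single_step_closed_form(self):
        x = np.r_[np.zeros(40), 2.0 * np.ones(30), np.zeros(30)]
        left, mid, right = 20, 40, 60
        expected = 2.0 * np.sqrt((mid - left + 1) * (right - mid) / (right - left + 1))
        assert iso.triplet_score(x, left, mid, right, iso.CONST) == \
            pytest.approx(expected)

    def test_non_change_scores_zero_on_noiseless_data(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        assert iso.triplet_score(x, 10, 25, 40, iso.CONST) == pytest.approx(0.0)

    def test_delegates_to_contrast(self, rng):
        x = rng.normal(size=80)
        assert iso.triplet_score(x, 10, 30, 70, iso.CONST) == \
            pytest.approx(iso.cusum_contrast(x, 10, 70, 30))
        assert iso.triplet_score(x, 10, 30, 70, iso.LINEAR) == \
            pytest.approx(iso.linear_contrast(x, 10, 70, 30))

    def test_inadmissible_mid_scores_zero(self):
        x = np.arange(20, dtype=float)
        assert iso.triplet_score(x, 5, 6, 7, iso.LINEAR) == 0.0


class TestSolutionPath:
    def test_single_candidate(self, rng):
        p = iso.build_solution_path(rng.normal(size=50), [20], iso.CONST)
        assert p.b == [20]

    def test_spurious_candidate_removed_first(self):
        x = np.r_[np.zeros(30), np.ones(30), np.zeros(40)]
        p = iso.build_solution_path(x, [30, 45, 60], iso.CONST)
        assert p.b[-1] == 45  # weakest, removed first
        assert set(p.b[:2]) == {30, 60}
        assert p.model_at(2) == [30, 60]

    def test_equal_scores_removed_smallest_index_first(self):
        x = np.zeros(100)  # all contrasts zero -> pure tie-breaking
        p = iso.build_solution_path(x, [20, 40, 60], iso.CONST)
        assert p.b == [60, 40, 20]  # 20 removed first, then 40, then 60

    def test_rss_non_increasing_along_nested_models(self, rng):
        f = np.repeat([0, 2, -1, 3.0], 50)
        x = f + rng.normal(size=200)
        res = iso.id_ssic(x, iso.CONST)
        path = res.solution_path
        rss = [iso.fit_signal(x, path.model_at(j), iso.CONST).rss
               for j in range(len(path) + 1)]
        assert all(rss[j + 1] <= rss[j] + 1e-9 for j in range(len(rss) - 1))


class TestSSIC:
    def test_zero_changepoint_formula(self, rng):
        x = rng.normal(size=200)
        x = x - x.mean()
        cfg = iso.SSICConfig()
        got = iso.ssic(x, [], iso.CONST, cfg)
        expected = 200 * np.log((x ** 2).sum() / 200) + np.log(200) ** cfg.alpha
        assert got == pytest.approx(expected)

    def test_parameter_counts_by_model(self):
        from isodetect.selection import _n_params
        free = iso.SSICConfig(count_locations_as_params=False)
        assert _n_params(3, iso.CONST, free) == 4
        assert _n_params(3, iso.LINEAR, free) == 5
        counted = iso.SSICConfig(count_locations_as_params=True)
        assert _n_params(3, iso.CONST, counted) == 7
        assert _n_params(3, iso.LINEAR, counted) == 8

    def test_true_model_minimizes_on_noiseless_data(self):
        x = np.r_[np.zeros(40), 2.0 * np.ones(40), np.zeros(40)]
        path = iso.build_solution_path(x, [40, 60, 80], iso.CONST)
        vals = [iso.ssic(x, path.model_at(j), iso.CONST) for j in range(4)]
        assert int(np.argmin(vals)) == 2
        assert path.model_at(2) == [40, 80]

    def test_selection_invariant_to_level_and_trend_shifts(self, rng):
        f = np.repeat([0, 2.0, 0.5], 60)
        x = f + rng.normal(size=180)
        base = iso.id_ssic(x, iso.CONST).changepoints
        assert iso.id_ssic(x + 37.0, iso.CONST).changepoints == base
        fw, _ = iso.gen_signal(iso.preset("wave"))
        xw = fw + rng.normal(size=fw.size)
        t = np.arange(1, fw.size + 1)
        basew = iso.id_ssic(xw, iso.LINEAR).changepoints
        assert iso.id_ssic(xw + 5 - 0.3 * t, iso.LINEAR).changepoints == basew

    def test_result_rss_and_trace_are_reproducible(self, rng):
        x = np.repeat([0, 3.0], 100) + rng.normal(size=200)
        res = iso.id_ssic(x, iso.CONST)
        refit = iso.fit_signal(x, res.changepoints, iso.CONST)
        assert res.rss == pytest.approx(refit.rss)
        assert res.ssic_trace[res.selected_j] == \
            pytest.approx(iso.ssic(x, res.changepoints, iso.CONST))

    def test_alpha_must_exceed_one(self):
        with pytest.raises(ValueError):
            iso.SSICConfig(alpha=1.0)


class TestIdSsic:
    def test_noiseless_two_steps_exact(self):
        x = np.r_[np.zeros(40), np.ones(40), np.zeros(40)]
        assert iso.id_ssic(x, iso.CONST).changepoints == [40, 80]

    def test_noiseless_wave_exact(self, wave_signal):
        f, truth = wave_signal
        assert iso.id_ssic(f, iso.LINEAR).changepoints == truth

    def test_mostly_silent_on_pure_noise(self):
        """Across seeded N(0,1) replicates the sSIC rule reports no
        change-points in the overwhelming majority."""
        zeros = 0
        for ss in np.random.SeedSequence(77).spawn(25):
            z = np.random.default_rng(ss).standard_normal(1000)
            zeros += iso.id_ssic(z, iso.CONST).n_changepoints == 0
        assert zeros >= 23


class TestHybrid:
    def test_default_parameters(self):
        assert HYBRID_LAMBDA_THRESHOLD == 3
        assert HYBRID_J_STAR == 100
        assert HYBRID_LAMBDA_SSIC == 10

    def test_noise_goes_through_ssic_stage(self, rng):
        res = iso.id_hybrid(rng.standard_normal(1500), iso.CONST)
        assert res.method == "ssic"
        assert res.n_changepoints <= 2

    def test_frequent_changes_accepted_at_threshold_stage(self):
        f, truth = iso.gen_signal(iso.preset("t1_j3"))
        res = iso.id_hybrid(f / 0.5, iso.CONST)  # noiseless, unit-noise scale
        assert res.method == "threshold"
        assert res.changepoints == truth
        assert res.n_changepoints == 999
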