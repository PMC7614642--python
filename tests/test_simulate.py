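import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from eventreact.context_bow import build_bow, jsd_similarity
from eventreact.events_io import apply_scene_exclusions
from eventreact.reactivation import boundary_scene_similarity, reactivation_index
from eventreact.representations import extract_boundary_reps, extract_scene_reps
from eventreact.simulate import (
    RunningLineFilter,
    SimulationConfig,
    SpectralHighpass,
    _SuiteEngine,
    gen_one_over_f,
    gen_scene_texts,
    gen_scene_timings,
    highpass_filter,
    inject_scene_patterns,
    null_bias_suite,
    plant_reactivation,
    scene_timings_fitting,
)

from conftest import make_run


class TestOneOverF:
    def test_power_slope_near_minus_one(self):
        x = gen_one_over_f(2048, 100, seed=0)
        spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
        f = np.fft.rfftfreq(2048)
        band = (f > 0.01) & (f < 0.3)
        slope = np.polyfit(np.log(f[band]), np.log(spec[band].mean(axis=1)), 1)[0]
        assert abs(slope + 1) < 0.15

    def test_seed_determinism_and_normalisation(self):
        a = gen_one_over_f(256, 5, seed=42)
        b = gen_one_over_f(256, 5, seed=42)
        assert np.array_equal(a, b)
        assert np.allclose(a.mean(axis=0), 0, atol=1e-12)  # DC removed
        assert np.allclose(a.std(axis=0), 1, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            gen_one_over_f(8, 2, seed=0)


class TestHighpass:
    def test_constant_series_goes_to_zero(self):
        x = np.full((300, 2), 7.0)
        for kind in ("spectral", "running_line"):
            assert np.allclose(highpass_filter(x, 1.5, 120.0, kind=kind), 0, atol=1e-8)

    def test_linear_ramp_mostly_removed(self):
        t = np.arange(400, dtype=float)
        ramp = (t - t.mean())[:, None]
        for kind, tol in (("running_line", 1e-8), ("spectral", 0.05)):
            out = highpass_filter(ramp, 1.5, 120.0, kind=kind)
            assert np.sqrt((out**2).mean()) < tol * np.sqrt((ramp**2).mean()) + 1e-12

    def test_filtered_white_noise_lag1_autocov_negative(self, rng):
        x = rng.standard_normal((200, 1000))
        out = highpass_filter(x, 1.5, 60.0)
        lag1 = np.mean(np.sum(out[:-1] * out[1:], axis=0) / (out.shape[0] - 1))
        assert lag1 < 0

    def test_running_line_matches_ndimage_reference(self, rng):
        # independent implementation of the Gaussian-weighted local line fit
        x = rng.standard_normal((150, 3))
        sigma = 90.0 / (2 * 1.5)
        t = np.arange(150, dtype=float)
        S = lambda f, ax=-1: gaussian_filter1d(f, sigma, axis=ax, mode="constant")
        W, Wx, Wxx = S(np.ones(150)), S(t), S(t * t)
        Wy, Wxy = S(x, 0), S(x * t[:, None], 0)
        denom = Wxx * W - Wx * Wx
        b = (Wxy * W[:, None] - Wx[:, None] * Wy) / denom[:, None]
        a = (Wy - b * Wx[:, None]) / W[:, None]
        want = x - (a + b * t[:, None])
        got = highpass_filter(x, 1.5, 90.0, kind="running_line")
        assert np.allclose(got, want, atol=1e-9)

    def test_plans_validate_length(self):
        filt = SpectralHighpass(100, 1.5, 60.0)
        with pytest.raises(ValueError):
            filt.apply(np.zeros((99, 2)))
        with pytest.raises(ValueError):
            RunningLineFilter(100, 1.5, 2.0)


class TestSceneTimings:
    def test_year21_labels_and_gaps(self):
        table = gen_scene_timings("year21_like", 45, seed=0)
        labs = list(table.narratives())
        assert labs[:4] == ["A", "B", "A", "B"]
        assert set(labs[30:]) == {"JOINT"}
        gaps = [
            b.onset_tr - a.offset_tr - 1 for a, b in zip(table.scenes, table.scenes[1:])
        ]
        assert set(gaps) <= {3, 4}
        lens = np.array([s.length_trs for s in table]) * 1.5
        assert lens.min() >= 60 - 1.5 and lens.max() <= 84 + 1.5

    def test_sherlock_contiguous(self):
        table = gen_scene_timings("sherlock_like", 48, seed=1)
        gaps = [
            b.onset_tr - a.offset_tr - 1 for a, b in zip(table.scenes, table.scenes[1:])
        ]
        assert set(gaps) == {0}

    def test_sherlock_median_length_targets_printed_value(self):
        rng = np.random.default_rng(5)
        lens = []
        for _ in range(25):  # 25 x 48 = 1200 scene draws
            t = gen_scene_timings("sherlock_like", 48, seed=rng)
            lens += [s.length_trs * 1.5 for s in t]
        assert 40 <= np.median(lens) <= 65
        assert min(lens) >= 12 - 1.5 and max(lens) <= 184.5 + 1.5

    def test_overrun_is_error(self):
        with pytest.raises(ValueError, match="beyond"):
            gen_scene_timings("sherlock_like", 48, seed=0, n_trs=500)

    def test_fitting_respects_config_and_exclusions(self):
        cfg = SimulationConfig.sherlock_like()
        table = scene_timings_fitting(cfg, np.random.default_rng(3))
        assert table.max_offset_tr + cfg.hrf_shift_trs + cfg.control_offset_trs <= cfg.n_trs
        assert table.scenes[-1].excluded  # last scene dropped
        assert all(s.length_trs >= 10 for s in table.included)


class TestInjectAndPlant:
    def test_weight_zero_is_identity(self, rng):
        table = gen_scene_timings("sherlock_like", 10, seed=0)
        data = rng.standard_normal((table.max_offset_tr + 10, 20))
        assert np.array_equal(
            inject_scene_patterns(data, table, "uniform", 0.0, seed=1), data
        )
        assert np.array_equal(
            plant_reactivation(data, table, weight=0.0, seed=1), data
        )

    def test_injection_is_constant_within_scene(self, rng):
        table = gen_scene_timings("sherlock_like", 10, seed=0)
        data = rng.standard_normal((table.max_offset_tr + 10, 20))
        out = inject_scene_patterns(data, table, "uniform", 1.0, seed=1)
        diff = out - data
        s = table.scenes[2]
        rows = diff[s.onset_tr - 1 : s.offset_tr]
        assert np.allclose(rows, rows[0])
        assert not np.allclose(rows[0], 0)

    def test_congruency_templates_raise_congruent_similarity(self, rng):
        table = gen_scene_timings("year21_like", 45, seed=2)
        data = rng.standard_normal((table.max_offset_tr + 10, 40))
        out = inject_scene_patterns(data, table, "congruency_templates", 2.0, seed=3)
        run = make_run(out.shape[0], out.shape[1], data=out)
        S = extract_scene_reps(run, table, gap_trs=5, hrf_shift_trs=4)
        r = np.corrcoef(S)
        labels = table.narratives()
        cong = (labels[:, None] == labels[None, :]) & ~np.eye(45, dtype=bool)
        incong = (labels[:, None] != labels[None, :])
        first30 = np.zeros((45, 45), bool)
        first30[:30, :30] = True
        assert r[cong & first30].mean() > r[incong & first30].mean()

    def test_plant_touches_only_boundary_rows(self, rng):
        table = gen_scene_timings("sherlock_like", 10, seed=0)
        data = rng.standard_normal((table.max_offset_tr + 10, 20))
        out = plant_reactivation(
            data, table, target_rule="fixed_lag", weight=1.0, lag=3, seed=1
        )
        changed = np.nonzero(np.any(out != data, axis=1))[0] + 1  # 1-based TRs
        boundary_rows = {
            s.boundary_tr + 4 for s in table.included if s.index > 3
        }
        assert set(changed) <= boundary_rows

    def test_planted_boundary_correlates_with_target_scene(self, rng):
        table = gen_scene_timings("sherlock_like", 12, seed=4)
        data = rng.standard_normal((table.max_offset_tr + 10, 60))
        out = plant_reactivation(data, table, weight=3.0, lag=3, seed=2)
        run = make_run(out.shape[0], out.shape[1], data=out)
        B = extract_boundary_reps(run, table)
        S = extract_scene_reps(run, table)
        idx = np.array([s.index for s in table.included])
        sim = boundary_scene_similarity(B, S, boundary_scene_index=idx, scene_index=idx)
        planted = [
            sim.z[i, j]
            for i, bi in enumerate(idx)
            for j, sj in enumerate(idx)
            if bi - sj == 3
        ]
        assert np.mean(planted) > 1.0
        assert reactivation_index(sim) > 0.05


class TestSceneTexts:
    def test_checkerboard_similarity(self):
        topics = [k % 2 for k in range(10)]
        texts = gen_scene_texts(10, 100, topics, words_per_scene=200, seed=0)
        sim = jsd_similarity(build_bow(texts))
        same = [sim[i, j] for i in range(10) for j in range(i + 1, 10) if (i - j) % 2 == 0]
        diff = [sim[i, j] for i in range(10) for j in range(i + 1, 10) if (i - j) % 2 == 1]
        assert np.mean(same) > np.mean(diff) + 0.1

    def test_single_topic_near_constant(self):
        texts = gen_scene_texts(8, 100, [0] * 8, words_per_scene=300, seed=0)
        sim = jsd_similarity(build_bow(texts))
        off = sim[~np.eye(8, dtype=bool)]
        assert off.std() < 0.05

    def test_determinism_and_drift_overlap(self):
        topics = [0] * 12
        a = gen_scene_texts(12, 100, topics, seed=3, drift=0.4)
        b = gen_scene_texts(12, 100, topics, seed=3, drift=0.4)
        assert a == b
        sim = jsd_similarity(build_bow(a))
        lag1 = np.mean([sim[i, i + 1] for i in range(11)])
        lag6 = np.mean([sim[i, i + 6] for i in range(6)])
        assert lag1 > lag6  # word overlap decays with scene lag


class TestSuiteEngine:
    def test_engine_agrees_with_public_api(self, rng):
        """The vectorised null-suite engine must reproduce the step-by-step
        pipeline (extraction, similarity, diagonal removal, index) exactly."""
        cfg = SimulationConfig.sherlock_like(n_subjects=1, n_voxels=40)
        table = scene_timings_fitting(cfg, rng)
        eng = _SuiteEngine(cfg, table, (0, 10), None, None, None)
        data = highpass_filter(
            gen_one_over_f(cfg.n_trs, cfg.n_voxels, seed=rng),
            cfg.tr_seconds,
            cfg.highpass_cutoff_s,
        )
        z = eng.zmatrix(data)
        run = make_run(cfg.n_trs, cfg.n_voxels, data=data)
        B = extract_boundary_reps(run, table, hrf_shift_trs=cfg.hrf_shift_trs)
        S = extract_scene_reps(
            run, table, gap_trs=cfg.gap_trs, hrf_shift_trs=cfg.hrf_shift_trs
        )
        idx = np.array([s.index for s in table.included])
        sim = boundary_scene_similarity(
            B, S, boundary_scene_index=idx, scene_index=idx
        )
        assert np.allclose(z[~sim.removal_mask], sim.z[~sim.removal_mask], atol=1e-9)
        assert eng.main_index(z, 0) == pytest.approx(
            reactivation_index(sim), abs=1e-9
        )
        assert eng.main_index(z, 10) == pytest.approx(
            reactivation_index(sim.with_diagonals_removed(10)), abs=1e-9
        )

    def test_suite_determinism(self):
        cfg = SimulationConfig.sherlock_like(
            n_subjects=2, n_voxels=30, n_trs=512, n_scenes=8
        )
        a = null_bias_suite(cfg, d_values=(0,), n_reps=3, seed=5)
        b = null_bias_suite(cfg, d_values=(0,), n_reps=3, seed=5)
        assert np.array_equal(a.indices[("main", 0)], b.indices[("main", 0)])

    def test_scene_pattern_immunity(self):
        """Symmetric scene-by-scene structure (stable injected patterns) must
        not shift the expected index: scene autocorrelations are a function
        of scene order, symmetric about boundaries, and cancel."""
        cfg = SimulationConfig.sherlock_like(n_subjects=4, n_voxels=60)
        plain = null_bias_suite(cfg, d_values=(10,), n_reps=25, seed=8)
        injected = null_bias_suite(
            cfg,
            d_values=(10,),
            n_reps=25,
            seed=8,
            scene_pattern_kind="uniform",
            scene_pattern_weight=1.0,
            table=plain.table,
        )
        for res in (plain, injected):
            v = res.indices[("main", 10)]
            se = v.std(ddof=1) / np.sqrt(v.size)
            assert abs(v.mean()) < 3.5 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig.sherlock_like(n_voxels=0)
        with pytest.raises(ValueError):
            SimulationConfig.sherlock_like(highpass_cutoff_s=2.0)
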