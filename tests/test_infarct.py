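import math

import numpy as np
import pandas as pd
import pytest

from lvmech.geometry import LVGeometry, chart_jacobian_analytic, make_quadrature, wall_volume
from lvmech.infarct import (
    HemoSettings,
    InfarctSpec,
    calibrate_emax,
    infarct_volume,
    kfold_cv,
    lesion_membership,
    run_study,
    simulate_cycle,
    slice_map,
    all_slice_maps,
    train_sv_surrogate,
)


@pytest.fixture(scope="module")
def baseline(opts):
    from lvmech.infarct import default_baseline

    return default_baseline(opts)


@pytest.fixture(scope="module")
def study_table(baseline, usyk, opts):
    return run_study(baseline, usyk, n=40, seed=7, options=opts)


class TestLesionGeometry:
    def test_degenerate_lesions_are_empty(self, midsize_lv):
        grid = make_quadrature(midsize_lv)
        for spec in (InfarctSpec(0.5, 0.0, 0.5, 0.5),
                     InfarctSpec(0.5, 1.0, 0.5, 0.0)):
            assert not lesion_membership(
                midsize_lv, spec, grid.psi, grid.t, grid.theta).any()

    def test_maximal_lesion_is_half_the_wall(self, midsize_lv):
        spec = InfarctSpec(0.5, math.pi, 1.0, 1.0)
        vol, frac = infarct_volume(midsize_lv, spec)
        assert frac == pytest.approx(0.5, abs=1e-6)
        assert vol == pytest.approx(wall_volume(midsize_lv) / 2, rel=1e-6)

    def test_volume_linear_in_circumferential_extent(self, midsize_lv):
        v1, _ = infarct_volume(midsize_lv, InfarctSpec(0.5, 0.6, 0.4, 0.7))
        v2, _ = infarct_volume(midsize_lv, InfarctSpec(0.5, 1.2, 0.4, 0.7))
        assert v2 == pytest.approx(2 * v1, rel=1e-6)

    def test_monte_carlo_volume_oracle(self, midsize_lv):
        # independent MC integral over the chart with Jacobian weights
        g = midsize_lv
        spec = InfarctSpec(0.4, 1.3, 0.5, 0.6)
        rng = np.random.default_rng(0)
        n = 100_000
        psi = rng.uniform(g.psi0, math.pi / 2, n)
        t = rng.uniform(0, 1, n)
        theta = rng.uniform(0, 2 * math.pi, n)
        det = np.abs(np.linalg.det(chart_jacobian_analytic(g, psi, t, theta)))
        member = lesion_membership(g, spec, psi, t, theta)
        box = (math.pi / 2 - g.psi0) * 1.0 * 2 * math.pi
        mc_vol = box * np.mean(det * member) / 1000.0
        vol, _ = infarct_volume(g, spec)
        assert vol == pytest.approx(mc_vol, rel=0.02)

    def test_transmural_apical_lesion_larger_than_shallow_basal(self, baseline):
        # deep transmural lesion vs shallower, narrower one
        deep = InfarctSpec(0.79, 1.57, 0.46, 1.0)
        shallow = InfarctSpec(0.43, 1.22, 0.40, 0.40)
        v_deep, _ = infarct_volume(baseline, deep)
        v_shallow, _ = infarct_volume(baseline, shallow)
        assert v_deep > v_shallow

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            InfarctSpec(0.5, 4.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            InfarctSpec(-0.1, 1.0, 0.5, 0.5)


class TestCycleModel:
    def test_calibration_hits_both_anchors(self, baseline, usyk, opts):
        hemo = HemoSettings()
        res0 = simulate_cycle(baseline, usyk, InfarctSpec(0.5, 0, 0, 0),
                              hemo, opts)
        assert res0.SV == pytest.approx(hemo.SV_target, abs=1e-6)
        res1 = simulate_cycle(baseline, usyk,
                              InfarctSpec(0.5, math.pi, 1.0, 1.0), hemo, opts)
        assert res1.SV == pytest.approx(hemo.SV_max_lesion, abs=1e-4)

    def test_calibration_rejects_small_ventricles(self):
        with pytest.raises(ValueError):
            calibrate_emax(edv=40.0)

    def test_sv_non_increasing_in_each_lesion_dimension(self, baseline, usyk,
                                                        opts):
        hemo = HemoSettings()
        from lvmech.mechanics import inflate

        edv = inflate(baseline, usyk, hemo.EDP, opts).cavity_vol
        el = calibrate_emax(edv, hemo)
        grid = make_quadrature(baseline)

        def sv(**kw):
            base = dict(long_pos=0.5, d_circ=1.5, d_long=0.5, depth=0.5)
            base.update(kw)
            return simulate_cycle(baseline, usyk, InfarctSpec(**base), hemo,
                                  opts, edv=edv, elastances=el, grid=grid).SV

        for axis in ("depth", "d_circ", "d_long"):
            vals = [sv(**{axis: v}) for v in (0.2, 0.5, 0.8)]
            assert vals[0] >= vals[1] >= vals[2], axis

    def test_sv_depends_on_lesion_only_through_wall_fraction(self, baseline,
                                                             usyk, opts):
        hemo = HemoSettings()
        from lvmech.mechanics import inflate

        edv = inflate(baseline, usyk, hemo.EDP, opts).cavity_vol
        el = calibrate_emax(edv, hemo)
        grid = make_quadrature(baseline)
        a = InfarctSpec(0.3, 1.2, 0.4, 0.8)
        _, frac_a = infarct_volume(baseline, a, grid)
        # different position/extents, circumference adjusted to match the
        # wall fraction exactly (volume is linear in d_circ)
        b0 = InfarctSpec(0.6, 1.0, 0.5, 0.6)
        _, frac_b = infarct_volume(baseline, b0, grid)
        b = InfarctSpec(0.6, b0.d_circ * frac_a / frac_b, 0.5, 0.6)
        res_a = simulate_cycle(baseline, usyk, a, hemo, opts, edv=edv,
                               elastances=el, grid=grid)
        res_b = simulate_cycle(baseline, usyk, b, hemo, opts, edv=edv,
                               elastances=el, grid=grid)
        assert res_a.SV == pytest.approx(res_b.SV, abs=1e-6)

    def test_clamped_stroke_volume_warns(self, baseline, usyk, opts):
        hemo = HemoSettings()
        with pytest.warns(UserWarning, match="clamped"):
            res = simulate_cycle(baseline, usyk,
                                 InfarctSpec(0.5, math.pi, 1.0, 1.0), hemo,
                                 opts, edv=200.0, elastances=(0.06, 0.001))
        assert res.SV == 0.0

    def test_pv_loop_reporting(self, baseline, usyk, opts):
        res = simulate_cycle(baseline, usyk, InfarctSpec(0.5, 1.0, 0.4, 0.5),
                             HemoSettings(), opts, with_pv_loop=True)
        assert res.pv_volume is not None
        assert res.EDV >= res.ESV >= HemoSettings().V0
        assert np.isfinite(res.pv_pressure).all()


class TestStudy:
    def test_design_size_and_bounds(self, study_table):
        assert len(study_table) == 40
        assert (study_table["SV"] >= 0).all()
        assert (study_table["SV"] <= HemoSettings().SV_target + 1e-9).all()

    def test_seeded_study_reproducible(self, baseline, usyk, opts,
                                       study_table):
        again = run_study(baseline, usyk, n=40, seed=7, options=opts)
        pd.testing.assert_frame_equal(study_table, again)

    def test_emulator_reproduces_training_points(self, study_table):
        reg = train_sv_surrogate(study_table, seed=0)
        pred = reg.predict(study_table[
            ["long_pos", "d_circ", "d_long", "depth"]].to_numpy())[:, 0]
        err = np.abs(pred - study_table["SV"].to_numpy())
        assert np.median(err) < 1.0

    def test_all_six_slice_maps_finite(self, study_table):
        reg = train_sv_surrogate(study_table, seed=0)
        maps = all_slice_maps(reg, n_grid=9)
        assert len(maps) == 6
        for (xi, yj, sv) in maps.values():
            assert np.isfinite(sv).all()

    def test_dominant_axes_are_depth_and_circumference(self, study_table):
        reg = train_sv_surrogate(study_table, seed=0)
        from lvmech.infarct import LESION_BOX

        mid = 0.5 * (LESION_BOX.lower + LESION_BOX.upper)
        ranges = {}
        for j, name in enumerate(["long_pos", "d_circ", "d_long", "depth"]):
            X = np.tile(mid, (21, 1))
            X[:, j] = np.linspace(LESION_BOX.lower[j], LESION_BOX.upper[j], 21)
            sv = reg.predict(X)[:, 0]
            ranges[name] = sv.max() - sv.min()
        top = max(ranges, key=ranges.get)
        assert top in ("depth", "d_circ")
        assert ranges["long_pos"] < ranges["depth"]
        assert ranges["long_pos"] < ranges["d_circ"]


class TestCrossValidation:
    def test_linear_surface_is_learned_almost_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(40, 4))
        table = pd.DataFrame(X, columns=["long_pos", "d_circ", "d_long",
                                         "depth"])
        table["SV"] = 50 - 10 * X[:, 1] - 20 * X[:, 3]
        assert kfold_cv(table, k=5, seed=0) < 0.5

    def test_error_decreases_with_training_size(self, study_table):
        errs_small, errs_full = [], []
        for s in range(8):
            errs_small.append(kfold_cv(study_table, k=5, seed=s, n_rows=10))
            errs_full.append(kfold_cv(study_table, k=5, seed=s))
        assert np.mean(errs_full) <= np.mean(errs_small)

    def test_needs_at_least_k_rows(self, study_table):
        with pytest.raises(ValueError):
            kfold_cv(study_table.head(3), k=5)
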