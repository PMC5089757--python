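"""Curve alignment, reference-curve estimation and TTP mapping."""

import json

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import cereflow as cf
from cereflow.synthetic import gamma_variate

from _util import (
    FRAMES,
    MASTER_TTP,
    master_curve,
    shift_only_ensemble,
    transform_ensemble,
    warped_master,
)


# --------------------------------------------------------------------------
# fit_linear_transform
# --------------------------------------------------------------------------

class TestFitLinearTransform:
    def test_self_fit_is_identity_with_zero_residual(self):
        c = cf.SignalCurve(master_curve())
        fr = cf.fit_linear_transform(c, cf.SignalCurve(master_curve()))
        t = fr.transform
        assert abs(t.time_shift) < 1e-9
        assert abs(t.time_scale - 1) < 1e-9
        assert abs(t.mag_shift) < 1e-9
        assert abs(t.mag_scale - 1) < 1e-9
        assert fr.residual < 1e-9

    def test_delayed_doubled_curve_recovered(self):
        """Moving = master delayed by 2 frames and doubled in amplitude;
        the fit must place the moving peak (7.0) onto the target peak (5.0)
        and halve the magnitude."""
        moving = cf.SignalCurve(2 * gamma_variate(FRAMES, 100, 4.0, 3.0, 1.0))
        target = cf.SignalCurve(master_curve())
        fr = cf.fit_linear_transform(moving, target)
        assert fr.transform.map_peak_time(7.0) == pytest.approx(5.0, abs=0.05)
        assert fr.transform.mag_scale == pytest.approx(0.5, rel=0.01)

    def test_constant_offset_solved_in_closed_form(self):
        moving = cf.SignalCurve(master_curve())
        target = cf.SignalCurve(master_curve() + 5.0)
        fr = cf.fit_linear_transform(moving, target)
        assert fr.transform.mag_shift == pytest.approx(5.0, abs=1e-6)
        assert fr.transform.time_shift == pytest.approx(0.0, abs=1e-6)
        assert fr.transform.time_scale == pytest.approx(1.0, abs=1e-6)
        assert fr.transform.mag_scale == pytest.approx(1.0, abs=1e-6)

    def test_flat_moving_curve_is_degenerate(self):
        with pytest.raises(cf.DegenerateCurveError):
            cf.fit_linear_transform(cf.SignalCurve(np.full(12, 3.0)),
                                    cf.SignalCurve(master_curve()))

    @pytest.mark.parametrize("t", [
        cf.LinearTransform(time_shift=1.0, time_scale=1.2,
                           mag_shift=5.0, mag_scale=2.0),
        cf.LinearTransform(time_shift=-0.8, time_scale=0.9,
                           mag_shift=0.0, mag_scale=0.5),
        cf.LinearTransform(time_shift=0.5, time_scale=1.05,
                           mag_shift=-3.0, mag_scale=1.5),
    ])
    def test_transform_consistency(self, t):
        """Fitting the T-warped curve back to the original recovers
        invert(T)'s time parameters.

        With the warped curve given analytically (no sampling), recovery is
        tight. With the warped curve known only at the 12 frames, cubic
        interpolation error moves the optimum along the flat shift/scale
        trade-off ridge, so individual parameters drift — but the peak
        transfer, the quantity the TTP pipeline consumes, stays accurate."""
        expected = t.invert()

        def analytic_warped(u):
            u = np.asarray(u, dtype=float)
            return (t.mag_scale
                    * gamma_variate(t.time_scale * u + t.time_shift,
                                    100, 2.0, 3.0, 1.0)
                    + t.mag_shift)

        fr = cf.fit_linear_transform(analytic_warped,
                                     cf.SignalCurve(master_curve()))
        assert fr.transform.time_shift == pytest.approx(
            expected.time_shift, abs=0.05)
        assert fr.transform.time_scale == pytest.approx(
            expected.time_scale, rel=0.01)

        warped_peak = (5.0 - t.time_shift) / t.time_scale
        fr = cf.fit_linear_transform(cf.SignalCurve(analytic_warped(FRAMES)),
                                     cf.SignalCurve(master_curve()))
        assert fr.transform.map_peak_time(warped_peak) == pytest.approx(
            5.0, abs=0.05)


# --------------------------------------------------------------------------
# mean_transform
# --------------------------------------------------------------------------

class TestMeanTransform:
    def test_identical_transforms_average_to_themselves(self):
        t = cf.LinearTransform(time_shift=1.5, time_scale=1.2,
                               mag_shift=-2.0, mag_scale=0.7)
        np.testing.assert_allclose(
            cf.mean_transform([t, t, t]).as_array(), t.as_array())

    def test_scale_and_its_inverse_average_to_identity(self):
        a = cf.LinearTransform(time_scale=2.0)
        b = cf.LinearTransform(time_scale=0.5)
        assert cf.mean_transform([a, b]).time_scale == pytest.approx(1.0)

    def test_shifts_average_arithmetically(self):
        a = cf.LinearTransform(time_shift=1.0)
        b = cf.LinearTransform(time_shift=3.0)
        assert cf.mean_transform([a, b]).time_shift == pytest.approx(2.0)

    def test_empty_list_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.mean_transform([])


# --------------------------------------------------------------------------
# reference curve and global TTP
# --------------------------------------------------------------------------

class TestBuildReferenceCurve:
    def test_identical_curves_reproduce_the_common_curve(self):
        curves = [cf.SignalCurve(master_curve()) for _ in range(50)]
        ref = cf.build_reference_curve(curves)
        assert ref.ttp == pytest.approx(MASTER_TTP, abs=0.05)
        rms = np.sqrt(np.mean((ref(FRAMES) - master_curve()) ** 2))
        assert rms < 0.01 * master_curve().max()

    def test_single_curve_reference_interpolates_its_samples(self):
        c = cf.SignalCurve(master_curve())
        ref = cf.build_reference_curve([c])
        np.testing.assert_allclose(ref(FRAMES), c.values, atol=1e-8)

    def test_all_flat_curves_are_degenerate(self):
        with pytest.raises(cf.DegenerateCurveError):
            cf.build_reference_curve(
                [cf.SignalCurve(np.full(12, 7.0)) for _ in range(5)])

    def test_agrees_with_brute_force_shift_oracle(self):
        """On small shift-only ensembles the reference TTP must match a
        brute-force oracle that grid-searches shifts at 0.01-frame
        resolution and averages the aligned curves."""
        for seed in (0, 1, 2):
            curves, _ = shift_only_ensemble(5, seed=seed)
            ref = cf.build_reference_curve(curves)
            oracle = _shift_oracle_ttp(curves)
            assert ref.ttp == pytest.approx(oracle, abs=0.1)

    def test_unbiased_over_replicate_ensembles(self):
        """Mean signed TTP error across replicate ensembles whose population
        mean transform is the identity (shifts centred on 0, scales drawn
        log-uniformly so their geometric mean is 1)."""
        errors = []
        for seed in range(20):
            curves = transform_ensemble(40, seed=300 + seed, noise_sd=2.0,
                                        log_uniform_scales=True)
            ref = cf.build_reference_curve(curves)
            errors.append(ref.ttp - MASTER_TTP)
        assert abs(np.mean(errors)) <= 0.05

    def test_shift_equivariance(self):
        """Delaying every input curve by one frame delays the global TTP by
        one frame."""
        curves, shifts = shift_only_ensemble(30, seed=9, noise_sd=1.0,
                                             shift_range=(-1.0, 1.0))
        delayed = [warped_master(1.0, b - 1.0) for b in shifts]
        ttp0 = cf.build_reference_curve(curves).ttp
        ttp1 = cf.build_reference_curve(delayed).ttp
        assert ttp1 - ttp0 == pytest.approx(1.0, abs=0.1)

    def test_magnitude_invariance(self):
        """A common positive intensity factor leaves the TTP unchanged."""
        curves = transform_ensemble(20, seed=4, noise_sd=2.0)
        scaled = [cf.SignalCurve(37.5 * c.values) for c in curves]
        ttp0 = cf.build_reference_curve(curves).ttp
        ttp1 = cf.build_reference_curve(scaled).ttp
        assert ttp1 == pytest.approx(ttp0, abs=1e-6)


def _shift_oracle_ttp(curves, step=0.01):
    """Brute-force reference TTP: grid-search pairwise shifts at ``step``
    resolution against the first curve, re-centre on the mean shift,
    average the aligned spline-interpolated curves, read off the argmax."""
    splines = [CubicSpline(FRAMES, c.values) for c in curves]
    grid = np.arange(-3.0, 3.0 + 1e-9, step)
    shifts = [0.0]
    for spl in splines[1:]:
        best_d, best_ss = None, np.inf
        for d in grid:
            tt = FRAMES + d
            ok = (tt >= 1) & (tt <= 12)
            if ok.sum() < 6:
                continue
            ss = np.mean((spl(tt[ok]) - splines[0](FRAMES[ok])) ** 2)
            if ss < best_ss:
                best_d, best_ss = d, ss
        shifts.append(best_d)
    dbar = np.mean(shifts)
    dense = np.arange(1.0, 12.0 + 1e-9, step)
    aligned = []
    for spl, d in zip(splines, shifts):
        tt = dense + (d - dbar)
        v = np.where((tt >= 1) & (tt <= 12), spl(np.clip(tt, 1, 12)), np.nan)
        aligned.append(v)
    mean_curve = np.nanmean(aligned, axis=0)
    return dense[np.nanargmax(mean_curve)]


class TestGlobalTTP:
    def test_gamma_variate_mode_recovered(self):
        """Spline through a gamma-variate with onset 2, shape 3, scale 1:
        the analytic mode is at frame 5."""
        ref = cf.build_reference_curve([cf.SignalCurve(master_curve())])
        ttp = cf.global_ttp(ref)
        assert float(ttp) == pytest.approx(5.0, abs=0.05)
        assert not ttp.at_boundary

    def test_monotone_curve_flags_boundary_maximum(self):
        ref = cf.build_reference_curve(
            [cf.SignalCurve(np.linspace(0.0, 10.0, 12))])
        ttp = cf.global_ttp(ref)
        assert float(ttp) == pytest.approx(12.0)
        assert ttp.at_boundary

    def test_ttp_stays_within_the_frame_axis(self):
        for seed in range(5):
            curves = transform_ensemble(25, seed=40 + seed, noise_sd=3.0)
            ttp = cf.global_ttp(cf.build_reference_curve(curves))
            assert 1.0 <= float(ttp) <= 12.0


# --------------------------------------------------------------------------
# per-voxel TTP and the end-to-end pipeline
# --------------------------------------------------------------------------

class TestVoxelTTPMap:
    def test_reference_like_voxel_maps_to_reference_ttp(self):
        ref = cf.build_reference_curve([cf.SignalCurve(master_curve())])
        rng = np.random.default_rng(0)
        data = np.zeros((2, 1, 1, 12))
        data[0, 0, 0, :] = master_curve()
        data[1, 0, 0, :] = rng.uniform(0, 100, 12)  # pure noise
        series = cf.Series4D(data)
        mask = cf.VesselMask(np.ones((2, 1, 1), dtype=bool))
        tmap = cf.voxel_ttp_map(series, mask, ref)
        assert tmap.values[0, 0, 0] == pytest.approx(ref.ttp, abs=0.05)
        assert np.isnan(tmap.values[1, 0, 0])  # residual over the threshold

    def test_phantom_gradient_recovered(self):
        """Tube phantom with a 0->3 frame arrival gradient at SNR 20: the
        per-voxel TTP map must track the imposed gradient."""
        ph = cf.generate_phantom(cf.PhantomSpec(seed=21))
        curves = cf.sample_vessel_curves(ph.series, ph.vessel_mask,
                                         n_curves=80, seed=1)
        ref = cf.build_reference_curve(curves)
        tmap = cf.voxel_ttp_map(ph.series, ph.vessel_mask, ref)
        both = tmap.defined & ph.vessel_mask.mask
        assert both.sum() >= 0.9 * ph.vessel_mask.n_voxels
        err = tmap.values[both] - ph.ttp_truth.values[both]
        assert np.sqrt(np.mean(err ** 2)) <= 0.25


class TestAnalyzeSeries:
    def test_same_seed_gives_byte_identical_report(self):
        ph = cf.generate_phantom(cf.PhantomSpec(grid_shape=(24, 24, 24),
                                                seed=6))
        runs = [cf.analyze_series(ph.series, seed=3, n_curves=40)
                for _ in range(2)]
        assert runs[0].to_json() == runs[1].to_json()
        json.loads(runs[0].to_json())  # valid JSON
        assert runs[0].report["seed"] == 3

    def test_empty_vasculature_names_the_failing_stage(self):
        series = cf.Series4D(np.full((8, 8, 8, 12), 2.0))
        with pytest.warns(RuntimeWarning):
            with pytest.raises(cf.PipelineError, match="segmentation"):
                cf.analyze_series(series, seed=0)
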