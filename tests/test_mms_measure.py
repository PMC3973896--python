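"""Measurement chain: tracking, geometry, mechanics, full pipeline."""

import numpy as np
import pytest

from cytomech import mms
from cytomech.frames import FrameSequence
from cytomech.simulate import (ImagingConfig, MechanicsTruth,
                               generate_mms_sequence)
from cytomech.simulate.mms import _render_frame


def _static_sequence(n_frames=6, tip_z=15.0, h=15.0, d=18.0, imaging=None):
    imaging = imaging or ImagingConfig(noise_sd=0.0)
    frame = _render_frame(h, d, tip_z, imaging, None)
    frames = np.repeat(frame[None], n_frames, axis=0)
    return FrameSequence(frames, np.arange(n_frames, dtype=float),
                         ["compression"] * n_frames,
                         np.zeros(n_frames), scale=imaging.scale,
                         spring_constant=9.6)


class TestTracking:
    def test_stationary_bar_has_zero_deflection(self, measurement_config):
        seq = _static_sequence()
        trace = mms.track_cantilever(seq, measurement_config)
        np.testing.assert_allclose(trace.deflection_um, 0.0, atol=1e-12)

    def test_48_pixel_shift_is_10_um(self, measurement_config):
        """At the 4.8 px/um calibration a 48-pixel edge shift is 10 um."""
        imaging = ImagingConfig(noise_sd=0.0)
        f0 = _render_frame(15.0, 18.0, 15.0, imaging, None)
        f1 = _render_frame(15.0, 18.0, 25.0, imaging, None)  # 48 px higher
        seq = FrameSequence(np.stack([f0, f1]), [0.0, 1.0],
                            ["compression"] * 2, [0.0, 0.0],
                            scale=imaging.scale, spring_constant=9.6)
        trace = mms.track_cantilever(seq, measurement_config)
        assert trace.tip_offset_um.iloc[1] == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("run_fixture", ["noisefree_run", "noisy_run"])
    def test_deflection_tracks_truth_within_one_pixel(self, run_fixture, request,
                                                      measurement_config):
        seq, table = request.getfixturevalue(run_fixture)
        trace = mms.track_cantilever(seq, measurement_config)
        err = np.abs(trace.deflection_um - table.truth_deflection_um)
        assert np.nanmax(err) <= 1.0 / measurement_config.scale + 1e-9


class TestGeometry:
    def test_circle_height_equals_diameter(self, measurement_config):
        imaging = ImagingConfig(noise_sd=0.0)
        seq = _static_sequence(h=12.0, d=12.0, tip_z=30.0, imaging=imaging)
        geom = mms.extract_geometry(seq, measurement_config)
        tol = 2.0 / measurement_config.scale
        assert abs(geom.height_um.iloc[0] - geom.diameter_um.iloc[0]) <= tol

    def test_ellipse_axes_recovered_within_two_pixels(self, measurement_config):
        imaging = ImagingConfig(noise_sd=0.0)
        seq = _static_sequence(h=15.0, d=18.0, tip_z=15.0, imaging=imaging)
        geom = mms.extract_geometry(seq, measurement_config)
        tol = 2.0 / measurement_config.scale
        assert geom.attrs["h0_um"] == pytest.approx(15.0, abs=tol)
        assert geom.attrs["d0_um"] == pytest.approx(18.0, abs=tol)

    def test_empty_frame_raises_no_cell(self, measurement_config):
        imaging = ImagingConfig(noise_sd=0.0)
        frame = np.full((imaging.image_height, imaging.image_width),
                        imaging.background_level, dtype=np.uint8)
        seq = FrameSequence(frame[None].repeat(3, axis=0), [0.0, 1.0, 2.0],
                            ["compression"] * 3, np.zeros(3),
                            scale=imaging.scale, spring_constant=9.6)
        with pytest.raises(mms.NoCellError, match="no cell"):
            mms.extract_geometry(seq, measurement_config)


class TestMechanicsArithmetic:
    def test_hookes_law_values(self):
        assert mms.force_from_deflection(0.0, 40.0) == 0.0
        assert mms.force_from_deflection(0.05, 40.0) == pytest.approx(2.0)
        f1 = mms.force_from_deflection(0.3, 40.0)
        f2 = mms.force_from_deflection(0.6, 40.0)
        assert f2 == pytest.approx(2 * f1)

    def test_strain_values(self):
        assert mms.strain_series([20.0], 20.0)[0] == 0.0
        assert mms.strain_series([15.0], 20.0)[0] == pytest.approx(0.25)
        assert mms.strain_series([22.0], 20.0)[0] == pytest.approx(0.10)
        with pytest.raises(ValueError):
            mms.strain_series([10.0], 0.0)

    def test_stress_arithmetic_oracle(self):
        sigma = mms.stress_series([10.0], [20.0])[0]
        assert sigma == pytest.approx(1000.0 * 10.0 / (np.pi * 20.0**2 / 4.0),
                                      rel=1e-12)
        assert sigma == pytest.approx(31.830988, rel=1e-6)
        assert mms.stress_series([0.0], [20.0])[0] == 0.0

    def test_stress_quarter_scaling_with_diameter(self):
        s1 = mms.stress_series([10.0], [10.0])[0]
        s2 = mms.stress_series([10.0], [20.0])[0]
        assert s1 == pytest.approx(4 * s2, rel=1e-12)

    def test_stress_agrees_with_si_unit_computation(self):
        """1 nN/um^2 = 1 kPa, checked against a full SI conversion."""
        f_nn, d_um = 7.3, 16.9
        sigma = mms.stress_series([f_nn], [d_um])[0]
        f_newton = f_nn * 1e-9
        area_m2 = np.pi * (d_um * 1e-6) ** 2 / 4.0
        assert sigma == pytest.approx(f_newton / area_m2, rel=1e-12)


class TestStiffnessFit:
    def test_exact_line_recovers_slope(self):
        eps = np.linspace(0.01, 0.2, 20)
        fit = mms.estimate_stiffness(500.0 * eps, eps)
        assert fit.e_pa == pytest.approx(500.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.poor_fit

    def test_matches_closed_form_constrained_slope(self):
        """Origin-constrained mode equals the analytic least-squares slope."""
        rng = np.random.default_rng(0)
        eps = np.linspace(0.02, 0.18, 15)
        sigma = 420.0 * eps + rng.normal(0, 5.0, eps.size)
        cfg = mms.MeasurementConfig(fit_intercept=False)
        fit = mms.estimate_stiffness(sigma, eps, cfg)
        assert fit.e_pa == pytest.approx(float(np.sum(sigma * eps) / np.sum(eps**2)),
                                         rel=1e-12)

    def test_zero_strain_raises(self):
        with pytest.raises(mms.MeasurementError, match="deformation"):
            mms.estimate_stiffness(np.ones(10), np.zeros(10))

    def test_single_point_mode(self):
        eps = np.linspace(0.01, 0.15, 10)
        cfg = mms.MeasurementConfig(single_point_stiffness=True)
        fit = mms.estimate_stiffness(300.0 * eps, eps, cfg)
        assert fit.e_pa == pytest.approx(300.0, rel=1e-12)


class TestAdhesion:
    def test_ramp_and_drop(self):
        force = np.concatenate([np.linspace(0, 30, 10), [0.0, 0.0]])
        phases = ["tension"] * 12
        res = mms.adhesion_force(force, phases)
        assert res.detached
        assert res.af_nn == pytest.approx(30.0)
        assert res.detachment_index == 10

    def test_flat_zero_tension_is_no_detachment(self):
        res = mms.adhesion_force(np.zeros(10), ["tension"] * 10)
        assert not res.detached
        assert np.isnan(res.af_nn)

    def test_partial_dip_is_not_detachment(self):
        # drops to 60% of peak then recovers: not a pull-off
        force = np.array([10, 20, 30, 18, 25, 31, 32, 0, 0], dtype=float)
        res = mms.adhesion_force(force, ["tension"] * 9)
        assert res.detachment_index == 7
        assert res.af_nn == pytest.approx(32.0)


class TestMeasureCell:
    def test_default_cell_fully_valid(self, noisy_run, measurement_config):
        seq, _ = noisy_run
        cell = mms.measure_cell(seq, measurement_config)
        assert cell.cs_valid and cell.ts_valid and cell.af_valid
        assert cell.cs_pa == pytest.approx(400.0, rel=0.10)
        assert cell.ts_pa == pytest.approx(600.0, rel=0.10)
        assert cell.af_nn == pytest.approx(30.0, abs=2.0)

    def test_zero_adhesion_flags_early_detachment(self, measurement_config):
        truth = MechanicsTruth(400.0, 600.0, 0.0)
        seq, _ = generate_mms_sequence(truth, ImagingConfig(noise_sd=0.0))
        cell = mms.measure_cell(seq, measurement_config)
        assert "early_detachment" in cell.flags
        assert not cell.ts_valid and not cell.af_valid
        assert cell.cs_valid  # compression already completed

    def test_too_short_sequence_raises(self, noisefree_run, measurement_config):
        seq, _ = noisefree_run
        short = FrameSequence(seq.frames[:4], seq.timestamps_s[:4],
                              seq.phases[:4], seq.base_displacement_um[:4],
                              seq.scale, seq.spring_constant)
        with pytest.raises(mms.InsufficientFramesError):
            mms.measure_cell(short, measurement_config)

    def test_stiffer_cell_raises_peak_force(self, noisefree_imaging):
        """Monotonicity of the constant-area model in the true modulus."""
        peaks = []
        for e in (200.0, 400.0, 800.0):
            truth = MechanicsTruth(e, e, 1e5)
            _, table = generate_mms_sequence(truth, noisefree_imaging,
                                             max_tension_travel_um=1.0)
            comp = table[table.truth_phase == "compression"]
            peaks.append(comp.truth_force_nn.max())
        assert peaks[0] < peaks[1] < peaks[2]
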