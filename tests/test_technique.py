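"""Technique chain: exposure bookkeeping, clamping, plan derivation, sweeps."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dts4d import (
    InfeasibleTechniqueError,
    InputError,
    RespiratoryWaveform,
    TechniqueConfig,
    VelocityMode,
    arc_duration_at,
    derive_technique_plan,
    mAs_per_projection,
    sweep_sinusoidal_extremes,
    technique_extremes,
    technique_from_velocity,
)


class TestExposure:
    def test_default_mAs_per_projection(self):
        assert mAs_per_projection(TechniqueConfig()) == pytest.approx(5.0 / 61.0)

    def test_identity_and_linearity(self):
        assert mAs_per_projection(
            TechniqueConfig(noise_scaling=61.0, projections_per_arc=61)
        ) == pytest.approx(1.0)
        full = mAs_per_projection(TechniqueConfig(noise_scaling=5.0))
        half = mAs_per_projection(TechniqueConfig(noise_scaling=2.5))
        assert half == pytest.approx(full / 2.0)


class TestArcDuration:
    def test_fast_breathing_unclamped(self):
        arc, clamped = arc_duration_at(29.522, TechniqueConfig())
        assert arc == pytest.approx(1.0 / 29.522)
        assert not clamped

    def test_still_breathing_clamped(self):
        arc, clamped = arc_duration_at(0.0, TechniqueConfig())
        assert arc == 0.495 and clamped

    def test_negative_velocity_rejected(self):
        with pytest.raises(InputError):
            arc_duration_at(-1.0, TechniqueConfig())


class TestChain:
    def test_table_corner_chain(self):
        """4 cm / 25 bpm average-velocity row: 0.034 s, 1801 Hz, 0.545 ms, 150.3 /s."""
        pt = technique_from_velocity(29.522)
        assert pt.arc_duration_s == pytest.approx(0.034, abs=0.001)
        assert pt.frame_rate_hz == pytest.approx(1801, abs=1)
        assert pt.pulse_duration_s * 1e3 == pytest.approx(0.545, abs=0.001)
        assert pt.tube_current_ratio == pytest.approx(150.3, abs=0.1)

    def test_abstract_fastest_chain(self):
        """Instantaneous peak 34.009 mm/s: 2074 Hz, 0.472 ms, 173.6 /s."""
        pt = technique_from_velocity(34.009)
        assert pt.frame_rate_hz == pytest.approx(2074, abs=1)
        assert pt.pulse_duration_s * 1e3 == pytest.approx(0.472, abs=0.001)
        assert pt.tube_current_ratio == pytest.approx(173.6, abs=0.1)

    def test_readout_limit_is_infeasible(self):
        cfg = TechniqueConfig()
        v_limit = cfg.capture_distance_mm * 1e5 / cfg.projections_per_arc  # frame = 100 kHz
        with pytest.raises(InfeasibleTechniqueError):
            technique_from_velocity(v_limit, cfg)

    @given(v=st.floats(0.1, 1000.0))
    def test_chain_identities(self, v):
        cfg = TechniqueConfig()
        try:
            pt = technique_from_velocity(v, cfg)
        except InfeasibleTechniqueError:
            return
        NP = cfg.projections_per_arc
        assert pt.frame_rate_hz * pt.arc_duration_s == pytest.approx(NP, rel=1e-9)
        assert pt.tube_current_ratio * pt.pulse_duration_s == pytest.approx(
            cfg.noise_scaling / NP, rel=1e-9
        )
        if not pt.clamped:
            assert pt.arc_duration_s * v == pytest.approx(cfg.capture_distance_mm, rel=1e-9)
        assert pt.pulse_duration_s > 0

    def test_monotone_in_velocity(self):
        pts = [technique_from_velocity(v) for v in (3.0, 10.0, 30.0, 100.0)]
        for lo, hi in zip(pts, pts[1:]):
            assert hi.arc_duration_s < lo.arc_duration_s
            assert hi.frame_rate_hz > lo.frame_rate_hz
            assert hi.pulse_duration_s < lo.pulse_duration_s
            assert hi.tube_current_ratio > lo.tube_current_ratio

    def test_f_scaling(self):
        a = technique_from_velocity(10.0, TechniqueConfig(noise_scaling=5.0))
        b = technique_from_velocity(10.0, TechniqueConfig(noise_scaling=10.0))
        assert b.tube_current_ratio == pytest.approx(2.0 * a.tube_current_ratio, rel=1e-12)
        assert b.arc_duration_s == a.arc_duration_s
        assert b.frame_rate_hz == a.frame_rate_hz
        assert b.pulse_duration_s == a.pulse_duration_s

    def test_D_scaling(self):
        a = technique_from_velocity(10.0, TechniqueConfig(capture_distance_mm=1.0))
        b = technique_from_velocity(10.0, TechniqueConfig(capture_distance_mm=2.0))
        assert b.arc_duration_s == pytest.approx(2.0 * a.arc_duration_s, rel=1e-12)
        assert b.frame_rate_hz == pytest.approx(a.frame_rate_hz / 2.0, rel=1e-12)


class TestPlan:
    def test_constant_ramp_equals_single_point_chain(self, ramp_waveform):
        plan = derive_technique_plan(ramp_waveform)
        pt = technique_from_velocity(2.0)
        np.testing.assert_allclose(plan.arc_duration_s, pt.arc_duration_s, rtol=1e-9)
        np.testing.assert_allclose(plan.frame_rate_hz, pt.frame_rate_hz, rtol=1e-9)
        np.testing.assert_allclose(plan.tube_current_ratio, pt.tube_current_ratio, rtol=1e-9)

    def test_flat_waveform_fully_clamped(self):
        t = np.arange(100) * 0.033
        wf = RespiratoryWaveform(times=t, displacements=np.zeros(100))
        plan = derive_technique_plan(wf)
        assert plan.clamped.all()
        np.testing.assert_allclose(plan.arc_duration_s, 0.495)
        np.testing.assert_allclose(plan.frame_rate_hz, 61.0 / 0.495)  # 123.23 Hz

    def test_extremes_match_brute_force(self, lujan_fast):
        from dts4d import generate_lujan_waveform

        wf = generate_lujan_waveform(lujan_fast, 30.0, mode=VelocityMode.REPLICATION)
        plan = derive_technique_plan(wf)
        ext = technique_extremes(plan)
        ok = ~plan.infeasible
        assert ext.min_arc_duration_s == np.min(plan.arc_duration_s[ok])
        assert ext.max_frame_rate_hz == np.max(plan.frame_rate_hz[ok])
        assert ext.min_pulse_duration_s == np.min(plan.pulse_duration_s[ok])
        assert ext.max_tube_current_ratio == np.max(plan.tube_current_ratio[ok])

    def test_constant_plan_extremes(self, ramp_waveform):
        plan = derive_technique_plan(ramp_waveform)
        ext = technique_extremes(plan)
        pt = technique_from_velocity(2.0)
        assert ext.min_arc_duration_s == pytest.approx(pt.arc_duration_s, rel=1e-9)
        assert ext.max_tube_current_ratio == pytest.approx(pt.tube_current_ratio, rel=1e-9)

    def test_infeasible_points_flagged_not_fatal(self):
        # 2000 mm/s sustained: frame rate 61*2000 = 122 kHz > 100 kHz readout limit
        t = np.arange(100) * 0.033
        wf = RespiratoryWaveform(times=t, displacements=2000.0 * t)
        plan = derive_technique_plan(wf)
        assert plan.infeasible.all()
        assert np.isnan(plan.pulse_duration_s).all()
        with pytest.raises(InputError):
            technique_extremes(plan)


class TestSweep:
    def test_grid_cardinality_and_monotonicity(self):
        table = sweep_sinusoidal_extremes(
            [10.0, 20.0, 30.0, 40.0],
            [12.0, 15.0, 20.0, 25.0],
            mode=VelocityMode.REPLICATION,
            velocity_method="instantaneous",
        )
        assert len(table) == 16
        # frame rate non-decreasing in b at fixed bpm and in bpm at fixed b
        for bpm, grp in table.groupby("rate_bpm"):
            assert grp.sort_values("displacement_mm")["max_frame_hz"].is_monotonic_increasing
        for b, grp in table.groupby("displacement_mm"):
            assert grp.sort_values("rate_bpm")["max_frame_hz"].is_monotonic_increasing

    def test_replication_instantaneous_corner(self):
        table = sweep_sinusoidal_extremes(
            [40.0], [25.0], mode=VelocityMode.REPLICATION, velocity_method="instantaneous"
        )
        assert table["min_pulse_ms"].iloc[0] == pytest.approx(0.472, abs=0.001)

    def test_literal_mode_is_faster_than_replication(self):
        lit = sweep_sinusoidal_extremes(
            [40.0], [25.0], mode=VelocityMode.LITERAL, velocity_method="instantaneous"
        )
        rep = sweep_sinusoidal_extremes(
            [40.0], [25.0], mode=VelocityMode.REPLICATION, velocity_method="instantaneous"
        )
        # pi*b/tau > (2*pi*b/tau)*3*sqrt(3)/16
        assert lit["max_frame_hz"].iloc[0] > rep["max_frame_hz"].iloc[0]

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            sweep_sinusoidal_extremes([], [12.0])
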