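"""Fiducials, TT sampling and the 65-parameter vector."""

import numpy as np
import pandas as pd
import pytest

from opmcg.containers import AveragedBeat
from opmcg.exceptions import FiducialError, InvalidArgumentError
from opmcg.features import (
    DELTA_NAMES,
    PARAMETER_NAMES,
    Fiducials,
    ParameterVector,
    compute_parameters,
    delta_parameters,
    locate_fiducials,
    timepoint_quantities,
    tt_sample_times,
)
from opmcg.simulate import forward_bz

from .conftest import make_noiseless_beat

T_PEAK = 300.0
T_SIGMA = 45.0


def make_static_beat(grid, angle_deg=-150.0, r_amp=1.0, t_amp=0.4,
                     fs=200.0) -> AveragedBeat:
    """Beat with a frozen spatial pattern: data = pattern x envelope.

    The field amplitude at any instant is exactly proportional to the
    envelope, so ratios such as RoART have closed-form expected values, and
    all geometric quantities are constant through the beat.
    """
    from .conftest import make_noiseless_beat  # reuse time axis conventions

    t = np.arange(-300.0, 500.0 + 2.5, 5.0)
    env = (r_amp * np.exp(-0.5 * (t / 12.0) ** 2)
           + t_amp * np.exp(-0.5 * ((t - T_PEAK) / T_SIGMA) ** 2)
           + 0.15 * np.exp(-0.5 * ((t + 180.0) / 22.0) ** 2))
    from opmcg.simulate import DipoleTrajectory

    m = np.array([np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))])
    traj = DipoleTrajectory(times=np.array([0.0, 1.0]),
                            positions=np.array([[0.0, 0.0, 6.0]] * 2),
                            moments=np.array([m, m]))
    pattern = forward_bz(traj, grid, 0.5)
    data = pattern[:, None] * env[None, :]
    return AveragedBeat(data=data, fs=fs, n_beats_used=50, n_beats_rejected=0,
                        offsets_ms=t)


class TestFiducials:
    def test_recovery_on_noiseless_beat(self, noiseless_beat):
        fid = locate_fiducials(noiseless_beat)
        assert fid.rp == pytest.approx(0.0, abs=5.0)
        assert fid.tp == pytest.approx(T_PEAK, abs=5.0)
        # T-onset: 10%-height crossing of the Gaussian T envelope
        expected_tb = T_PEAK - T_SIGMA * np.sqrt(2.0 * np.log(10.0))
        assert fid.tb == pytest.approx(expected_tb, abs=10.0)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(FiducialError):
            Fiducials(rp=0.0, tb=-10.0, tp=300.0)
        with pytest.raises(FiducialError):
            Fiducials(rp=0.0, tb=300.0, tp=200.0)

    def test_flat_tt_segment_fails(self, grid):
        t = np.arange(-300.0, 500.0 + 2.5, 5.0)
        env = np.exp(-0.5 * (t / 12.0) ** 2)  # QRS only, no T wave
        data = np.ones((36, t.size)) * env[None, :]
        beat = AveragedBeat(data=data, fs=200.0, n_beats_used=50,
                            n_beats_rejected=0, offsets_ms=t)
        with pytest.raises(FiducialError):
            locate_fiducials(beat)


class TestTTSampling:
    def test_eleven_points_with_tau_spacing(self):
        f = Fiducials(rp=0.0, tb=400.0, tp=500.0)
        assert f.tau == pytest.approx(10.0)
        times = tt_sample_times(f)
        assert times.size == 11
        assert np.allclose(times, np.arange(400.0, 501.0, 10.0))

    def test_count_always_eleven(self, noiseless_beat):
        fid = locate_fiducials(noiseless_beat)
        assert tt_sample_times(fid).size == 11


class TestTimepointQuantities:
    def test_moment_orientation_recovered_at_t_peak(self, grid):
        beat = make_static_beat(grid, angle_deg=-150.0)
        q = timepoint_quantities(beat, grid, T_PEAK)
        # pole axis is orthogonal to the -150 deg moment: MA near -60
        assert q.ma == pytest.approx(-60.0, abs=5.0)
        assert abs((q.ca - (-150.0) + 180.0) % 360.0 - 180.0) < 5.0

    def test_scaling_doubles_amplitude_only(self, grid):
        beat = make_static_beat(grid)
        doubled = AveragedBeat(data=2.0 * beat.data, fs=beat.fs,
                               n_beats_used=beat.n_beats_used,
                               n_beats_rejected=0, offsets_ms=beat.offsets_ms)
        q1 = timepoint_quantities(beat, grid, T_PEAK)
        q2 = timepoint_quantities(doubled, grid, T_PEAK)
        assert q2.mm == pytest.approx(2.0 * q1.mm)
        assert q2.ma == pytest.approx(q1.ma)
        assert q2.ca == pytest.approx(q1.ca)
        assert q2.cppp == q1.cppp
        assert q2.npa >= 0.0


class TestParameterVector:
    def test_manifest_is_frozen(self):
        assert len(PARAMETER_NAMES) == 65
        assert len(set(PARAMETER_NAMES)) == 65
        for required in ("RoART", "NPAmax", "MAmax", "CPPPPmax", "CAmax"):
            assert required in PARAMETER_NAMES
        # canonical order is stable: spot-check the frozen anchors
        assert PARAMETER_NAMES[0] == "MAmax"
        assert PARAMETER_NAMES[-1] == "RoART"
        assert DELTA_NAMES == tuple("d" + n for n in PARAMETER_NAMES)

    def test_roart_equals_envelope_ratio(self, grid):
        beat = make_static_beat(grid, r_amp=6.0, t_amp=3.0)
        pv = compute_parameters(beat, grid, locate_fiducials(beat))
        # static pattern: amplitude ratio reduces to the envelope ratio at
        # the located fiducials
        rp_env = 6.0
        tb = locate_fiducials(beat)
        t_env = (6.0 * np.exp(-0.5 * (tb.tp / 12.0) ** 2)
                 + 3.0 * np.exp(-0.5 * ((tb.tp - T_PEAK) / T_SIGMA) ** 2))
        assert pv["RoART"] == pytest.approx(rp_env / t_env, rel=1e-6)

    def test_static_dipole_has_no_tt_dynamics(self, grid):
        beat = make_static_beat(grid)
        fid = locate_fiducials(beat)
        pv = compute_parameters(beat, grid, fid)
        assert pv["CPPPPmax"] == pytest.approx(0.0, abs=1e-9)
        assert pv["MArange"] == pytest.approx(0.0, abs=1e-9)
        assert pv["MAmax"] == pytest.approx(
            timepoint_quantities(beat, grid, fid.tb).ma)

    def test_all_parameters_finite_and_ordered(self, grid, noiseless_beat):
        pv = compute_parameters(noiseless_beat, grid,
                                locate_fiducials(noiseless_beat))
        assert len(pv) == 65
        assert tuple(pv.data.index) == PARAMETER_NAMES
        assert np.all(np.isfinite(pv.data.to_numpy()))

    def test_time_shift_invariance(self, grid, noiseless_beat):
        pv1 = compute_parameters(noiseless_beat, grid,
                                 locate_fiducials(noiseless_beat))
        shifted = AveragedBeat(data=noiseless_beat.data, fs=noiseless_beat.fs,
                               n_beats_used=100, n_beats_rejected=0,
                               offsets_ms=noiseless_beat.offsets_ms + 40.0)
        pv2 = compute_parameters(shifted, grid, locate_fiducials(shifted))
        pd.testing.assert_series_equal(pv1.data, pv2.data, rtol=1e-9)

    def test_ischemia_increases_delta_markers(self, grid):
        """TT-segment pathology markers grow monotonically with ischemia."""
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        npa, disp, ma = [], [], []
        for lvl in levels:
            beat = make_noiseless_beat(grid, ischemia=lvl)
            pv = compute_parameters(beat, grid, locate_fiducials(beat))
            npa.append(pv["NPAmax"])
            disp.append(pv["CPPPPmax"])
            ma.append(pv["MAmax"])
        assert all(a < b for a, b in zip(npa, npa[1:]))
        assert all(a < b for a, b in zip(disp, disp[1:]))
        assert all(a < b for a, b in zip(ma, ma[1:]))


class TestDeltaParameters:
    def test_identical_scans_give_zero_delta(self, grid, noiseless_beat):
        pv = compute_parameters(noiseless_beat, grid,
                                locate_fiducials(noiseless_beat))
        d = delta_parameters(pv, pv)
        assert np.allclose(d.data.to_numpy(), 0.0)
        assert tuple(d.data.index) == DELTA_NAMES

    def test_antisymmetry(self, grid, noiseless_beat, ischemic_beat):
        pre = compute_parameters(noiseless_beat, grid,
                                 locate_fiducials(noiseless_beat))
        post = compute_parameters(ischemic_beat, grid,
                                  locate_fiducials(ischemic_beat))
        fwd = delta_parameters(pre, post).data.to_numpy()
        rev = delta_parameters(post, pre).data.to_numpy()
        assert np.allclose(fwd, -rev)

    def test_simple_difference(self):
        base = pd.Series(np.zeros(65), index=list(PARAMETER_NAMES))
        pre = base.copy()
        pre[:] = 1.0
        pre["RoART"] = 2.0
        post = pre.copy()
        post["RoART"] = 2.5
        d = delta_parameters(ParameterVector(pre), ParameterVector(post))
        assert d["dRoART"] == pytest.approx(0.5)
        assert d["dNPAmax"] == pytest.approx(0.0)
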