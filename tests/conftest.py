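import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from t1234 import phantom as phantom_mod
from t1234.protocol import packaged_protocol


@pytest.fixture(scope="session")
def retro():
    """Highly segmented whole-brain protocol (930/2368/8/23/3097 ms, FA 10)."""
    return packaged_protocol("retrospective")


@pytest.fixture(scope="session")
def acq_matched():
    """Acquisition distortion-matched protocol (1378/3793/26/78/5050 ms, FA 10)."""
    return packaged_protocol("acquisition_matched")


@pytest.fixture(scope="session")
def phantom64():
    return phantom_mod.make_phantom((64, 64, 64), seed=0)


@pytest.fixture(scope="session")
def ideal_vols(phantom64, retro):
    """Noise- and artifact-free signal volumes at both inversion times."""
    s1 = phantom_mod.ideal_signal_volume(phantom64, retro, 1)
    s2 = phantom_mod.ideal_signal_volume(phantom64, retro, 2)
    return s1, s2


def euler_ir_cycle(p, t1, mz_start, b1_scale=1.0, dt=0.01, m0=1.0):
    """Brute-force fixed-step forward-Euler integration of one IR cycle.

    Independent oracle for the event-driven recursion: relaxation is
    integrated with explicit Euler steps of ``dt`` ms; inversion and
    excitation pulses are applied instantaneously at their event times.
    Returns Mz immediately before each excitation.
    """
    from t1234.bloch import shot_times

    times, block = shot_times(p)
    alphas = np.deg2rad(np.where(block == 1, p.fa1, p.fa2)) * b1_scale
    mz = -p.inversion_efficiency * mz_start
    out = np.empty(len(times))
    t = 0.0
    for k, (t_k, a) in enumerate(zip(times, alphas)):
        n_steps = int(round((t_k - t) / dt))
        for _ in range(n_steps):
            mz += dt * (m0 - mz) / t1
        out[k] = mz
        mz *= np.cos(a)
        t = t_k
    return out


def steady_state_cycle_start(p, t1, b1_scale=1.0, m0=1.0):
    """Mz just before the inversion pulse of a steady-state cycle."""
    from t1234.bloch import simulate_ir_cycles, TissueParams

    traj = simulate_ir_cycles(p, TissueParams("t", t1, m0), b1_scale=b1_scale)
    a_last = np.deg2rad(p.fa2) * b1_scale
    mz = traj.mz_before[-1] * m0 * np.cos(a_last)
    dt = p.tr_ir - traj.times[-1]
    return m0 + (mz - m0) * np.exp(-dt / t1)
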