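import numpy as np
import pytest

from peersync.preprocess import RRSeries, UniformHeartRate


@pytest.fixture
def rr_series_factory():
    """Build an RRSeries from a list of rr values (ms), cumulative timestamps."""

    def make(rr_ms, phase_marks=None, subject_id="s1"):
        rr = np.asarray(rr_ms, dtype=float)
        t = np.cumsum(rr) / 1000.0
        return RRSeries(subject_id=subject_id, session_id="sess",
                        times_s=t, rr_ms=rr, phase_marks=phase_marks or {})

    return make


@pytest.fixture
def sinusoid_hr_factory():
    """Uniform 1 Hz heart-rate trajectory with optional sinusoidal content."""

    def make(n=256, freqs_amps=((0.25, 1.0),), noise_sd=0.0, seed=0,
             subject_id="a", phase="story", mean=80.0):
        rng = np.random.default_rng(seed)
        t = np.arange(n, dtype=float)
        x = np.full(n, mean)
        for f, a in freqs_amps:
            x = x + a * np.sin(2 * np.pi * f * t)
        if noise_sd:
            x = x + noise_sd * rng.standard_normal(n)
        return UniformHeartRate(subject_id=subject_id, phase_label=phase,
                                t0_s=0.0, sample_rate_hz=1.0, hr_bpm=x,
                                valid_mask=np.ones(n, dtype=bool))

    return make


@pytest.fixture
def modulated_rr_factory():
    """Beat series whose rr is sinusoidally modulated: rr(t) = base + A sin(2π f t)."""

    def make(duration_s=600.0, base_ms=800.0, amp_ms=50.0, freq_hz=0.25,
             phase_marks=None, subject_id="s1"):
        times = []
        t = 0.0
        while t < duration_s:
            rr = base_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
            t += rr / 1000.0
            times.append((t, rr))
        ts = np.array([x[0] for x in times])
        rr = np.array([x[1] for x in times])
        return RRSeries(subject_id=subject_id, session_id="sess", times_s=ts,
                        rr_ms=rr,
                        phase_marks=phase_marks or {"story": (0.0, duration_s)})

    return make
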