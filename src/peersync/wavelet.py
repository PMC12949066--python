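"""Continuous Morlet wavelet transform and dyadic cross-wavelet synchrony.

The transform convolves the (mean-centred, zero-padded) signal with
time-sampled analytic Morlet daughters, carried out via FFT. Because the
daughters are sampled in the time domain, the FFT route is numerically
identical to brute-force convolution — the equivalence the oracle tests
assert.

Cross-wavelet power |W_a . conj(W_b)| is reduced to per-band maxima over
consecutive 20-second intervals, truncated to a common phase length, and
z-scored against the pooled sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import UniformHeartRate

__all__ = [
    "WaveletSpec",
    "CWTResult",
    "CrossWaveletSpectrum",
    "SynchronySeries",
    "cwt",
    "cwt_brute_force",
    "cross_power",
    "band_interval_max",
    "truncate_and_zscore",
    "HF_SYNC_BAND",
    "LF_SYNC_BAND",
]

logger = logging.getLogger(__name__)

HF_SYNC_BAND = (0.125, 0.5)
LF_SYNC_BAND = (0.031, 0.125)

#: phase lengths (minutes) every dyad is truncated to before pooling
STORY_MINUTES = 8
DISCUSSION_MINUTES = 10


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet transform configuration."""

    omega0: float = 6.0
    scales_per_octave: int = 12
    freq_min_hz: float = 0.031
    freq_max_hz: float = 0.5
    pad_pow2: bool = True

    @property
    def fourier_factor(self) -> float:
        """Wavelength-per-scale conversion for the Morlet mother."""
        return 4.0 * np.pi / (self.omega0 + np.sqrt(2.0 + self.omega0**2))

    def scales(self, dt: float) -> np.ndarray:
        """Geometric scale grid covering [freq_min, freq_max] entirely."""
        s_min = 1.0 / (self.fourier_factor * self.freq_max_hz)
        s_max = 1.0 / (self.fourier_factor * self.freq_min_hz)
        n_oct = np.log2(s_max / s_min)
        j = np.arange(int(np.ceil(n_oct * self.scales_per_octave)) + 1)
        return s_min * 2.0 ** (j / self.scales_per_octave)

    def frequencies(self, dt: float) -> np.ndarray:
        return 1.0 / (self.fourier_factor * self.scales(dt))

    def efold_time(self, scale: float) -> float:
        return np.sqrt(2.0) * scale


@dataclass(frozen=True)
class CWTResult:
    """Complex wavelet coefficients on a (scale x time) grid."""

    subject_id: str
    phase_label: str
    t0_s: float
    dt_s: float
    freqs_hz: np.ndarray          # descending
    scales: np.ndarray
    coeffs: np.ndarray            # (n_scales, n_times) complex
    coi_freq_hz: np.ndarray       # per-time lowest reliable frequency


@dataclass(frozen=True)
class CrossWaveletSpectrum:
    dyad_id: str
    phase_label: str
    t0_s: float
    dt_s: float
    freqs_hz: np.ndarray
    power: np.ndarray             # (n_scales, n_times), >= 0
    coi_freq_hz: np.ndarray


@dataclass
class SynchronySeries:
    """Per-dyad, per-phase 20-s band maxima of cross-wavelet power."""

    dyad_id: str
    group_id: str
    phase_label: str
    hf_raw: np.ndarray
    lf_raw: np.ndarray
    hf_z: np.ndarray | None = None
    lf_z: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_intervals(self) -> int:
        return int(np.asarray(self.hf_raw).size)


def _morlet_daughter(eta: np.ndarray, omega0: float) -> np.ndarray:
    return np.pi ** (-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)


def _pad_length(n: int, pad_pow2: bool) -> int:
    if not pad_pow2:
        return 2 * n
    return int(2 ** np.ceil(np.log2(2 * n)))


def cwt(hr: UniformHeartRate, spec: WaveletSpec = WaveletSpec()) -> CWTResult:
    """Morlet CWT of a uniformly sampled heart-rate trajectory.

    The signal is mean-centred and zero-padded (next power of two) before
    the FFT-based convolution with each scaled daughter wavelet.
    """
    x = np.asarray(hr.hr_bpm, dtype=float)
    n = x.size
    dt = 1.0 / hr.sample_rate_hz
    scales = spec.scales(dt)
    if n * dt < 2.0 * spec.efold_time(scales[-1]):
        raise ValueError(
            f"signal of {n * dt:.0f} s is shorter than twice the largest "
            f"wavelet support ({2 * spec.efold_time(scales[-1]):.0f} s)"
        )
    npad = _pad_length(n, spec.pad_pow2)
    xp = np.zeros(npad)
    xp[:n] = x - x.mean()
    xhat = np.fft.fft(xp)

    # daughters sampled in time on the padded circular grid (eta = k*dt/s,
    # negative lags wrapped), so the FFT product equals direct convolution
    k = np.fft.fftfreq(npad, d=1.0 / npad)  # 0,1,...,-1 ordering of lags
    lags = k * dt
    coeffs = np.empty((scales.size, n), dtype=complex)
    for i, s in enumerate(scales):
        psi = np.sqrt(dt / s) * _morlet_daughter(lags / s, spec.omega0)
        w = np.fft.ifft(xhat * np.conj(np.fft.fft(psi)))
        coeffs[i] = w[:n]

    freqs = 1.0 / (spec.fourier_factor * scales)
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    with np.errstate(divide="ignore"):
        coi = np.sqrt(2.0) / (spec.fourier_factor * t_edge)
    return CWTResult(
        subject_id=hr.subject_id,
        phase_label=hr.phase_label,
        t0_s=hr.t0_s,
        dt_s=dt,
        freqs_hz=freqs,
        scales=scales,
        coeffs=coeffs,
        coi_freq_hz=coi,
    )


def cwt_brute_force(
    x: np.ndarray, dt: float, spec: WaveletSpec = WaveletSpec()
) -> np.ndarray:
    """Direct time-domain convolution oracle for :func:`cwt`.

    Computes, for each scale s and output time index m,
    ``sum_k x0[k] * sqrt(dt/s) * conj(psi((k - m) dt / s))`` over the same
    zero-padded circular grid the FFT route uses. O(n * npad * n_scales);
    only for short signals in tests.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    scales = spec.scales(dt)
    npad = _pad_length(n, spec.pad_pow2)
    xp = np.zeros(npad)
    xp[:n] = x - x.mean()
    idx = np.arange(npad)
    out = np.empty((scales.size, n), dtype=complex)
    for i, s in enumerate(scales):
        for m in range(n):
            lag = (idx - m) % npad
            lag = np.where(lag >= npad // 2, lag - npad, lag)
            psi = np.sqrt(dt / s) * _morlet_daughter(lag * dt / s, spec.omega0)
            out[i, m] = np.sum(xp * np.conj(psi))
    return out


def cross_power(a: CWTResult, b: CWTResult) -> CrossWaveletSpectrum:
    """Pointwise cross-wavelet power |W_a . conj(W_b)| (order-invariant)."""
    if a.coeffs.shape != b.coeffs.shape or not np.array_equal(a.freqs_hz, b.freqs_hz):
        raise ValueError("wavelet transforms are on different time/scale grids")
    if a.dt_s != b.dt_s or a.t0_s != b.t0_s:
        raise ValueError("wavelet transforms are not time-aligned")
    # |W_a . conj(W_b)| = |W_a| |W_b|; computed factor-wise so the result is
    # bit-identical under member swap
    power = np.abs(a.coeffs) * np.abs(b.coeffs)
    coi = np.maximum(a.coi_freq_hz, b.coi_freq_hz)
    return CrossWaveletSpectrum(
        dyad_id=f"{a.subject_id}-{b.subject_id}",
        phase_label=a.phase_label,
        t0_s=a.t0_s,
        dt_s=a.dt_s,
        freqs_hz=a.freqs_hz,
        power=power,
        coi_freq_hz=coi,
    )


def band_interval_max(
    spectrum: CrossWaveletSpectrum,
    band: tuple[float, float],
    interval_s: float = 20.0,
    coi_mask: bool = True,
) -> np.ndarray:
    """Maximum cross-wavelet power per consecutive ``interval_s`` block.

    The maximum runs over every time point in the interval and every
    frequency bin whose centre lies inside ``band`` (inclusive). Samples
    below the cone-of-influence bound are excluded when ``coi_mask`` is on;
    an interval with every in-band sample masked yields NaN.
    """
    f = spectrum.freqs_hz
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError(f"band {band} outside spectrum coverage "
                         f"[{f.min():.3f}, {f.max():.3f}] Hz")
    p = spectrum.power[in_band].copy()
    if coi_mask:
        unreliable = f[in_band][:, None] < spectrum.coi_freq_hz[None, :]
        p[unreliable] = np.nan
    n_t = p.shape[1]
    step = int(round(interval_s / spectrum.dt_s))
    n_intervals = n_t // step
    out = np.full(n_intervals, np.nan)
    for i in range(n_intervals):
        block = p[:, i * step:(i + 1) * step]
        if np.any(np.isfinite(block)):
            out[i] = np.nanmax(block)
    return out


_PHASE_BINS = {
    "story": STORY_MINUTES * 3,        # 20-s bins
    "discussion": DISCUSSION_MINUTES * 3,
}


def truncate_and_zscore(
    all_series: list[SynchronySeries],
    story_min: int = STORY_MINUTES,
    discussion_min: int = DISCUSSION_MINUTES,
) -> list[SynchronySeries]:
    """Truncate phase series to common lengths and z-score per band.

    Truncation keeps the first 8 minutes (story) / 10 minutes (discussion)
    of 20-s bins; series shorter than their target are dropped with a
    warning. Z-scoring subtracts/divides the pooled mean/SD (ddof=1) over
    all retained dyads, phases and intervals, separately for each band.
    """
    targets = {"story": story_min * 3, "discussion": discussion_min * 3}
    kept: list[SynchronySeries] = []
    for s in all_series:
        target = targets.get(s.phase_label)
        if target is None:
            target = s.n_intervals
        if s.n_intervals < target:
            warnings.warn(
                f"dropping {s.dyad_id}/{s.phase_label}: "
                f"{s.n_intervals} < {target} intervals",
                stacklevel=2,
            )
            continue
        kept.append(
            replace(s, hf_raw=np.asarray(s.hf_raw, dtype=float)[:target],
                    lf_raw=np.asarray(s.lf_raw, dtype=float)[:target])
        )
    if not kept:
        return kept

    for band in ("hf", "lf"):
        pooled = np.concatenate([getattr(s, f"{band}_raw") for s in kept])
        pooled = pooled[np.isfinite(pooled)]
        mu = pooled.mean()
        sd = pooled.std(ddof=1)
        for s in kept:
            raw = getattr(s, f"{band}_raw")
            setattr(s, f"{band}_z", (raw - mu) / sd)
    return kept


def synchrony_frame(all_series: list[SynchronySeries]) -> pd.DataFrame:
    """Long-format table: one row per dyad x phase x 20-s interval."""
    rows = []
    for s in all_series:
        for i in range(s.n_intervals):
            rows.append(
                {
                    "dyad_id": s.dyad_id,
                    "group_id": s.group_id,
                    "phase": s.phase_label,
                    "interval_index": i,
                    "hf_raw": s.hf_raw[i],
                    "lf_raw": s.lf_raw[i],
                    "hf_z": s.hf_z[i] if s.hf_z is not None else np.nan,
                    "lf_z": s.lf_z[i] if s.lf_z is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def plot_synchrony_trajectories(frame: pd.DataFrame, out_path=None):
    """Mean z-scored synchrony over interval index, one line per band/phase."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, band in zip(axes, ("hf_z", "lf_z")):
        for phase, grp in frame.groupby("phase"):
            mean = grp.groupby("interval_index")[band].mean()
            ax.plot(mean.index * 20 / 60.0, mean.values, label=phase)
        ax.set_title(band.replace("_z", "").upper() + " synchrony")
        ax.set_xlabel("minutes")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.legend()
    axes[0].set_ylabel("z-scored cross-wavelet power")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
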