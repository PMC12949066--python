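"""Beat-interval (R-R) preprocessing.

Reads raw beat-interval exports, applies artifact correction (relative-change
outlier rule), fills long gaps by interpolation, flags subjects whose data
were changed too heavily, and resamples to an evenly sampled heart-rate
trajectory per task phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "RRSeries",
    "PreprocessReport",
    "UniformHeartRate",
    "read_rr_export",
    "correct_outliers",
    "interpolate_gaps",
    "preprocess_series",
    "resample_heart_rate",
    "make_report",
]

#: subjects are dropped when at least this fraction of beats was changed
EXCLUSION_FRACTION = 0.10


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat interval sequence for one subject and session.

    ``times_s`` holds the beat timestamps in seconds from session start and
    ``rr_ms`` the interval (in milliseconds) ending at that beat.
    ``phase_marks`` maps phase labels to ``(start_s, end_s)`` windows.
    """

    subject_id: str
    session_id: str
    times_s: np.ndarray
    rr_ms: np.ndarray
    phase_marks: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "rr_ms", rr)
        if t.shape != rr.shape:
            raise ValueError("times_s and rr_ms must have equal length")
        if rr.size and np.any(rr <= 0):
            raise ValueError("all rr intervals must be positive")
        if rr.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")
        _check_phases(self.phase_marks)

    @property
    def n_beats(self) -> int:
        return int(self.rr_ms.size)

    def phase_slice(self, phase: str) -> "RRSeries":
        """Restrict the series to beats inside a phase window."""
        if phase not in self.phase_marks:
            raise KeyError(f"phase {phase!r} not marked in series")
        start, end = self.phase_marks[phase]
        keep = (self.times_s >= start) & (self.times_s <= end)
        return replace(
            self,
            times_s=self.times_s[keep],
            rr_ms=self.rr_ms[keep],
            phase_marks={phase: (start, end)},
        )


def _check_phases(phase_marks: dict[str, tuple[float, float]]) -> None:
    windows = sorted(phase_marks.values())
    for (s0, e0), (s1, _e1) in zip(windows, windows[1:]):
        if e0 > s1:
            raise ValueError("phase windows overlap")
    for s, e in windows:
        if e <= s:
            raise ValueError("phase window must have positive duration")


@dataclass
class PreprocessReport:
    """Bookkeeping of how many beats the correction rules touched."""

    subject_id: str
    n_beats_in: int
    n_removed: int = 0
    n_synthesized: int = 0
    reasons: list[str] = field(default_factory=list)

    @property
    def n_modified(self) -> int:
        return self.n_removed + self.n_synthesized

    @property
    def fraction_modified(self) -> float:
        if self.n_beats_in == 0:
            return 0.0
        return self.n_modified / self.n_beats_in

    @property
    def excluded(self) -> bool:
        return self.fraction_modified >= EXCLUSION_FRACTION

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        if other.subject_id != self.subject_id:
            raise ValueError("cannot merge reports for different subjects")
        return PreprocessReport(
            subject_id=self.subject_id,
            n_beats_in=self.n_beats_in,
            n_removed=self.n_removed + other.n_removed,
            n_synthesized=self.n_synthesized + other.n_synthesized,
            reasons=self.reasons + other.reasons,
        )

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_beats_in": self.n_beats_in,
            "n_removed": self.n_removed,
            "n_synthesized": self.n_synthesized,
            "n_modified": self.n_modified,
            "fraction_modified": self.fraction_modified,
            "excluded": self.excluded,
            "reasons": "; ".join(self.reasons),
        }


def make_report(subject_id: str, n_beats_in: int, n_removed: int = 0,
                n_synthesized: int = 0) -> PreprocessReport:
    return PreprocessReport(subject_id, n_beats_in, n_removed, n_synthesized)


@dataclass(frozen=True)
class UniformHeartRate:
    """Evenly sampled heart-rate trajectory (bpm) for one subject and phase."""

    subject_id: str
    phase_label: str
    t0_s: float
    sample_rate_hz: float
    hr_bpm: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        hr = np.asarray(self.hr_bpm, dtype=float)
        vm = np.asarray(self.valid_mask, dtype=bool)
        object.__setattr__(self, "hr_bpm", hr)
        object.__setattr__(self, "valid_mask", vm)
        if hr.shape != vm.shape:
            raise ValueError("hr_bpm and valid_mask must have equal length")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.hr_bpm.size) / self.sample_rate_hz

    def plausibility_warnings(self, lo: float = 40.0, hi: float = 220.0) -> list[str]:
        out = []
        bad = (self.hr_bpm < lo) | (self.hr_bpm > hi)
        if np.any(bad & self.valid_mask):
            out.append(
                f"{self.subject_id}/{self.phase_label}: "
                f"{int(np.sum(bad & self.valid_mask))} samples outside "
                f"[{lo}, {hi}] bpm"
            )
        return out


def read_rr_export(
    path,
    *,
    delimiter: str = ",",
    rr_column: str | int = 0,
    time_column: str | int | None = None,
    header: bool = False,
    subject_id: str = "",
    session_id: str = "",
    phase_marks: dict[str, tuple[float, float]] | None = None,
) -> RRSeries:
    """Read a chest-strap logger export (one beat interval in ms per row).

    When no timestamp column exists, cumulative timestamps are reconstructed
    from the intervals themselves: the first beat lands at ``rr[0]/1000`` s.
    """
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                     dtype=str, skip_blank_lines=True, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty beat-interval file")

    def _col(key):
        if isinstance(key, int):
            return df.iloc[:, key]
        return df[key]

    raw = _col(rr_column)
    rr = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(rr))
    if bad.size:
        line = int(bad[0]) + 1 + (1 if header else 0)
        raise ValueError(
            f"{path}: non-numeric beat interval {raw.iloc[bad[0]]!r} on line {line}"
        )
    if np.any(rr <= 0):
        line = int(np.flatnonzero(rr <= 0)[0]) + 1 + (1 if header else 0)
        raise ValueError(f"{path}: non-positive beat interval on line {line}")

    if time_column is not None:
        t = pd.to_numeric(_col(time_column), errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            line = int(np.flatnonzero(~np.isfinite(t))[0]) + 1 + (1 if header else 0)
            raise ValueError(f"{path}: non-numeric timestamp on line {line}")
    else:
        t = np.cumsum(rr) / 1000.0

    return RRSeries(
        subject_id=subject_id or str(path),
        session_id=session_id,
        times_s=t,
        rr_ms=rr,
        phase_marks=phase_marks or {},
    )


def correct_outliers(
    series: RRSeries, threshold: float = 0.30
) -> tuple[RRSeries, PreprocessReport]:
    """Drop beats whose interval differs from the previous retained beat by
    strictly more than ``threshold`` (relative). The first beat is always
    kept; removals leave gaps for :func:`interpolate_gaps` to handle.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if series.n_beats == 0:
        raise ValueError("cannot correct an empty series")

    rr = series.rr_ms
    keep = np.ones(rr.size, dtype=bool)
    prev = rr[0]
    for i in range(1, rr.size):
        if abs(rr[i] - prev) / prev > threshold:
            keep[i] = False
        else:
            prev = rr[i]
    n_removed = int(np.sum(~keep))
    out = replace(series, times_s=series.times_s[keep], rr_ms=rr[keep])
    report = PreprocessReport(series.subject_id, series.n_beats, n_removed=n_removed)
    if n_removed:
        report.reasons.append(f"{n_removed} beats removed by >{threshold:.0%} rule")
    return out, report


def interpolate_gaps(
    series: RRSeries, max_gap_s: float = 2.0
) -> tuple[RRSeries, PreprocessReport]:
    """Fill inter-beat gaps longer than ``max_gap_s`` with synthetic beats.

    Synthetic beat intervals ramp linearly (in time) between the flanking
    retained beats; each synthesized beat counts as a modified data point.
    Gaps at the series boundary have no flanking value and are left open.
    """
    t, rr = series.times_s, series.rr_ms
    report = PreprocessReport(series.subject_id, series.n_beats)
    if t.size < 2:
        return series, report

    new_t: list[float] = [t[0]]
    new_rr: list[float] = [rr[0]]
    n_syn = 0
    for i in range(1, t.size):
        gap = t[i] - t[i - 1]
        if gap > max_gap_s:
            # linear rr ramp across the gap; spacing equals the local rr
            t_left, t_right = t[i - 1], t[i]
            rr_left, rr_right = rr[i - 1], rr[i]
            cur = t_left
            while True:
                frac = (cur - t_left) / (t_right - t_left)
                rr_here = rr_left + frac * (rr_right - rr_left)
                nxt = cur + rr_here / 1000.0
                # stop when the next synthetic beat would crowd the right flank
                if nxt >= t_right - 0.5 * rr_right / 1000.0:
                    break
                new_t.append(nxt)
                new_rr.append(rr_here)
                n_syn += 1
                cur = nxt
        new_t.append(t[i])
        new_rr.append(rr[i])
    report.n_synthesized = n_syn
    if n_syn:
        report.reasons.append(f"{n_syn} beats synthesized in gaps > {max_gap_s} s")
    # boundary gaps have no flanking beat on one side and stay unfilled
    if series.phase_marks:
        first = min(s for s, _e in series.phase_marks.values())
        last = max(e for _s, e in series.phase_marks.values())
        if t[0] - first > max_gap_s:
            report.reasons.append(
                f"unfilled boundary gap of {t[0] - first:.1f} s at series start")
        if last - t[-1] > max_gap_s:
            report.reasons.append(
                f"unfilled boundary gap of {last - t[-1]:.1f} s at series end")
    out = replace(series, times_s=np.asarray(new_t), rr_ms=np.asarray(new_rr))
    return out, report


def preprocess_series(
    series: RRSeries,
    threshold: float = 0.30,
    max_gap_s: float = 2.0,
) -> tuple[RRSeries, PreprocessReport]:
    """Outlier removal followed by gap interpolation, with one merged report.

    ``fraction_modified`` is (removed + synthesized) / original beat count;
    the subject is flagged ``excluded`` when it reaches 10%.
    """
    n_in = series.n_beats
    corrected, rep1 = correct_outliers(series, threshold=threshold)
    filled, rep2 = interpolate_gaps(corrected, max_gap_s=max_gap_s)
    merged = PreprocessReport(
        subject_id=series.subject_id,
        n_beats_in=n_in,
        n_removed=rep1.n_removed,
        n_synthesized=rep2.n_synthesized,
        reasons=rep1.reasons + rep2.reasons,
    )
    if merged.excluded:
        merged.reasons.append(
            f"excluded: {merged.fraction_modified:.1%} of beats changed"
        )
    return filled, merged


def resample_heart_rate(
    series: RRSeries, phase: str, rate_hz: float = 1.0
) -> UniformHeartRate:
    """Evaluate instantaneous heart rate (60000/rr) on the beat grid and
    interpolate it onto a uniform grid spanning the phase window.

    Interpolation is shape-preserving piecewise cubic (no overshoot) inside
    the beat span, with nearest-value fill at the edges.
    """
    sub = series.phase_slice(phase)
    if sub.n_beats < 10:
        raise ValueError(
            f"phase {phase!r} has only {sub.n_beats} beats; need at least 10"
        )
    start, end = series.phase_marks[phase]
    n = int(np.floor((end - start) * rate_hz)) + 1
    grid = start + np.arange(n) / rate_hz

    hr_beats = 60000.0 / sub.rr_ms
    interp = PchipInterpolator(sub.times_s, hr_beats, extrapolate=False)
    hr = interp(grid)
    valid = np.isfinite(hr)
    # nearest-value fill outside beat coverage
    if not valid.all():
        hr[grid < sub.times_s[0]] = hr_beats[0]
        hr[grid > sub.times_s[-1]] = hr_beats[-1]
    return UniformHeartRate(
        subject_id=series.subject_id,
        phase_label=phase,
        t0_s=start,
        sample_rate_hz=rate_hz,
        hr_bpm=hr,
        valid_mask=valid,
    )
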