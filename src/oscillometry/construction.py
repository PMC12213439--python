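"""Automated construction of measured oscillograms from a cuff recording.

Pipeline over the slow-deflation segment of a cuff-pressure recording:

1. band-pass filter (6th-order Butterworth, 0.75-5 Hz, zero-phase) to extract
   the cuff-pressure oscillations;
2. low-pass filter (4th-order Butterworth, 0.3 Hz, zero-phase) to extract the
   applied cuff-pressure trend;
3. detect oscillation pulses, gated by amplitude thresholds (peaks must reach
   0.2 mmHg, valleys must dip to -0.1 mmHg) and by a pulse-interval rule
   relative to the FFT-estimated pulse rate (intervals outside
   [0.65/PR, 1.35/PR] are rejected);
4. compute per-pulse features relative to the chord connecting the pulse feet
   (height, area, area-to-height ratio, left/right area ratio);
5. assemble each feature against the cuff-pressure trend at the pulse peak,
   smooth with a 5-point centered moving average, trim the flat tails, flag
   inverted-U completeness, and optionally align/normalize.

Filters are applied forward-backward (zero phase, so pulse timing is not
shifted); the stated orders are the designed orders, and the effective order
is doubled by the two passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .models import OscillogramKind
from .simulator import CuffRecording
from .waveforms import SampledWaveform

__all__ = [
    "PulseFeatureRecord",
    "MeasuredOscillogram",
    "PulseDetectionError",
    "extract_oscillations",
    "extract_applied_pressure",
    "detect_pulses",
    "pulse_features",
    "assemble_oscillogram",
    "build_oscillograms",
]


@dataclass(frozen=True)
class PulseFeatureRecord:
    """Per-pulse features computed against the foot-to-foot chord baseline."""

    foot_start: int
    peak: int
    foot_end: int
    cuff_pressure_at_pulse: float  # mmHg, low-passed trend at the peak time
    height: float  # mmHg
    area: float  # mmHg*s
    area_to_height: float  # s
    left_right_area_ratio: float  # dimensionless


@dataclass(frozen=True)
class MeasuredOscillogram:
    """Feature-vs-cuff-pressure curve after smoothing, trimming, normalization."""

    kind: OscillogramKind
    cuff_pressures: np.ndarray  # mmHg, ascending, within [Pc_min, Pc_max]
    amplitudes: np.ndarray
    Pc_min: float
    Pc_max: float
    normalized: bool
    complete: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", OscillogramKind(self.kind))
        Pc = np.asarray(self.cuff_pressures, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        if Pc.shape != amp.shape or Pc.ndim != 1:
            raise ValueError("cuff_pressures and amplitudes must be equal-length 1-D arrays")
        if self.Pc_min >= self.Pc_max:
            raise ValueError("require Pc_min < Pc_max")
        object.__setattr__(self, "cuff_pressures", Pc)
        object.__setattr__(self, "amplitudes", amp)


class PulseDetectionError(RuntimeError):
    """No pulses survived gating; carries per-rule rejection counts."""

    def __init__(self, message: str, rejections: dict[str, int]):
        super().__init__(f"{message} (rejections: {rejections})")
        self.rejections = rejections


def _deflation_window(rec: CuffRecording) -> tuple[float, float]:
    return rec.protocol.deflation_start, rec.protocol.deflation_end


def extract_oscillations(
    rec: CuffRecording,
    band: tuple[float, float] = (0.75, 5.0),
    order: int = 6,
) -> SampledWaveform:
    """Band-passed cuff-pressure oscillations over the deflation segment.

    ``order`` is the designed band-pass order (must be even); zero-phase
    forward-backward application preserves pulse timing.
    """
    fs = rec.waveform.sampling_rate
    if fs < 2.0 * band[1]:
        raise ValueError("sampling rate must be at least twice the upper band edge")
    if order % 2:
        raise ValueError("band-pass order must be even")
    t0, t1 = _deflation_window(rec)
    if rec.waveform.duration < t1 - rec.waveform.times[0]:
        raise ValueError("recording too short to cover the deflation segment")
    sos = signal.butter(order // 2, band, btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.waveform.values)
    full = SampledWaveform(rec.waveform.times, filtered, fs)
    return full.slice_time(t0, t1)


def extract_applied_pressure(
    rec: CuffRecording,
    cutoff: float = 0.3,
    order: int = 4,
) -> SampledWaveform:
    """Low-passed applied cuff-pressure trend over the deflation segment."""
    fs = rec.waveform.sampling_rate
    t0, t1 = _deflation_window(rec)
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.waveform.values)
    full = SampledWaveform(rec.waveform.times, filtered, fs)
    return full.slice_time(t0, t1)


def estimate_pulse_rate(
    osc: SampledWaveform, band: tuple[float, float] = (0.75, 3.0)
) -> float:
    """Dominant periodogram frequency within the physiological pulse band, Hz."""
    freqs, power = signal.periodogram(osc.values, fs=osc.sampling_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask) or not np.any(power[mask] > 0):
        raise ValueError("no spectral power in the pulse-rate search band")
    return float(freqs[mask][np.argmax(power[mask])])


def detect_pulses(
    osc: SampledWaveform,
    peak_min: float = 0.2,
    valley_max: float = -0.1,
    interval_lo: float = 0.65,
    interval_hi: float = 1.35,
    pr_band: tuple[float, float] = (0.75, 3.0),
    with_report: bool = False,
):
    """Detect gated oscillation pulses as (foot_start, peak, foot_end) indices.

    Candidate peaks below ``peak_min`` mmHg and valleys above ``valley_max``
    mmHg are rejected; a surviving peak is kept only if at least one of its
    peak-to-peak intervals to the neighbouring surviving peaks lies inside
    ``[interval_lo/PR, interval_hi/PR]`` where PR is the FFT-based pulse rate.
    Each retained pulse is delimited by its flanking retained valleys.
    """
    x = osc.values
    if x.size == 0:
        raise ValueError("empty oscillation signal")
    rejections = {"peak_amplitude": 0, "valley_amplitude": 0, "interval": 0, "missing_feet": 0}

    all_peaks, _ = signal.find_peaks(x)
    all_valleys, _ = signal.find_peaks(-x)
    peaks = all_peaks[x[all_peaks] >= peak_min]
    rejections["peak_amplitude"] = int(all_peaks.size - peaks.size)
    valleys = all_valleys[x[all_valleys] <= valley_max]
    rejections["valley_amplitude"] = int(all_valleys.size - valleys.size)

    if peaks.size == 0:
        raise PulseDetectionError("no pulses retained", rejections)

    pr = estimate_pulse_rate(osc, pr_band)
    lo, hi = interval_lo / pr, interval_hi / pr
    keep = np.zeros(peaks.size, dtype=bool)
    if peaks.size == 1:
        keep[0] = True  # no interval evidence against a lone peak
    else:
        intervals = np.diff(osc.times[peaks])
        ok = (intervals >= lo) & (intervals <= hi)
        keep[0] = ok[0]
        keep[-1] = ok[-1]
        for i in range(1, peaks.size - 1):
            keep[i] = ok[i - 1] or ok[i]
    rejections["interval"] = int(np.count_nonzero(~keep))
    peaks = peaks[keep]

    pulses: list[tuple[int, int, int]] = []
    for p in peaks:
        before = valleys[valleys < p]
        after = valleys[valleys > p]
        if before.size == 0 or after.size == 0:
            rejections["missing_feet"] += 1
            continue
        pulses.append((int(before[-1]), int(p), int(after[0])))

    if not pulses:
        raise PulseDetectionError("no pulses retained", rejections)
    if with_report:
        report = {"pulse_rate_hz": pr, "n_pulses": len(pulses), "rejections": rejections}
        return pulses, report
    return pulses


def pulse_features(
    osc: SampledWaveform,
    bounds: tuple[int, int, int],
    Pc_trend: SampledWaveform,
) -> PulseFeatureRecord:
    """Features of one pulse relative to its foot-to-foot chord baseline."""
    i0, ip, i1 = bounds
    if not i0 < ip < i1:
        raise ValueError(f"require foot_start < peak < foot_end, got {bounds}")
    t = osc.times[i0 : i1 + 1]
    y = osc.values[i0 : i1 + 1]
    chord = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    rel = y - chord
    k = ip - i0
    height = float(rel[k])
    if height <= 0:
        raise ValueError("degenerate pulse: peak does not rise above the foot chord")
    area = float(np.trapezoid(rel, t))
    left = float(np.trapezoid(rel[: k + 1], t[: k + 1]))
    right = area - left
    if area <= 0 or right <= 0 or left <= 0:
        raise ValueError("degenerate pulse: nonpositive area")
    Pc_at_peak = float(np.interp(osc.times[ip], Pc_trend.times, Pc_trend.values))
    return PulseFeatureRecord(
        foot_start=i0,
        peak=ip,
        foot_end=i1,
        cuff_pressure_at_pulse=Pc_at_peak,
        height=height,
        area=area,
        area_to_height=area / height,
        left_right_area_ratio=left / right,
    )


_FEATURE_ATTR = {
    OscillogramKind.HEIGHT: "height",
    OscillogramKind.AREA: "area",
    OscillogramKind.AREA_TO_HEIGHT: "area_to_height",
    OscillogramKind.AREA_RATIO: "left_right_area_ratio",
}

_INVERTED_U_KINDS = (OscillogramKind.HEIGHT, OscillogramKind.AREA, OscillogramKind.AREA_RATIO)


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with edge shrinking (window must be odd)."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        j0 = max(0, i - half)
        j1 = min(x.size, i + half + 1)
        out[i] = x[j0:j1].mean()
    return out


def _trim_bounds(amp: np.ndarray, i_ref: int, rise_run: int, floor_frac: float) -> tuple[int, int]:
    """Walk outward from the maximum; cut where the curve turns back up for
    ``rise_run`` consecutive samples or first falls below ``floor_frac`` of it."""
    floor = floor_frac * amp[i_ref]

    def walk(direction: int) -> int:
        last = i_ref
        rises = 0
        i = i_ref
        while True:
            j = i + direction
            if j < 0 or j >= amp.size:
                return last
            if amp[j] > amp[i]:
                rises += 1
                if rises >= rise_run:
                    return last
            else:
                rises = 0
                last = j
            if amp[j] < floor:
                return j  # include the first sub-floor sample as the end point
            i = j

    return walk(-1), walk(+1)


def assemble_oscillogram(
    features: Sequence[PulseFeatureRecord],
    kind: OscillogramKind | str,
    smooth_window: int = 5,
    trim_rise_run: int = 3,
    trim_floor_frac: float = 0.10,
    completeness_frac: float = 0.80,
    align: bool = False,
    normalize: bool = False,
) -> MeasuredOscillogram:
    """Assemble, smooth, trim, and optionally align/normalize an oscillogram.

    Points are sorted by ascending cuff pressure, smoothed by a centered
    moving average, and tail-trimmed by walking outward from the maximum
    (flat-tail rule: a sustained rise of ``trim_rise_run`` samples or a fall
    below ``trim_floor_frac`` of the maximum ends the curve).  For inverted-U
    kinds the completeness flag requires both trimmed ends to fall to at most
    ``completeness_frac`` of the maximum.  Alignment shifts the fiducial point
    (maximum; minimum for the area-to-height kind) to 0 mmHg.
    """
    kind = OscillogramKind(kind)
    if len(features) < smooth_window:
        raise ValueError(f"need at least {smooth_window} pulses, got {len(features)}")
    attr = _FEATURE_ATTR[kind]
    Pc = np.array([f.cuff_pressure_at_pulse for f in features], dtype=float)
    amp = np.array([getattr(f, attr) for f in features], dtype=float)
    order = np.argsort(Pc)
    Pc, amp = Pc[order], amp[order]
    amp = moving_average(amp, smooth_window)

    inverted_u = kind in _INVERTED_U_KINDS
    if inverted_u:
        i_ref = int(np.argmax(amp))
        j0, j1 = _trim_bounds(amp, i_ref, trim_rise_run, trim_floor_frac)
        Pc, amp = Pc[j0 : j1 + 1], amp[j0 : j1 + 1]
        i_ref -= j0
        peak = amp[i_ref]
        complete = bool(amp[0] <= completeness_frac * peak and amp[-1] <= completeness_frac * peak)
    else:
        i_ref = int(np.argmin(amp))
        complete = True

    if align:
        Pc = Pc - Pc[i_ref]
    if normalize:
        peak = float(np.max(amp))
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero oscillogram")
        amp = amp / peak
    return MeasuredOscillogram(
        kind=kind,
        cuff_pressures=Pc,
        amplitudes=amp,
        Pc_min=float(Pc[0]),
        Pc_max=float(Pc[-1]),
        normalized=normalize,
        complete=complete,
    )


def build_oscillograms(
    rec: CuffRecording,
    kinds: Sequence[OscillogramKind | str] = (OscillogramKind.HEIGHT, OscillogramKind.AREA),
    normalize: bool = True,
    align: bool = False,
    **assemble_kwargs,
):
    """Run the full construction pipeline on a recording.

    Returns ``(oscillograms, qc)`` where ``oscillograms`` maps kind to
    :class:`MeasuredOscillogram` and ``qc`` is a QC report dict (pulse counts,
    rejections per rule, trim bounds, completeness flags).
    """
    osc = extract_oscillations(rec)
    trend = extract_applied_pressure(rec)
    pulses, report = detect_pulses(osc, with_report=True)
    # pulse indices re-expressed on the full recording grid (the oscillation
    # signal is the deflation-segment slice)
    offset = int(round((osc.times[0] - rec.waveform.times[0]) * rec.waveform.sampling_rate))
    report["pulse_windows"] = [(i0 + offset, i1 + offset) for i0, _, i1 in pulses]
    features = []
    n_degenerate = 0
    for bounds in pulses:
        try:
            features.append(pulse_features(osc, bounds, trend))
        except ValueError:
            n_degenerate += 1
    report["rejections"]["degenerate"] = n_degenerate
    out = {}
    qc = dict(report)
    qc["oscillograms"] = {}
    for kind in kinds:
        kind = OscillogramKind(kind)
        measured = assemble_oscillogram(
            features, kind, align=align, normalize=normalize, **assemble_kwargs
        )
        out[kind] = measured
        qc["oscillograms"][kind.value] = {
            "Pc_min": measured.Pc_min,
            "Pc_max": measured.Pc_max,
            "n_points": int(measured.amplitudes.size),
            "complete": measured.complete,
        }
    return out, qc
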