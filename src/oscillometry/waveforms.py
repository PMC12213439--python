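"""Blood-pressure input waveforms and cuff deflation protocols.

Generates the deterministic inputs the forward simulator consumes: a sampled
triangular BP pulse train (the shape assumed by the closed-form area model), a
smoother band-limited surrogate for a real arterial waveform, and the
fast-inflation / slow-deflation / constant-hold cuff pressure protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BPPulseSpec

INFLATION_DURATION_S = 5.0  # fixed fast-inflation segment; discarded by construction


@dataclass(frozen=True)
class CuffProtocol:
    """Cuff pressure protocol: fast inflation, slow linear deflation, hold.

    Defaults: inflate to 180 mmHg, deflate at 3 mmHg/s (clinical range is
    2-4 mmHg/s) down to a 60 mmHg hold, sampled at 250 Hz.
    """

    inflate_to: float = 180.0
    deflation_rate: float = 3.0
    hold_pressure: float = 60.0
    hold_duration: float = 10.0
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.inflate_to <= self.hold_pressure:
            raise ValueError("inflate_to must exceed hold_pressure")
        if self.deflation_rate <= 0 or self.sampling_rate <= 0 or self.hold_duration < 0:
            raise ValueError("deflation_rate and sampling_rate must be positive")

    @property
    def deflation_duration(self) -> float:
        return (self.inflate_to - self.hold_pressure) / self.deflation_rate

    @property
    def deflation_start(self) -> float:
        return INFLATION_DURATION_S

    @property
    def deflation_end(self) -> float:
        return INFLATION_DURATION_S + self.deflation_duration

    @property
    def total_duration(self) -> float:
        return self.deflation_end + self.hold_duration


@dataclass(frozen=True)
class SampledWaveform:
    """Uniformly sampled waveform: times in s, values in mmHg."""

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("times and values must be equal-length 1-D arrays (n >= 2)")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise ValueError("waveform samples must be finite")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-6:
            raise ValueError("sampling must be uniform at the stated rate (1e-6 s jitter allowed)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def slice_time(self, t0: float, t1: float) -> "SampledWaveform":
        """Sub-waveform with t0 <= t <= t1 (inclusive)."""
        mask = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        if np.count_nonzero(mask) < 2:
            raise ValueError(f"time window [{t0}, {t1}] selects fewer than 2 samples")
        return SampledWaveform(self.times[mask], self.values[mask], self.sampling_rate)


def triangular_pulse_value(t, spec: BPPulseSpec) -> np.ndarray:
    """Exact triangular pulse: periodic rise Pd->Ps over Ts, fall over T-Ts."""
    t = np.asarray(t, dtype=float)
    tau = t - spec.T * np.floor(t / spec.T)
    rising = tau < spec.Ts
    out = np.where(
        rising,
        spec.Pd + spec.PP * tau / spec.Ts,
        spec.Ps - spec.PP * (tau - spec.Ts) / (spec.T - spec.Ts),
    )
    return out


def triangular_bp(spec: BPPulseSpec, n_beats: int, sampling_rate: float = 250.0) -> SampledWaveform:
    """Sampled triangular BP pulse train with exact period ``spec.T``."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    n = int(round(n_beats * spec.T * sampling_rate))
    times = np.arange(n) / sampling_rate
    return SampledWaveform(times, triangular_pulse_value(times, spec), sampling_rate)


def _pulse_template(harmonics: int, n_grid: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited arterial-pulse template: Fourier truncation of a skewed bump.

    The underlying shape ``phi^2 (1-phi)^6`` peaks early in the beat, giving
    the sharper upstroke / slower downstroke of an arterial pulse while
    remaining C1-periodic.  Returns cosine/sine coefficients for harmonics
    1..harmonics (the DC term is irrelevant after per-beat rescaling).
    """
    phi = np.arange(n_grid) / n_grid
    shape = phi**2 * (1.0 - phi) ** 6
    spec = np.fft.rfft(shape) / n_grid
    k = np.arange(1, harmonics + 1)
    return 2.0 * spec[k].real, -2.0 * spec[k].imag


def _eval_template(phi: np.ndarray, ak: np.ndarray, bk: np.ndarray) -> np.ndarray:
    k = np.arange(1, ak.size + 1)
    ang = 2.0 * np.pi * np.outer(phi, k)
    return np.cos(ang) @ ak + np.sin(ang) @ bk


def realistic_bp(
    spec: BPPulseSpec,
    harmonics: int = 8,
    beat_jitter: float = 0.0,
    seed: int | None = None,
    n_beats: int = 10,
    sampling_rate: float = 250.0,
) -> SampledWaveform:
    """Smooth band-limited BP surrogate with per-beat extrema pinned to Ps/Pd.

    Each beat is the truncated-Fourier template rescaled so its maximum equals
    ``Ps`` and its minimum ``Pd`` exactly.  ``beat_jitter`` (s, SD) perturbs
    beat durations reproducibly under ``seed``.
    """
    if harmonics < 2:
        raise ValueError("harmonics must be >= 2")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)
    durations = np.full(n_beats, spec.T)
    if beat_jitter > 0:
        durations = durations + rng.normal(0.0, beat_jitter, size=n_beats)
        durations = np.clip(durations, 0.5 * spec.T, 1.5 * spec.T)
    ak, bk = _pulse_template(harmonics)
    segments = []
    for T_i in durations:
        n_i = max(int(round(T_i * sampling_rate)), 4)
        phi = np.arange(n_i) / n_i
        raw = _eval_template(phi, ak, bk)
        lo, hi = raw.min(), raw.max()
        segments.append(spec.Pd + spec.PP * (raw - lo) / (hi - lo))
    values = np.concatenate(segments)
    times = np.arange(values.size) / sampling_rate
    return SampledWaveform(times, values, sampling_rate)


def cuff_ramp(protocol: CuffProtocol, duration: float | None = None) -> SampledWaveform:
    """Cuff pressure: 5 s linear inflation from 0, linear deflation, constant hold."""
    if duration is None:
        duration = protocol.total_duration
    t_infl = INFLATION_DURATION_S
    t_defl_end = protocol.deflation_end
    if duration < t_defl_end:
        raise ValueError(
            f"duration {duration:.1f} s too short to reach the hold pressure "
            f"(deflation ends at {t_defl_end:.1f} s)"
        )
    n = int(round(duration * protocol.sampling_rate))
    t = np.arange(n) / protocol.sampling_rate
    values = np.empty_like(t)
    infl = t < t_infl
    values[infl] = protocol.inflate_to * t[infl] / t_infl
    defl = (~infl) & (t < t_defl_end)
    values[defl] = protocol.inflate_to - protocol.deflation_rate * (t[defl] - t_infl)
    hold = t >= t_defl_end
    values[hold] = protocol.hold_pressure
    return SampledWaveform(t, values, protocol.sampling_rate)
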