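"""Forward simulation of cuff-pressure recordings.

Transforms a BP waveform and a cuff-pressure ramp into the blood-volume
waveform of the artery under the cuff and then into observed cuff-pressure
oscillations, under three cuff-arm-artery system hypotheses:

* **elastic** — the volume is the static sigmoid of transmural pressure,
  ``V(t) = f(Pa(t) - Pc(t))``;
* **hammerstein** — static nonlinearity followed by a linear damper: the
  elastic volume is passed through a first-order unity-gain low-pass with
  cutoff ``w`` (rad/s), representing cuff-arm-artery viscoelasticity;
* **wiener** — damper first: the transmural pressure is low-pass filtered,
  then mapped through the sigmoid.

Volume oscillations become cuff-pressure oscillations through a scale factor:
either a constant ``k`` (mmHg/mL) or the variable ``kv(t) = Pc(t)/Patm + 1``
accounting for compression of the cuff air column by the arterial pulsation.
A physical Boyle's-law model of the cuff-arm system is also provided, which
maps enclosed volume and pumped-air volume to cuff pressure through an
implicit equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .compliance import ComplianceParams, volume
from .waveforms import CuffProtocol, SampledWaveform, cuff_ramp

__all__ = [
    "SystemKind",
    "SystemConfig",
    "ScaleMode",
    "ScaleConfig",
    "CuffMechanics",
    "CuffRecording",
    "first_order_lowpass",
    "simulate_volume",
    "to_oscillations",
    "boyle_cuff_pressure",
    "synthesize_recording",
]

DEFAULT_PATM_MMHG = 760.0


class SystemKind(str, Enum):
    ELASTIC = "elastic"
    HAMMERSTEIN = "hammerstein"
    WIENER = "wiener"


@dataclass(frozen=True)
class SystemConfig:
    """Cuff-arm-artery system hypothesis and viscoelastic cutoff.

    ``cutoff`` is the first-order low-pass cutoff in rad/s (reported in Hz as
    ``cutoff / 2 pi``); ignored for the elastic system.
    """

    system: SystemKind = SystemKind.ELASTIC
    cutoff: float = 2.0 * np.pi * 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", SystemKind(self.system))
        if self.system is not SystemKind.ELASTIC and not (
            np.isfinite(self.cutoff) and self.cutoff > 0
        ):
            raise ValueError("cutoff (rad/s) must be positive for viscoelastic systems")

    @property
    def cutoff_hz(self) -> float:
        return self.cutoff / (2.0 * np.pi)


class ScaleMode(str, Enum):
    CONSTANT = "constant"
    VARIABLE = "variable"


@dataclass(frozen=True)
class ScaleConfig:
    """Volume-to-cuff-pressure oscillation scale: constant k or variable kv."""

    mode: ScaleMode = ScaleMode.CONSTANT
    k: float = 1.0
    Patm: float = DEFAULT_PATM_MMHG

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ScaleMode(self.mode))
        if self.k <= 0 or self.Patm <= 0:
            raise ValueError("k and Patm must be positive")

    def factor(self, Pc: np.ndarray) -> np.ndarray:
        if self.mode is ScaleMode.CONSTANT:
            return np.full_like(np.asarray(Pc, dtype=float), self.k)
        return np.asarray(Pc, dtype=float) / self.Patm + 1.0


@dataclass(frozen=True)
class CuffMechanics:
    """Physical cuff-arm parameters for the Boyle's-law cuff model.

    ``Ec`` (mmHg) and ``n`` set the power-law cuff elasticity, ``Vc0`` (mL) is
    the cuff air volume at zero cuff pressure, ``Vi0`` (mL) the incompressible
    arm volume.  The linearized oscillation-scale approximation requires
    ``Vi0 + Vc0 << Ec``; construction warns (via ``regime_ok``) when violated.
    """

    Ec: float = 1.0e7
    n: float = 1.0
    Vc0: float = 200.0
    Vi0: float = 800.0
    Patm: float = DEFAULT_PATM_MMHG

    def __post_init__(self) -> None:
        if min(self.Ec, self.n, self.Vc0, self.Vi0, self.Patm) <= 0:
            raise ValueError("all cuff mechanics parameters must be positive")

    @property
    def regime_ok(self) -> bool:
        """True when the Vi0 + Vc0 << Ec simplification is justified."""
        return self.Ec >= 100.0 * (self.Vi0 + self.Vc0)


@dataclass(frozen=True)
class CuffRecording:
    """Raw cuff-pressure recording plus its protocol and provenance metadata."""

    waveform: SampledWaveform
    protocol: CuffProtocol
    metadata: dict[str, Any] = field(default_factory=dict)


def first_order_lowpass(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """First-order unity-gain low-pass, cutoff in rad/s, bilinear discretization.

    The filter state is initialized at the first sample's steady state, so a
    constant input passes through unchanged from the first sample.
    """
    b, a = signal.bilinear([cutoff], [1.0, cutoff], fs=fs)
    zi = signal.lfilter_zi(b, a) * x[0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def _check_same_grid(u: SampledWaveform, v: SampledWaveform) -> None:
    if u.times.shape != v.times.shape or not np.allclose(u.times, v.times, atol=1e-9):
        raise ValueError("waveforms must share the same time grid")


def simulate_volume(
    Pa: SampledWaveform,
    Pc: SampledWaveform,
    params: ComplianceParams,
    sys: SystemConfig = SystemConfig(),
) -> SampledWaveform:
    """Blood-volume waveform (mL) under the configured system hypothesis."""
    _check_same_grid(Pa, Pc)
    P = Pa.values - Pc.values
    fs = Pa.sampling_rate
    if sys.system is SystemKind.ELASTIC:
        V = volume(P, params)
    elif sys.system is SystemKind.HAMMERSTEIN:
        V = first_order_lowpass(volume(P, params), sys.cutoff, fs)
    else:  # wiener
        V = volume(first_order_lowpass(P, sys.cutoff, fs), params)
    return SampledWaveform(Pa.times, V, fs)


def to_oscillations(
    V: SampledWaveform,
    Pc: SampledWaveform,
    scale: ScaleConfig = ScaleConfig(),
    highpass_cutoff: float = 0.5,
) -> SampledWaveform:
    """Cuff-pressure oscillations (mmHg) from the blood-volume waveform.

    High-pass filters the volume (2nd-order Butterworth, zero-phase; cutoff in
    Hz, 0 disables filtering) and applies the volume-to-pressure scale factor
    samplewise.
    """
    _check_same_grid(V, Pc)
    x = V.values
    if highpass_cutoff > 0:
        sos = signal.butter(2, highpass_cutoff, btype="highpass", fs=V.sampling_rate, output="sos")
        x = signal.sosfiltfilt(sos, x)
    osc = x * scale.factor(Pc.values)
    return SampledWaveform(V.times, osc, V.sampling_rate)


def _boyle_residual(Pc: float, Va_num: float, V_solid: float, mech: CuffMechanics) -> float:
    """Residual of the implicit cuff equation at candidate pressure Pc.

    Air volume in the cuff follows Boyle's law, Va = Patm (Vp + Vc0)/(Pc + Patm);
    the enclosed total volume Va + Vi0 + V loads the power-law cuff elasticity
    Pc = Ec ((Vout/Vout0)^(1/n) - 1)^n with Vout0 = Vi0 + Vc0.

    The fractional volume excess Vout/Vout0 - 1 is tiny when Ec is large, so
    it is computed without cancellation (log1p/expm1); otherwise the Ec-scaled
    elasticity term would carry an O(Ec * eps) round-off floor.
    """
    vout0 = mech.Vi0 + mech.Vc0
    delta = (Va_num / (Pc + mech.Patm) - mech.Vc0 + (V_solid - mech.Vi0)) / vout0
    if delta <= 0.0:
        return Pc
    stretch = np.expm1(np.log1p(delta) / mech.n)
    return Pc - mech.Ec * stretch**mech.n


def boyle_cuff_pressure(V: SampledWaveform, mech: CuffMechanics, Vp) -> SampledWaveform:
    """Cuff pressure from enclosed blood volume and pumped-air volume.

    Solves the implicit Boyle's-law/cuff-elasticity equation per sample by
    bracketed Brent iteration on ``[0, 10 Ec]``; the residual at the returned
    pressure is below 1e-9 mmHg.  ``Vp`` (mL) may be a scalar or an array on
    the same grid.
    """
    Vp = np.broadcast_to(np.asarray(Vp, dtype=float), V.values.shape)
    if np.any(V.values + mech.Vi0 <= 0):
        raise ValueError("V + Vi0 must stay positive")
    out = np.empty_like(V.values)
    for i, (v, vp) in enumerate(zip(V.values, Vp)):
        va_num = mech.Patm * (vp + mech.Vc0)
        v_solid = mech.Vi0 + v
        lo, hi = 0.0, 10.0 * mech.Ec
        r_lo = _boyle_residual(lo, va_num, v_solid, mech)
        r_hi = _boyle_residual(hi, va_num, v_solid, mech)
        if r_lo == 0.0:
            out[i] = lo
            continue
        if r_lo * r_hi > 0:
            raise ValueError(
                f"no sign change of the cuff equation residual on [0, {hi:.3g}] mmHg "
                f"at sample {i} (V={v:.3g} mL, Vp={vp:.3g} mL)"
            )
        pc = brentq(
            _boyle_residual, lo, hi, args=(va_num, v_solid, mech), xtol=1e-12, rtol=8.9e-16
        )
        # Newton polish: the residual slope scales with Ec, so the Brent
        # x-tolerance alone does not guarantee a sub-1e-9-mmHg residual.
        for _ in range(3):
            r = _boyle_residual(pc, va_num, v_solid, mech)
            if abs(r) < 1e-11:
                break
            vout0 = mech.Vi0 + mech.Vc0
            delta = (va_num / (pc + mech.Patm) - mech.Vc0 + (v_solid - mech.Vi0)) / vout0
            ddelta = -va_num / ((pc + mech.Patm) ** 2 * vout0)
            if delta > 0:
                stretch = np.expm1(np.log1p(delta) / mech.n)
                dstretch = (1.0 + stretch) / (mech.n * (1.0 + delta)) * ddelta
                dr = 1.0 - mech.Ec * mech.n * stretch ** (mech.n - 1.0) * dstretch
            else:
                dr = 1.0
            pc = pc - r / dr
        out[i] = pc
    return SampledWaveform(V.times, out, V.sampling_rate)


def synthesize_recording(
    bp: SampledWaveform,
    protocol: CuffProtocol,
    params: ComplianceParams,
    sys: SystemConfig = SystemConfig(),
    scale: ScaleConfig = ScaleConfig(),
    noise_sd: float = 0.0,
    seed: int | None = None,
    highpass_cutoff: float = 0.5,
) -> CuffRecording:
    """Compose a full synthetic cuff recording with known ground truth.

    Builds the protocol's pressure ramp over the BP waveform's duration,
    simulates the blood volume, converts it to oscillations, superimposes them
    on the ramp, and adds optional white Gaussian noise (mmHg SD, seeded).
    Ground-truth parameters are embedded in the recording metadata.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = bp.values.size
    duration = n / protocol.sampling_rate
    ramp = cuff_ramp(protocol, duration)
    if ramp.values.size != n:
        raise ValueError("BP waveform and protocol ramp sample counts disagree")
    if abs(bp.sampling_rate - protocol.sampling_rate) > 1e-9:
        raise ValueError("BP waveform must be sampled at the protocol rate")
    V = simulate_volume(bp, ramp, params, sys)
    osc = to_oscillations(V, ramp, scale, highpass_cutoff=highpass_cutoff)
    values = ramp.values + osc.values
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=n)
    metadata = {
        "b": params.width_neg,
        "c": params.width_pos,
        "a": params.amplitude,
        "form": params.form.value,
        "system": sys.system.value,
        "cutoff_rad_s": sys.cutoff if sys.system is not SystemKind.ELASTIC else None,
        "scale_mode": scale.mode.value,
        "k": scale.k,
        "Patm": scale.Patm,
        "Ps": float(np.max(bp.values)),
        "Pd": float(np.min(bp.values)),
        "noise_sd": noise_sd,
        "seed": seed,
        "highpass_cutoff_hz": highpass_cutoff,
    }
    wf = SampledWaveform(ramp.times, values, protocol.sampling_rate)
    return CuffRecording(wf, protocol, metadata)
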