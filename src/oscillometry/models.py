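r"""Closed-form height- and area-oscillogram models and their peak positions.

An oscillogram is a per-pulse oscillation feature plotted against the applied
cuff pressure ``Pc``.  With the exponential-linear compliance sigmoid
(``compliance`` module), both the conventional *height* oscillogram

    OH(Pc) = k [ f(Ps - Pc) - f(Pd - Pc) ]

and the *area* oscillogram (per-beat oscillation area above the diastolic
level, for a triangular pressure pulse of beat duration ``T``)

    OA(Pc) = k [ \int_0^T f(Pa(t) - Pc) dt - T f(Pd - Pc) ]

admit closed forms.  Because the triangular pulse sweeps pressure linearly in
time, the time integral reduces to a pressure integral and the systolic
duration drops out of OA entirely; only the antiderivative of ``f`` appears.
The models are evaluated here as explicit piecewise expressions over the three
regions ``Pc < Pd``, ``Pd <= Pc < Ps``, ``Pc >= Ps`` (half-open boundary
membership; the expressions are continuous across the boundaries, so the
convention is irrelevant to ~1e-15).

The scale ``d = a * k`` (arterial compliance amplitude times the
volume-to-cuff-pressure scale factor) multiplies both models and is removed by
normalization, leaving four interpretable parameters: the compliance-curve
widths ``b`` and ``c`` and the systolic/diastolic pressures ``Ps`` and ``Pd``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BPPulseSpec",
    "OscillogramKind",
    "ModelOscillogram",
    "height_model",
    "area_model",
    "peak_pressure_height",
    "peak_pressure_height_weights",
    "peak_pressure_area",
    "peak_pressure_area_simplified",
    "normalize",
]


@dataclass(frozen=True)
class BPPulseSpec:
    """Triangular blood-pressure pulse: systolic/diastolic levels and timing.

    ``Ps``/``Pd`` in mmHg, beat duration ``T`` and systolic (rise) duration
    ``Ts`` in seconds.  Pulse pressure ``PP = Ps - Pd``.
    """

    Ps: float
    Pd: float
    T: float = 1.0
    Ts: float = 0.3

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.Ps, self.Pd, self.T, self.Ts])):
            raise ValueError("pulse spec values must be finite")
        if self.Ps <= self.Pd:
            raise ValueError(f"require Ps > Pd, got Ps={self.Ps}, Pd={self.Pd}")
        if not 0 < self.Ts < self.T:
            raise ValueError(f"require 0 < Ts < T, got Ts={self.Ts}, T={self.T}")

    @property
    def PP(self) -> float:
        return self.Ps - self.Pd


class OscillogramKind(str, Enum):
    HEIGHT = "height"
    AREA = "area"
    AREA_TO_HEIGHT = "area_to_height"
    AREA_RATIO = "area_ratio"


@dataclass(frozen=True)
class ModelOscillogram:
    """Model oscillogram sampled on an ascending cuff-pressure grid."""

    kind: OscillogramKind
    cuff_pressures: np.ndarray
    amplitudes: np.ndarray
    scale: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        Pc = np.asarray(self.cuff_pressures, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        if Pc.shape != amp.shape or Pc.ndim != 1:
            raise ValueError("cuff_pressures and amplitudes must be equal-length 1-D arrays")
        object.__setattr__(self, "cuff_pressures", Pc)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "kind", OscillogramKind(self.kind))


def _check_bc(b: float, c: float) -> None:
    if not (np.isfinite(b) and np.isfinite(c) and b > 0 and c > 0):
        raise ValueError(f"widths must be finite and positive, got b={b}, c={c}")


def _check_bp(Ps: float, Pd: float) -> None:
    if not (np.isfinite(Ps) and np.isfinite(Pd)) or Ps <= Pd:
        raise ValueError(f"require finite Ps > Pd, got Ps={Ps}, Pd={Pd}")


def _height_amplitude(Pc: np.ndarray, b: float, c: float, Ps: float, Pd: float) -> np.ndarray:
    """Unit-scale height oscillogram, explicit three-region piecewise form."""
    out = np.empty_like(Pc)
    xd = Pd - Pc  # transmural pressure at diastole
    xs = Ps - Pc  # transmural pressure at systole

    r1 = Pc < Pd  # artery pressurized throughout the beat: xd, xs > 0
    r3 = Pc >= Ps  # artery collapsed throughout: xd, xs <= 0
    r2 = ~(r1 | r3)

    out[r1] = (xd[r1] + 2 * c) * np.exp(-xd[r1] / c) - (xs[r1] + 2 * c) * np.exp(-xs[r1] / c)
    out[r2] = (
        2 * (b + c)
        + (xd[r2] - 2 * b) * np.exp(xd[r2] / b)
        - (xs[r2] + 2 * c) * np.exp(-xs[r2] / c)
    )
    out[r3] = (xd[r3] - 2 * b) * np.exp(xd[r3] / b) - (xs[r3] - 2 * b) * np.exp(xs[r3] / b)
    return out


def height_model(
    Pc_grid: Sequence[float],
    b: float,
    c: float,
    Ps: float,
    Pd: float,
    d: float = 1.0,
) -> ModelOscillogram:
    """Height oscillogram model OH(Pc) on a cuff-pressure grid.

    Nonnegative, continuous across the region boundaries ``Pc = Pd`` and
    ``Pc = Ps``, and decaying to zero as ``Pc`` moves far outside
    ``[Pd, Ps]``.  Amplitudes in mmHg for a scale ``d`` in mmHg (per unit
    normalized sigmoid).
    """
    _check_bc(b, c)
    _check_bp(Ps, Pd)
    Pc = np.atleast_1d(np.asarray(Pc_grid, dtype=float))
    if not np.all(np.isfinite(Pc)):
        raise ValueError("cuff pressure grid must be finite")
    amp = d * _height_amplitude(Pc, b, c, Ps, Pd)
    # Clamp the ~1e-16-level negative round-off in the far tails.
    np.clip(amp, 0.0, None, out=amp)
    return ModelOscillogram(OscillogramKind.HEIGHT, Pc, amp, scale=d)


def _f_unit(x: np.ndarray, b: float, c: float) -> np.ndarray:
    """Unit-amplitude volume sigmoid (exp-linear form)."""
    out = np.empty_like(x)
    neg = x < 0
    out[neg] = (2 * b - x[neg]) * np.exp(x[neg] / b)
    out[~neg] = 2 * (b + c) - (2 * c + x[~neg]) * np.exp(-x[~neg] / c)
    return out


def _F_unit(x: np.ndarray, b: float, c: float) -> np.ndarray:
    """Antiderivative of the unit-amplitude volume sigmoid, continuous at 0."""
    out = np.empty_like(x)
    neg = x < 0
    out[neg] = b * (3 * b - x[neg]) * np.exp(x[neg] / b)
    xp = x[~neg]
    out[~neg] = 2 * (b + c) * xp + c * (3 * c + xp) * np.exp(-xp / c) + 3 * (b * b - c * c)
    return out


def _g_unit(x: np.ndarray, b: float, c: float) -> np.ndarray:
    """Unit-amplitude compliance curve (exp-linear form)."""
    w = np.where(x < 0, b, c)
    z = np.abs(x) / w
    return np.exp(-z) * (1.0 + z)


def area_model(
    Pc_grid: Sequence[float],
    b: float,
    c: float,
    Ps: float,
    Pd: float,
    d: float = 1.0,
    T: float = 1.0,
) -> ModelOscillogram:
    """Area oscillogram model OA(Pc), mmHg*s, on a cuff-pressure grid.

    Closed-form solution of the per-beat area integral for a triangular
    pressure pulse; linear in both ``T`` and ``d`` and independent of the
    systolic duration (which cancels exactly in the integration).
    """
    _check_bc(b, c)
    _check_bp(Ps, Pd)
    if not (np.isfinite(T) and T > 0):
        raise ValueError(f"beat duration T must be positive, got {T}")
    Pc = np.atleast_1d(np.asarray(Pc_grid, dtype=float))
    if not np.all(np.isfinite(Pc)):
        raise ValueError("cuff pressure grid must be finite")
    PP = Ps - Pd
    xd = Pd - Pc
    xs = Ps - Pc
    if PP < 1e-5 * (b + c):
        # Vanishing-pulse-pressure limit: the generic expression divides the
        # antiderivative difference by PP and loses all precision; use the
        # first-order expansion OA -> d T (PP/2) g(Pd - Pc) instead.
        amp = d * T * (PP / 2.0) * _g_unit(xd, b, c)
    else:
        amp = d * T * ((_F_unit(xs, b, c) - _F_unit(xd, b, c)) / PP - _f_unit(xd, b, c))
    # Clamp the ~1e-16-level negative round-off in the far tails.
    np.clip(amp, 0.0, None, out=amp)
    return ModelOscillogram(OscillogramKind.AREA, Pc, amp, scale=d)


def peak_pressure_height(b: float, c: float, Ps: float, Pd: float) -> float:
    """Cuff pressure at the height-oscillogram maximum.

    ``PHmax = Pd + b (Ps - Pd)/(b + c)``, a weighted average of ``Ps`` and
    ``Pd`` with weights ``b/(b+c)`` and ``c/(b+c)``; always inside
    ``(Pd, Ps)``.  The same expression holds for both compliance forms.
    """
    _check_bc(b, c)
    _check_bp(Ps, Pd)
    return Pd + b * (Ps - Pd) / (b + c)


def peak_pressure_height_weights(b: float, c: float) -> tuple[float, float]:
    """Weights (on Ps, on Pd) of the height-peak weighted-average formula."""
    _check_bc(b, c)
    return b / (b + c), c / (b + c)


def _area_peak_condition(Pc: float, b: float, c: float, Ps: float, Pd: float, form: str):
    """Stationarity condition of the area oscillogram, dOA/dPc = 0.

    For exp_linear this is f(Pd-Pc) - f(Ps-Pc) + PP*g(Pd-Pc) = 0, valid in all
    three regions; for the exp form it reduces to
    (beta+PP) e^{(Pd-Pc)/beta} + gamma e^{(Pc-Ps)/gamma} - (beta+gamma).
    """
    PP = Ps - Pd
    xd = np.atleast_1d(np.asarray(Pd - Pc, dtype=float))
    xs = np.atleast_1d(np.asarray(Ps - Pc, dtype=float))
    if form == "exp_linear":
        val = _f_unit(xd, b, c) - _f_unit(xs, b, c) + PP * _g_unit(xd, b, c)
    else:
        fd = np.where(xd < 0, b * np.exp(np.minimum(xd, 0) / b),
                      b + c * (1 - np.exp(-np.maximum(xd, 0) / c)))
        fs = np.where(xs < 0, b * np.exp(np.minimum(xs, 0) / b),
                      b + c * (1 - np.exp(-np.maximum(xs, 0) / c)))
        gd = np.where(xd < 0, np.exp(np.minimum(xd, 0) / b), np.exp(-np.maximum(xd, 0) / c))
        val = fd - fs + PP * gd
    return float(val[0])


def peak_pressure_area(
    b: float,
    c: float,
    Ps: float,
    Pd: float,
    form: str = "exp_linear",
    xtol: float = 1e-8,
) -> float:
    """Cuff pressure at the area-oscillogram maximum (numeric root).

    The stationarity condition has no closed-form solution; it is solved by
    bracketed Brent root finding on ``(Pd - 5(b+c), Ps)``, expanding the lower
    end toward -inf if the root is not initially bracketed.
    """
    _check_bc(b, c)
    _check_bp(Ps, Pd)
    form = ComplianceFormStr(form)
    lo = Pd - 5.0 * (b + c)
    hi = Ps
    f_hi = _area_peak_condition(hi, b, c, Ps, Pd, form)
    f_lo = _area_peak_condition(lo, b, c, Ps, Pd, form)
    n_expand = 0
    while f_lo * f_hi > 0 and n_expand < 60:
        lo -= 10.0 * (b + c)
        f_lo = _area_peak_condition(lo, b, c, Ps, Pd, form)
        n_expand += 1
    if f_lo * f_hi > 0:
        raise ValueError(
            f"area-peak condition not bracketed on [{lo:.3g}, {hi:.3g}] "
            f"(b={b}, c={c}, Ps={Ps}, Pd={Pd})"
        )
    return float(brentq(_area_peak_condition, lo, hi, args=(b, c, Ps, Pd, form), xtol=xtol))


def ComplianceFormStr(form: str) -> str:
    form = str(getattr(form, "value", form))
    if form not in ("exp_linear", "exp"):
        raise ValueError(f"form must be 'exp_linear' or 'exp', got {form!r}")
    return form


def peak_pressure_area_simplified(beta: float, gamma: float, Ps: float, Pd: float) -> float:
    """Closed approximation to the area-peak position for the exp form.

    ``PAmax = Pd + beta * ln((beta + PP)/(beta + gamma))``; obtained by
    dropping the small second exponential term of the exact stationarity
    condition.
    """
    _check_bc(beta, gamma)
    _check_bp(Ps, Pd)
    PP = Ps - Pd
    return Pd + beta * np.log((beta + PP) / (beta + gamma))


def normalize(osc: ModelOscillogram) -> ModelOscillogram:
    """Scale the oscillogram to unit maximum, eliminating the ``d`` scale.

    Idempotent; raises on an all-zero oscillogram.
    """
    peak = float(np.max(osc.amplitudes))
    if peak <= 0:
        raise ValueError("cannot normalize an oscillogram with no positive amplitude")
    return replace(osc, amplitudes=osc.amplitudes / peak, scale=1.0, normalized=True)
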