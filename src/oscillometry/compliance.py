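"""Arterial compliance and blood-volume sigmoids.

The oscillometric models in this package rest on a sigmoidal relationship
between the transmural pressure of an artery (``P = Pa - Pc``, internal blood
pressure minus external cuff pressure, mmHg) and the blood volume it holds.
The sigmoid is the integral of a unimodal "arterial compliance curve" ``g(P)``
that peaks at zero transmural pressure.  Two parameterizations are supported:

``exp_linear``
    ``g(P) = a * exp(-|P|/w) * (1 + |P|/w)`` with ``w = b`` for ``P < 0`` and
    ``w = c`` for ``P > 0``.  ``a`` is the maximal compliance (mL/mmHg) at
    ``P = 0``; ``b`` and ``c`` are the widths (mmHg) of the compliance curve
    over the negative and positive transmural ranges.

``exp``
    ``g(P) = a * exp(-|P|/w)``, a simpler two-sided exponential with analogous
    parameters (often written alpha, beta, gamma).

The blood volume is ``f(P) = integral of g``, anchored so that
``f(-inf) = 0``.  Both branches agree at ``P = 0`` (the unit step there is
taken as 1; the two formula branches evaluate identically, so the convention
is observationally irrelevant).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class ComplianceForm(str, Enum):
    """Functional form of the arterial compliance curve."""

    EXP_LINEAR = "exp_linear"
    EXP = "exp"


@dataclass(frozen=True)
class ComplianceParams:
    """Parameters of the arterial compliance sigmoid.

    Parameters
    ----------
    amplitude : float
        Compliance at zero transmural pressure, mL/mmHg (``a`` / alpha).
    width_neg : float
        Width over the negative transmural range, mmHg (``b`` / beta).
    width_pos : float
        Width over the positive transmural range, mmHg (``c`` / gamma).
    form : ComplianceForm
        ``exp_linear`` (default) or ``exp``.
    """

    amplitude: float
    width_neg: float
    width_pos: float
    form: ComplianceForm = ComplianceForm.EXP_LINEAR

    def __post_init__(self) -> None:
        for name in ("amplitude", "width_neg", "width_pos"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")
        object.__setattr__(self, "form", ComplianceForm(self.form))

    @property
    def plateau(self) -> float:
        """Blood volume as P -> +inf, mL."""
        a, b, c = self.amplitude, self.width_neg, self.width_pos
        if self.form is ComplianceForm.EXP_LINEAR:
            return 2.0 * a * (b + c)
        return a * (b + c)


def _validate_pressure(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("transmural pressure must be finite")
    return P


def compliance(P, params: ComplianceParams) -> np.ndarray:
    """Arterial compliance ``g(P)`` in mL/mmHg.

    Continuous everywhere, strictly positive, and maximal at ``P = 0`` where it
    equals ``params.amplitude`` for both functional forms.
    """
    P = _validate_pressure(P)
    a, b, c = params.amplitude, params.width_neg, params.width_pos
    width = np.where(P < 0, b, c)
    # |P|/width with the exponent kept nonpositive: exp never overflows.
    z = np.abs(P) / width
    if params.form is ComplianceForm.EXP_LINEAR:
        out = a * np.exp(-z) * (1.0 + z)
    else:
        out = a * np.exp(-z)
    return out


def volume(P, params: ComplianceParams) -> np.ndarray:
    """Blood volume sigmoid ``f(P)`` in mL (``f(-inf) = 0``)."""
    P = _validate_pressure(P)
    a, b, c = params.amplitude, params.width_neg, params.width_pos
    neg = P < 0
    out = np.empty_like(P, dtype=float)
    if params.form is ComplianceForm.EXP_LINEAR:
        Pn = P[neg]
        out[neg] = a * (2.0 * b - Pn) * np.exp(Pn / b)
        Pp = P[~neg]
        out[~neg] = 2.0 * a * (b + c) - a * (2.0 * c + Pp) * np.exp(-Pp / c)
    else:
        out[neg] = a * b * np.exp(P[neg] / b)
        out[~neg] = a * (b + c) - a * c * np.exp(-P[~neg] / c)
    return out


def volume_antiderivative(P, params: ComplianceParams) -> np.ndarray:
    """Antiderivative ``F(P)`` of the volume sigmoid, continuous at 0.

    Used by the closed-form area-oscillogram model: integrating the volume
    sigmoid over the linear rise/fall of a triangular pressure pulse reduces to
    differences of ``F``.  Anchored so ``F(-inf) = 0``.
    """
    P = _validate_pressure(P)
    a, b, c = params.amplitude, params.width_neg, params.width_pos
    neg = P < 0
    out = np.empty_like(P, dtype=float)
    if params.form is ComplianceForm.EXP_LINEAR:
        Pn = P[neg]
        out[neg] = a * b * (3.0 * b - Pn) * np.exp(Pn / b)
        Pp = P[~neg]
        out[~neg] = (
            2.0 * a * (b + c) * Pp
            + a * c * (3.0 * c + Pp) * np.exp(-Pp / c)
            + 3.0 * a * (b * b - c * c)
        )
    else:
        out[neg] = a * b * b * np.exp(P[neg] / b)
        Pp = P[~neg]
        out[~neg] = a * (b + c) * Pp + a * c * c * np.exp(-Pp / c) + a * (b * b - c * c)
    return out
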