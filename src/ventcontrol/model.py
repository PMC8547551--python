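"""Steady-state model of chemoreflex control of breathing.

The model has two components:

* the **isometabolic (metabolic) hyperbola** linking alveolar ventilation
  ``VA`` (L/min, BTPS) to alveolar/arterial CO2 tension ``paCO2`` (mmHg) at a
  fixed metabolic CO2 production ``V̇CO2`` (ml/min, STPD):

  .. math:: VA = 0.863 \\cdot \\dot{V}CO_2 / paCO_2

* the **chemosensitivity line**: ventilation rises linearly with paCO2 above
  the apnea threshold (the paCO2 at which ventilation ceases), with slope
  equal to the controller gain (L/min/mmHg); below the threshold ventilation
  is zero.

The eupneic operating point is the intersection of the two curves.  From it
follow the derived quantities used throughout ventilatory-stability work:
plant gain (reciprocal slope of the hyperbola's tangent, mmHg per L/min),
loop gain (controller gain x plant gain, dimensionless), the CO2 reserve
(eupneic paCO2 minus apnea threshold) and the ventilatory (VA) reserve (the
ventilation increase that drives paCO2 down to the apnea threshold along the
hyperbola).

Alveolar and arterial CO2 tensions are treated as equal; "paCO2" is used for
both.  Units are fixed (ml/min, L/min, mmHg) and no automatic conversion is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "K_BTPS",
    "InvalidGeometryError",
    "MetabolicCurve",
    "ChemoController",
    "OperatingPoint",
    "metabolic_va",
    "controller_va",
    "derive_controller",
    "solve_eupnea",
    "plant_gain_at",
    "loop_gain",
]

#: Conversion constant of the isometabolic hyperbola: with CO2 production in
#: ml/min (STPD) and paCO2 in mmHg, ``0.863 * vco2 / paco2`` is alveolar
#: ventilation in L/min (BTPS).
K_BTPS: float = 0.863


class InvalidGeometryError(ValueError):
    """The requested configuration has no physiological solution."""


@dataclass(frozen=True)
class MetabolicCurve:
    """Isometabolic hyperbola ``VA = k * vco2 / paco2`` at fixed CO2 production.

    Parameters
    ----------
    vco2 : float
        Metabolic CO2 production in ml/min (STPD). Must be positive.
    """

    vco2: float
    #: fixed unit-conversion constant (class-level, not configurable)
    k = K_BTPS

    def __post_init__(self) -> None:
        if not self.vco2 > 0:
            raise InvalidGeometryError(f"vco2 must be positive, got {self.vco2!r}")

    def va(self, paco2: float) -> float:
        return metabolic_va(self, paco2)

    def plant_gain(self, paco2: float) -> float:
        return plant_gain_at(self, paco2)


@dataclass(frozen=True)
class ChemoController:
    """Rectified-linear chemosensitivity: ``VA = gain * (paco2 - apnea_threshold)``, floored at 0.

    Parameters
    ----------
    gain : float
        Controller gain (ventilatory response to CO2), L/min/mmHg; positive.
    apnea_threshold : float
        paCO2 at which ventilation ceases, mmHg; positive.
    """

    gain: float
    apnea_threshold: float

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise InvalidGeometryError(f"gain must be positive, got {self.gain!r}")
        if not self.apnea_threshold > 0:
            raise InvalidGeometryError(
                f"apnea_threshold must be positive, got {self.apnea_threshold!r}"
            )

    def va(self, paco2: float) -> float:
        return controller_va(self, paco2)


@dataclass(frozen=True)
class OperatingPoint:
    """Eupneic steady state with its derived gains and reserves.

    Attributes
    ----------
    paco2_eup : float
        paCO2 at eupneic ventilation, mmHg.
    va_eup : float
        Eupneic alveolar ventilation, L/min.
    plant_gain : float
        Reciprocal tangent slope of the hyperbola at eupnea, mmHg per L/min.
    loop_gain : float
        Controller gain x plant gain (dimensionless). Meaningful for
        *relative* change; it is not scaled to dynamic loop-gain measurements.
    co2_reserve : float
        paco2_eup minus the apnea threshold, mmHg.
    va_reserve : float
        Ventilation increase from eupnea that brings paCO2 down to the apnea
        threshold along the hyperbola, L/min.
    """

    paco2_eup: float
    va_eup: float
    plant_gain: float
    loop_gain: float
    co2_reserve: float
    va_reserve: float

    def as_record(self) -> dict[str, float]:
        """Flat mapping of named scalars (for serialization)."""
        return {
            "paco2_eup": self.paco2_eup,
            "va_eup": self.va_eup,
            "plant_gain": self.plant_gain,
            "loop_gain": self.loop_gain,
            "co2_reserve": self.co2_reserve,
            "va_reserve": self.va_reserve,
        }


def metabolic_va(curve: MetabolicCurve, paco2: float) -> float:
    """Alveolar ventilation (L/min) on the isometabolic hyperbola at ``paco2``."""
    if not paco2 > 0:
        raise InvalidGeometryError(f"paco2 must be positive, got {paco2!r}")
    return K_BTPS * curve.vco2 / paco2


def controller_va(ctrl: ChemoController, paco2: float) -> float:
    """Chemoreflex ventilation (L/min): linear above the apnea threshold, zero below."""
    if paco2 < 0:
        raise InvalidGeometryError(f"paco2 must be non-negative, got {paco2!r}")
    return max(0.0, ctrl.gain * (paco2 - ctrl.apnea_threshold))


def derive_controller(
    vco2: float, paco2_eup: float, apnea_threshold: float
) -> ChemoController:
    """Controller line fixed by the eupneic point on the hyperbola and the threshold.

    The slope is the ventilation at the eupneic point divided by the CO2
    reserve, so that the line passes through both the apnea threshold (zero
    ventilation) and the eupneic operating point.
    """
    if not vco2 > 0:
        raise InvalidGeometryError(f"vco2 must be positive, got {vco2!r}")
    if not apnea_threshold > 0:
        raise InvalidGeometryError(
            f"apnea_threshold must be positive, got {apnea_threshold!r}"
        )
    if not paco2_eup > apnea_threshold:
        raise InvalidGeometryError(
            f"eupneic paCO2 ({paco2_eup!r}) must exceed the apnea threshold "
            f"({apnea_threshold!r})"
        )
    va_eup = K_BTPS * vco2 / paco2_eup
    gain = va_eup / (paco2_eup - apnea_threshold)
    return ChemoController(gain=gain, apnea_threshold=apnea_threshold)


def solve_eupnea(curve: MetabolicCurve, ctrl: ChemoController) -> OperatingPoint:
    """Intersection of the chemosensitivity line and the isometabolic hyperbola.

    Setting ``gain * (p - AT) = k * vco2 / p`` gives the quadratic
    ``gain*p^2 - gain*AT*p - k*vco2 = 0`` whose unique root above the apnea
    threshold is taken in closed form:

    .. math:: p = \\tfrac{1}{2}\\left(AT + \\sqrt{AT^2 + 4 k \\dot{V}CO_2 / G}\\right)

    The root always exists for valid inputs (the discriminant exceeds AT^2),
    so no iteration or bracketing is needed.
    """
    at = ctrl.apnea_threshold
    kv = K_BTPS * curve.vco2
    paco2 = 0.5 * (at + math.sqrt(at * at + 4.0 * kv / ctrl.gain))
    va = kv / paco2
    pg = paco2 * paco2 / kv
    return OperatingPoint(
        paco2_eup=paco2,
        va_eup=va,
        plant_gain=pg,
        loop_gain=ctrl.gain * pg,
        co2_reserve=paco2 - at,
        va_reserve=kv / at - va,
    )


def plant_gain_at(curve: MetabolicCurve, paco2: float) -> float:
    """Plant gain (mmHg per L/min): reciprocal tangent slope of the hyperbola.

    Differentiating ``VA = k*vco2/p`` gives ``dVA/dp = -k*vco2/p^2``; the plant
    gain is the magnitude of its reciprocal, ``p^2/(k*vco2)``, which satisfies
    ``plant_gain * VA(p) = p`` identically.
    """
    if not paco2 > 0:
        raise InvalidGeometryError(f"paco2 must be positive, got {paco2!r}")
    return paco2 * paco2 / (K_BTPS * curve.vco2)


def loop_gain(gain: float, plant_gain: float) -> float:
    """Loop gain as the product of controller gain and plant gain."""
    if not (gain > 0 and plant_gain > 0):
        raise InvalidGeometryError("controller gain and plant gain must be positive")
    return gain * plant_gain
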