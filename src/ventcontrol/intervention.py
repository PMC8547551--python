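"""Intervention simulations on the steady-state control-of-breathing model.

An intervention is expressed as percent changes of up to three quantities:
the apnea threshold (a negative change is a left shift of the
chemosensitivity line, the primary effect of acetazolamide), metabolic CO2
production, and controller gain.  Applying an intervention re-solves the
eupneic operating point and reports the percent change of every derived
quantity, mirroring how model predictions are compared against pooled
empirical estimates.

Two sensitivity sweeps are provided:

* :func:`sweep_baseline` varies one baseline parameter (controller gain,
  eupneic paCO2, or CO2 production) across its physiological range while the
  other anchors are held at their pooled values, and reports the loop-gain
  change and its relative reduction ``RR = %dLG / %dLG0`` at each grid point;
* :func:`sweep_shift` varies the magnitude of the apnea-threshold left shift.

``%dLG0`` is the loop-gain change produced by the reference intervention at
the pooled baseline (about -21.8% for a pure -15% left shift), so RR > 1
marks baselines with a greater-than-reference loop-gain reduction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    K_BTPS,
    ChemoController,
    InvalidGeometryError,
    MetabolicCurve,
    OperatingPoint,
    derive_controller,
    solve_eupnea,
)

__all__ = [
    "BaselineInputs",
    "InterventionSpec",
    "ModelComparison",
    "SweepResult",
    "DEFAULT_BASELINE",
    "REFERENCE_INTERVENTIONS",
    "PHYSIOLOGICAL_RANGES",
    "apply_intervention",
    "compose_lg_change",
    "intervention_report",
    "sweep_baseline",
    "sweep_shift",
]


@dataclass(frozen=True)
class BaselineInputs:
    """The three scalars that fix the baseline system.

    vco2 : CO2 production, ml/min; paco2_eup : eupneic paCO2, mmHg;
    apnea_threshold : mmHg.  The controller gain is *derived* from these
    (the chemosensitivity line must pass through the eupneic point on the
    hyperbola and through the threshold).
    """

    vco2: float = 206.0
    paco2_eup: float = 38.2
    apnea_threshold: float = 33.5

    def __post_init__(self) -> None:
        if not self.vco2 > 0:
            raise InvalidGeometryError(f"vco2 must be positive, got {self.vco2!r}")
        if not self.paco2_eup > self.apnea_threshold > 0:
            raise InvalidGeometryError(
                "need paco2_eup > apnea_threshold > 0, got "
                f"paco2_eup={self.paco2_eup!r}, apnea_threshold={self.apnea_threshold!r}"
            )

    def controller(self) -> ChemoController:
        return derive_controller(self.vco2, self.paco2_eup, self.apnea_threshold)

    def solve(self) -> OperatingPoint:
        return solve_eupnea(MetabolicCurve(self.vco2), self.controller())


#: Pooled control-condition anchors (CO2 production 206 ml/min, eupneic paCO2
#: 38.2 mmHg, apnea threshold 33.5 mmHg).
DEFAULT_BASELINE = BaselineInputs()


@dataclass(frozen=True)
class InterventionSpec:
    """Percent changes applied multiplicatively to the baseline system.

    ``at_shift_pct``: percent change of the apnea threshold (negative = left
    shift); ``vco2_change_pct``: percent change of CO2 production;
    ``cg_change_pct``: percent change of controller gain.
    """

    at_shift_pct: float = 0.0
    vco2_change_pct: float = 0.0
    cg_change_pct: float = 0.0

    def __post_init__(self) -> None:
        for name, pct in (
            ("at_shift_pct", self.at_shift_pct),
            ("vco2_change_pct", self.vco2_change_pct),
            ("cg_change_pct", self.cg_change_pct),
        ):
            if pct <= -100.0:
                raise InvalidGeometryError(
                    f"{name}={pct!r} would make the parameter non-positive"
                )


#: The four standard acetazolamide scenarios: a -15% apnea-threshold left
#: shift alone, then combined with +9% CO2 production and/or -11% controller
#: gain, keyed by model id 1-4.
REFERENCE_INTERVENTIONS: dict[int, InterventionSpec] = {
    1: InterventionSpec(at_shift_pct=-15.0),
    2: InterventionSpec(at_shift_pct=-15.0, vco2_change_pct=9.0),
    3: InterventionSpec(at_shift_pct=-15.0, cg_change_pct=-11.0),
    4: InterventionSpec(at_shift_pct=-15.0, vco2_change_pct=9.0, cg_change_pct=-11.0),
}

#: Physiological sweep ranges per baseline parameter.
PHYSIOLOGICAL_RANGES: dict[str, tuple[float, float]] = {
    "controller_gain": (0.5, 3.0),
    "paco2_eup": (30.0, 50.0),
    "vco2": (155.0, 255.0),
}


@dataclass(frozen=True)
class ModelComparison:
    """Baseline vs. intervened operating point, with percent changes.

    Percent changes are exact (unrounded); :meth:`as_record` offers 1-decimal
    display companions.  ``delta_paco2_eup`` and ``delta_at`` are absolute
    changes in mmHg.
    """

    baseline: OperatingPoint
    treated: OperatingPoint
    d_va_eup_pct: float
    d_paco2_eup_pct: float
    d_co2_reserve_pct: float
    d_va_reserve_pct: float
    d_plant_gain_pct: float
    d_loop_gain_pct: float
    delta_paco2_eup: float
    delta_at: float

    def as_record(self, rounded: bool = True) -> dict[str, float]:
        rec = {
            "d_va_eup_pct": self.d_va_eup_pct,
            "d_paco2_eup_pct": self.d_paco2_eup_pct,
            "d_co2_reserve_pct": self.d_co2_reserve_pct,
            "d_va_reserve_pct": self.d_va_reserve_pct,
            "d_plant_gain_pct": self.d_plant_gain_pct,
            "d_loop_gain_pct": self.d_loop_gain_pct,
            "delta_paco2_eup_mmhg": self.delta_paco2_eup,
            "delta_at_mmhg": self.delta_at,
        }
        if rounded:
            rec.update({k + "_1dp": round(v, 1) for k, v in rec.items()})
        return rec


def _pct(new: float, old: float) -> float:
    return (new / old - 1.0) * 100.0


def apply_intervention(
    base: BaselineInputs, spec: InterventionSpec
) -> ModelComparison:
    """Apply percent changes to the baseline system and re-solve eupnea.

    The controller gain is derived from the baseline anchors; the
    intervention multiplies the apnea threshold by ``1 + at_shift_pct/100``,
    CO2 production by ``1 + vco2_change_pct/100`` and controller gain by
    ``1 + cg_change_pct/100``, and the new operating point is solved on the
    updated hyperbola.
    """
    ctrl0 = base.controller()
    before = solve_eupnea(MetabolicCurve(base.vco2), ctrl0)

    new_at = ctrl0.apnea_threshold * (1.0 + spec.at_shift_pct / 100.0)
    new_vco2 = base.vco2 * (1.0 + spec.vco2_change_pct / 100.0)
    new_gain = ctrl0.gain * (1.0 + spec.cg_change_pct / 100.0)
    if new_at <= 0 or new_vco2 <= 0 or new_gain <= 0:
        raise InvalidGeometryError("intervention drives a parameter non-positive")
    after = solve_eupnea(
        MetabolicCurve(new_vco2), ChemoController(gain=new_gain, apnea_threshold=new_at)
    )

    return ModelComparison(
        baseline=before,
        treated=after,
        d_va_eup_pct=_pct(after.va_eup, before.va_eup),
        d_paco2_eup_pct=_pct(after.paco2_eup, before.paco2_eup),
        d_co2_reserve_pct=_pct(after.co2_reserve, before.co2_reserve),
        d_va_reserve_pct=_pct(after.va_reserve, before.va_reserve),
        d_plant_gain_pct=_pct(after.plant_gain, before.plant_gain),
        d_loop_gain_pct=_pct(after.loop_gain, before.loop_gain),
        delta_paco2_eup=after.paco2_eup - before.paco2_eup,
        delta_at=new_at - ctrl0.apnea_threshold,
    )


def compose_lg_change(dcg_pct: float, dpg_pct: float) -> float:
    """Percent loop-gain change from percent changes of its two factors.

    ``%dLG = ((1 + %dCG/100) * (1 + %dPG/100) - 1) * 100``.
    """
    if dcg_pct <= -100.0 or dpg_pct <= -100.0:
        raise InvalidGeometryError("percent changes must exceed -100")
    return ((1.0 + dcg_pct / 100.0) * (1.0 + dpg_pct / 100.0) - 1.0) * 100.0


def intervention_report(
    base: BaselineInputs = DEFAULT_BASELINE,
    interventions: dict[int, InterventionSpec] | None = None,
) -> dict[int, ModelComparison]:
    """The four standard scenarios applied to ``base``, keyed by model id."""
    if interventions is None:
        interventions = REFERENCE_INTERVENTIONS
    return {mid: apply_intervention(base, spec) for mid, spec in interventions.items()}


@dataclass(frozen=True)
class SweepResult:
    """Result of a one-parameter sensitivity sweep.

    ``values`` is the grid of the swept quantity; ``dlg_pct`` the loop-gain
    percent change at each point; ``rr`` the relative reduction
    ``dlg_pct / ref_dlg``; ``valid`` flags points whose baseline geometry was
    solvable (invalid points carry NaN rather than being dropped).
    """

    param: str
    values: np.ndarray
    dlg_pct: np.ndarray
    rr: np.ndarray
    ref_dlg: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            object.__setattr__(self, "valid", np.isfinite(np.asarray(self.dlg_pct)))

    def records(self) -> list[dict[str, float]]:
        return [
            {
                "param": self.param,
                "value": float(v),
                "dLG_pct": float(d),
                "RR": float(r),
            }
            for v, d, r in zip(self.values, self.dlg_pct, self.rr)
        ]


def _self_consistent_baseline(
    param: str, value: float, base: BaselineInputs
) -> tuple[MetabolicCurve, ChemoController]:
    """Re-derive a coherent baseline when one anchor is moved off its pooled value.

    The chemosensitivity line must still pass through the (possibly moved)
    eupneic point on the (possibly moved) hyperbola, so the apnea threshold is
    re-derived as ``paco2_eup - va_eup / gain`` in every case:

    * sweeping controller gain: hold vco2 and paco2_eup at pooled values;
    * sweeping paco2_eup: hold vco2 and the pooled-derived controller gain;
    * sweeping vco2: hold paco2_eup and the pooled-derived controller gain.

    Holding the apnea threshold fixed instead would reverse the direction of
    the eupneic-paCO2 effect, contradicting the hyperbola geometry.
    """
    pooled_gain = base.controller().gain
    if param == "controller_gain":
        vco2, paco2_eup, gain = base.vco2, base.paco2_eup, value
    elif param == "paco2_eup":
        vco2, paco2_eup, gain = base.vco2, value, pooled_gain
    elif param == "vco2":
        vco2, paco2_eup, gain = value, base.paco2_eup, pooled_gain
    else:
        raise ValueError(
            f"unknown sweep parameter {param!r}; expected one of "
            f"{sorted(PHYSIOLOGICAL_RANGES)}"
        )
    va_eup = K_BTPS * vco2 / paco2_eup
    at = paco2_eup - va_eup / gain
    if at <= 0:
        raise InvalidGeometryError(
            f"{param}={value!r} implies a non-positive apnea threshold"
        )
    return MetabolicCurve(vco2), ChemoController(gain=gain, apnea_threshold=at)


def _apply_to(
    curve: MetabolicCurve,
    ctrl: ChemoController,
    spec: InterventionSpec,
    shift_mode: str,
    pooled_at: float,
) -> float:
    """Loop-gain percent change of ``spec`` applied to an arbitrary system."""
    before = solve_eupnea(curve, ctrl)
    if shift_mode == "relative":
        new_at = ctrl.apnea_threshold * (1.0 + spec.at_shift_pct / 100.0)
    elif shift_mode == "absolute":
        # same mmHg shift everywhere: the spec percentage of the *pooled* AT
        new_at = ctrl.apnea_threshold + pooled_at * spec.at_shift_pct / 100.0
    else:
        raise ValueError(f"shift_mode must be 'relative' or 'absolute', got {shift_mode!r}")
    new_vco2 = curve.vco2 * (1.0 + spec.vco2_change_pct / 100.0)
    new_gain = ctrl.gain * (1.0 + spec.cg_change_pct / 100.0)
    if new_at <= 0 or new_vco2 <= 0 or new_gain <= 0:
        raise InvalidGeometryError("intervention drives a parameter non-positive")
    after = solve_eupnea(
        MetabolicCurve(new_vco2), ChemoController(gain=new_gain, apnea_threshold=new_at)
    )
    return _pct(after.loop_gain, before.loop_gain)


def _reference_dlg(base: BaselineInputs, spec: InterventionSpec) -> float:
    return apply_intervention(base, spec).d_loop_gain_pct


def sweep_baseline(
    param: str,
    grid: np.ndarray | list[float] | None = None,
    spec: InterventionSpec = REFERENCE_INTERVENTIONS[1],
    ref_dlg: float | None = None,
    base: BaselineInputs = DEFAULT_BASELINE,
    shift_mode: str = "relative",
    n_points: int = 101,
) -> SweepResult:
    """Loop-gain response of ``spec`` as one baseline parameter varies.

    ``grid`` defaults to ``n_points`` evenly spaced values across the
    physiological range of ``param``; values outside that range trigger a
    warning but are still computed.  ``ref_dlg`` (the %dLG0 normalizer)
    defaults to the exact loop-gain change of ``spec`` at the pooled baseline,
    so RR equals 1 at the pooled point by construction.
    """
    lo, hi = PHYSIOLOGICAL_RANGES[param]
    values = np.linspace(lo, hi, n_points) if grid is None else np.asarray(grid, float)
    if values.size and (values.min() < lo or values.max() > hi):
        warnings.warn(
            f"grid for {param} extends outside the physiological range [{lo}, {hi}]",
            stacklevel=2,
        )
    if ref_dlg is None:
        ref_dlg = _reference_dlg(base, spec)
    if ref_dlg == 0:
        raise ValueError("reference loop-gain change must be non-zero")

    dlg = np.full(values.shape, np.nan)
    valid = np.zeros(values.shape, dtype=bool)
    for i, v in enumerate(values):
        try:
            curve, ctrl = _self_consistent_baseline(param, float(v), base)
            dlg[i] = _apply_to(curve, ctrl, spec, shift_mode, base.apnea_threshold)
            valid[i] = True
        except InvalidGeometryError:
            pass  # flagged via valid mask, point retained as NaN
    return SweepResult(param=param, values=values, dlg_pct=dlg, rr=dlg / ref_dlg,
                       ref_dlg=ref_dlg, valid=valid)


def sweep_shift(
    shift_grid: np.ndarray | list[float] | None = None,
    base: BaselineInputs = DEFAULT_BASELINE,
    ref_dlg: float | None = None,
    n_points: int = 101,
) -> SweepResult:
    """Loop-gain response to varying apnea-threshold left-shift magnitudes.

    ``shift_grid`` holds percent changes in ``(-100, 0]``; default is
    ``n_points`` points from 0 to -30%.  RR is normalized to the reference
    -15% shift, so RR(0) = 0 and RR(-15) = 1.
    """
    if shift_grid is None:
        values = np.linspace(0.0, -30.0, n_points)
    else:
        values = np.asarray(shift_grid, float)
    if values.size and (values.min() <= -100.0 or values.max() > 0.0):
        raise InvalidGeometryError("shifts must lie in (-100, 0]")
    if ref_dlg is None:
        ref_dlg = _reference_dlg(base, REFERENCE_INTERVENTIONS[1])

    dlg = np.array(
        [
            apply_intervention(base, InterventionSpec(at_shift_pct=float(s))).d_loop_gain_pct
            for s in values
        ]
    )
    return SweepResult(param="at_shift_pct", values=values, dlg_pct=dlg,
                       rr=dlg / ref_dlg, ref_dlg=ref_dlg)
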