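"""Voltage-clamp quantification of I_h and the persistent sodium current.

The hyperpolarisation-activated current (I_h) is measured on a step trace as
the difference between the instantaneous current (just after the capacitive
transient) and the steady-state current at the end of the step; current at
the most negative step divided by cell capacitance gives the density.

The persistent sodium current (I_NaP) is isolated by subtracting the
ramp-evoked current recorded under blockers from the control ramp current.
Currents are transformed to conductances with g = I / (V - ENa), ENa =
56 mV, normalised by the maximum measured conductance, and fitted with a
four-parameter Boltzmann activation curve

    g/gmax = Bottom + (Top - Bottom) / (1 + exp((V50 - V) / Slope)).

All command voltages are corrected for the liquid junction potential
(11.5 mV with the gluconate-based internal solution) before analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import InsufficientDataError

__all__ = [
    "E_NA_MV",
    "JUNCTION_POTENTIAL_MV",
    "VoltageClampTrace",
    "IhWindows",
    "IhMeasurement",
    "correct_junction_potential",
    "measure_ih",
    "current_density",
    "isolate_persistent_current",
    "conductance_points",
    "normalize_conductance",
    "boltzmann",
    "BoltzmannFit",
    "FitError",
    "fit_boltzmann",
]

#: Calculated sodium reversal potential (mV) used in the conductance transform.
E_NA_MV = 56.0
#: Liquid junction potential (mV), corrected offline.
JUNCTION_POTENTIAL_MV = 11.5


class FitError(RuntimeError):
    """Raised when the Boltzmann fit fails to converge."""


@dataclass(frozen=True)
class VoltageClampTrace:
    """A uniformly sampled voltage-clamp sweep.

    ``command_voltage`` is a scalar (mV) for step protocols or a per-sample
    array for ramps.
    """

    time: np.ndarray            # s
    current: np.ndarray         # pA
    command_voltage: float | np.ndarray   # mV
    holding_voltage: float      # mV

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time must be a 1-D array with >= 2 samples")
        if i.shape != t.shape:
            raise ValueError("current and time must have the same shape")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly ascending")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        cmd = self.command_voltage
        if np.ndim(cmd) > 0:
            cmd = np.asarray(cmd, dtype=float)
            if cmd.shape != t.shape:
                raise ValueError("per-sample command must match time shape")
            object.__setattr__(self, "command_voltage", cmd)

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


def correct_junction_potential(v, offset: float = JUNCTION_POTENTIAL_MV):
    """Subtract the liquid junction potential from a command voltage (mV)."""
    arr = np.asarray(v, dtype=float) - offset
    return float(arr) if np.ndim(v) == 0 else arr


@dataclass(frozen=True)
class IhWindows:
    """Measurement windows (s, relative to step onset at t = 0).

    Defaults: instantaneous current 5-15 ms after onset (past the capacitive
    transient), steady state over the final 100 ms of the 1.5 s step.
    """

    instantaneous: tuple[float, float] = (0.005, 0.015)
    steady: tuple[float, float] = (1.4, 1.5)


@dataclass(frozen=True)
class IhMeasurement:
    """I_h metrics of one hyperpolarising step.

    ``amplitude`` is the absolute steady-minus-instantaneous difference; the
    raw signed difference is kept as ``signed_difference`` because the sign
    convention of the published definition is ambiguous.  ``density`` is the
    signed difference per picofarad (NaN when no capacitance was given).
    """

    step_voltage: float          # mV
    instantaneous_current: float  # pA
    steady_state_current: float   # pA
    amplitude: float              # pA
    signed_difference: float      # pA
    capacitance: float            # pF
    density: float                # pA/pF


def _window_mean(trace: VoltageClampTrace, window: tuple[float, float]) -> float:
    lo, hi = window
    # the nominal step end sits one sampling interval past the last sample
    slack = trace.sampling_interval
    if lo < trace.time[0] - 1e-12 or hi > trace.time[-1] + slack or hi <= lo:
        raise ValueError(f"window {window} outside the recorded step")
    mask = (trace.time >= lo) & (trace.time <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return float(trace.current[mask].mean())


def measure_ih(
    trace: VoltageClampTrace,
    capacitance: float = math.nan,
    windows: IhWindows | None = None,
) -> IhMeasurement:
    """Measure I_h on a step trace (time origin = step onset).

    The instantaneous and steady-state currents are means over the
    configured windows; amplitude is their absolute difference.  Adding a
    constant to the whole trace leaves the amplitude unchanged.
    """
    windows = windows or IhWindows()
    inst = _window_mean(trace, windows.instantaneous)
    steady = _window_mean(trace, windows.steady)
    signed = steady - inst
    density = signed / capacitance if capacitance and not math.isnan(capacitance) else math.nan
    step_v = trace.command_voltage
    if np.ndim(step_v) > 0:
        raise ValueError("measure_ih expects a step trace with scalar command")
    return IhMeasurement(
        step_voltage=float(step_v),
        instantaneous_current=inst,
        steady_state_current=steady,
        amplitude=abs(signed),
        signed_difference=signed,
        capacitance=float(capacitance),
        density=density,
    )


def current_density(current_pa: float, capacitance_pf: float) -> float:
    """Current (pA) divided by cell capacitance (pF) -> pA/pF, sign kept."""
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return current_pa / capacitance_pf


def isolate_persistent_current(
    control: VoltageClampTrace,
    blocked: VoltageClampTrace,
    junction_mv: float = JUNCTION_POTENTIAL_MV,
) -> pd.DataFrame:
    """Blocker-sensitive ramp current: control minus blocked, pointwise.

    Both traces must share the same time base and command ramp.  Returns a
    DataFrame with the junction-corrected ramp voltage (``voltage_mv``) and
    the difference current (``current_pa``).
    """
    if control.time.shape != blocked.time.shape or not np.allclose(
        control.time, blocked.time
    ):
        raise ValueError("control and blocked traces have different sampling")
    cmd_c, cmd_b = control.command_voltage, blocked.command_voltage
    if np.ndim(cmd_c) != np.ndim(cmd_b) or not np.allclose(cmd_c, cmd_b):
        raise ValueError("control and blocked traces have different commands")
    voltage = correct_junction_potential(
        np.broadcast_to(cmd_c, control.time.shape), junction_mv
    )
    return pd.DataFrame(
        {
            "voltage_mv": np.asarray(voltage, dtype=float),
            "current_pa": control.current - blocked.current,
        }
    )


def conductance_points(
    voltage_mv,
    current_pa,
    e_na: float = E_NA_MV,
    exclusion_mv: float = 1.0,
) -> pd.DataFrame:
    """Transform currents to chord conductances: g = I / (V - ENa), in nS.

    The transform is singular at the reversal potential; points within
    ``exclusion_mv`` of ENa are refused with a ValueError.
    """
    v = np.asarray(voltage_mv, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    if v.shape != i.shape:
        raise ValueError("voltage and current must have the same shape")
    near = np.abs(v - e_na) < exclusion_mv
    if near.any():
        raise ValueError(
            f"{int(near.sum())} point(s) within {exclusion_mv} mV of "
            f"ENa = {e_na} mV; the conductance transform is undefined there"
        )
    return pd.DataFrame({"voltage_mv": v, "g_ns": i / (v - e_na)})


def normalize_conductance(g_ns) -> tuple[np.ndarray, float]:
    """Normalise by the maximum measured conductance (gmax), returning
    ``(g/gmax, gmax)``."""
    g = np.asarray(g_ns, dtype=float)
    gmax = float(np.max(g))
    if gmax <= 0:
        raise ValueError("maximum measured conductance must be positive")
    return g / gmax, gmax


def boltzmann(v, v50: float, slope: float, top: float = 1.0, bottom: float = 0.0):
    """Boltzmann activation: Bottom + (Top-Bottom)/(1 + exp((V50 - V)/Slope))."""
    return bottom + (top - bottom) / (1.0 + np.exp((v50 - np.asarray(v)) / slope))


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted activation parameters; at V = V50 the curve is (Top+Bottom)/2."""

    v50: float          # mV
    slope: float        # mV, > 0 for activation
    top: float
    bottom: float
    gmax: float         # nS, the normalising maximum measured conductance
    residual_norm: float
    n_points: int

    def predict(self, v):
        return boltzmann(v, self.v50, self.slope, self.top, self.bottom)

    @property
    def half_activation_value(self) -> float:
        return 0.5 * (self.top + self.bottom)


def _initial_guess(v: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(v)
    vs, gs = v[order], g[order]
    bottom0, top0 = float(gs.min()), float(gs.max())
    span = top0 - bottom0
    half = bottom0 + 0.5 * span

    def crossing(level: float) -> float:
        above = gs >= level
        idx = int(np.argmax(above)) if above.any() else len(gs) - 1
        if idx == 0:
            return float(vs[0])
        v0, v1 = vs[idx - 1], vs[idx]
        g0, g1 = gs[idx - 1], gs[idx]
        if g1 == g0:
            return float(v1)
        return float(v0 + (level - g0) * (v1 - v0) / (g1 - g0))

    v50_0 = crossing(half)
    v20 = crossing(bottom0 + 0.2 * span)
    v80 = crossing(bottom0 + 0.8 * span)
    slope0 = max((v80 - v20) / 4.0, 0.5)
    return v50_0, slope0, top0, bottom0


def fit_boltzmann(voltage_mv, g_norm, gmax: float = math.nan) -> BoltzmannFit:
    """Least-squares four-parameter Boltzmann fit of normalised conductance.

    Needs at least 6 points spanning the activation transition.  Initial
    values come from the data (half-range crossing for V50, the 20-80% span
    for the slope, the extremes for Top/Bottom).  Non-convergence raises
    :class:`FitError` with diagnostics.
    """
    v = np.asarray(voltage_mv, dtype=float)
    g = np.asarray(g_norm, dtype=float)
    if v.shape != g.shape:
        raise ValueError("voltage and conductance must have the same shape")
    if v.size < 6:
        raise InsufficientDataError("Boltzmann fit needs >= 6 points")
    p0 = _initial_guess(v, g)
    bounds = ([-np.inf, 1e-6, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(
            boltzmann, v, g, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"Boltzmann fit did not converge (init v50={p0[0]:.2f}, "
            f"slope={p0[1]:.2f}): {exc}"
        ) from exc
    resid = g - boltzmann(v, *popt)
    return BoltzmannFit(
        v50=float(popt[0]),
        slope=float(popt[1]),
        top=float(popt[2]),
        bottom=float(popt[3]),
        gmax=float(gmax),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=int(v.size),
    )
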