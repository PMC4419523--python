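"""Behavioural model of a single PCMO memristive synapse.

The device is a two-terminal analogue memory whose conductance ``g`` (in
nA/V) plays the role of a synaptic weight.  Three behaviours are modelled:

* **Linear read** — at small bias (|v| ≤ ``v_read``) the device is ohmic and
  the read current is simply ``g · v``.
* **Threshold-gated switching** — pulses with |v| below the switching
  threshold ``v_switch`` (≈ 1 V) leave the state unchanged; this is what
  makes the half-bias write scheme of the crossbar possible.
* **State-dependent, saturating updates** — a supra-threshold pulse of
  potentiating polarity moves the conductance a fixed fraction of the
  remaining headroom towards ``g_max``; a depressing pulse moves it towards
  ``g_min``::

      Δg = +alpha_pot · (g_max − g)      (potentiation)
      Δg = −alpha_dep · (g − g_min)      (depression)

  This exponential-saturation rule reproduces the measured per-pulse change
  of roughly 0.2–0.5 nA/V near the low-conductance state, falling to
  0.02–0.05 nA/V as the device approaches saturation, and converges
  geometrically to the bounds (1.5 and 5.5 nA/V at defaults).

Polarity convention: ``v_cell`` is the bottom-electrode potential minus the
top-electrode potential; positive supra-threshold pulses potentiate,
negative ones depress.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DeviceParams",
    "SynapseState",
    "read_current",
    "apply_pulse",
    "calibrate_rate",
    "pulse_train",
    "update_conductance",
    "RATE_LOW",
    "RATE_HIGH",
]

#: Printed per-pulse conductance-change window near g_min (nA/V).
RATE_LOW: Tuple[float, float] = (0.2, 0.5)
#: Printed per-pulse conductance-change window near saturation (nA/V).
RATE_HIGH: Tuple[float, float] = (0.02, 0.05)

#: Default per-pulse rate at g_min used to calibrate alpha (midpoint of RATE_LOW).
DEFAULT_RATE_AT_GMIN = 0.35


@dataclass(frozen=True)
class DeviceParams:
    """Parameters of the synapse model.

    Attributes
    ----------
    g_min, g_max : float
        Conductance bounds in nA/V.
    v_switch : float
        Switching threshold V_R in volts; pulses with |v| ≤ v_switch do not
        change the state (up to the optional disturb model).
    v_read : float
        Maximum bias magnitude for which the linear read model is valid.
    alpha_pot, alpha_dep : float
        Fraction of the remaining headroom moved per supra-threshold pulse.
    rate_low, rate_high : (float, float)
        Documented per-pulse Δg windows near g_min and near g_max; used for
        calibration checks and for the optional rate jitter.
    disturb_enabled : bool
        If True, half-selected (sub-threshold) pulses apply a reduced update
        scaled by ``disturb_fraction`` — a knob for studying unintended
        switching.  Off by default, which models the ideal scheme.
    disturb_fraction : float
        Scale factor for sub-threshold disturb updates.
    jitter : bool
        If True (and an rng is supplied to :func:`apply_pulse`) the per-pulse
        rate at g_min is drawn uniformly from ``rate_low`` instead of using
        the deterministic alpha; models cycle-to-cycle variability.
    """

    g_min: float = 1.5
    g_max: float = 5.5
    v_switch: float = 1.0
    v_read: float = 1.0
    alpha_pot: float = DEFAULT_RATE_AT_GMIN / (5.5 - 1.5)
    alpha_dep: float = DEFAULT_RATE_AT_GMIN / (5.5 - 1.5)
    rate_low: Tuple[float, float] = RATE_LOW
    rate_high: Tuple[float, float] = RATE_HIGH
    disturb_enabled: bool = False
    disturb_fraction: float = 0.0
    jitter: bool = False

    def __post_init__(self) -> None:
        if not self.g_min < self.g_max:
            raise ValueError("g_min must be strictly below g_max")
        if self.v_switch <= 0:
            raise ValueError("v_switch must be positive")
        for name in ("alpha_pot", "alpha_dep"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.disturb_fraction < 0:
            raise ValueError("disturb_fraction must be non-negative")

    @property
    def g_range(self) -> float:
        return self.g_max - self.g_min

    @property
    def g_mid(self) -> float:
        return 0.5 * (self.g_min + self.g_max)


@dataclass
class SynapseState:
    """Mutable conductance of one device (nA/V)."""

    g: float

    def validate(self, params: DeviceParams) -> None:
        if not params.g_min <= self.g <= params.g_max:
            raise ValueError(
                f"conductance {self.g} outside [{params.g_min}, {params.g_max}]"
            )


def read_current(state: SynapseState, v: float, params: Optional[DeviceParams] = None) -> float:
    """Linear read current ``g · v`` in nA.

    Raises ``ValueError`` when |v| exceeds the read regime ``v_read``.
    """
    params = params or DeviceParams()
    if abs(v) > params.v_read + 1e-12:
        raise ValueError(
            f"|v| = {abs(v)} V exceeds the linear read regime (v_read = {params.v_read} V)"
        )
    return state.g * v


def update_conductance(
    g: np.ndarray | float,
    params: DeviceParams,
    v_cell: np.ndarray | float,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray | float:
    """Vectorised conductance update shared by the scalar and crossbar paths.

    Applies the threshold-gated saturating update elementwise and clamps to
    the bounds.  ``g`` and ``v_cell`` broadcast against each other.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v_cell, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("pulse voltage must be finite")

    if params.jitter and rng is not None:
        rate = rng.uniform(*params.rate_low, size=np.broadcast_shapes(g.shape, v.shape))
        a_pot = rate / params.g_range
        a_dep = rate / params.g_range
    else:
        a_pot = params.alpha_pot
        a_dep = params.alpha_dep

    supra = np.abs(v) > params.v_switch
    pot = supra & (v > 0)
    dep = supra & (v < 0)
    dg = np.zeros(np.broadcast_shapes(g.shape, v.shape))
    dg = np.where(pot, a_pot * (params.g_max - g), dg)
    dg = np.where(dep, -a_dep * (g - params.g_min), dg)
    if params.disturb_enabled and params.disturb_fraction > 0:
        sub = ~supra & (v != 0)
        sub_dg = np.where(
            v > 0,
            a_pot * (params.g_max - g),
            -a_dep * (g - params.g_min),
        )
        dg = np.where(sub, params.disturb_fraction * sub_dg, dg)
    out = np.clip(g + dg, params.g_min, params.g_max)
    return out if out.ndim else float(out)


def apply_pulse(
    state: SynapseState,
    params: DeviceParams,
    v_cell: float,
    rng: Optional[np.random.Generator] = None,
) -> SynapseState:
    """Apply one programming pulse of amplitude ``v_cell`` and return the new state.

    Scalar reference implementation of the update rule; the crossbar uses the
    vectorised :func:`update_conductance` with identical arithmetic.
    """
    if not np.isfinite(v_cell):
        raise ValueError("pulse voltage must be finite")
    g = state.g
    if params.jitter and rng is not None:
        rate = float(rng.uniform(*params.rate_low))
        a_pot = a_dep = rate / params.g_range
    else:
        a_pot, a_dep = params.alpha_pot, params.alpha_dep

    if abs(v_cell) > params.v_switch:
        if v_cell > 0:
            g = g + a_pot * (params.g_max - g)
        else:
            g = g - a_dep * (g - params.g_min)
    elif params.disturb_enabled and params.disturb_fraction > 0 and v_cell != 0:
        if v_cell > 0:
            g = g + params.disturb_fraction * a_pot * (params.g_max - g)
        else:
            g = g - params.disturb_fraction * a_dep * (g - params.g_min)
    g = min(max(g, params.g_min), params.g_max)
    return SynapseState(g=g)


def calibrate_rate(params: DeviceParams, target_rate_at_gmin: float) -> DeviceParams:
    """Return params with alpha set so one pulse at g_min changes g by the target rate.

    The target must lie inside the documented low-state window ``rate_low``;
    potentiation and depression are calibrated symmetrically, mirroring the
    device's symmetric pulse response.
    """
    lo, hi = params.rate_low
    if not lo <= target_rate_at_gmin <= hi:
        raise ValueError(
            f"target rate {target_rate_at_gmin} nA/V outside the documented window [{lo}, {hi}]"
        )
    alpha = target_rate_at_gmin / params.g_range
    return replace(params, alpha_pot=alpha, alpha_dep=alpha)


def pulse_train(
    state: SynapseState,
    params: DeviceParams,
    n: int,
    polarity: str = "potentiate",
    v_amplitude: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Conductance after each of ``n`` identical supra-threshold pulses.

    ``polarity`` is ``"potentiate"`` or ``"depress"``; the returned array has
    length ``n`` and is monotone, converging to g_max (potentiation) or g_min
    (depression).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if polarity not in ("potentiate", "depress"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if abs(v_amplitude) <= params.v_switch:
        raise ValueError("pulse amplitude must exceed the switching threshold")
    v = abs(v_amplitude) if polarity == "potentiate" else -abs(v_amplitude)
    out = np.empty(n, dtype=float)
    s = state
    for i in range(n):
        s = apply_pulse(s, params, v, rng=rng)
        out[i] = s.g
    return out
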