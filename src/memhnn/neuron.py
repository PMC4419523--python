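"""Leaky integrate-and-fire post-neuron.

The hardware post-neuron is an inverting leaky integrator followed by a
comparator.  Starting from the reset level ``v_reset`` (4 V), the output
falls as synaptic current accumulates on the integration capacitor,
approaching the saturation level set by the input current and the RC time
constant::

    v(t)  = v_sat + (v_reset − v_sat) · exp(−t / tau)
    v_sat = v_reset − gain · i_in

For small ``t`` the drop is almost linear; the neuron fires when the output
crosses the comparator threshold ``v_th`` (3 V) from above, which happens
iff ``gain · i_in > v_reset − v_th`` and, in a finite integration window,
only if the closed-form crossing time falls inside that window.  After the
integration phase a refractory phase discharges the capacitor and returns
every output to ``v_reset``.

Both a closed-form solution and an exponential-integrator stepped
simulation are provided; they agree to machine precision because the system
is linear time-invariant within a trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .crossbar import Crossbar, row_currents
from .codes import FeatureCode

__all__ = [
    "NeuronParams",
    "NeuronState",
    "integrate",
    "time_to_fire",
    "step_trace",
    "run_trial",
    "TrialResult",
]

#: Default transimpedance gain (V per nA).  Chosen so the comparator
#: threshold sits between the two current populations a trained array
#: produces — the class-labelled rows (whose active synapses saturate high)
#: and every other row; see the methods note for the calibration analysis.
DEFAULT_GAIN = 1.0 / 60.0


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants.

    v_reset, v_th : volts — reset level (4 V) and comparator threshold (3 V).
    tau : seconds — RC time constant of the leaky integrator.
    gain : V/nA — transimpedance scale mapping input current to the
        saturation drop ``v_sat = v_reset − gain · i_in``.
    t_integrate, t_refractory : seconds — phase durations.
    dt : seconds — step size of the stepped simulation (must resolve tau).
    """

    v_reset: float = 4.0
    v_th: float = 3.0
    tau: float = 10e-3
    gain: float = DEFAULT_GAIN
    t_integrate: float = 50e-3
    t_refractory: float = 10e-3
    dt: float = 0.1e-3

    def __post_init__(self):
        if self.v_reset <= self.v_th:
            raise ValueError("v_reset must exceed v_th")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.dt < self.tau / 10:
            raise ValueError("dt must be below tau/10 to resolve the integrator")

    @property
    def fire_margin(self) -> float:
        """Voltage drop needed to reach threshold: v_reset − v_th (1 V at defaults)."""
        return self.v_reset - self.v_th

    def threshold_current(self) -> float:
        """Smallest input current (nA) that fires within the integration window."""
        window = 1.0 - math.exp(-self.t_integrate / self.tau)
        return self.fire_margin / (self.gain * window)


@dataclass
class NeuronState:
    """Output voltage and fire record of one post-neuron."""

    v_out: float
    fired: bool = False
    t_fire: Optional[float] = None


def integrate(params: NeuronParams, i_in: float, t: float) -> float:
    """Closed-form integrator output ``v(t)`` for a constant input current (nA)."""
    if i_in < 0:
        raise ValueError("input current must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    v_sat = params.v_reset - params.gain * i_in
    return v_sat + (params.v_reset - v_sat) * math.exp(-t / params.tau)


def time_to_fire(params: NeuronParams, i_in: float) -> Optional[float]:
    """Closed-form threshold-crossing time, or None if the neuron never fires.

    The neuron fires iff the saturation level lies strictly below the
    threshold (gain · i_in > v_reset − v_th); exact equality counts as not
    fired.  The returned time ignores the finite integration window — the
    trial runner applies that cut.
    """
    if i_in < 0:
        raise ValueError("input current must be non-negative")
    v_sat = params.v_reset - params.gain * i_in
    if v_sat >= params.v_th:
        return None
    return params.tau * math.log((params.v_reset - v_sat) / (params.v_th - v_sat))


def step_trace(
    params: NeuronParams, i_in: float, t_end: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Stepped simulation of the integrator using the exact exponential update.

    Returns (times, voltages) sampled every ``dt`` from 0 to ``t_end``
    (default: the integration window).  The per-step update
    ``v ← v_sat + (v − v_sat)·exp(−dt/tau)`` is the exact solution of the
    linear ODE, so the trace matches :func:`integrate` to round-off.
    """
    if i_in < 0:
        raise ValueError("input current must be non-negative")
    t_end = params.t_integrate if t_end is None else t_end
    n = int(round(t_end / params.dt))
    times = np.arange(n + 1) * params.dt
    v_sat = params.v_reset - params.gain * i_in
    decay = math.exp(-params.dt / params.tau)
    v = np.empty(n + 1)
    v[0] = params.v_reset
    for k in range(n):
        v[k + 1] = v_sat + (v[k] - v_sat) * decay
    return times, v


@dataclass
class TrialResult:
    """Outcome of presenting one feature code to the six post-neurons."""

    currents: np.ndarray                 # nA per row
    t_fire: List[Optional[float]]        # crossing time within the window, or None
    times: np.ndarray                    # trace time axis (integrate + refractory)
    traces: np.ndarray                   # (n_neurons, n_times) integrator outputs
    states: List[NeuronState]            # post-refractory states (all reset)

    @property
    def n_fired(self) -> int:
        return sum(t is not None for t in self.t_fire)


def run_trial(
    xbar: Crossbar,
    code: FeatureCode,
    params: NeuronParams = NeuronParams(),
    v_read: float = 1.0,
) -> TrialResult:
    """Integrate all post-neurons for one code and record threshold crossings.

    The integrating phase runs for ``t_integrate``; crossings are taken from
    the closed form (the stepped trace is the same dynamics) and only count
    inside the window.  The refractory phase then resets every trace to
    ``v_reset`` and clears the fire flags so the array is ready for the next
    code.
    """
    currents = row_currents(xbar, code, v_read=v_read)
    t_fire: List[Optional[float]] = []
    for i in currents:
        t = time_to_fire(params, float(i))
        t_fire.append(t if (t is not None and t <= params.t_integrate) else None)

    n_int = int(round(params.t_integrate / params.dt))
    n_ref = int(round(params.t_refractory / params.dt))
    times = np.arange(n_int + n_ref + 1) * params.dt
    traces = np.empty((len(currents), times.size))
    for r, i in enumerate(currents):
        _, v = step_trace(params, float(i), params.t_integrate)
        traces[r, : n_int + 1] = v
        # refractory discharge back toward the reset level
        decay = np.exp(-np.arange(1, n_ref + 1) * params.dt / params.tau)
        traces[r, n_int + 1 :] = params.v_reset + (v[-1] - params.v_reset) * decay
    if n_ref:
        traces[:, -1] = params.v_reset  # fully discharged at the end of the phase

    states = [NeuronState(v_out=params.v_reset, fired=False, t_fire=None) for _ in currents]
    return TrialResult(
        currents=currents, t_fire=t_fire, times=times, traces=traces, states=states
    )


def write_traces(path, result: TrialResult) -> None:
    """Write integrator traces as delimited text: time column + one column per neuron."""
    data = np.column_stack([result.times, result.traces.T])
    header = "time_s\t" + "\t".join(f"v{r}" for r in range(result.traces.shape[0]))
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header=header)
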