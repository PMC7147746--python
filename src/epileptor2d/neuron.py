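"""Representative-neuron observer: an adaptive quadratic integrate-and-fire
cell driven by a recorded population input current.

The population model produces a smooth mean input u(t) (stored as u/g_L in
mV); the observer converts it to a picoampere drive through a configurable
gain and integrates

    C_U dU/dt   = g_U (U - U1)(U - U2) - w + u + I_a
    tau_w dw/dt = -w
    if U > V_T:   U -> V_reset,  w -> w + delta_w

producing the burst-clustered spiking seen in single-cell recordings during
ictal events.  The observer does not feed back on the population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .params import NeuronParameters

__all__ = ["SpikeTrace", "integrate_neuron", "resting_potentials"]

#: Default conversion from the population input (u/g_L, mV) to pA.
DEFAULT_GAIN_PA_PER_MV = 10.0


@dataclass
class SpikeTrace:
    """Voltage/adaptation time series and spike times of the observer."""

    t: np.ndarray
    U: np.ndarray            # mV
    w: np.ndarray            # pA
    spike_times: List[float] = field(default_factory=list)


def resting_potentials(p: NeuronParameters, u_pA: float = 0.0):
    """Fixed points of the zero-adaptation voltage equation.

    Roots of g_U (U - U1)(U - U2) + I_a + u = 0; returns ``(stable,
    unstable)`` or ``None`` when the drive exceeds the saddle-node point
    (tonic spiking, no rest state).
    """
    a = p.g_U
    b = -p.g_U * (p.U1 + p.U2)
    c = p.g_U * p.U1 * p.U2 + p.I_a + u_pA
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    r1 = (-b - np.sqrt(disc)) / (2 * a)
    r2 = (-b + np.sqrt(disc)) / (2 * a)
    return (min(r1, r2), max(r1, r2))  # lower root is the stable node


def integrate_neuron(u_trace: np.ndarray, dt: float,
                     p: NeuronParameters | None = None,
                     gain: float = DEFAULT_GAIN_PA_PER_MV) -> SpikeTrace:
    """Integrate the observer along a uniformly sampled input trace.

    Parameters
    ----------
    u_trace : array
        Population input u/g_L in mV, sampled every ``dt`` seconds (the
        probe cadence of the engine, 1 ms by default).
    dt : float
        Sample period in seconds; must be positive and uniform.
    gain : float
        pA of observer drive per mV of population input.

    Explicit Euler at the trace's own sample period, matching the engine's
    scheme; ``U(0) = U0`` and ``w(0) = 0``.
    """
    if p is None:
        p = NeuronParameters()
    u_trace = np.asarray(u_trace, dtype=float)
    if u_trace.size == 0:
        raise ValueError("empty input trace")
    if dt <= 0:
        raise ValueError("sample period must be positive")
    n = u_trace.size
    dt_ms = dt * 1e3
    U = np.empty(n)
    w = np.empty(n)
    U[0] = p.U0
    w[0] = 0.0
    spikes: List[float] = []
    for k in range(n - 1):
        I = (p.g_U * (U[k] - p.U1) * (U[k] - p.U2) - w[k]
             + gain * u_trace[k] + p.I_a)
        U_next = U[k] + dt_ms * I / p.C_U
        w_next = w[k] - dt_ms * w[k] / p.tau_w
        if U_next > p.V_T:
            U_next = p.V_reset
            w_next += p.delta_w
            spikes.append((k + 1) * dt)
        U[k + 1] = U_next
        w[k + 1] = w_next
    t = np.arange(n) * dt
    return SpikeTrace(t=t, U=U, w=w, spike_times=spikes)
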