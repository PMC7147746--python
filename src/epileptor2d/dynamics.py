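"""Point-wise right-hand sides and closures of the Epileptor-2 equations.

These are the per-cell (reaction) parts of the model: the Nernst relation,
the Na/K pump, the firing-rate sigmoid, the input current and the local time
derivatives of the five dynamical fields.  Spatial coupling (potassium
diffusion and the presynaptic-rate elliptic equation) lives in
:mod:`epileptor2d.operators`; the time stepping in :mod:`epileptor2d.engine`.

All functions accept scalars or numpy arrays and operate element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import K_INTRA, NERNST_MV, ModelParameters

__all__ = [
    "GridState",
    "nernst_potential",
    "pump_current",
    "firing_rate",
    "input_current",
    "local_rhs",
    "rest_state_residual",
]


@dataclass
class GridState:
    """The five dynamical fields on the grid at one instant.

    K_o (mM), Na_i (mM) and V (mV) evolve by differential equations; x_D is
    the synaptic resource fraction in (0, 1]; phi (Hz) is the presynaptic
    rate, algebraically slaved to the somatic rate.  ``t`` is simulation
    time in seconds.
    """

    K_o: np.ndarray
    Na_i: np.ndarray
    V: np.ndarray
    x_D: np.ndarray
    phi: np.ndarray
    t: float = 0.0

    def copy(self) -> "GridState":
        return GridState(self.K_o.copy(), self.Na_i.copy(), self.V.copy(),
                         self.x_D.copy(), self.phi.copy(), self.t)

    def validate(self) -> None:
        """Raise with the offending field and cell on non-finite values."""
        for name in ("K_o", "Na_i", "V", "x_D", "phi"):
            arr = np.asarray(getattr(self, name))
            bad = ~np.isfinite(arr)
            if bad.any():
                cell = tuple(int(c) for c in
                             np.unravel_index(int(np.argmax(bad)), arr.shape))
                raise FloatingPointError(
                    f"non-finite value in field {name!r} at cell {cell} "
                    f"(t = {self.t:.3f} s)")


def nernst_potential(K_o):
    """Potassium reversal potential from the extracellular concentration.

    V_K = 26.6 mV * ln([K]_o / [K]_i) with the intracellular concentration
    fixed at 130 mM.  Strictly increasing in K_o.

    Parameters
    ----------
    K_o : float or ndarray
        Extracellular potassium concentration in mM; must be positive.

    Returns
    -------
    float or ndarray
        Reversal potential in mV (0 at 130 mM, about -100.3 mV at 3 mM).
    """
    K_o = np.asarray(K_o, dtype=float)
    if np.any(K_o <= 0):
        raise ValueError("nernst_potential requires K_o > 0")
    out = NERNST_MV * np.log(K_o / K_INTRA)
    return float(out) if out.ndim == 0 else out


def pump_current(K_o, Na_i, rho: float = 0.2):
    """Na+/K+ pump flux, a product of two sigmoids in [K]_o and [Na]_i.

    I_pump = rho / ((1 + exp(3.5 - [K]_o)) * (1 + exp((25 - [Na]_i)/3)))

    Bounded in (0, rho), smooth, and increasing in both concentrations.
    Units: mM/s (the pump enters the concentration balances directly).
    """
    K_o = np.asarray(K_o, dtype=float)
    Na_i = np.asarray(Na_i, dtype=float)
    out = rho / ((1.0 + np.exp(3.5 - K_o)) * (1.0 + np.exp((25.0 - Na_i) / 3.0)))
    return float(out) if out.ndim == 0 else out


def firing_rate(V, p: ModelParameters):
    """Somatic firing rate: a rectified sigmoid of the membrane potential.

    nu = nu_max * [2 / (1 + exp(-2 (V - V_th)/k_v)) - 1]_+

    which equals ``nu_max * tanh((V - V_th)/k_v)`` above threshold and 0 at
    or below it.  Monotone non-decreasing, saturating at nu_max.
    """
    V = np.asarray(V, dtype=float)
    arg = np.clip(-2.0 * (V - p.V_th) / p.k_v, -700.0, 700.0)
    x = 2.0 / (1.0 + np.exp(arg)) - 1.0
    out = p.nu_max * np.maximum(x, 0.0)
    return float(out) if out.ndim == 0 else out


def input_current(V_K, phi, x_D, xi, p: ModelParameters, Gsyn_over_gL=None):
    """Total input current u/g_L (mV): potassium leak + synaptic + noise.

    u/g_L = gK_leak/g_L * (V_K - V_K0)
          + Gsyn/g_L * phi * (x_D - c_IE)
          + sigma/g_L * xi

    The synaptic factor combines depressing excitation (``phi * x_D``) and
    non-depressing inhibition (``-c_IE * phi``) through the single per-cell
    conductance ``Gsyn_over_gL`` (elevated inside the excitation disk).

    Parameters
    ----------
    V_K : float or ndarray
        Potassium reversal potential (mV).
    phi : float or ndarray
        Rate driving the synapses (Hz); the presynaptic rate for the
        synaptic variants, the somatic rate for the diffusion-only variant.
    x_D : float or ndarray
        Synaptic resource fraction.
    xi : float or ndarray
        Standard-normal noise draw.
    Gsyn_over_gL : float or ndarray, optional
        Per-cell synaptic strength map; defaults to ``p.Gsyn_over_gL``.
    """
    if Gsyn_over_gL is None:
        Gsyn_over_gL = p.Gsyn_over_gL
    out = (p.gK_leak_over_gL * (np.asarray(V_K, dtype=float) - p.V_K0)
           + np.asarray(Gsyn_over_gL) * np.asarray(phi) * (np.asarray(x_D) - p.c_IE)
           + p.sigma_over_gL * np.asarray(xi))
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def local_rhs(K_o, Na_i, V, x_D, theta, u, p: ModelParameters, K_bath=None):
    """Per-cell time derivatives of (K_o, Na_i, V, x_D); diffusion excluded.

    d[K]_o/dt  = ([K]_bath - [K]_o)/tau_K - 2 gamma I_pump + delta_K theta
    d[Na]_i/dt = ([Na]_i0 - [Na]_i)/tau_Na - 3 I_pump + delta_Na theta
    dV/dt      = (-V + u)/tau_m
    dx_D/dt    = (1 - x_D)/tau_D - delta_x x_D theta

    ``theta`` is the rate that loads the ion balances and depresses the
    synapse: the somatic rate nu for the diffusion-only variant, the
    presynaptic rate phi otherwise.  ``u`` is the input current as u/g_L in
    mV.  The potassium diffusion term is added by the engine.

    Returns
    -------
    tuple of ndarrays ``(dK_o, dNa_i, dV, dx_D)`` in units per second.
    """
    if K_bath is None:
        K_bath = p.K_bath
    I_p = pump_current(K_o, Na_i, p.rho)
    theta = np.asarray(theta, dtype=float)
    dK = ((np.asarray(K_bath) - K_o) / p.tau_K
          - 2.0 * p.gamma * I_p + p.delta_K * theta)
    dNa = (p.Na_i0 - np.asarray(Na_i)) / p.tau_Na - 3.0 * I_p + p.delta_Na * theta
    dV = (-np.asarray(V) + np.asarray(u)) / p.tau_m
    dxD = (1.0 - np.asarray(x_D)) / p.tau_D - p.delta_x * np.asarray(x_D) * theta
    return dK, dNa, dV, dxD


def rest_state_residual(x, p: ModelParameters):
    """Residual of the quiescent (theta = 0) fixed point of (K_o, Na_i).

    Feed to a root-finder: the deterministic rest state without firing
    solves both concentration balances simultaneously.
    """
    K_o, Na_i = x
    I_p = pump_current(K_o, Na_i, p.rho)
    return ((p.K_bath - K_o) / p.tau_K - 2.0 * p.gamma * I_p,
            (p.Na_i0 - Na_i) / p.tau_Na - 3.0 * I_p)
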