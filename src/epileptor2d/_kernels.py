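"""Numba-compiled inner kernels for the time stepper.

The fused update applies one explicit Euler(-Maruyama) step of the four
differential fields in a single pass over the grid; the rate kernel
evaluates the firing sigmoid and returns the maximum (used to skip the
elliptic solve while the tissue is silent, where phi = 0 exactly).

These kernels are numerically identical (IEEE order preserved, no fastmath)
to the reference numpy expressions in :mod:`epileptor2d.dynamics`.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def firing_rate_kernel(V, V_th, k_v, nu_max, out):  # pragma: no cover - jit
    ny, nx = V.shape
    m = 0.0
    for i in range(ny):
        for j in range(nx):
            x = 2.0 / (1.0 + np.exp(-2.0 * (V[i, j] - V_th) / k_v)) - 1.0
            v = nu_max * x if x > 0.0 else 0.0
            out[i, j] = v
            if v > m:
                m = v
    return m


@nb.njit(cache=True)
def fused_step_kernel(K, Na, V, xD, K_new, theta, Gsyn, Kbath,
                      open_x, open_y,
                      xi_field, xi_scalar, use_field,
                      dt, dx, VK0, DK,
                      tau_K, tau_Na, tau_m, tau_D,
                      delta_K, delta_Na, delta_x,
                      sigma, rho, gamma, c_IE, gK_leak, Na_i0):  # pragma: no cover
    """One explicit step; reads K, writes K_new, updates Na/V/xD in place."""
    ny, nx = K.shape
    inv_dx2 = 1.0 / (dx * dx)
    for i in range(ny):
        for j in range(nx):
            lap = 0.0
            if DK > 0.0:
                s = 0.0
                if i > 0:
                    s += open_y[i - 1, j] * (K[i - 1, j] - K[i, j])
                if i < ny - 1:
                    s += open_y[i, j] * (K[i + 1, j] - K[i, j])
                if j > 0:
                    s += open_x[i, j - 1] * (K[i, j - 1] - K[i, j])
                if j < nx - 1:
                    s += open_x[i, j] * (K[i, j + 1] - K[i, j])
                lap = s * inv_dx2
            VK = 26.6 * np.log(K[i, j] / 130.0)
            Ip = rho / ((1.0 + np.exp(3.5 - K[i, j]))
                        * (1.0 + np.exp((25.0 - Na[i, j]) / 3.0)))
            xi = xi_field[i, j] if use_field else xi_scalar
            u = (gK_leak * (VK - VK0)
                 + Gsyn[i, j] * theta[i, j] * (xD[i, j] - c_IE)
                 + sigma * xi)
            # concentrations must stay positive: the explicit update can
            # undershoot zero when the pump runs near its maximum
            Kn = K[i, j] + dt * ((Kbath[i, j] - K[i, j]) / tau_K
                                 - 2.0 * gamma * Ip
                                 + delta_K * theta[i, j]
                                 + DK * lap)
            # NaN fails both comparisons and propagates to the
            # finiteness check instead of being silently floored
            if Kn <= 0.05:
                Kn = 0.05
            K_new[i, j] = Kn
            Nan = Na[i, j] + dt * ((Na_i0 - Na[i, j]) / tau_Na
                                   - 3.0 * Ip + delta_Na * theta[i, j])
            if Nan <= 0.05:
                Nan = 0.05
            Na[i, j] = Nan
            V[i, j] += dt * (-V[i, j] + u) / tau_m
            x = xD[i, j] + dt * ((1.0 - xD[i, j]) / tau_D
                                 - delta_x * xD[i, j] * theta[i, j])
            xD[i, j] = min(max(x, 0.0), 1.0)
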