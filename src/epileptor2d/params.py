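"""Model parameters for the spatially extended Epileptor-2 system.

The internal unit system is seconds, millimetres, millivolts, millimolar and
hertz.  Configuration files accept the conventional mixed units of the
modelling literature (diffusion in cm^2/s, membrane and adaptation time
constants in ms); conversion happens once, at load time.

Currents that enter the membrane-potential equation are carried as ``u/g_L``
in mV throughout: the leak conductance never appears on its own in the model,
only in ratios, so the voltage-like representation avoids a redundant symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

#: Nernst prefactor RT/F at warm temperature, mV.
NERNST_MV = 26.6

#: Intracellular potassium concentration, held fixed (mM).
K_INTRA = 130.0


@dataclass
class ModelParameters:
    """Population-model parameters.

    Defaults are the reference values of the model; time constants are stored
    in seconds and the diffusion coefficient in mm^2/s.

    Attributes
    ----------
    tau_K : float
        Extracellular potassium relaxation time constant (s).
    tau_Na : float
        Intracellular sodium relaxation time constant (s).
    tau_m : float
        Membrane time constant C/g_L (s).
    tau_D : float
        Synaptic-depression recovery time constant (s).
    D_K : float
        Extracellular potassium diffusion coefficient (mm^2/s).
    delta_K, delta_Na : float
        Concentration increments per unit firing rate (mM per spike, i.e.
        mM*s when multiplied by a rate in Hz).
    delta_x : float
        Synaptic-resource decrement per spike (dimensionless).
    sigma_over_gL : float
        Noise amplitude entering the input current, as u/g_L (mV).
    rho : float
        Maximum Na/K pump flux (mM/s).
    gamma : float
        Intra/extracellular volume ratio scaling the pump's potassium term.
    Gsyn_over_gL : float
        Postsynaptic charge per presynaptic spike, as u/g_L (mV*s).  The
        domain may override this per cell (excitation disk vs. periphery).
    c_IE : float
        Inhibitory-to-excitatory conductance ratio.
    gK_leak_over_gL : float
        Potassium leak conductance relative to g_L (dimensionless).
    K_o0, Na_i0 : float
        Initial (resting) concentrations (mM).
    K_bath : float
        Bath potassium concentration the tissue relaxes toward (mM).
    nu_max : float
        Maximal somatic firing rate (Hz).
    lambda_conn : float
        Characteristic length of the connectivity kernel (mm).
    V_th : float
        Firing threshold of the rate sigmoid (mV).
    k_v : float
        Gain (width) of the rate sigmoid (mV).
    model_variant : int
        1 = potassium diffusion only (theta = nu), 2 = axo-dendritic spread
        only (theta = phi), 3 = both mechanisms.
    """

    tau_K: float = 100.0
    tau_Na: float = 20.0
    tau_m: float = 0.010
    tau_D: float = 2.0
    D_K: float = 4.0e-4
    delta_K: float = 0.04
    delta_Na: float = 0.03
    delta_x: float = 0.01
    sigma_over_gL: float = 25.0
    rho: float = 0.2
    gamma: float = 20.0
    Gsyn_over_gL: float = 5.0
    c_IE: float = 0.5
    gK_leak_over_gL: float = 1.0
    K_o0: float = 3.0
    K_bath: float = 7.0
    Na_i0: float = 10.0
    nu_max: float = 100.0
    lambda_conn: float = 0.385
    V_th: float = 25.0
    k_v: float = 20.0
    model_variant: int = 2

    @property
    def V_K0(self) -> float:
        """Potassium reversal potential at the initial concentration (mV)."""
        return NERNST_MV * math.log(self.K_o0 / K_INTRA)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tau_K", "tau_Na", "tau_m", "tau_D", "gamma",
                     "K_o0", "K_bath", "Na_i0", "nu_max", "lambda_conn",
                     "k_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be positive, "
                                 f"got {getattr(self, name)}")
        for name in ("D_K", "rho", "sigma_over_gL"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative, "
                                 f"got {getattr(self, name)}")
        if self.c_IE < 0:
            raise ValueError(f"c_IE must be non-negative, got {self.c_IE}")
        if not 0.0 <= self.delta_x <= 1.0:
            raise ValueError(f"delta_x must lie in [0, 1], got {self.delta_x}")
        if self.model_variant not in (1, 2, 3):
            raise ValueError(f"model_variant must be 1, 2 or 3, "
                             f"got {self.model_variant}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(overrides)
        return ModelParameters(**values)


@dataclass
class NeuronParameters:
    """Adaptive quadratic integrate-and-fire neuron-observer parameters.

    Units follow single-cell convention: pF, nS, mV, pA, ms.
    """

    C_U: float = 1050.0     # pF
    g_U: float = 1.5        # nS/mV
    V_T: float = 25.0       # mV, spike threshold
    V_reset: float = -40.0  # mV
    U1: float = -60.0       # mV
    U2: float = -40.0       # mV
    U0: float = -70.0       # mV, initial potential
    I_a: float = 116.0      # pA, tonic current
    tau_w: float = 200.0    # ms
    delta_w: float = 100.0  # pA

    def __post_init__(self) -> None:
        if self.C_U <= 0 or self.g_U <= 0:
            raise ValueError("C_U and g_U must be positive")
        if not self.U1 < self.U2:
            raise ValueError(f"requires U1 < U2, got U1={self.U1}, U2={self.U2}")
        if not self.V_reset < self.V_T:
            raise ValueError("requires V_reset < V_T")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
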