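"""Time integration of the spatially extended Epileptor-2 system.

The engine owns the cortical-sheet geometry (:class:`Domain`), advances the
five dynamical fields with an explicit Euler(-Maruyama) scheme at a fixed
time step, and records probe traces, a radial potassium/rate profile and
periodic field snapshots into a :class:`SimulationRecord`.

Three model variants share one stepper:

* variant 1 — potassium diffusion only; the rate loading the ion balances
  and driving the synapses is the local somatic rate (theta = nu),
* variant 2 — axo-dendritic spread only; theta is the presynaptic rate phi
  from the screened-Poisson connectivity solve, and the potassium diffusion
  term is absent,
* variant 3 — both mechanisms active.

While the whole sheet is silent (nu = 0 everywhere) the connectivity solve
is skipped: phi = 0 is then the exact solution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from ._kernels import firing_rate_kernel, fused_step_kernel
from .dynamics import GridState, firing_rate, input_current, nernst_potential
from .operators import LesionMask, ScreenedPoissonSolver, make_lesion_mask
from .params import ModelParameters

__all__ = [
    "Domain",
    "build_domain",
    "generate_noise",
    "Simulator",
    "SimulationRecord",
    "run",
    "sweep",
]

PROBE_FIELDS = ("K_o", "Na_i", "V", "x_D", "phi", "nu", "u")

#: Explicit-diffusion stability bound on D_K * dt / dx^2.
STABILITY_LIMIT = 0.25


@dataclass
class Domain:
    """Grid geometry and per-cell parameter maps.

    The default configuration is a 6 x 6 mm sheet of 80 x 80 cells with a
    central excitation disk of radius 0.3 mm in which the synaptic strength
    is elevated (Gsyn/gL = 5 mV s against 1 mV s in the periphery).
    Cell (i, j) is centred at ((j + 1/2) dx, (i + 1/2) dx), i indexing y.
    """

    nx: int
    ny: int
    dx: float
    Gsyn_map: np.ndarray
    Kbath_map: np.ndarray
    excitation_center: Tuple[float, float]
    excitation_radius: float
    lesion: LesionMask = field(default_factory=LesionMask)
    probes: List[Tuple[str, float, float]] = field(default_factory=list)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def width(self) -> float:
        return self.nx * self.dx

    @property
    def height(self) -> float:
        return self.ny * self.dx

    def cell_of(self, x: float, y: float) -> Tuple[int, int]:
        """Grid cell containing the point (x, y) in mm."""
        j = int(np.clip(x / self.dx, 0, self.nx - 1))
        i = int(np.clip(y / self.dx, 0, self.ny - 1))
        return i, j

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        xs = (np.arange(self.nx) + 0.5) * self.dx
        ys = (np.arange(self.ny) + 0.5) * self.dx
        return np.meshgrid(xs, ys)


def build_domain(width: float = 6.0, height: float = 6.0,
                 nx: int = 80, ny: int = 80,
                 excitation_center: Optional[Tuple[float, float]] = None,
                 excitation_radius: float = 0.3,
                 Gsyn_center: float = 5.0, Gsyn_periphery: float = 1.0,
                 Kbath_center: Optional[float] = None,
                 Kbath_periphery: float = 7.0,
                 lesion_geometry: Optional[dict] = None,
                 probes: Optional[Sequence[Tuple[str, float, float]]] = None,
                 ) -> Domain:
    """Construct the domain with its per-cell maps.

    Disk membership is decided by cell-centre distance to the excitation
    centre.  ``Kbath_center`` zones the bath concentration over the same
    disk (used by the complete-lesion preset); by default the bath is
    uniform at ``Kbath_periphery``.  Default probes are S1 at the
    excitation centre and S2 two millimetres toward the +x boundary.
    """
    if nx <= 0 or ny <= 0:
        raise ValueError("grid dimensions must be positive")
    dx = width / nx
    if abs(height / ny - dx) > 1e-12:
        raise ValueError("cells must be square: width/nx must equal height/ny")
    if dx <= 0:
        raise ValueError("dx must be positive")
    if excitation_center is None:
        excitation_center = (width / 2.0, height / 2.0)
    xc, yc = excitation_center
    if excitation_radius < 0:
        raise ValueError("excitation_radius must be non-negative")
    if not (0 <= xc <= width and 0 <= yc <= height):
        raise ValueError("excitation disk centre lies outside the domain")

    X, Y = np.meshgrid((np.arange(nx) + 0.5) * dx, (np.arange(ny) + 0.5) * dx)
    disk = (X - xc) ** 2 + (Y - yc) ** 2 <= excitation_radius ** 2
    Gsyn_map = np.where(disk, Gsyn_center, Gsyn_periphery).astype(float)
    if Kbath_center is None:
        Kbath_map = np.full((ny, nx), float(Kbath_periphery))
    else:
        Kbath_map = np.where(disk, Kbath_center, Kbath_periphery).astype(float)

    lesion = make_lesion_mask(lesion_geometry, (ny, nx), dx)
    if probes is None:
        probes = [("S1", xc, yc), ("S2", min(xc + 2.0, width - dx / 2), yc)]
    return Domain(nx=nx, ny=ny, dx=dx, Gsyn_map=Gsyn_map, Kbath_map=Kbath_map,
                  excitation_center=(xc, yc), excitation_radius=excitation_radius,
                  lesion=lesion, probes=list(probes))


def generate_noise(mode: str, shape: Tuple[int, int],
                   rng: np.random.Generator) -> np.ndarray:
    """One noise field: a shared draw (homogeneous) or i.i.d. per cell.

    Spatially homogeneous noise is a single standard-normal value broadcast
    to every cell — the same realization the simulator consumes, so records
    are reproducible either way through the seeded generator.
    """
    if mode == "homogeneous":
        return np.full(shape, rng.standard_normal())
    if mode == "inhomogeneous":
        return rng.standard_normal(shape)
    raise ValueError(f"unknown noise mode {mode!r}")


@dataclass
class SimulationRecord:
    """Probe traces, radial profiles, snapshots and reproducibility metadata."""

    t_probe: np.ndarray                       # (n,)
    probes: Dict[str, np.ndarray]             # label -> (n, 7), PROBE_FIELDS
    ray_t: np.ndarray                         # (m,)
    ray_r: np.ndarray                         # (nr,) radial distance, mm
    ray_K: np.ndarray                         # (m, nr)
    ray_nu: np.ndarray                        # (m, nr)
    snap_t: np.ndarray                        # (s,)
    snap_K: np.ndarray                        # (s, ny, nx)
    snap_V: np.ndarray                        # (s, ny, nx)
    snap_phi: np.ndarray                      # (s, ny, nx)
    seed: int
    model_variant: int
    dt: float
    dx: float
    config_echo: dict = field(default_factory=dict)
    roi_t: Optional[np.ndarray] = None        # burst-rate ROI capture
    roi_y: Optional[np.ndarray] = None
    roi_V: Optional[np.ndarray] = None        # (len(roi_t), ny)

    def probe_frame(self, label: str) -> pd.DataFrame:
        df = pd.DataFrame(self.probes[label], columns=list(PROBE_FIELDS))
        df.insert(0, "t", self.t_probe)
        return df

    # -- persistence ---------------------------------------------------
    def save(self, out_dir) -> None:
        """Probe series as CSV (one file per probe), fields as HDF5."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label in self.probes:
            self.probe_frame(label).to_csv(out / f"probe_{label}.csv",
                                           index=False)
        with h5py.File(out / "fields.h5", "w") as h5:
            h5.attrs["seed"] = self.seed
            h5.attrs["model_variant"] = self.model_variant
            h5.attrs["dt"] = self.dt
            h5.attrs["dx"] = self.dx
            h5.attrs["units"] = "s, mm, mV, mM, Hz"
            # field snapshots under their physical names, time on axis 0
            for dset, attr in (("K_o", "snap_K"), ("V", "snap_V"),
                               ("phi", "snap_phi"), ("snapshot_t", "snap_t")):
                h5.create_dataset(dset, data=getattr(self, attr))
            for name in ("ray_t", "ray_r", "ray_K", "ray_nu"):
                h5.create_dataset(name, data=getattr(self, name))
            for name in ("roi_t", "roi_y", "roi_V"):
                val = getattr(self, name)
                if val is not None:
                    h5.create_dataset(name, data=val)
        (out / "config.json").write_text(
            json.dumps(self.config_echo, indent=2, sort_keys=True))
        t = self.t_probe
        probe_df = pd.DataFrame(
            {label: arr[:, 0] for label, arr in self.probes.items()})
        probe_df.insert(0, "t", t)
        probe_df.to_csv(out / "probes_K_o.csv", index=False)

    @classmethod
    def load(cls, out_dir) -> "SimulationRecord":
        out = Path(out_dir)
        with h5py.File(out / "fields.h5", "r") as h5:
            kw = {name: h5[name][...] for name in
                  ("ray_t", "ray_r", "ray_K", "ray_nu")}
            kw.update(snap_t=h5["snapshot_t"][...], snap_K=h5["K_o"][...],
                      snap_V=h5["V"][...], snap_phi=h5["phi"][...])
            for name in ("roi_t", "roi_y", "roi_V"):
                kw[name] = h5[name][...] if name in h5 else None
            seed = int(h5.attrs["seed"])
            variant = int(h5.attrs["model_variant"])
            dt = float(h5.attrs["dt"])
            dx = float(h5.attrs["dx"])
        probes = {}
        t_probe = None
        for f in sorted(out.glob("probe_*.csv")):
            label = f.stem[len("probe_"):]
            df = pd.read_csv(f)
            t_probe = df["t"].to_numpy()
            probes[label] = df[list(PROBE_FIELDS)].to_numpy()
        config_echo = {}
        cfg = out / "config.json"
        if cfg.exists():
            config_echo = json.loads(cfg.read_text())
        return cls(t_probe=t_probe, probes=probes, seed=seed,
                   model_variant=variant, dt=dt, dx=dx,
                   config_echo=config_echo, **kw)


class Simulator:
    """Explicit stepper for one configured domain and parameter set.

    Parameters
    ----------
    domain : Domain
    params : ModelParameters
        ``params.model_variant`` selects the propagation mechanism.
    noise_mode : {"homogeneous", "inhomogeneous"}
        Shared noise draw per step versus i.i.d. per cell.
    noise_convention : {"per_step", "step_invariant"}
        ``per_step`` adds sigma * xi to the input current with a fresh draw
        each step (the reference convention at dt = 1 ms).
        ``step_invariant`` rescales the amplitude by sqrt(1 ms / dt) so the
        stationary voltage variance is independent of the step size.
    dt : float
        Time step in seconds (default 1 ms).
    """

    def __init__(self, domain: Domain, params: ModelParameters,
                 noise_mode: str = "homogeneous",
                 noise_convention: str = "per_step",
                 dt: float = 1e-3):
        if noise_mode not in ("homogeneous", "inhomogeneous"):
            raise ValueError(f"unknown noise mode {noise_mode!r}")
        if noise_convention not in ("per_step", "step_invariant"):
            raise ValueError(f"unknown noise convention {noise_convention!r}")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.domain = domain
        self.params = params
        self.noise_mode = noise_mode
        self.noise_convention = noise_convention
        self.dt = float(dt)

        self._DK = params.D_K if params.model_variant in (1, 3) else 0.0
        stability = self._DK * self.dt / domain.dx ** 2
        if stability >= STABILITY_LIMIT:
            raise ValueError(
                f"explicit diffusion unstable: D_K*dt/dx^2 = {stability:.3g} "
                f">= {STABILITY_LIMIT} (reduce dt or D_K)")

        self._open_x, self._open_y = domain.lesion.edge_openness(
            domain.shape, for_phi=False)
        self._phi_solver: Optional[ScreenedPoissonSolver] = None
        if params.model_variant in (2, 3):
            self._phi_solver = ScreenedPoissonSolver(
                domain.shape, params.lambda_conn, domain.dx, domain.lesion)
        self._sigma_eff = params.sigma_over_gL
        if noise_convention == "step_invariant":
            self._sigma_eff *= math.sqrt(1e-3 / self.dt)
        self._Gsyn = np.ascontiguousarray(domain.Gsyn_map, dtype=float)
        self._Kbath = np.ascontiguousarray(domain.Kbath_map, dtype=float)
        self._dummy_field = np.zeros((1, 1))

    # ------------------------------------------------------------------
    def initial_state(self) -> GridState:
        """Rest state: concentrations at their initial values, V = 0,
        full synaptic resource, phi from the elliptic solve at t = 0."""
        p = self.params
        shape = self.domain.shape
        K = np.full(shape, p.K_o0)
        Na = np.full(shape, p.Na_i0)
        V = np.zeros(shape)
        xD = np.ones(shape)
        nu = firing_rate(V, p)
        phi = (self._phi_solver.solve(nu) if self._phi_solver is not None
               else np.zeros(shape))
        return GridState(K, Na, V, xD, phi, t=0.0)

    def rate_fields(self, state: GridState) -> Tuple[np.ndarray, np.ndarray, float]:
        """Somatic rate nu, loading rate theta and max(nu) for the state."""
        p = self.params
        nu = np.empty_like(state.V)
        nu_max = firing_rate_kernel(state.V, p.V_th, p.k_v, p.nu_max, nu)
        if self._phi_solver is not None:
            theta = (self._phi_solver.solve(nu) if nu_max > 0.0
                     else np.zeros_like(nu))
        else:
            theta = nu
        return nu, theta, nu_max

    def _advance(self, K, Na, V, xD, K_buf, theta, xi_field, xi_scalar,
                 use_field: bool) -> None:
        p = self.params
        fused_step_kernel(
            K, Na, V, xD, K_buf, theta, self._Gsyn, self._Kbath,
            self._open_x, self._open_y,
            xi_field, xi_scalar, use_field,
            self.dt, self.domain.dx, p.V_K0, self._DK,
            p.tau_K, p.tau_Na, p.tau_m, p.tau_D,
            p.delta_K, p.delta_Na, p.delta_x,
            self._sigma_eff, p.rho, p.gamma, p.c_IE, p.gK_leak_over_gL,
            p.Na_i0)

    def step(self, state: GridState, rng: np.random.Generator) -> GridState:
        """One explicit update of all fields; returns a new state.

        Aborts with a diagnostic naming the field and cell when any value
        turns non-finite.  The hot loop inside :meth:`run` performs the
        identical update in place with a sparser validity check.
        """
        new = state.copy()
        nu, theta, _ = self.rate_fields(state)
        if self.noise_mode == "homogeneous":
            xi_scalar = rng.standard_normal()
            xi_field, use_field = self._dummy_field, False
        else:
            xi_field = rng.standard_normal(state.V.shape)
            xi_scalar, use_field = 0.0, True
        K_buf = np.empty_like(new.K_o)
        self._advance(new.K_o, new.Na_i, new.V, new.x_D, K_buf, theta,
                      xi_field, xi_scalar, use_field)
        new.K_o = K_buf
        new.phi = theta if self._phi_solver is not None else nu
        new.t = state.t + self.dt
        new.validate()
        return new

    # ------------------------------------------------------------------
    def run(self, T: float, seed: int,
            ray_dt: float = 0.25, snapshot_dt: float = 1.0,
            probe_stride: int = 1,
            roi_window: Optional[Tuple[float, float]] = None,
            config_echo: Optional[dict] = None,
            progress: bool = False) -> SimulationRecord:
        """Integrate from the rest state to ``T`` seconds.

        Identical ``(configuration, seed)`` give bit-identical records.
        Probes sample every ``probe_stride`` steps; the radial ray (from the
        excitation centre toward the +x boundary) and full-field snapshots
        sample at their own cadences.  ``roi_window`` optionally captures
        the vertical strip through the excitation centre at every step
        inside the window (burst-rate resolution for space-time burst diagrams).
        """
        if T < 0:
            raise ValueError("T must be non-negative")
        p = self.params
        dom = self.domain
        dt = self.dt
        rng = np.random.default_rng(seed)
        nsteps = int(round(T / dt))

        state = self.initial_state()
        K, Na, V, xD = state.K_o, state.Na_i, state.V, state.x_D
        K_buf = np.empty_like(K)
        zero_theta = np.zeros_like(K)

        probe_cells = [(label, dom.cell_of(x, y)) for label, x, y in dom.probes]
        n_rec = nsteps // probe_stride + 1
        t_probe = np.empty(n_rec)
        probe_data = {label: np.empty((n_rec, len(PROBE_FIELDS)))
                      for label, _ in probe_cells}

        ci, cj = dom.cell_of(*dom.excitation_center)
        ray_cols = np.arange(cj, dom.nx)
        ray_r = (ray_cols - cj) * dom.dx
        ray_every = max(1, int(round(ray_dt / dt)))
        snap_every = max(1, int(round(snapshot_dt / dt)))
        ray_t, ray_K, ray_nu = [], [], []
        snap_t, snap_K, snap_V, snap_phi = [], [], [], []
        roi_t, roi_V = [], []

        check_every = 500
        homog = self.noise_mode == "homogeneous"
        xi_field, use_field = self._dummy_field, False

        rec_i = 0
        for n in range(nsteps + 1):
            t = n * dt
            nu, theta, nu_peak = self._rate_inplace(V)
            if homog:
                xi_scalar = rng.standard_normal()
            else:
                xi_field = rng.standard_normal(K.shape)
                xi_scalar, use_field = 0.0, True

            if n % probe_stride == 0:
                t_probe[rec_i] = t
                for label, (i, j) in probe_cells:
                    xi_ij = xi_scalar if homog else xi_field[i, j]
                    VK = 26.6 * math.log(K[i, j] / 130.0)
                    u = (p.gK_leak_over_gL * (VK - p.V_K0)
                         + self._Gsyn[i, j] * theta[i, j] * (xD[i, j] - p.c_IE)
                         + self._sigma_eff * xi_ij)
                    probe_data[label][rec_i] = (K[i, j], Na[i, j], V[i, j],
                                                xD[i, j], theta[i, j],
                                                nu[i, j], u)
                rec_i += 1
            if n % ray_every == 0:
                ray_t.append(t)
                ray_K.append(K[ci, ray_cols].copy())
                ray_nu.append(nu[ci, ray_cols].copy())
            if n % snap_every == 0:
                snap_t.append(t)
                snap_K.append(K.copy())
                snap_V.append(V.copy())
                snap_phi.append(np.array(theta, copy=True))
            if roi_window is not None and roi_window[0] <= t <= roi_window[1]:
                roi_t.append(t)
                roi_V.append(V[:, cj].copy())

            if n == nsteps:
                break
            self._advance(K, Na, V, xD, K_buf, theta, xi_field, xi_scalar,
                          use_field)
            K, K_buf = K_buf, K
            if (n + 1) % check_every == 0:
                self._check_finite(K, Na, V, xD, t + dt)
            if progress and n % int(1.0 / dt) == 0:  # pragma: no cover
                import sys
                print(f"\rsimulated {t:8.1f} / {T:.1f} s", end="",
                      file=sys.stderr)
        self._check_finite(K, Na, V, xD, nsteps * dt)
        if progress:  # pragma: no cover
            import sys
            print(file=sys.stderr)

        roi_y = ((np.arange(dom.ny) + 0.5) * dom.dx if roi_window is not None
                 else None)
        return SimulationRecord(
            t_probe=t_probe[:rec_i],
            probes={lab: arr[:rec_i] for lab, arr in probe_data.items()},
            ray_t=np.asarray(ray_t), ray_r=ray_r,
            ray_K=np.asarray(ray_K), ray_nu=np.asarray(ray_nu),
            snap_t=np.asarray(snap_t),
            snap_K=np.asarray(snap_K), snap_V=np.asarray(snap_V),
            snap_phi=np.asarray(snap_phi),
            seed=seed, model_variant=p.model_variant, dt=dt, dx=dom.dx,
            config_echo=config_echo or {},
            roi_t=np.asarray(roi_t) if roi_window is not None else None,
            roi_y=roi_y,
            roi_V=np.asarray(roi_V) if roi_window is not None else None)

    def _rate_inplace(self, V):
        p = self.params
        if not hasattr(self, "_nu_buf") or self._nu_buf.shape != V.shape:
            self._nu_buf = np.empty_like(V)
            self._zero_buf = np.zeros_like(V)
        nu = self._nu_buf
        nu_peak = firing_rate_kernel(V, p.V_th, p.k_v, p.nu_max, nu)
        if self._phi_solver is not None:
            theta = (self._phi_solver.solve(nu) if nu_peak > 0.0
                     else self._zero_buf)
        else:
            theta = nu
        return nu, theta, nu_peak

    @staticmethod
    def _check_finite(K, Na, V, xD, t) -> None:
        for name, arr in (("K_o", K), ("Na_i", Na), ("V", V), ("x_D", xD)):
            if not np.isfinite(arr).all():
                bad = ~np.isfinite(arr)
                cell = tuple(int(c) for c in
                             np.unravel_index(int(np.argmax(bad)), arr.shape))
                raise FloatingPointError(
                    f"non-finite value in field {name!r} at cell {cell} "
                    f"(t = {t:.3f} s)")


# ----------------------------------------------------------------------
def run(config, seed: Optional[int] = None,
        progress: bool = False) -> SimulationRecord:
    """Run a full simulation described by a :class:`~epileptor2d.config.RunConfig`."""
    sim = Simulator(config.make_domain(), config.make_params(),
                    noise_mode=config.noise_mode,
                    noise_convention=config.noise_convention,
                    dt=config.dt)
    use_seed = config.seed if seed is None else seed
    return sim.run(config.total_time, seed=use_seed,
                   ray_dt=config.ray_dt, snapshot_dt=config.snapshot_dt,
                   probe_stride=config.probe_stride,
                   roi_window=config.roi_window,
                   config_echo=config.echo(), progress=progress)


def sweep(config, parameter: str, values: Sequence[float],
          seed: Optional[int] = None, progress: bool = False) -> pd.DataFrame:
    """Front-speed scan over one parameter on the configured domain.

    Intended for the narrow-strip preset (a 6 x 0.6 mm domain with the
    excitation disk at one end).  ``values`` are in configuration units
    (D_K in cm^2/s).  Each row reports the first-wave speed measured from
    threshold arrival times along the strip; failed runs are flagged rather
    than aborting the scan.
    """
    from .analysis import front_arrival_times, wavefront_speed

    allowed = {"D_K", "lambda_conn", "c_IE", "gK_leak_over_gL"}
    if parameter not in allowed:
        raise ValueError(f"sweep parameter must be one of {sorted(allowed)}, "
                         f"got {parameter!r}")
    rows = []
    for value in values:
        cfg = config.with_overrides(**{parameter: value})
        try:
            rec = run(cfg, seed=seed, progress=progress)
            front = front_arrival_times(rec.ray_t, rec.ray_r, rec.ray_K)
            fit = wavefront_speed(front)
            rows.append({"value": value, "speed": fit.speed,
                         "n_arrivals": fit.n_points,
                         "residual": fit.residual, "error": ""})
        except Exception as exc:  # noqa: BLE001 - flagged per row by contract
            rows.append({"value": value, "speed": np.nan, "n_arrivals": 0,
                         "residual": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
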