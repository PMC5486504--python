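"""Unsteady incompressible flow on the masked grid.

The solver integrates the 2-D incompressible Navier–Stokes equations with a
finite-volume discretization on a staggered (MAC) grid and SIMPLE
pressure–velocity coupling: first-order upwind convection, central
diffusion, implicit Euler in time, and under-relaxed momentum / pressure
corrections.  Boundary conditions follow the physiological setup: no-slip
rigid walls, a flat (uniform) velocity profile at the inlet scaled to the
instantaneous flow rate, and a zero-pressure outflow (implemented as a
zero-gradient outlet velocity rescaled for exact global mass balance, with
the pressure level pinned to zero at the outlet).

The pulsatile inflow is a single-harmonic waveform fixed by its mean, its
maximum and the heart rate — the three quantities that characterize the
transcranial-Doppler flow conditions — and several cycles are integrated so
the start-up transient decays; only the last cycle is returned.

The 2-D channel is matched to the physiological regime through the
reference vessel diameter: the mean velocity is that of a circular vessel
carrying the mean flow, so the channel Reynolds and Womersley numbers equal
their in-vivo counterparts (Re ~= 364, alpha ~= 2.32 at the defaults).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import units
from .meshing import Mesh

__all__ = [
    "FlowConditions",
    "Numerics",
    "FlowField",
    "SolverError",
    "inlet_waveform",
    "reynolds_number",
    "womersley_number",
    "diameter_for_reynolds",
    "diameter_for_womersley",
    "analytic_channel_solution",
    "simulate_pulsatile",
    "simulate_steady",
]

#: dimensionless numbers of the physiological inflow (printed TCD regime)
PHYSIOLOGIC_REYNOLDS = 364.0
PHYSIOLOGIC_WOMERSLEY = 2.32


class SolverError(RuntimeError):
    """SIMPLE failed to converge; carries the residual history."""

    def __init__(self, msg: str, residuals: list[float] | None = None):
        super().__init__(msg)
        self.residuals = residuals or []


@dataclass(frozen=True)
class FlowConditions:
    """Fluid properties and pulsatile inflow parameters.

    Units are clinical at this interface: flows in ml/min, heart rate in
    beats/min, diameter in mm; density and viscosity in SI.
    """

    density: float = 1050.0  # kg/m^3
    viscosity: float = 3.5e-3  # Pa s
    mean_flow: float = 185.0  # ml/min
    max_flow: float = 301.0  # ml/min
    heart_rate: float = 64.0  # bpm
    n_cycles: int = 3
    reference_diameter: float | None = None  # mm; derived from Re=364 if None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")
        if not (0 <= self.mean_flow <= self.max_flow):
            raise ValueError("need 0 <= mean_flow <= max_flow")
        if self.heart_rate <= 0 or self.n_cycles < 1:
            raise ValueError("heart_rate must be > 0 and n_cycles >= 1")

    @property
    def period(self) -> float:
        """Cardiac period in seconds (60 / heart rate)."""
        return 60.0 / self.heart_rate

    @property
    def diameter_mm(self) -> float:
        """Reference vessel caliber in mm (from Re = 364 unless given)."""
        if self.reference_diameter is not None:
            return self.reference_diameter
        return diameter_for_reynolds(self, PHYSIOLOGIC_REYNOLDS)

    def mean_velocity(self) -> float:
        """Cross-section mean velocity (m/s) of a circular vessel at mean flow."""
        d = units.mm_to_m(self.diameter_mm)
        return units.mlmin_to_m3s(self.mean_flow) / (math.pi * (d / 2.0) ** 2)

    def per_depth_rate(self, t: float | np.ndarray, channel_height_mm: float):
        """Instantaneous 2-D per-depth flow rate q(t) in m^2/s.

        The channel carries the same mean velocity as the reference
        circular vessel, so q = U(t) * H with U(t) the instantaneous tube
        mean velocity.
        """
        u = self.mean_velocity() * inlet_waveform(t, self) / max(self.mean_flow, 1e-300)
        return u * units.mm_to_m(channel_height_mm)


def inlet_waveform(t, flow: FlowConditions):
    """Single-harmonic inflow rate (ml/min) at time ``t`` seconds.

    Q(t) = Q_mean + (Q_max - Q_mean) sin(2 pi t / T): periodic with the
    cardiac period, time-mean Q_mean, maximum Q_max.
    """
    t = np.asarray(t, dtype=float)
    q = flow.mean_flow + (flow.max_flow - flow.mean_flow) * np.sin(
        2.0 * math.pi * t / flow.period
    )
    return q if q.ndim else float(q)


def reynolds_number(flow: FlowConditions) -> float:
    """Tube Reynolds number Re = rho U D / mu = 4 rho Q / (mu pi D)."""
    q = units.mlmin_to_m3s(flow.mean_flow)
    d = units.mm_to_m(flow.diameter_mm)
    return 4.0 * flow.density * q / (flow.viscosity * math.pi * d)


def womersley_number(flow: FlowConditions) -> float:
    """Womersley number alpha = R sqrt(omega rho / mu), R the vessel radius."""
    r = units.mm_to_m(flow.diameter_mm) / 2.0
    omega = units.bpm_to_rad_s(flow.heart_rate)
    return r * math.sqrt(omega * flow.density / flow.viscosity)


def diameter_for_reynolds(flow: FlowConditions, re: float) -> float:
    """Vessel diameter (mm) at which the mean flow gives Reynolds ``re``."""
    q = units.mlmin_to_m3s(flow.mean_flow)
    return units.m_to_mm(4.0 * flow.density * q / (flow.viscosity * math.pi * re))


def diameter_for_womersley(flow: FlowConditions, alpha: float) -> float:
    """Vessel diameter (mm) at which the heart rate gives Womersley ``alpha``."""
    omega = units.bpm_to_rad_s(flow.heart_rate)
    r = alpha / math.sqrt(omega * flow.density / flow.viscosity)
    return units.m_to_mm(2.0 * r)


def analytic_channel_solution(h, q_mean, q_amp, freq, rho, mu, t, y):
    """Exact developed velocity in a plane channel under q(t)=q_mean+q_amp sin.

    Plane Poiseuille for the steady part plus the oscillatory
    (Womersley-type) profile for the harmonic part; ``h`` channel height
    (m), per-depth rates in m^2/s, ``freq`` in Hz.  ``t`` and ``y``
    broadcast.  The zero-frequency limit is the steady parabola.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    u = 6.0 * q_mean / h**3 * y * (h - y)
    if q_amp == 0.0 or freq == 0.0:
        return u + np.zeros(np.broadcast_shapes(t.shape, y.shape))
    omega = 2.0 * math.pi * freq
    k = np.sqrt(1j * omega * rho / mu)
    phi = 1.0 - np.cosh(k * (y - h / 2.0)) / np.cosh(k * h / 2.0)
    q_of_phi = h - (2.0 / k) * np.tanh(k * h / 2.0)
    c = -1j * q_amp / q_of_phi
    return u + np.real(c * phi * np.exp(1j * omega * t))


@dataclass(frozen=True)
class Numerics:
    """SIMPLE / time-integration settings (all configurable, defaults robust).

    ``dt`` defaults to period/200; momentum and pressure under-relaxation
    0.7 / 0.3; per-step mass tolerance 1e-5 of the inflow flux, steady
    tolerance 1e-6.
    """

    dt: float | None = None  # s; None -> period / steps_per_cycle
    steps_per_cycle: int = 200
    alpha_u: float = 0.7
    alpha_p: float = 0.3
    tol_mass: float = 1e-5
    tol_steady: float = 1e-6
    tol_velocity: float = 1e-4  # relative velocity stationarity per outer iter
    momentum_sweeps: int = 4
    lu_refresh: int = 8  # refactor the pressure matrix every N outer iters
    max_inner: int = 400
    steady_max_iter: int = 4000


@dataclass
class FlowField:
    """Last-cycle staggered velocity and pressure snapshots.

    ``times`` are seconds within the last cycle (0 .. T inclusive); ``u``
    has shape (n_t, nx+1, ny), ``v`` (n_t, nx, ny+1), ``p`` (n_t, nx, ny).
    """

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    period: float
    mesh: Mesh
    convergence_log: list[tuple[int, int, float]] = field(default_factory=list)

    def cell_u(self, k: int) -> np.ndarray:
        """x-velocity at cell centres for snapshot k."""
        return 0.5 * (self.u[k, :-1, :] + self.u[k, 1:, :])


# ---------------------------------------------------------------------------
# SIMPLE machinery


class _Simple:
    """Precomputed stencils + SIMPLE iteration for one mesh and one fluid."""

    def __init__(self, mesh: Mesh, rho: float, mu: float, num: Numerics):
        self.mesh, self.rho, self.mu, self.num = mesh, rho, mu, num
        self.h = units.mm_to_m(mesh.cell_size)
        nx, ny = mesh.nx, mesh.ny
        fluid = mesh.fluid_mask
        self.nx, self.ny = nx, ny
        self.fluid = fluid

        inlet = np.zeros((nx + 1, ny), dtype=bool)
        inlet[0, mesh.inlet_rows] = True
        outlet = np.zeros((nx + 1, ny), dtype=bool)
        outlet[nx, mesh.outlet_rows] = True
        self.inlet_mask, self.outlet_mask = inlet, outlet

        u_unknown = np.zeros((nx + 1, ny), dtype=bool)
        u_unknown[1:nx, :] = fluid[:-1, :] & fluid[1:, :]
        v_unknown = np.zeros((nx, ny + 1), dtype=bool)
        v_unknown[:, 1:ny] = fluid[:, :-1] & fluid[:, 1:]
        self.u_unknown, self.v_unknown = u_unknown, v_unknown

        self.u_eq = -np.ones((nx + 1, ny), dtype=np.int64)
        self.u_eq[u_unknown] = np.arange(u_unknown.sum())
        self.v_eq = -np.ones((nx, ny + 1), dtype=np.int64)
        self.v_eq[v_unknown] = np.arange(v_unknown.sum())
        self.p_eq = -np.ones((nx, ny), dtype=np.int64)
        self.p_eq[fluid] = np.arange(fluid.sum())

        self._build_u_stencil()
        self._build_v_stencil()
        self._build_p_stencil()

    # -- index helpers ----------------------------------------------------
    def _uid(self, i, j):
        ok = (i >= 0) & (i <= self.nx) & (j >= 0) & (j < self.ny)
        out = np.where(ok, i * self.ny + j, -1)
        return out

    def _vid(self, i, j):
        ok = (i >= 0) & (i < self.nx) & (j >= 0) & (j <= self.ny)
        return np.where(ok, i * (self.ny + 1) + j, -1)

    def _pid(self, i, j):
        ok = (i >= 0) & (i < self.nx) & (j >= 0) & (j < self.ny)
        return np.where(ok, i * self.ny + j, -1)

    def _build_u_stencil(self):
        iu, ju = np.nonzero(self.u_unknown)
        self.iu, self.ju = iu, ju
        self.u_self = self._uid(iu, ju)
        self.u_nb = {
            "W": self._uid(iu - 1, ju),
            "E": self._uid(iu + 1, ju),
            "S": self._uid(iu, ju - 1),
            "N": self._uid(iu, ju + 1),
        }
        eqflat = np.append(self.u_eq.ravel(), -1)
        self.u_nb_eq = {k: eqflat[v] for k, v in self.u_nb.items()}
        # tangential (N/S) neighbours that are not unknowns sit on a wall
        self.u_wallN = self.u_nb_eq["N"] < 0
        self.u_wallS = self.u_nb_eq["S"] < 0
        self.u_vNW = self._vid(iu - 1, ju + 1)
        self.u_vNE = self._vid(iu, ju + 1)
        self.u_vSW = self._vid(iu - 1, ju)
        self.u_vSE = self._vid(iu, ju)
        self.u_pW = self._pid(iu - 1, ju)
        self.u_pE = self._pid(iu, ju)
        # unknown u faces always sit between two fluid cells
        peq = self.p_eq.ravel()
        self.u_pW_eq = peq[self.u_pW]
        self.u_pE_eq = peq[self.u_pE]

    def _build_v_stencil(self):
        iv, jv = np.nonzero(self.v_unknown)
        self.iv, self.jv = iv, jv
        self.v_self = self._vid(iv, jv)
        self.v_nb = {
            "W": self._vid(iv - 1, jv),
            "E": self._vid(iv + 1, jv),
            "S": self._vid(iv, jv - 1),
            "N": self._vid(iv, jv + 1),
        }
        eqflat = np.append(self.v_eq.ravel(), -1)
        self.v_nb_eq = {k: eqflat[v] for k, v in self.v_nb.items()}
        # tangential (W/E) non-unknown neighbours: inlet plane / solid wall
        # at half a cell (no-slip ghost); at the outlet, zero-gradient
        self.v_wallW = (self.v_nb_eq["W"] < 0)
        self.v_wallE = (self.v_nb_eq["E"] < 0) & (iv + 1 <= self.nx - 1)
        self.v_outletE = (self.v_nb_eq["E"] < 0) & (iv + 1 > self.nx - 1)
        self.v_uNW = self._uid(iv, jv)
        self.v_uNE = self._uid(iv + 1, jv)
        self.v_uSW = self._uid(iv, jv - 1)
        self.v_uSE = self._uid(iv + 1, jv - 1)
        self.v_pS = self._pid(iv, jv - 1)
        self.v_pN = self._pid(iv, jv)
        peq = self.p_eq.ravel()
        self.v_pS_eq = peq[self.v_pS]
        self.v_pN_eq = peq[self.v_pN]

    def _build_p_stencil(self):
        ic, jc = np.nonzero(self.fluid)
        self.ic, self.jc = ic, jc
        self.c_uE = self._uid(ic + 1, jc)
        self.c_uW = self._uid(ic, jc)
        self.c_vN = self._vid(ic, jc + 1)
        self.c_vS = self._vid(ic, jc)
        ueq = np.append(self.u_eq.ravel(), -1)
        veq = np.append(self.v_eq.ravel(), -1)
        self.c_uE_eq, self.c_uW_eq = ueq[self.c_uE], ueq[self.c_uW]
        self.c_vN_eq, self.c_vS_eq = veq[self.c_vN], veq[self.c_vS]
        peq = np.append(self.p_eq.ravel(), -1)
        self.c_pE = peq[self._pid(ic + 1, jc)]
        self.c_pW = peq[self._pid(ic - 1, jc)]
        self.c_pN = peq[self._pid(ic, jc + 1)]
        self.c_pS = peq[self._pid(ic, jc - 1)]
        # pressure reference cell: first outlet-column fluid cell
        ref = np.nonzero((ic == self.nx - 1))[0]
        self.p_ref_eq = int(self.p_eq[ic[ref[0]], jc[ref[0]]]) if len(ref) else 0

    # -- field helpers -----------------------------------------------------
    @staticmethod
    def _gather(flat: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.append(flat, 0.0)[idx]

    def set_inlet(self, u: np.ndarray, q_per_depth: float) -> None:
        height = self.h * len(self.mesh.inlet_rows)
        u[0, self.mesh.inlet_rows] = q_per_depth / height

    def fix_outlet(self, u: np.ndarray, q_per_depth: float) -> None:
        """Zero-gradient outlet profile rescaled to the instantaneous inflow."""
        rows = self.mesh.outlet_rows
        prof = u[self.nx - 1, rows]
        raw = float(prof.sum()) * self.h
        if raw <= 1e-14 * max(abs(q_per_depth), 1e-30) or raw <= 0.0:
            height = self.h * len(rows)
            u[self.nx, rows] = q_per_depth / height
        else:
            u[self.nx, rows] = prof * (q_per_depth / raw)

    def _momentum(self, comp, u, v, p, dt_term, old, prev):
        """Assemble one under-relaxed momentum system (first-order upwind
        convection, central diffusion, half-cell no-slip ghosts) and return
        ``(diag, neighbour coefficient dict, neighbour eq dict, rhs)``; the
        relaxation is folded into ``diag`` and ``rhs``."""
        rho, mu, h = self.rho, self.mu, self.h
        uf, vf, pf = u.ravel(), v.ravel(), p.ravel()
        g = self._gather
        if comp == "u":
            uP = g(uf, self.u_self)
            Fe = rho * h * 0.5 * (uP + g(uf, self.u_nb["E"]))
            Fw = rho * h * 0.5 * (g(uf, self.u_nb["W"]) + uP)
            Fn = rho * h * 0.5 * (g(vf, self.u_vNW) + g(vf, self.u_vNE))
            Fs = rho * h * 0.5 * (g(vf, self.u_vSW) + g(vf, self.u_vSE))
            nb_eq, nb_idx = self.u_nb_eq, self.u_nb
            wallN, wallS = self.u_wallN, self.u_wallS
            wallW = np.zeros(len(uP), dtype=bool)
            wallE = np.zeros(len(uP), dtype=bool)
            outletE = np.zeros(len(uP), dtype=bool)
            b_press = h * (g(pf, self.u_pW) - g(pf, self.u_pE))
            src = uf
        else:
            vP = g(vf, self.v_self)
            Fe = rho * h * 0.5 * (g(uf, self.v_uNE) + g(uf, self.v_uSE))
            Fw = rho * h * 0.5 * (g(uf, self.v_uNW) + g(uf, self.v_uSW))
            Fn = rho * h * 0.5 * (vP + g(vf, self.v_nb["N"]))
            Fs = rho * h * 0.5 * (g(vf, self.v_nb["S"]) + vP)
            nb_eq, nb_idx = self.v_nb_eq, self.v_nb
            wallN = np.zeros(len(vP), dtype=bool)
            wallS = np.zeros(len(vP), dtype=bool)
            wallW, wallE, outletE = self.v_wallW, self.v_wallE, self.v_outletE
            b_press = h * (g(pf, self.v_pS) - g(pf, self.v_pN))
            src = vf

        D = mu
        aE = D + np.maximum(-Fe, 0.0)
        aW = D + np.maximum(Fw, 0.0)
        aN = D + np.maximum(-Fn, 0.0)
        aS = D + np.maximum(Fs, 0.0)
        # wall ghosts at half a cell: diffusion doubles, convection vanishes
        aE = np.where(wallE | outletE, 0.0, aE)
        aW = np.where(wallW, 0.0, aW)
        aN = np.where(wallN, 0.0, aN)
        aS = np.where(wallS, 0.0, aS)
        wall_extra = 2.0 * D * (
            wallN.astype(float) + wallS.astype(float)
            + wallW.astype(float) + wallE.astype(float)
        )
        dF = Fe - Fw + Fn - Fs
        aP = aE + aW + aN + aS + wall_extra + np.maximum(dF, 0.0) + dt_term

        b = b_press + dt_term * old
        alpha = self.num.alpha_u
        diag = aP / alpha
        a_known = {}
        for key, a_nb in (("E", aE), ("W", aW), ("N", aN), ("S", aS)):
            eq = nb_eq[key]
            known = eq < 0
            # known neighbours contribute their (boundary) value to the RHS;
            # unknown ones stay as gathered coefficients for the sweeps
            bv = self._gather(src, nb_idx[key][known])
            b[known] += a_nb[known] * bv
            a_known[key] = np.where(known, 0.0, a_nb)
        b += (1.0 - alpha) * diag * prev
        return diag, a_known, nb_eq, b

    @staticmethod
    def _sweep(x, diag, a_nb, nb_eq, b, n_sweeps):
        """Jacobi sweeps of the assembled momentum system (diagonally
        dominant by construction, so a few sweeps inside the SIMPLE outer
        loop are sufficient)."""
        for _ in range(n_sweeps):
            acc = b.copy()
            for key in ("E", "W", "N", "S"):
                acc += a_nb[key] * np.append(x, 0.0)[nb_eq[key]]
            x = acc / diag
        return x

    def _pressure_rhs(self, u, v):
        rho, h = self.rho, self.h
        g = self._gather
        uf, vf = u.ravel(), v.ravel()
        m = rho * h * (
            g(uf, self.c_uE) - g(uf, self.c_uW) + g(vf, self.c_vN) - g(vf, self.c_vS)
        )
        b = -m
        b[self.p_ref_eq] = 0.0
        return b, m

    def _pressure_lu(self, du, dv):
        """Factorize the pressure-correction matrix for the face-mobility
        arrays ``du``/``dv`` (= A_face / a_P); the reference cell is pinned
        to remove the Neumann null space."""
        rho, h = self.rho, self.h
        g = self._gather
        d_uE = np.where(self.c_uE_eq >= 0, g(du, self.c_uE_eq), 0.0)
        d_uW = np.where(self.c_uW_eq >= 0, g(du, self.c_uW_eq), 0.0)
        d_vN = np.where(self.c_vN_eq >= 0, g(dv, self.c_vN_eq), 0.0)
        d_vS = np.where(self.c_vS_eq >= 0, g(dv, self.c_vS_eq), 0.0)
        aE, aW = rho * h * d_uE, rho * h * d_uW
        aN, aS = rho * h * d_vN, rho * h * d_vS
        n = len(aE)
        rows = [np.arange(n)]
        cols = [np.arange(n)]
        vals = [aE + aW + aN + aS]
        for a_nb, nb in ((aE, self.c_pE), (aW, self.c_pW), (aN, self.c_pN), (aS, self.c_pS)):
            ok = nb >= 0
            rows.append(np.nonzero(ok)[0])
            cols.append(nb[ok])
            vals.append(-a_nb[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        keep = rows != self.p_ref_eq
        rows = np.append(rows[keep], self.p_ref_eq)
        cols = np.append(cols[keep], self.p_ref_eq)
        vals = np.append(vals[keep], 1.0)
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        return splu(A)

    def mass_residual(self, u, v, q_scale):
        g = self._gather
        uf, vf = u.ravel(), v.ravel()
        m = self.rho * self.h * (
            g(uf, self.c_uE) - g(uf, self.c_uW) + g(vf, self.c_vN) - g(vf, self.c_vS)
        )
        norm = self.rho * max(abs(q_scale), 1e-30)
        return float(np.abs(m).sum() / norm)

    def simple_step(self, u, v, p, q_inst, dt, u_old, v_old, tol, q_scale):
        """Iterate SIMPLE at one time level until the mass residual meets
        ``tol``; mutates u, v, p in place and returns (iterations, residual
        history)."""
        rho, h = self.rho, self.h
        dt_term = 0.0 if dt is None else rho * h * h / dt
        self.set_inlet(u, q_inst)
        self.fix_outlet(u, q_inst)
        old_u = 0.0 if dt is None else u_old.ravel()[self.u_self]
        old_v = 0.0 if dt is None else v_old.ravel()[self.v_self]
        history: list[float] = []
        cap = self.num.max_inner if dt is not None else self.num.steady_max_iter
        lu = None
        lu_every = self.num.lu_refresh
        u_ref = max(abs(q_scale) / (h * len(self.mesh.inlet_rows)), 1e-30)
        for it in range(1, cap + 1):
            u_prev = u.ravel()[self.u_self]
            v_prev = v.ravel()[self.v_self]
            diag_u, a_u, eq_u, b_u = self._momentum("u", u, v, p, dt_term, old_u, u_prev)
            u[self.iu, self.ju] = self._sweep(
                u_prev, diag_u, a_u, eq_u, b_u, self.num.momentum_sweeps
            )
            diag_v, a_v, eq_v, b_v = self._momentum("v", u, v, p, dt_term, old_v, v_prev)
            v[self.iv, self.jv] = self._sweep(
                v_prev, diag_v, a_v, eq_v, b_v, self.num.momentum_sweeps
            )
            self.fix_outlet(u, q_inst)
            du, dv = h / diag_u, h / diag_v
            if lu is None or (it - 1) % lu_every == 0:
                lu = self._pressure_lu(du, dv)
            b_p, _ = self._pressure_rhs(u, v)
            pc = lu.solve(b_p)
            p[self.ic, self.jc] += self.num.alpha_p * pc
            u[self.iu, self.ju] += du * (pc[self.u_pW_eq] - pc[self.u_pE_eq])
            v[self.iv, self.jv] += dv * (pc[self.v_pS_eq] - pc[self.v_pN_eq])
            self.fix_outlet(u, q_inst)
            res = self.mass_residual(u, v, q_scale)
            history.append(res)
            dvel = max(
                float(np.abs(u.ravel()[self.u_self] - u_prev).max(initial=0.0)),
                float(np.abs(v.ravel()[self.v_self] - v_prev).max(initial=0.0)),
            ) / u_ref
            if res < tol and dvel < self.num.tol_velocity and it >= 2:
                return it, history
        raise SolverError(
            f"SIMPLE did not reach mass tolerance {tol:g} within {cap} "
            f"iterations (last residual {history[-1]:.3e})",
            history,
        )


def _zero_pressure_outlet(solver: _Simple, p: np.ndarray) -> None:
    """Shift the pressure level so the outlet-column mean is zero."""
    rows = solver.mesh.outlet_rows
    p -= p[solver.nx - 1, rows].mean()


def simulate_steady(
    mesh: Mesh,
    flow: FlowConditions,
    numerics: Numerics | None = None,
    q_per_depth: float | None = None,
) -> FlowField:
    """Steady solve at the mean flow (or at an explicit per-depth rate).

    Returned as a degenerate one-snapshot :class:`FlowField` (times [0]).
    """
    num = numerics or Numerics()
    solver = _Simple(mesh, flow.density, flow.viscosity, num)
    caliber_mm = mesh.ny_parent * mesh.cell_size
    if q_per_depth is None:
        q_per_depth = flow.mean_velocity() * units.mm_to_m(caliber_mm)
    nx, ny = mesh.nx, mesh.ny
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    if q_per_depth == 0.0:
        field_ = FlowField(
            times=np.array([0.0]), u=u[None], v=v[None], p=p[None],
            period=flow.period, mesh=mesh, convergence_log=[(0, 0, 0.0)],
        )
        return field_
    it, hist = solver.simple_step(
        u, v, p, q_per_depth, None, None, None, num.tol_steady, q_per_depth
    )
    _zero_pressure_outlet(solver, p)
    return FlowField(
        times=np.array([0.0]),
        u=u[None],
        v=v[None],
        p=p[None],
        period=flow.period,
        mesh=mesh,
        convergence_log=[(0, it, hist[-1])],
    )


def simulate_pulsatile(
    mesh: Mesh, flow: FlowConditions, numerics: Numerics | None = None
) -> FlowField:
    """Integrate ``flow.n_cycles`` cardiac cycles from rest; return the last.

    Implicit Euler with ``numerics.dt`` (default period/200); each step's
    SIMPLE loop must meet the mass tolerance or a :class:`SolverError` with
    the residual history is raised.  A warning is emitted if the advective
    CFL number exceeds 1.
    """
    num = numerics or Numerics()
    solver = _Simple(mesh, flow.density, flow.viscosity, num)
    T = flow.period
    n_steps = num.steps_per_cycle if num.dt is None else max(round(T / num.dt), 1)
    dt = T / n_steps
    caliber_mm = mesh.ny_parent * mesh.cell_size

    nx, ny = mesh.nx, mesh.ny
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    q_scale = flow.mean_velocity() * units.mm_to_m(caliber_mm)

    if flow.max_flow == 0.0:
        times = np.linspace(0.0, T, n_steps + 1)
        z = np.zeros((n_steps + 1,) + u.shape)
        return FlowField(
            times=times, u=z, v=np.zeros((n_steps + 1,) + v.shape),
            p=np.zeros((n_steps + 1,) + p.shape), period=T, mesh=mesh,
        )

    log: list[tuple[int, int, float]] = []
    last_u, last_v, last_p, times = [], [], [], []
    total_steps = flow.n_cycles * n_steps
    first_of_last = (flow.n_cycles - 1) * n_steps
    cfl_warned = False
    for step in range(total_steps):
        t_new = (step + 1) * dt
        q_inst = flow.per_depth_rate(t_new, caliber_mm)
        u_old, v_old = u.copy(), v.copy()
        it, hist = solver.simple_step(
            u, v, p, q_inst, dt, u_old, v_old, num.tol_mass, q_scale
        )
        log.append((step, it, hist[-1]))
        cfl = float(np.abs(u).max()) * dt / solver.h
        if cfl > 1.0 and not cfl_warned:
            warnings.warn(f"advective CFL = {cfl:.2f} > 1 at step {step}", stacklevel=2)
            cfl_warned = True
        if step == first_of_last - 1:
            # state at the start of the last cycle
            _record(last_u, last_v, last_p, times, u, v, p, 0.0)
        if step >= first_of_last:
            _record(last_u, last_v, last_p, times, u, v, p, t_new - first_of_last * dt)
    if flow.n_cycles == 1:
        # single-cycle run: prepend the rest state
        last_u.insert(0, np.zeros_like(u))
        last_v.insert(0, np.zeros_like(v))
        last_p.insert(0, np.zeros_like(p))
        times.insert(0, 0.0)
    p_out = np.array(last_p)
    for k in range(p_out.shape[0]):
        p_out[k] -= p_out[k, nx - 1, mesh.outlet_rows].mean()
    return FlowField(
        times=np.array(times),
        u=np.array(last_u),
        v=np.array(last_v),
        p=p_out,
        period=T,
        mesh=mesh,
        convergence_log=log,
    )


def _record(lu, lv, lp, times, u, v, p, t):
    lu.append(u.copy())
    lv.append(v.copy())
    lp.append(p.copy())
    times.append(t)
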