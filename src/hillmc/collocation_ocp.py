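"""Tracking optimal control problem via Legendre-Gauss-Radau collocation.

Transcribes the activation/contraction dynamics of all MTUs, the
moment-matching path constraints (with bounded reserve actuators) and the
implicit Hill-equilibrium constraints into a nonlinear program with all
decision variables affinely scaled to [-1, 1], and solves it with a
sequential-quadratic-programming solver. Solver failures are returned as
data (status "failed"), never raised: infeasible Monte Carlo draws are an
expected outcome.

Cost = volume-weighted squared activations + squared (scaled) reserves +
squared (scaled) state-derivative controls, integrated with the Radau
quadrature of the transcription.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.special import roots_jacobi

from hillmc import limb_model as lm
from hillmc.hill_mtu import (
    ACTIVATION_TIME_CONSTANT,
    DEACTIVATION_TIME_CONSTANT,
    DEFAULT_CURVES,
    hill_residual_core,
)

__all__ = [
    "OCPSettings",
    "CollocationSolution",
    "TranscribedNLP",
    "radau_scheme",
    "radau_integrate",
    "effort_term",
    "reserve_term",
    "control_term",
    "transcribe",
    "solve",
    "track",
    "classify_feasibility",
]


@dataclass(frozen=True)
class OCPSettings:
    """Transcription and solver settings.

    Defaults mirror the published framework where printed (50 mesh
    intervals, third-order state polynomials, +/-25 N*m knee reserve
    scaled to +/-1); weights and tolerances are unprinted and exposed
    here for configuration.
    """

    n_mesh_intervals: int = 50
    poly_degree: int = 3
    reserve_bound: float = 25.0           # N*m, scaled to +/-1
    w_reserve: float = 10.0
    w_control: float = 0.01
    tol: float = 1e-4                     # solver convergence tolerance
    constr_tol: float = 1e-6              # accepted constraint violation
    max_iter: int = 3000
    activation_bounds: tuple = (0.0, 1.0)
    tendon_force_bounds: tuple = (0.0, 3.5)
    activation_rate_scale: float = 1.0 / ACTIVATION_TIME_CONSTANT   # 1/s
    tendon_force_rate_scale: float = 50.0                           # 1/s
    feasibility_threshold_pct: float = 9.0
    feasibility_floor_nm: float = 1.0
    initial_activation: float = 0.1
    initial_tendon_force: float = 0.2

    def __post_init__(self) -> None:
        if self.n_mesh_intervals < 1:
            raise ValueError("n_mesh_intervals must be >= 1")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.reserve_bound <= 0:
            raise ValueError("reserve_bound must be positive")

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "OCPSettings":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
        return cls(**doc)


# ---------------------------------------------------------------------------
# Radau scheme
# ---------------------------------------------------------------------------

def radau_scheme(degree: int):
    """Flipped Legendre-Gauss-Radau collocation scheme on (0, 1].

    Returns (points, weights, diff_matrix):
      * points: the ``degree`` collocation points, ending at exactly 1.0
      * weights: quadrature weights on [0, 1] (exact to degree 2d-2)
      * diff_matrix: shape (degree, degree+1); row k gives the derivative
        of the interpolating polynomial through the points {0, tau_1..tau_d}
        evaluated at tau_k, i.e. xdot(tau_k) = sum_p D[k, p] * x_p.
    """
    if not (1 <= degree <= 9):
        raise ValueError("supported collocation degrees are 1..9")
    if degree == 1:
        pts = np.array([1.0])
    else:
        # interior Radau-right points: roots of Jacobi P^(1,0)_{d-1} on [-1,1]
        xj, _ = roots_jacobi(degree - 1, 1.0, 0.0)
        pts = np.concatenate([(xj + 1.0) / 2.0, [1.0]])
    # weights from moment conditions (unique for d points; Radau points make
    # the rule exact to degree 2d-2)
    V = np.vander(pts, increasing=True).T          # V[k, j] = pts_j^k
    moments = 1.0 / np.arange(1, degree + 1)       # int_0^1 tau^k dtau
    weights = np.linalg.solve(V, moments)

    nodes = np.concatenate([[0.0], pts])
    # barycentric weights
    bw = np.array([
        1.0 / np.prod(nodes[j] - np.delete(nodes, j)) for j in range(degree + 1)
    ])
    D = np.zeros((degree + 1, degree + 1))
    for k in range(degree + 1):
        for j in range(degree + 1):
            if j != k:
                D[k, j] = (bw[j] / bw[k]) / (nodes[k] - nodes[j])
        D[k, k] = -np.sum(D[k, :])
    return pts, weights, D[1:, :]


def radau_integrate(rhs, x0: float, duration: float, n_intervals: int,
                    degree: int = 3):
    """Integrate a scalar ODE xdot = rhs(t, x) with the same Radau
    collocation scheme used by the transcription (implicit, per-interval
    nonlinear solve). Returns (times, states) at all state points.

    Used as an independent limit-case oracle for the transcription's
    dynamics constraints.
    """
    pts, _, D = radau_scheme(degree)
    h = duration / n_intervals
    times = [0.0]
    states = [x0]
    xstart = x0
    t0 = 0.0
    for _ in range(n_intervals):
        tk = t0 + pts * h

        def eqs(xc):
            xall = np.concatenate([[xstart], xc])
            return D @ xall / h - np.array([rhs(t, x) for t, x in zip(tk, xc)])

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            xc = scipy.optimize.fsolve(eqs, np.full(degree, xstart),
                                       xtol=1e-12)
        times.extend(tk.tolist())
        states.extend(xc.tolist())
        xstart = xc[-1]
        t0 += h
    return np.asarray(times), np.asarray(states)


# ---------------------------------------------------------------------------
# objective terms (recomputable outside the solver)
# ---------------------------------------------------------------------------

def effort_term(activations, volume_fractions, quad_weights) -> float:
    """Volume-weighted squared-activation effort:
    sum_j PV_j * integral(a_j^2 dt), with the collocation quadrature."""
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    pv = np.asarray(volume_fractions, dtype=float)
    w = np.asarray(quad_weights, dtype=float)
    if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
        raise ValueError("activations outside [0, 1]")
    return float(np.sum(pv[:, None] * a**2 * w[None, :]))


def reserve_term(reserves_scaled, quad_weights, w_reserve: float = 1.0) -> float:
    """w_reserve * sum_i integral(scaled_reserve_i^2 dt)."""
    r = np.atleast_2d(np.asarray(reserves_scaled, dtype=float))
    w = np.asarray(quad_weights, dtype=float)
    return float(w_reserve * np.sum(r**2 * w[None, :]))


def control_term(activation_rates, tendon_force_rates, quad_weights,
                 w_control: float = 1.0) -> float:
    """w_control * sum_j [integral(dFt_j^2 dt) + integral(da_j^2 dt)]."""
    ua = np.atleast_2d(np.asarray(activation_rates, dtype=float))
    uf = np.atleast_2d(np.asarray(tendon_force_rates, dtype=float))
    w = np.asarray(quad_weights, dtype=float)
    return float(w_control * (np.sum(uf**2 * w[None, :])
                              + np.sum(ua**2 * w[None, :])))


# ---------------------------------------------------------------------------
# transcription
# ---------------------------------------------------------------------------

class TranscribedNLP:
    """A transcribed tracking problem: scaled decision vector, linear
    constraint matrices, the nonlinear Hill-equilibrium block, and the
    quadratic objective. All variables are bounded in [-1, 1]."""

    def __init__(self, model: lm.LimbModel, reference, kinematics,
                 settings: OCPSettings, perturbed_params=None, curves=None):
        self.model = model
        self.reference = reference
        self.kinematics = kinematics
        self.settings = settings
        self.curves = curves or DEFAULT_CURVES
        params = perturbed_params or [m.params for m in model.mtus]
        if len(params) != model.n_mtus:
            raise ValueError("one parameter set per MTU required")
        self.params = params

        n, d = settings.n_mesh_intervals, settings.poly_degree
        m = model.n_mtus
        coords = list(model.coordinates)
        nc = len(coords)
        self.n_mesh_intervals, self.poly_degree = n, d
        self.coords = coords
        self.m = m

        t = np.asarray(kinematics.time)
        if abs(t[0]) > 1e-12:
            raise ValueError("kinematics grid must start at t=0")
        self.duration = float(t[-1])
        self.h = self.duration / n
        pts, wq, D = radau_scheme(d)
        self.radau_points, self.radau_weights, self.D = pts, wq, D

        # global grids -----------------------------------------------------
        self.K = n * d                      # collocation points
        self.P = n * (d + 1)                # state points
        tc = np.concatenate([(i + pts) * self.h for i in range(n)])
        ts = np.concatenate([
            np.concatenate([[i * self.h], (i + pts) * self.h]) for i in range(n)
        ])
        self.times_colloc, self.times_states = tc, ts
        self.quad_weights = np.tile(wq * self.h, n)

        # prescribed kinematics at collocation points (model coordinates)
        omega = abs(float(kinematics.angular_velocity[0]))  # rad/s
        flex0 = float(np.degrees(kinematics.angle[0]))
        flex_deg = flex0 - np.degrees(omega) * tc
        q_knee = lm.knee_q_from_flexion_deg(flex_deg)
        qdot = {model.knee_coordinate: omega}

        # geometry grids: lengths, velocities, moment arms per MTU
        self.l_mtu = np.zeros((m, self.K))
        self.v_mtu = np.zeros((m, self.K))
        self.arms = {c: np.zeros((m, self.K)) for c in coords}
        for j, mtu in enumerate(model.mtus):
            for i, q in enumerate(q_knee):
                angles = model.pose(q)
                self.l_mtu[j, i] = lm.mtu_length(mtu.kinematics, angles)
                self.v_mtu[j, i] = lm.mtu_velocity(mtu.kinematics, angles, qdot)
                for c in coords:
                    self.arms[c][j, i] = lm.moment_arm(mtu.kinematics, angles, c)

        # reference moments per coordinate (zero off the knee)
        self.m_ref = {c: np.zeros(self.K) for c in coords}
        self.m_ref[model.knee_coordinate] = reference.interpolator()(tc)

        # scales -----------------------------------------------------------
        a_lo, a_hi = settings.activation_bounds
        f_lo, f_hi = settings.tendon_force_bounds
        self.alpha_a, self.beta_a = (a_hi - a_lo) / 2, (a_hi + a_lo) / 2
        self.alpha_f, self.beta_f = (f_hi - f_lo) / 2, (f_hi + f_lo) / 2
        self.alpha_ua = settings.activation_rate_scale
        self.alpha_uf = settings.tendon_force_rate_scale
        self.alpha_r = settings.reserve_bound

        # variable layout --------------------------------------------------
        self.S0 = 0
        self.U0 = 2 * m * self.P
        self.R0 = self.U0 + 2 * m * self.K
        self.n_vars = self.R0 + nc * self.K

        P_idx = np.arange(self.P)
        K_idx = np.arange(self.K)
        self.idx_a_state = (P_idx[None, :] * 2 * m) + np.arange(m)[:, None]
        self.idx_f_state = self.idx_a_state + m
        base_u = self.U0 + K_idx[None, :] * 2 * m
        self.idx_ua = base_u + np.arange(m)[:, None]
        self.idx_uf = self.idx_ua + m
        self.idx_r = self.R0 + K_idx[None, :] * nc + np.arange(nc)[:, None]
        # state indices at collocation points (local point p = k+1)
        colloc_state_pts = np.concatenate(
            [i * (d + 1) + 1 + np.arange(d) for i in range(n)])
        self.idx_a_colloc = self.idx_a_state[:, colloc_state_pts]
        self.idx_f_colloc = self.idx_f_state[:, colloc_state_pts]
        self._colloc_state_pts = colloc_state_pts

        # parameter arrays for the vectorized Hill block
        self.f_max = np.array([p.f_max for p in params])
        self._l_opt = np.array([p.l_opt for p in params])[:, None]
        self._alpha_opt = np.array([p.alpha_opt for p in params])[:, None]
        self._k_tendon = np.array([p.k_tendon for p in params])[:, None]
        self._v_max = np.array([p.v_max for p in params])[:, None]
        self._l_slack = np.array([p.l_tendon_slack for p in params])[:, None]
        self.volume_fractions = np.array([p.volume_fraction for p in params])

        self._build_linear_constraints()
        self._build_objective()
        self.counts = {
            "variables": self.n_vars,
            "n_mesh_intervals": n,
            "poly_degree": d,
            "dynamics": n * d * 2 * m,
            "continuity": (n - 1) * 2 * m,
            "moment_balance": self.K * nc,
            "hill_equilibrium": self.K * m,
            "rate_inequalities": 2 * self.K * m,
        }

    # -- assembly ---------------------------------------------------------
    def _build_linear_constraints(self) -> None:
        n, d, m = self.n_mesh_intervals, self.poly_degree, self.m
        nc = len(self.coords)
        D, h = self.D, self.h
        rows, cols, vals, b = [], [], [], []
        r = 0

        def add(row, col, val):
            rows.append(row)
            cols.append(col)
            vals.append(val)

        # collocation dynamics: sum_p D[k,p] x_{i,p}/h - u_{i,k} = 0,
        # scaled by alpha_x / alpha_u
        for i in range(n):
            for k in range(d):
                kk = i * d + k
                for j in range(m):
                    for p in range(d + 1):
                        sp_idx = i * (d + 1) + p
                        add(r, self.idx_a_state[j, sp_idx],
                            D[k, p] * self.alpha_a / (h * self.alpha_ua))
                        add(r + 1, self.idx_f_state[j, sp_idx],
                            D[k, p] * self.alpha_f / (h * self.alpha_uf))
                    add(r, self.idx_ua[j, kk], -1.0)
                    add(r + 1, self.idx_uf[j, kk], -1.0)
                    b.extend([0.0, 0.0])
                    r += 2
        self._r_dynamics = r

        # continuity: x_{i,0} - x_{i-1,d} = 0 (same affine scale, cancels)
        for i in range(1, n):
            p_start = i * (d + 1)
            p_prev_end = i * (d + 1) - 1
            for j in range(m):
                add(r, self.idx_a_state[j, p_start], 1.0)
                add(r, self.idx_a_state[j, p_prev_end], -1.0)
                b.append(0.0)
                r += 1
                add(r, self.idx_f_state[j, p_start], 1.0)
                add(r, self.idx_f_state[j, p_prev_end], -1.0)
                b.append(0.0)
                r += 1
        self._r_continuity = r

        # moment balance per coordinate and collocation point, divided by the
        # reserve bound: sum_j r_j F_j + tau = M_ref
        rb = self.alpha_r
        for ci, c in enumerate(self.coords):
            arms_c = self.arms[c]
            for kk in range(self.K):
                const = 0.0
                for j in range(m):
                    coeff = arms_c[j, kk] * self.f_max[j]
                    if coeff != 0.0:
                        add(r, self.idx_f_colloc[j, kk], coeff * self.alpha_f / rb)
                        const += coeff * self.beta_f
                add(r, self.idx_r[ci, kk], 1.0)
                b.append((self.m_ref[c][kk] - const) / rb)
                r += 1
        self._r_moment = r

        self.A_eq = sp.csr_matrix(
            (vals, (rows, cols)), shape=(r, self.n_vars))
        self.b_eq = np.asarray(b)
        self.n_linear_eq = r

        # rate inequalities (A z >= b), scaled by 1/alpha_ua
        rows, cols, vals, b = [], [], [], []
        r = 0
        ta, td = ACTIVATION_TIME_CONSTANT, DEACTIVATION_TIME_CONSTANT
        for j in range(m):
            for kk in range(self.K):
                ia = self.idx_a_colloc[j, kk]
                iu = self.idx_ua[j, kk]
                # (1 - a)/ta - ua >= 0
                rows += [r, r]
                cols += [ia, iu]
                vals += [-self.alpha_a / (ta * self.alpha_ua), -1.0]
                b.append(-(1.0 - self.beta_a) / (ta * self.alpha_ua))
                r += 1
                # ua + a/td >= 0
                rows += [r, r]
                cols += [ia, iu]
                vals += [self.alpha_a / (td * self.alpha_ua), 1.0]
                b.append(-self.beta_a / (td * self.alpha_ua))
                r += 1
        self.A_ineq = sp.csr_matrix(
            (vals, (rows, cols)), shape=(r, self.n_vars))
        self.b_ineq = np.asarray(b)

        self._A_eq_dense = None
        self._A_ineq_dense = None

    def _build_objective(self) -> None:
        s = self.settings
        Hd = np.zeros(self.n_vars)
        g = np.zeros(self.n_vars)
        c0 = 0.0
        wq = self.quad_weights
        pv = self.volume_fractions
        # effort: sum_j pv_j wq (alpha_a z + beta_a)^2
        for j in range(self.m):
            idx = self.idx_a_colloc[j]
            Hd[idx] += 2.0 * pv[j] * wq * self.alpha_a**2
            g[idx] += 2.0 * pv[j] * wq * self.alpha_a * self.beta_a
            c0 += pv[j] * np.sum(wq) * self.beta_a**2
        # reserves (scaled) and controls (scaled)
        Hd[self.idx_r.ravel()] += np.tile(2.0 * s.w_reserve * wq,
                                          (len(self.coords), 1)).ravel()
        Hd[self.idx_ua.ravel()] += np.tile(2.0 * s.w_control * wq,
                                           (self.m, 1)).ravel()
        Hd[self.idx_uf.ravel()] += np.tile(2.0 * s.w_control * wq,
                                           (self.m, 1)).ravel()
        self._H_diag, self._g, self._c0 = Hd, g, c0

    # -- callables --------------------------------------------------------
    def objective(self, z):
        return float(0.5 * np.dot(z**2, self._H_diag) + np.dot(self._g, z)
                     + self._c0)

    def objective_grad(self, z):
        return self._H_diag * z + self._g

    def _hill_arrays(self, za, zf, zuf):
        a = self.alpha_a * za + self.beta_a
        ft = self.alpha_f * zf + self.beta_f
        uf = self.alpha_uf * zuf
        return hill_residual_core(
            a, ft, uf, self.l_mtu, self.v_mtu,
            self.params[0], self.curves,
            l_opt=self._l_opt, alpha_opt=self._alpha_opt,
            k_tendon=self._k_tendon, v_max=self._v_max,
            l_tendon_slack=self._l_slack)

    def hill_residuals(self, z):
        """Hill-equilibrium residual at every (MTU, collocation point)."""
        za = z[self.idx_a_colloc]
        zf = z[self.idx_f_colloc]
        zuf = z[self.idx_uf]
        return np.real(self._hill_arrays(za, zf, zuf)).ravel()

    def hill_jacobian_entries(self, z):
        """Partial derivatives of each Hill residual w.r.t. its three scaled
        variables (za, zf, zuf), via complex-step differentiation."""
        za = z[self.idx_a_colloc].astype(complex)
        zf = z[self.idx_f_colloc].astype(complex)
        zuf = z[self.idx_uf].astype(complex)
        hstep = 1e-20
        d_a = np.imag(self._hill_arrays(za + 1j * hstep, zf, zuf)) / hstep
        d_f = np.imag(self._hill_arrays(za, zf + 1j * hstep, zuf)) / hstep
        d_u = np.imag(self._hill_arrays(za, zf, zuf + 1j * hstep)) / hstep
        return d_a, d_f, d_u

    def eq_constraints(self, z):
        return np.concatenate([self.A_eq @ z - self.b_eq,
                               self.hill_residuals(z)])

    def eq_jacobian(self, z):
        if self._A_eq_dense is None:
            self._A_eq_dense = self.A_eq.toarray()
        n_hill = self.m * self.K
        J = np.zeros((self.n_linear_eq + n_hill, self.n_vars))
        J[:self.n_linear_eq] = self._A_eq_dense
        d_a, d_f, d_u = self.hill_jacobian_entries(z)
        rows = self.n_linear_eq + np.arange(n_hill)
        J[rows, self.idx_a_colloc.ravel()] = d_a.ravel()
        J[rows, self.idx_f_colloc.ravel()] = d_f.ravel()
        J[rows, self.idx_uf.ravel()] = d_u.ravel()
        return J

    def ineq_constraints(self, z):
        return self.A_ineq @ z - self.b_ineq

    def ineq_jacobian(self, z):
        if self._A_ineq_dense is None:
            self._A_ineq_dense = self.A_ineq.toarray()
        return self._A_ineq_dense

    # -- guesses and unscaling -------------------------------------------
    def default_guess(self) -> np.ndarray:
        s = self.settings
        z = np.zeros(self.n_vars)
        z[self.idx_a_state.ravel()] = (s.initial_activation - self.beta_a) / self.alpha_a
        z[self.idx_f_state.ravel()] = (s.initial_tendon_force - self.beta_f) / self.alpha_f
        return z

    def reserve_bounds_nm(self, coordinate: str | None = None):
        """Unscaled bounds (N*m) on the reserve decision variables."""
        coordinate = coordinate or self.model.knee_coordinate
        if coordinate not in self.coords:
            raise KeyError(coordinate)
        return (-self.settings.reserve_bound, self.settings.reserve_bound)

    def unscale(self, z) -> dict:
        return {
            "activation": self.alpha_a * z[self.idx_a_state] + self.beta_a,
            "tendon_force": self.alpha_f * z[self.idx_f_state] + self.beta_f,
            "activation_rate": self.alpha_ua * z[self.idx_ua],
            "tendon_force_rate": self.alpha_uf * z[self.idx_uf],
            "reserves": self.alpha_r * z[self.idx_r],
        }

    def reduced(self) -> "_ReducedProblem":
        """Equivalent reduced-space problem used by :func:`solve` (controls
        and duplicated interval-boundary states eliminated through the
        dynamics and continuity equalities)."""
        if getattr(self, "_reduced_cache", None) is None:
            self._reduced_cache = _ReducedProblem(self)
        return self._reduced_cache


class _ReducedProblem:
    """Solver-internal condensed formulation of a :class:`TranscribedNLP`.

    The collocation dynamics define the controls linearly from the state
    polynomial (u = D x / h) and the continuity equalities identify each
    interval's start state with the previous interval's final collocation
    state (the flipped-Radau scheme contains the right endpoint). Both sets
    of equalities are eliminated by substitution, which shrinks the
    decision vector to the shared state grid plus the reserves without
    changing the optimum. Solutions map back to the full decision vector.
    """

    def __init__(self, nlp: TranscribedNLP):
        self.nlp = nlp
        n, d, m = nlp.n_mesh_intervals, nlp.poly_degree, nlp.m
        nc = len(nlp.coords)
        K = nlp.K
        self.G = G = K + 1    # shared state grid: t=0 plus all colloc points
        self.n_vars = 2 * m * G + nc * K

        g_idx = np.arange(G)
        self.iya = g_idx[None, :] * 2 * m + np.arange(m)[:, None]
        self.iyf = self.iya + m
        self.iyr = 2 * m * G + np.arange(K)[None, :] * nc \
            + np.arange(nc)[:, None]
        # shared-grid index of collocation point kk is kk+1
        self.iya_c = self.iya[:, 1:]
        self.iyf_c = self.iyf[:, 1:]

        # control maps: scaled rate at colloc point = C_row . y
        # ua_scaled[j,kk] = (alpha_a/(h*alpha_ua)) * sum_p D[k,p] za[j, i*d+p]
        rows_a, cols_a, vals_a = [], [], []
        rows_f, cols_f, vals_f = [], [], []
        ca = nlp.alpha_a / (nlp.h * nlp.alpha_ua)
        cf = nlp.alpha_f / (nlp.h * nlp.alpha_uf)
        for i in range(n):
            for k in range(d):
                kk = i * d + k
                for j in range(m):
                    for p in range(d + 1):
                        gpt = i * d + p
                        rows_a.append(kk * m + j)
                        cols_a.append(self.iya[j, gpt])
                        vals_a.append(nlp.D[k, p] * ca)
                        rows_f.append(kk * m + j)
                        cols_f.append(self.iyf[j, gpt])
                        vals_f.append(nlp.D[k, p] * cf)
        shape = (K * m, self.n_vars)
        self.C_ua = sp.csr_matrix((vals_a, (rows_a, cols_a)), shape=shape)
        self.C_uf = sp.csr_matrix((vals_f, (rows_f, cols_f)), shape=shape)

        # moment balance equalities
        rows, cols, vals, b = [], [], [], []
        r = 0
        rb = nlp.alpha_r
        for ci, c in enumerate(nlp.coords):
            arms_c = nlp.arms[c]
            for kk in range(K):
                const = 0.0
                for j in range(m):
                    coeff = arms_c[j, kk] * nlp.f_max[j]
                    if coeff != 0.0:
                        rows.append(r)
                        cols.append(self.iyf_c[j, kk])
                        vals.append(coeff * nlp.alpha_f / rb)
                        const += coeff * nlp.beta_f
                rows.append(r)
                cols.append(self.iyr[ci, kk])
                vals.append(1.0)
                b.append((nlp.m_ref[c][kk] - const) / rb)
                r += 1
        self.A_eq = sp.csr_matrix((vals, (rows, cols)),
                                  shape=(r, self.n_vars))
        self.b_eq = np.asarray(b)
        self.n_linear_eq = r

        # inequalities: activation-rate limits and tendon-force-rate bounds
        ta, td = ACTIVATION_TIME_CONSTANT, DEACTIVATION_TIME_CONSTANT
        blocks = []
        rhs = []
        # (1-a)/ta - ua >= 0  ->  -(alpha_a/(ta*alpha_ua)) za - ua_s >= -(1-beta_a)/(ta*alpha_ua)
        sel = sp.csr_matrix(
            (np.full(K * m, nlp.alpha_a / (ta * nlp.alpha_ua)),
             (np.arange(K * m),
              (self.iya_c.T).ravel())),
            shape=shape)
        blocks.append(-sel - self.C_ua)
        rhs.append(np.full(K * m, -(1.0 - nlp.beta_a) / (ta * nlp.alpha_ua)))
        # ua + a/td >= 0
        sel2 = sp.csr_matrix(
            (np.full(K * m, nlp.alpha_a / (td * nlp.alpha_ua)),
             (np.arange(K * m),
              (self.iya_c.T).ravel())),
            shape=shape)
        blocks.append(sel2 + self.C_ua)
        rhs.append(np.full(K * m, -nlp.beta_a / (td * nlp.alpha_ua)))
        # tendon force rate bounds |uf_s| <= 1
        blocks.append(self.C_uf)
        rhs.append(np.full(K * m, -1.0))
        blocks.append(-self.C_uf)
        rhs.append(np.full(K * m, -1.0))
        self.A_ineq = sp.vstack(blocks).tocsr()
        self.b_ineq = np.concatenate(rhs)

        # objective: quadratic diag part + control-term coupling
        wq = nlp.quad_weights
        pv = nlp.volume_fractions
        s = nlp.settings
        Hd = np.zeros(self.n_vars)
        g = np.zeros(self.n_vars)
        c0 = 0.0
        for j in range(m):
            idx = self.iya_c[j]
            Hd[idx] += 2.0 * pv[j] * wq * nlp.alpha_a**2
            g[idx] += 2.0 * pv[j] * wq * nlp.alpha_a * nlp.beta_a
            c0 += pv[j] * np.sum(wq) * nlp.beta_a**2
        Hd[self.iyr.ravel()] += np.tile(
            2.0 * s.w_reserve * wq, (nc, 1)).ravel()
        W = sp.diags(np.repeat(wq, m))
        H_ctrl = 2.0 * s.w_control * (
            self.C_ua.T @ W @ self.C_ua + self.C_uf.T @ W @ self.C_uf)
        self.H = (sp.diags(Hd) + H_ctrl).tocsr()
        self.g, self.c0 = g, c0
        self._A_eq_dense = None
        self._A_ineq_dense = None

    # -- callables --------------------------------------------------------
    def objective(self, y):
        return float(0.5 * y @ (self.H @ y) + self.g @ y + self.c0)

    def objective_grad(self, y):
        return self.H @ y + self.g

    def _hill_arrays(self, ya, yf, uf_s):
        nlp = self.nlp
        a = nlp.alpha_a * ya + nlp.beta_a
        ft = nlp.alpha_f * yf + nlp.beta_f
        uf = nlp.alpha_uf * uf_s
        return hill_residual_core(
            a, ft, uf, nlp.l_mtu, nlp.v_mtu, nlp.params[0], nlp.curves,
            l_opt=nlp._l_opt, alpha_opt=nlp._alpha_opt,
            k_tendon=nlp._k_tendon, v_max=nlp._v_max,
            l_tendon_slack=nlp._l_slack)

    def _uf_scaled(self, y):
        # (K*m,) ordered point-major; reshape to (m, K)
        return np.asarray((self.C_uf @ y)).reshape(self.nlp.K, self.nlp.m).T

    def hill_residuals(self, y):
        r = self._hill_arrays(y[self.iya_c], y[self.iyf_c], self._uf_scaled(y))
        return np.real(r).ravel()

    def eq_constraints(self, y):
        return np.concatenate([self.A_eq @ y - self.b_eq,
                               self.hill_residuals(y)])

    def eq_jacobian(self, y):
        nlp = self.nlp
        m, K = nlp.m, nlp.K
        if self._A_eq_dense is None:
            self._A_eq_dense = self.A_eq.toarray()
        n_hill = m * K
        J = np.zeros((self.n_linear_eq + n_hill, self.n_vars))
        J[:self.n_linear_eq] = self._A_eq_dense
        ya = y[self.iya_c].astype(complex)
        yf = y[self.iyf_c].astype(complex)
        uf = self._uf_scaled(y).astype(complex)
        h = 1e-20
        d_a = np.imag(self._hill_arrays(ya + 1j * h, yf, uf)) / h
        d_f = np.imag(self._hill_arrays(ya, yf + 1j * h, uf)) / h
        d_u = np.imag(self._hill_arrays(ya, yf, uf + 1j * h)) / h
        rows = self.n_linear_eq + np.arange(n_hill)
        J[rows, self.iya_c.ravel()] += d_a.ravel()
        J[rows, self.iyf_c.ravel()] += d_f.ravel()
        # chain rule through uf_s = C_uf y: residual (j,kk) corresponds to
        # C_uf row kk*m + j
        d_u_rows = sp.diags(
            d_u.T.ravel()) @ self.C_uf   # (K*m, n_vars), point-major
        d_u_rows = d_u_rows.tocoo()
        # map point-major row (kk*m + j) to hill row (j*K + kk)
        jj = d_u_rows.row % m
        kk = d_u_rows.row // m
        J[self.n_linear_eq + jj * K + kk, d_u_rows.col] += d_u_rows.data
        return J

    def ineq_constraints(self, y):
        return self.A_ineq @ y - self.b_ineq

    def ineq_jacobian(self, y):
        if self._A_ineq_dense is None:
            self._A_ineq_dense = self.A_ineq.toarray()
        return self._A_ineq_dense

    # -- mapping ----------------------------------------------------------
    def y_from_full(self, z) -> np.ndarray:
        nlp = self.nlp
        n, d, m = nlp.n_mesh_intervals, nlp.poly_degree, nlp.m
        y = np.zeros(self.n_vars)
        # shared grid point g: for g>0, interval i=(g-1)//d, local p=(g-1)%d+1
        y[self.iya[:, 0]] = z[nlp.idx_a_state[:, 0]]
        y[self.iyf[:, 0]] = z[nlp.idx_f_state[:, 0]]
        for g in range(1, self.G):
            i = (g - 1) // d
            p = (g - 1) % d + 1
            sp_idx = i * (d + 1) + p
            y[self.iya[:, g]] = z[nlp.idx_a_state[:, sp_idx]]
            y[self.iyf[:, g]] = z[nlp.idx_f_state[:, sp_idx]]
        y[self.iyr.ravel()] = z[nlp.idx_r.ravel()]
        return y

    def full_from_y(self, y) -> np.ndarray:
        nlp = self.nlp
        n, d = nlp.n_mesh_intervals, nlp.poly_degree
        z = np.zeros(nlp.n_vars)
        for i in range(n):
            for p in range(d + 1):
                sp_idx = i * (d + 1) + p
                g = i * d + p
                z[nlp.idx_a_state[:, sp_idx]] = y[self.iya[:, g]]
                z[nlp.idx_f_state[:, sp_idx]] = y[self.iyf[:, g]]
        z[nlp.idx_ua.ravel()] = np.asarray(
            self.C_ua @ y).reshape(nlp.K, nlp.m).T.ravel()
        z[nlp.idx_uf.ravel()] = np.asarray(
            self.C_uf @ y).reshape(nlp.K, nlp.m).T.ravel()
        z[nlp.idx_r.ravel()] = y[self.iyr.ravel()]
        return z


def quasi_static_guess(nlp: TranscribedNLP,
                       group_activations: dict | None = None) -> np.ndarray:
    """Initial guess from the quasi-static Hill equilibrium.

    Fixes activations per muscle group, root-finds the equilibrium tendon
    force at every state point (zero force rate), derives the tendon force
    rates from the collocation differentiation matrix so the dynamics
    equalities hold at the guess, and assigns the residual knee/hip/ankle
    moments to the (bounded) reserves so the moment balance is satisfied
    where possible.
    """
    from scipy.optimize import brentq

    from hillmc import reference_gen as rg

    acts = dict(rg.DEFAULT_ORACLE_ACTIVATIONS)
    if group_activations:
        acts.update(group_activations)
    model, st = nlp.model, nlp.settings
    m, P = nlp.m, nlp.P
    d = nlp.poly_degree

    # geometry at *state* points (interval start + collocation points)
    flex0 = float(np.degrees(nlp.kinematics.angle[0]))
    omega = abs(float(nlp.kinematics.angular_velocity[0]))
    flex_deg = flex0 - np.degrees(omega) * nlp.times_states
    q_knee = lm.knee_q_from_flexion_deg(flex_deg)

    a_guess = np.zeros((m, P))
    f_guess = np.zeros((m, P))
    f_lo, f_hi = st.tendon_force_bounds
    for j, mtu in enumerate(model.mtus):
        p = nlp.params[j]
        a = acts.get(mtu.group, 0.1)
        a_guess[j, :] = a
        for i, q in enumerate(q_knee):
            angles = model.pose(q)
            l_mtu = float(lm.mtu_length(mtu.kinematics, angles))
            v_mtu = float(lm.mtu_velocity(
                mtu.kinematics, angles, {model.knee_coordinate: omega}))

            def resid(ft):
                return float(hill_residual_core(
                    a, ft, 0.0, l_mtu, v_mtu, p, nlp.curves,
                    l_opt=p.l_opt, alpha_opt=p.alpha_opt,
                    k_tendon=p.k_tendon, v_max=p.v_max))

            rlo, rhi = resid(f_lo), resid(f_hi)
            if rlo >= 0.0:
                ft = f_lo
            elif rhi <= 0.0:
                ft = f_hi
            else:
                ft = brentq(resid, f_lo, f_hi, xtol=1e-10)
            f_guess[j, i] = ft

    z = np.zeros(nlp.n_vars)
    z[nlp.idx_a_state] = (a_guess - nlp.beta_a) / nlp.alpha_a
    z[nlp.idx_f_state] = (f_guess - nlp.beta_f) / nlp.alpha_f

    # state-derivative controls consistent with the collocation dynamics
    for i in range(nlp.n_mesh_intervals):
        pts = i * (d + 1) + np.arange(d + 1)
        kk = i * d + np.arange(d)
        dfdt = (f_guess[:, pts] @ nlp.D.T) / nlp.h
        z[nlp.idx_uf[:, kk]] = np.clip(dfdt / nlp.alpha_uf, -1.0, 1.0)

    # reserves absorb the remaining moment imbalance (clipped to bounds)
    f_colloc = f_guess[:, nlp._colloc_state_pts]
    for ci, c in enumerate(nlp.coords):
        muscle = np.einsum("jk,j,jk->k", f_colloc, nlp.f_max, nlp.arms[c])
        tau = np.clip(nlp.m_ref[c] - muscle, -nlp.alpha_r, nlp.alpha_r)
        z[nlp.idx_r[ci]] = tau / nlp.alpha_r
    return z


def transcribe(model: lm.LimbModel, reference, kinematics,
               settings: OCPSettings = OCPSettings(),
               perturbed_params=None, curves=None) -> TranscribedNLP:
    """Transcribe the tracking OCP into an NLP structure (see
    :class:`TranscribedNLP`)."""
    return TranscribedNLP(model, reference, kinematics, settings,
                          perturbed_params=perturbed_params, curves=curves)


# ---------------------------------------------------------------------------
# solution container and solve
# ---------------------------------------------------------------------------

@dataclass
class CollocationSolution:
    """Solved (or failed) tracking problem on the collocation grid."""

    status: str                       # "converged" or "failed"
    message: str
    times_states: np.ndarray
    times_colloc: np.ndarray
    activation: np.ndarray            # (m, P)
    tendon_force: np.ndarray          # (m, P), normalized
    activation_rate: np.ndarray       # (m, K), 1/s
    tendon_force_rate: np.ndarray     # (m, K), 1/s
    reserves: np.ndarray              # (nc, K), N*m
    coordinates: list
    knee_coordinate: str
    objective: float
    j_effort: float
    j_reserves: float
    j_controls: float
    knee_moment_residual: np.ndarray  # (K,), N*m
    reference_moment: np.ndarray      # (K,), N*m
    n_iter: int = 0
    max_constraint_violation: float = math.nan
    z: np.ndarray | None = None       # scaled decision vector (warm starts)

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def knee_reserve(self) -> np.ndarray:
        return self.reserves[self.coordinates.index(self.knee_coordinate)]

    def to_csv(self, path) -> None:
        """Long-format trajectory table: time, variable, value."""
        recs = []
        m = self.activation.shape[0]
        for j in range(m):
            for t, a, f in zip(self.times_states, self.activation[j],
                               self.tendon_force[j]):
                recs.append((t, f"a[{j}]", a))
                recs.append((t, f"Ft[{j}]", f))
            for t, ua, uf in zip(self.times_colloc, self.activation_rate[j],
                                 self.tendon_force_rate[j]):
                recs.append((t, f"da[{j}]", ua))
                recs.append((t, f"dFt[{j}]", uf))
        for ci, c in enumerate(self.coordinates):
            for t, tau in zip(self.times_colloc, self.reserves[ci]):
                recs.append((t, f"tau_res[{c}]", tau))
        pd.DataFrame(recs, columns=["time_s", "variable", "value"]).to_csv(
            path, index=False, float_format="%.12g")

    def summary(self) -> dict:
        return {
            "status": self.status,
            "objective": self.objective,
            "j_effort": self.j_effort,
            "j_reserves": self.j_reserves,
            "j_controls": self.j_controls,
            "n_iter": self.n_iter,
            "max_constraint_violation": self.max_constraint_violation,
            "max_knee_reserve_nm": float(np.max(np.abs(self.knee_reserve))),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1, sort_keys=True)


def solve(nlp: TranscribedNLP, settings: OCPSettings | None = None,
          initial_guess: np.ndarray | None = None) -> CollocationSolution:
    """Solve the transcribed NLP with SLSQP.

    Failures (non-convergence, residual constraint violation above the
    accepted tolerance, numerical errors) are returned as solutions with
    status "failed"; they are data, not exceptions.
    """
    settings = settings or nlp.settings
    z0 = nlp.default_guess() if initial_guess is None else np.array(initial_guess)
    status, message, n_iter = "failed", "", 0
    red = nlp.reduced()
    y0 = red.y_from_full(z0)
    y = y0
    try:
        res = scipy.optimize.minimize(
            red.objective, y0, jac=red.objective_grad, method="SLSQP",
            bounds=[(-1.0, 1.0)] * red.n_vars,
            constraints=[
                {"type": "eq", "fun": red.eq_constraints,
                 "jac": red.eq_jacobian},
                {"type": "ineq", "fun": red.ineq_constraints,
                 "jac": red.ineq_jacobian},
            ],
            options={"maxiter": settings.max_iter, "ftol": settings.tol * 1e-2},
        )
        y = res.x
        n_iter = int(res.get("nit", 0))
        message = str(res.message)
        if res.success:
            status = "converged"
    except (ValueError, FloatingPointError, ZeroDivisionError) as exc:  # pragma: no cover
        message = f"solver raised: {exc}"
    z = red.full_from_y(y)

    eq = nlp.eq_constraints(z)
    ineq = nlp.ineq_constraints(z)
    viol = max(float(np.max(np.abs(eq))) if len(eq) else 0.0,
               float(-min(np.min(ineq), 0.0)) if len(ineq) else 0.0)
    if status == "converged" and viol > 10.0 * settings.constr_tol:
        status = "failed"
        message += f" (constraint violation {viol:.2e} above tolerance)"

    u = nlp.unscale(z)
    knee_ci = nlp.coords.index(nlp.model.knee_coordinate)
    m_ref = nlp.m_ref[nlp.model.knee_coordinate]
    muscle_moment = np.einsum(
        "jk,j,jk->k", u["tendon_force"][:, nlp._colloc_state_pts],
        nlp.f_max, nlp.arms[nlp.model.knee_coordinate])
    moment_resid = muscle_moment + u["reserves"][knee_ci] - m_ref

    j_eff = effort_term(u["activation"][:, nlp._colloc_state_pts],
                        nlp.volume_fractions, nlp.quad_weights)
    j_res = reserve_term(u["reserves"] / nlp.alpha_r, nlp.quad_weights,
                         settings.w_reserve)
    j_ctl = control_term(u["activation_rate"] / nlp.alpha_ua,
                         u["tendon_force_rate"] / nlp.alpha_uf,
                         nlp.quad_weights, settings.w_control)

    return CollocationSolution(
        status=status, message=message,
        times_states=nlp.times_states, times_colloc=nlp.times_colloc,
        activation=u["activation"], tendon_force=u["tendon_force"],
        activation_rate=u["activation_rate"],
        tendon_force_rate=u["tendon_force_rate"],
        reserves=u["reserves"], coordinates=list(nlp.coords),
        knee_coordinate=nlp.model.knee_coordinate,
        objective=j_eff + j_res + j_ctl,
        j_effort=j_eff, j_reserves=j_res, j_controls=j_ctl,
        knee_moment_residual=moment_resid, reference_moment=m_ref,
        n_iter=n_iter, max_constraint_violation=viol, z=z)


def track(model: lm.LimbModel, reference, kinematics,
          settings: OCPSettings = OCPSettings(), perturbed_params=None,
          initial_guess=None, curves=None) -> CollocationSolution:
    """Transcribe and solve a tracking problem in one call."""
    nlp = transcribe(model, reference, kinematics, settings,
                     perturbed_params=perturbed_params, curves=curves)
    return solve(nlp, settings, initial_guess=initial_guess)


def classify_feasibility(solution: CollocationSolution, post_reference,
                         threshold_pct: float = 9.0,
                         floor_nm: float = 1.0):
    """Feasibility rule: converged AND the knee reserve stays within
    ``threshold_pct`` percent of the instantaneous reference moment at
    every collocation time (a floor guards near-zero reference moments).

    Returns (feasible, max_reserve_pct).
    """
    m_ref = post_reference.interpolator()(solution.times_colloc)
    denom = np.maximum(np.abs(m_ref), floor_nm)
    pct = 100.0 * np.abs(solution.knee_reserve) / denom
    max_pct = float(np.max(pct))
    feasible = bool(solution.converged and np.all(pct <= threshold_pct))
    return feasible, max_pct
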