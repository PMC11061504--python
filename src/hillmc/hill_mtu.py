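"""Hill-type muscle-tendon-unit model.

Normalized characteristic curves (tendon, active/passive force-length,
force-velocity), constant-thickness pennation geometry, the implicit Hill
equilibrium with normalized tendon force as a state variable, activation
rate limits, and grouped parameter perturbation.

All curve functions accept scalars or numpy arrays and are analytic in
their arguments (complex-step differentiable), which the collocation
transcription relies on for exact constraint Jacobians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "MTUParameters",
    "MTUState",
    "MTUControls",
    "GroupPerturbation",
    "CharacteristicCurves",
    "DEFAULT_CURVES",
    "TENDON_CALIBRATION_STRAIN",
    "ACTIVATION_TIME_CONSTANT",
    "DEACTIVATION_TIME_CONSTANT",
    "tendon_force_norm",
    "tendon_strain_from_force",
    "tendon_stiffness_offset",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "pennation_angle",
    "fiber_state_from_tendon_force",
    "hill_equilibrium_residual",
    "hill_residual_core",
    "activation_rate_bounds",
    "apply_perturbation",
]

# Excitation-activation time constants (s).
ACTIVATION_TIME_CONSTANT = 0.015
DEACTIVATION_TIME_CONSTANT = 0.06

# The tendon curve is calibrated so its slope at this strain equals the
# dimensionless stiffness parameter exactly.
TENDON_CALIBRATION_STRAIN = 0.04

# Pennation guard: geometry is rejected once cos(angle) would fall below this.
_MIN_COS_PENNATION = 0.1


@dataclass(frozen=True)
class CharacteristicCurves:
    """Coefficients of the normalized characteristic curves.

    The defaults are a three-Gaussian active force-length curve with its
    global maximum pinned at normalized length 1, an exponential passive
    curve reaching 1 at the strain limit, and a monotone arsinh
    force-velocity curve calibrated to (f(-1), f(0), f(+1)) =
    (0.015, 1, 1.5). They are surfaced here (rather than hard-coded in the
    functions) so alternative fits can be swapped in via configuration.
    """

    # active force-length: sum of Gaussians w*exp(-(l-c)^2/(2 s^2))
    fl_weights: tuple[float, ...] = (1.0, 0.12, 0.12)
    fl_centers: tuple[float, ...] = (1.0, 0.70, 1.30)
    fl_widths: tuple[float, ...] = (0.16, 0.14, 0.14)
    # passive force-length: strain limit and exponential shape
    passive_strain_limit: float = 0.6
    passive_shape: float = 4.0
    # force-velocity: f(v) = d1*arcsinh(d2*v + d3) + d4
    fv_d1: float = 0.2686371347945174
    fv_d2: float = 8.0
    fv_d3: float = 1.2730416901796029
    fv_d4: float = 0.7147324722870662

    @property
    def fl_norm(self) -> float:
        """Value of the raw Gaussian sum at l=1 (normalization constant)."""
        w = np.asarray(self.fl_weights)
        c = np.asarray(self.fl_centers)
        s = np.asarray(self.fl_widths)
        return float(np.sum(w * np.exp(-((1.0 - c) ** 2) / (2.0 * s**2))))


DEFAULT_CURVES = CharacteristicCurves()


@dataclass(frozen=True)
class MTUParameters:
    """The perturbable Hill parameters plus tendon slack length and
    volume fraction for one muscle-tendon unit.

    ``v_max`` is stored in absolute units (m/s) and perturbed independently
    of the optimal fibre length.
    """

    name: str
    f_max: float            # maximum isometric force, N
    l_opt: float            # optimal fibre length, m
    alpha_opt: float        # pennation angle at optimal fibre length, rad
    v_max: float            # maximum shortening velocity, m/s
    k_tendon: float         # dimensionless tendon stiffness shape
    l_tendon_slack: float   # tendon slack length, m
    volume_fraction: float  # fraction of total muscle volume

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.f_max, self.l_opt, self.alpha_opt, self.v_max,
                      self.k_tendon, self.l_tendon_slack, self.volume_fraction)
        ):
            raise ValueError(f"MTU {self.name!r}: non-finite parameter")
        if self.f_max <= 0:
            raise ValueError(f"MTU {self.name!r}: f_max must be positive")
        if self.l_opt <= 0:
            raise ValueError(f"MTU {self.name!r}: l_opt must be positive")
        if not (0 <= self.alpha_opt < math.pi / 2):
            raise ValueError(f"MTU {self.name!r}: alpha_opt outside [0, pi/2)")
        if self.v_max <= 0:
            raise ValueError(f"MTU {self.name!r}: v_max must be positive")
        if self.k_tendon <= 0:
            raise ValueError(f"MTU {self.name!r}: k_tendon must be positive")
        if self.l_tendon_slack <= 0:
            raise ValueError(f"MTU {self.name!r}: l_tendon_slack must be positive")
        if not (0 <= self.volume_fraction <= 1):
            raise ValueError(f"MTU {self.name!r}: volume_fraction outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MTUParameters":
        return cls(**d)


@dataclass(frozen=True)
class MTUState:
    """State of one MTU: activation and normalized tendon force."""

    activation: float
    tendon_force_norm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.activation)
                and math.isfinite(self.tendon_force_norm)):
            raise ValueError("non-finite MTU state")
        if not (0.0 <= self.activation <= 1.0):
            raise ValueError("activation outside [0, 1]")


@dataclass(frozen=True)
class MTUControls:
    """First time derivatives of the MTU state, used as controls."""

    activation_rate: float       # 1/s
    tendon_force_rate: float     # 1/s (normalized force per second)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.activation_rate)
                and math.isfinite(self.tendon_force_rate)):
            raise ValueError("non-finite MTU controls")


# Default Monte Carlo perturbation boundaries, percent of baseline.
_DEFAULT_PCT_BOUNDS = {
    "mif_pct": (40.0, 100.0),
    "ofl_pct": (60.0, 100.0),
    "opa_pct": (75.0, 100.0),
    "msv_pct": (50.0, 200.0),
    "tc_pct": (40.0, 100.0),
}


@dataclass(frozen=True)
class GroupPerturbation:
    """Percentage perturbations (100 = unperturbed) for the five
    perturbable parameters of one muscle group."""

    mif_pct: float = 100.0
    ofl_pct: float = 100.0
    opa_pct: float = 100.0
    msv_pct: float = 100.0
    tc_pct: float = 100.0

    def validate(self, bounds: dict | None = None) -> None:
        bounds = bounds or _DEFAULT_PCT_BOUNDS
        for key, (lo, hi) in bounds.items():
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"perturbation {key}={v} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# characteristic curves
# ---------------------------------------------------------------------------

def tendon_stiffness_offset(k_tendon):
    """Offset constant c = exp(-calibration_strain * k) of the tendon curve.

    Chosen so force is zero at zero strain and the slope at the calibration
    strain (4%) equals ``k_tendon`` exactly; recomputed from the (possibly
    perturbed) stiffness so the calibration identity is preserved.
    """
    return np.exp(-TENDON_CALIBRATION_STRAIN * k_tendon)


def tendon_force_norm(strain, k_tendon):
    """Normalized tendon force c*(exp(k*strain) - 1), c = exp(-0.04 k)."""
    strain = np.asarray(strain)
    if not np.all(np.isfinite(strain if strain.dtype.kind != "c"
                              else strain.real)):
        raise ValueError("non-finite tendon strain")
    if np.any(np.real(strain) <= -1.0):
        raise ValueError("tendon strain must exceed -1")
    if np.any(np.real(k_tendon) <= 0):
        raise ValueError("k_tendon must be positive")
    c = tendon_stiffness_offset(k_tendon)
    out = c * (np.exp(k_tendon * strain) - 1.0)
    return out if out.ndim else out[()]


def tendon_strain_from_force(force_norm, k_tendon):
    """Invert the calibrated tendon curve: strain as a function of force."""
    c = tendon_stiffness_offset(k_tendon)
    return np.log(force_norm / c + 1.0) / k_tendon


def active_force_length(fib_len_norm, curves: CharacteristicCurves = DEFAULT_CURVES):
    """Active force-length multiplier, a sum of three Gaussians normalized
    to exactly 1 at optimal fibre length."""
    l = np.asarray(fib_len_norm)
    if np.any(np.real(l) <= 0):
        raise ValueError("normalized fibre length must be positive")
    total = 0.0
    for w, c, s in zip(curves.fl_weights, curves.fl_centers, curves.fl_widths):
        total = total + w * np.exp(-((l - c) ** 2) / (2.0 * s**2))
    out = total / curves.fl_norm
    return out if np.ndim(out) else np.asarray(out)[()]


def passive_force_length(fib_len_norm, curves: CharacteristicCurves = DEFAULT_CURVES):
    """Passive (parallel elastic) multiplier: exponential in fibre strain,
    ~0 below optimal length and exactly 1 at the strain limit."""
    l = np.asarray(fib_len_norm)
    if np.any(np.real(l) <= 0):
        raise ValueError("normalized fibre length must be positive")
    kp = curves.passive_shape
    e0 = curves.passive_strain_limit
    out = (np.exp(kp * (l - 1.0) / e0) - 1.0) / (np.exp(kp) - 1.0)
    return out if np.ndim(out) else np.asarray(out)[()]


def force_velocity(fib_vel_norm, curves: CharacteristicCurves = DEFAULT_CURVES):
    """Force-velocity multiplier (shortening negative), arsinh form.

    Equals 1 at zero velocity, ~0 at maximal shortening (v = -1), and
    saturates logarithmically on the eccentric side (< 1.8 for v <= 3).
    """
    v = np.asarray(fib_vel_norm)
    if v.dtype.kind != "c" and not np.all(np.isfinite(v)):
        raise ValueError("non-finite fibre velocity")
    out = curves.fv_d1 * np.arcsinh(curves.fv_d2 * v + curves.fv_d3) + curves.fv_d4
    return out if np.ndim(out) else np.asarray(out)[()]


def pennation_angle(fib_len_norm, alpha_opt):
    """Pennation angle under constant-thickness geometry:
    asin(sin(alpha_opt) / fib_len_norm)."""
    l = np.asarray(fib_len_norm, dtype=float)
    sin_a = math.sin(alpha_opt) / l
    if np.any(sin_a > math.sqrt(1.0 - _MIN_COS_PENNATION**2)):
        raise ValueError(
            "pennation geometry unsolvable: fibre too short for its "
            "pennation height (cos(angle) < 0.1)")
    out = np.arcsin(sin_a)
    return out if np.ndim(out) else out[()]


# ---------------------------------------------------------------------------
# Hill equilibrium
# ---------------------------------------------------------------------------

def _fiber_geometry(tendon_force_norm_, mtu_length, params: MTUParameters,
                    l_opt=None, alpha_opt=None, k_tendon=None,
                    l_tendon_slack=None):
    """Shared smooth geometry: returns (l_tilde, l_fib, l_proj, cos_alpha,
    tendon_length, strain). Complex-step safe."""
    l_opt = params.l_opt if l_opt is None else l_opt
    alpha_opt = params.alpha_opt if alpha_opt is None else alpha_opt
    k_tendon = params.k_tendon if k_tendon is None else k_tendon
    l_slack = params.l_tendon_slack if l_tendon_slack is None else l_tendon_slack
    strain = tendon_strain_from_force(tendon_force_norm_, k_tendon)
    l_ten = l_slack * (1.0 + strain)
    l_proj = mtu_length - l_ten
    h = l_opt * np.sin(alpha_opt)
    l_fib = np.sqrt(l_proj**2 + h**2)
    cos_alpha = l_proj / l_fib
    l_tilde = l_fib / l_opt
    return l_tilde, l_fib, l_proj, cos_alpha, l_ten, strain


def fiber_state_from_tendon_force(tendon_force_norm_, mtu_length,
                                  params: MTUParameters):
    """Recover (normalized fibre length, pennation angle, tendon length)
    from the normalized tendon force by inverting the calibrated tendon
    curve with constant-thickness pennation geometry."""
    if np.any(np.asarray(tendon_force_norm_) < 0):
        raise ValueError("tendon force must be non-negative")
    l_tilde, _, l_proj, cos_alpha, l_ten, _ = _fiber_geometry(
        tendon_force_norm_, mtu_length, params)
    if np.any(np.asarray(l_proj) <= 0) or np.any(np.asarray(cos_alpha) < _MIN_COS_PENNATION):
        raise ValueError(
            f"MTU {params.name!r}: negative or degenerate implied fibre "
            f"length (mtu_length={mtu_length}, tendon={np.max(np.asarray(l_ten))})")
    alpha = np.arccos(np.clip(np.asarray(cos_alpha, dtype=float), -1.0, 1.0))
    return l_tilde, alpha, l_ten


def hill_residual_core(activation, tendon_force_norm_, tendon_force_rate,
                       mtu_length, mtu_velocity, params: MTUParameters,
                       curves: CharacteristicCurves = DEFAULT_CURVES,
                       l_opt=None, alpha_opt=None, k_tendon=None,
                       v_max=None, l_tendon_slack=None, check: bool = False):
    """Vectorized, complex-step-safe Hill equilibrium residual.

    residual = F_tendon - (a*f_act(l)*f_v(v) + f_pas(l)) * cos(pennation)

    The fibre velocity is obtained from the tendon force rate via the chain
    rule through the inverted tendon curve and pennation geometry.
    Optional keyword overrides allow evaluating with perturbed parameters
    without rebuilding ``MTUParameters`` objects.
    """
    k_tendon = params.k_tendon if k_tendon is None else k_tendon
    v_max = params.v_max if v_max is None else v_max
    l_slack = params.l_tendon_slack if l_tendon_slack is None else l_tendon_slack
    l_tilde, _, l_proj, cos_alpha, _, strain = _fiber_geometry(
        tendon_force_norm_, mtu_length, params,
        l_opt=l_opt, alpha_opt=alpha_opt, k_tendon=k_tendon,
        l_tendon_slack=l_slack)
    if check and (np.any(np.real(l_proj) <= 0)
                  or np.any(np.real(cos_alpha) < _MIN_COS_PENNATION)):
        raise ValueError(f"MTU {params.name!r}: degenerate fibre geometry")
    # d(F~t)/d(l_ten) of the tendon curve, used to convert force rate to
    # tendon lengthening rate: dl_ten/dt = dF/dt / (dF/dl_ten)
    c = tendon_stiffness_offset(k_tendon)
    dF_dlten = c * k_tendon * np.exp(k_tendon * strain) / l_slack
    lten_rate = tendon_force_rate / dF_dlten
    fib_vel = cos_alpha * (mtu_velocity - lten_rate)
    v_tilde = fib_vel / v_max
    f_act = active_force_length(l_tilde, curves)
    f_v = force_velocity(v_tilde, curves)
    f_pas = passive_force_length(l_tilde, curves)
    return tendon_force_norm_ - (activation * f_act * f_v + f_pas) * cos_alpha


def hill_equilibrium_residual(state: MTUState, controls: MTUControls,
                              mtu_length: float, mtu_velocity: float,
                              params: MTUParameters,
                              curves: CharacteristicCurves = DEFAULT_CURVES) -> float:
    """Hill equilibrium residual for one MTU at one instant (see
    :func:`hill_residual_core`); zero exactly when the projected
    contractile-plus-passive fibre force balances the tendon force."""
    return float(
        hill_residual_core(state.activation, state.tendon_force_norm,
                           controls.tendon_force_rate, mtu_length,
                           mtu_velocity, params, curves, check=True))


def activation_rate_bounds(activation,
                           t_act: float = ACTIVATION_TIME_CONSTANT,
                           t_deact: float = DEACTIVATION_TIME_CONSTANT):
    """Admissible activation-rate interval (min_rate, max_rate) derived
    from the activation and deactivation time constants."""
    a = np.asarray(activation, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activation outside [0, 1]")
    min_rate = -a / t_deact
    max_rate = (1.0 - a) / t_act
    return min_rate, max_rate


def apply_perturbation(params: MTUParameters, p: GroupPerturbation,
                       bounds: dict | None = None) -> MTUParameters:
    """Scale the five perturbable parameters of one MTU by the group's
    percentages. Tendon slack length is never perturbed; v_max is scaled
    independently of the fibre-length perturbation."""
    p.validate(bounds)
    return replace(
        params,
        f_max=params.f_max * p.mif_pct / 100.0,
        l_opt=params.l_opt * p.ofl_pct / 100.0,
        alpha_opt=params.alpha_opt * p.opa_pct / 100.0,
        v_max=params.v_max * p.msv_pct / 100.0,
        k_tendon=params.k_tendon * p.tc_pct / 100.0,
    )
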