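"""Synthetic reference data.

Builds pre/post-unloading knee extension moment profiles by anchoring a
normative moment-vs-angle fraction table at the 30-degree-flexion value,
generates isokinetic kinematics, and produces oracle post-unloading
references from a known ground-truth parameter perturbation for
parameter-recovery experiments.

The magnitudes in :func:`default_scenario` are synthetic stand-ins for
unavailable bed-rest dynamometry literature values; they are generated
deterministically from a seed and documented in the scenario metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from hillmc import limb_model as lm
from hillmc.hill_mtu import GroupPerturbation, apply_perturbation, hill_residual_core

__all__ = [
    "NormativeProfileTable",
    "ReferenceMomentProfile",
    "isokinetic_kinematics",
    "fractions_from_normative",
    "build_reference",
    "default_scenario",
    "oracle_post_reference",
    "DEFAULT_ORACLE_ACTIVATIONS",
]

# Fixed activations used by the quasi-static oracle, by muscle group.
DEFAULT_ORACLE_ACTIVATIONS = {
    lm.KNEE_EXTENSOR: 0.9,
    lm.KNEE_FLEXOR: 0.05,
    lm.NON_KNEE: 0.1,
}

_ANCHOR_ANGLE_DEG = 30.0


@dataclass(frozen=True)
class NormativeProfileTable:
    """Moment fractions at 10-degree knee flexion intervals, expressed
    relative to the 30-degree value (which is exactly 1)."""

    angle_deg: np.ndarray
    moment_fraction: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.angle_deg, dtype=float)
        f = np.asarray(self.moment_fraction, dtype=float)
        if len(a) != len(f):
            raise ValueError("angle and fraction arrays differ in length")
        if np.any(f <= 0):
            raise ValueError("fractions must be positive")
        i30 = np.nonzero(np.isclose(a, _ANCHOR_ANGLE_DEG))[0]
        if len(i30) != 1 or not math.isclose(f[i30[0]], 1.0):
            raise ValueError("fraction at 30 deg flexion must be exactly 1")


@dataclass(frozen=True)
class ReferenceMomentProfile:
    """Net knee extension moment over an isokinetic motion."""

    condition: str                # "pre" or "post"
    angular_velocity_deg_s: float
    time: np.ndarray              # s
    angle_deg: np.ndarray         # knee flexion, 90 -> 0
    moment_nm: np.ndarray         # extension positive

    def __post_init__(self) -> None:
        if self.condition not in ("pre", "post"):
            raise ValueError("condition must be 'pre' or 'post'")
        if not (len(self.time) == len(self.angle_deg) == len(self.moment_nm)):
            raise ValueError("profile arrays must share one grid")

    def interpolator(self) -> PchipInterpolator:
        """Monotone-cubic moment as a function of time."""
        return PchipInterpolator(self.time, self.moment_nm)

    def to_csv(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame({
            "time_s": self.time,
            "angle_deg": self.angle_deg,
            "moment_Nm": self.moment_nm,
        })
        df.to_csv(path, index=False, float_format="%.10g")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump({"condition": self.condition,
                           "angular_velocity_deg_s": self.angular_velocity_deg_s},
                          fh, sort_keys=True)

    @classmethod
    def from_csv(cls, path, condition, angular_velocity_deg_s) -> "ReferenceMomentProfile":
        df = pd.read_csv(path)
        return cls(condition=condition,
                   angular_velocity_deg_s=float(angular_velocity_deg_s),
                   time=df["time_s"].to_numpy(),
                   angle_deg=df["angle_deg"].to_numpy(),
                   moment_nm=df["moment_Nm"].to_numpy())


def isokinetic_kinematics(angular_velocity_deg_s: float, start_deg: float = 90.0,
                          end_deg: float = 0.0, n_samples: int = 101
                          ) -> lm.CoordinateTrajectory:
    """Constant-velocity knee flexion trajectory from ``start_deg`` down to
    ``end_deg``; duration = (start - end) / angular_velocity."""
    if angular_velocity_deg_s <= 0:
        raise ValueError("angular velocity must be positive")
    duration = (start_deg - end_deg) / angular_velocity_deg_s
    t = np.linspace(0.0, duration, n_samples)
    angle_deg = start_deg - angular_velocity_deg_s * t
    return lm.CoordinateTrajectory(
        name="knee_flexion",
        time=t,
        angle=np.radians(angle_deg),
        angular_velocity=np.full(n_samples, -math.radians(angular_velocity_deg_s)),
    )


def fractions_from_normative(angle_deg, raw_moments) -> NormativeProfileTable:
    """Express raw normative moments as fractions of the 30-deg value."""
    a = np.asarray(angle_deg, dtype=float)
    m = np.asarray(raw_moments, dtype=float)
    i30 = np.nonzero(np.isclose(a, _ANCHOR_ANGLE_DEG))[0]
    if len(i30) != 1:
        raise ValueError("normative table must contain exactly one 30 deg entry")
    anchor = m[i30[0]]
    if anchor == 0:
        raise ValueError("moment at 30 deg flexion must be nonzero")
    return NormativeProfileTable(angle_deg=a, moment_fraction=m / anchor)


def build_reference(moment_at_30deg: float, fractions: NormativeProfileTable,
                    kinematics: lm.CoordinateTrajectory, condition: str = "pre"
                    ) -> ReferenceMomentProfile:
    """Anchor * fraction(angle), monotone-cubic interpolated onto the
    kinematics grid. Reproduces the anchor at 30 deg exactly (the
    interpolant passes through the tabulated knots)."""
    if moment_at_30deg <= 0:
        raise ValueError("anchor moment must be positive")
    order = np.argsort(fractions.angle_deg)
    interp = PchipInterpolator(np.asarray(fractions.angle_deg)[order],
                               np.asarray(fractions.moment_fraction)[order])
    angle_deg = np.degrees(np.asarray(kinematics.angle))
    moment = moment_at_30deg * interp(angle_deg)
    omega = abs(math.degrees(kinematics.angular_velocity[0]))
    return ReferenceMomentProfile(
        condition=condition, angular_velocity_deg_s=omega,
        time=np.asarray(kinematics.time), angle_deg=angle_deg,
        moment_nm=np.asarray(moment))


def default_scenario(seed: int = 0, n_samples: int = 101) -> dict:
    """Plausible synthetic pre/post x {30, 180 deg/s} reference set.

    Normative fractions are bell-shaped, peaking near 60-70 deg flexion;
    post anchors are 30-45% below pre, and 180 deg/s anchors below the
    30 deg/s anchors. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    peak_deg = rng.uniform(58.0, 68.0)
    width = rng.uniform(30.0, 36.0)
    angle_knots = np.arange(90.0, -1.0, -10.0)
    base = 0.38 + 0.62 * np.exp(-((angle_knots - peak_deg) / width) ** 2)
    fractions = fractions_from_normative(angle_knots, base)

    pre30 = rng.uniform(150.0, 190.0)
    drop = rng.uniform(0.30, 0.45)       # post reduction
    vel_ratio = rng.uniform(0.72, 0.82)  # 180 deg/s anchors are smaller
    anchors = {
        ("pre", 30.0): pre30,
        ("post", 30.0): pre30 * (1.0 - drop),
        ("pre", 180.0): pre30 * vel_ratio,
        ("post", 180.0): pre30 * vel_ratio * (1.0 - drop),
    }
    out = {"fractions": fractions, "anchors": anchors, "profiles": {},
           "meta": {"seed": seed, "peak_deg": peak_deg,
                    "post_reduction": drop, "velocity_ratio": vel_ratio}}
    for (cond, vel), anchor in anchors.items():
        kin = isokinetic_kinematics(vel, n_samples=n_samples)
        out["profiles"][(cond, vel)] = build_reference(
            anchor, fractions, kin, condition=cond)
    return out


def recovery_scenario(seed: int = 3, n_samples: int = 41,
                      velocities=(30.0, 180.0)) -> dict:
    """Desk-scale parameter-recovery study setup.

    Builds a small synthetic model (3 knee extensors, 2 knee flexors, 2
    non-knee muscles), fixes a known ground-truth perturbation p* (weakened
    knee extensors, more compliant extensor tendons) and generates the
    post-unloading oracle reference for each angular velocity with
    moderate extensor activations, leaving strength headroom so that the
    feasibility boundary is governed by fibre-length perturbations rather
    than raw strength. p* is feasible by construction.

    Returns a dict with keys: model, pstar (15,), activations,
    kinematics {vel: CoordinateTrajectory}, references {vel: profile}.
    """
    model = lm.build_default_model(n_extensors=3, n_flexors=2,
                                   n_non_knee=2, seed=seed)
    pstar = np.array([70.0, 90.0, 90.0, 100.0, 80.0] + [100.0] * 10)
    activations = {lm.KNEE_EXTENSOR: 0.45, lm.KNEE_FLEXOR: 0.05,
                   lm.NON_KNEE: 0.05}
    kins, refs = {}, {}
    for vel in velocities:
        kins[vel] = isokinetic_kinematics(vel, n_samples=n_samples)
        refs[vel] = oracle_post_reference(
            model, pstar, kins[vel], activation_profile=activations)
    return {"model": model, "pstar": pstar, "activations": activations,
            "kinematics": kins, "references": refs}


def _perturbation_by_group(true_perturbation) -> dict:
    """Normalize a 15-vector / mapping into {group: GroupPerturbation}."""
    if isinstance(true_perturbation, dict) and all(
            isinstance(v, GroupPerturbation) for v in true_perturbation.values()):
        return dict(true_perturbation)
    vec = np.asarray(true_perturbation, dtype=float).ravel()
    if vec.shape != (15,):
        raise ValueError("expected 15 perturbation percentages")
    groups = (lm.KNEE_EXTENSOR, lm.KNEE_FLEXOR, lm.NON_KNEE)
    return {
        g: GroupPerturbation(*vec[5 * i:5 * i + 5]) for i, g in enumerate(groups)
    }


def oracle_post_reference(model: lm.LimbModel, true_perturbation,
                          kinematics: lm.CoordinateTrajectory,
                          activation_profile: dict | None = None,
                          condition: str = "post") -> ReferenceMomentProfile:
    """Net knee moment of the perturbed model under quasi-static Hill
    equilibrium (zero tendon force rate) with fixed group activations.

    By construction the returned profile is attainable by the model
    perturbed with ``true_perturbation``, so that perturbation lies inside
    the feasible set of any campaign tracking this reference.
    """
    acts = dict(DEFAULT_ORACLE_ACTIVATIONS)
    if activation_profile:
        acts.update(activation_profile)
    for v in acts.values():
        if not (0.0 <= v <= 1.0):
            raise ValueError("activations must lie in [0, 1]")
    pert = _perturbation_by_group(true_perturbation)

    flex_deg = np.degrees(np.asarray(kinematics.angle))
    qs = lm.knee_q_from_flexion_deg(flex_deg)
    qdot = -np.asarray(kinematics.angular_velocity)  # extension coordinate rate

    moments = np.zeros(len(qs))
    for m in model.mtus:
        if m.group is None:
            raise ValueError(f"MTU {m.params.name!r} has no group label")
        p = apply_perturbation(m.params, pert[m.group])
        a = acts[m.group]
        for i, (q, qd) in enumerate(zip(qs, qdot)):
            angles = model.pose(q)
            l_mtu = float(lm.mtu_length(m.kinematics, angles))
            vels = {model.knee_coordinate: qd}
            v_mtu = float(lm.mtu_velocity(m.kinematics, angles, vels))
            r = float(lm.moment_arm(m.kinematics, angles, model.knee_coordinate))

            def resid(ft):
                return float(hill_residual_core(a, ft, 0.0, l_mtu, v_mtu, p))

            lo, hi = 0.0, 3.5
            rlo, rhi = resid(lo), resid(hi)
            if rlo >= 0.0:
                # fibre force non-positive (slack, slightly negative passive
                # term): the tendon cannot push, so it carries zero force
                ft = 0.0
            elif rhi < 0:
                raise RuntimeError(
                    f"Hill equilibrium root not bracketed for MTU "
                    f"{p.name!r} at t={kinematics.time[i]:.3f}s")
            else:
                ft = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-12)
            moments[i] += r * ft * p.f_max

    omega = abs(math.degrees(kinematics.angular_velocity[0]))
    return ReferenceMomentProfile(
        condition=condition, angular_velocity_deg_s=omega,
        time=np.asarray(kinematics.time), angle_deg=flex_deg,
        moment_nm=moments)
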