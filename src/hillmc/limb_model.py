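"""Synthetic right-leg model.

Generalized coordinates with prescribed (seated isokinetic) kinematics,
polynomial MTU lengths / velocities / moment arms, muscle grouping by knee
moment arm, and strength scaling from muscle volumes.

Coordinate convention
---------------------
The model's knee generalized coordinate ``q`` measures extension away from
the seated 90-degree-flexed start: q = 0 at 90 deg flexion, q = pi/2 at
full extension, so q increases (positive velocity) during the knee
extension task. With the moment arm defined as r = -d(length)/dq, a
positive r produces a positive (extension) knee moment under tendon
tension, knee extensors carry positive arms and shorten during the task,
and knee flexors carry negative arms and lengthen. User-facing reference
profiles remain in degrees of knee *flexion* (90 -> 0); conversion happens
at the model boundary (``knee_q_from_flexion_deg``).

Hip and ankle are retained as static coordinates (hip fixed at 60 deg
flexion equivalent, ankle neutral) so that non-knee muscles enter the
moment-balance constraints of the tracking problem.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from hillmc.hill_mtu import MTUParameters

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinateTrajectory",
    "MTUKinematicsPoly",
    "MTU",
    "LimbModel",
    "KNEE_EXTENSOR",
    "KNEE_FLEXOR",
    "NON_KNEE",
    "GROUP_LABELS",
    "mtu_length",
    "moment_arm",
    "mtu_velocity",
    "scale_max_isometric_force",
    "classify_muscle_groups",
    "net_joint_moment",
    "build_default_model",
    "knee_q_from_flexion_deg",
    "DEFAULT_POSE",
]

KNEE_EXTENSOR = "knee_extensor"
KNEE_FLEXOR = "knee_flexor"
NON_KNEE = "non_knee"
GROUP_LABELS = (KNEE_EXTENSOR, KNEE_FLEXOR, NON_KNEE)

# Moment-arm magnitude below which a muscle does not "cross" the knee.
_GROUP_ARM_THRESHOLD = 1e-3  # m
_MAX_MOMENT_ARM = 0.12       # |r| bound, m

# Static posture: hip flexed (femur parallel to ground), ankle neutral.
DEFAULT_POSE = {"hip": math.radians(60.0), "knee": 0.0, "ankle": 0.0}


def knee_q_from_flexion_deg(flexion_deg):
    """Map knee flexion angle in degrees (90 -> 0 over the task) to the
    model's knee extension coordinate in radians (0 -> pi/2)."""
    return np.radians(90.0 - np.asarray(flexion_deg, dtype=float))


@dataclass(frozen=True)
class CoordinateTrajectory:
    """Prescribed trajectory of a single generalized coordinate."""

    name: str
    time: np.ndarray              # s, strictly increasing
    angle: np.ndarray             # rad
    angular_velocity: np.ndarray  # rad/s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        if not (len(t) == len(self.angle) == len(self.angular_velocity)):
            raise ValueError("trajectory arrays must share one grid")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class MTUKinematicsPoly:
    """Additively separable polynomial MTU length:

    length(q) = constant + sum_c poly_c(q_c),   max degree 4 per coordinate.

    Moment arm about coordinate c is -d(length)/d(q_c).
    """

    constant: float
    coords: dict  # coordinate name -> 1-D coefficient array (low -> high)
    valid_range: dict = field(default_factory=dict)  # name -> (lo, hi) rad

    def __post_init__(self) -> None:
        for name, coeffs in self.coords.items():
            c = np.asarray(coeffs, dtype=float)
            if c.ndim != 1 or len(c) > 5:
                raise ValueError(
                    f"coordinate {name!r}: polynomial degree above 4")

    def _check_range(self, angles: dict) -> None:
        for name, (lo, hi) in self.valid_range.items():
            q = angles.get(name, 0.0)
            if np.any(np.asarray(q) < lo) or np.any(np.asarray(q) > hi):
                warnings.warn(
                    f"angle for coordinate {name!r} outside the polynomial "
                    f"validity range [{lo}, {hi}]; extrapolating",
                    stacklevel=3)
                logger.warning("extrapolating MTU polynomial for %s", name)


def mtu_length(poly: MTUKinematicsPoly, angles: dict):
    """Evaluate MTU length (m) at the given coordinate angles (rad)."""
    poly._check_range(angles)
    total = poly.constant
    for name, coeffs in poly.coords.items():
        total = total + npoly.polyval(np.asarray(angles.get(name, 0.0)), coeffs)
    return total


def moment_arm(poly: MTUKinematicsPoly, angles: dict, coordinate: str):
    """Moment arm -d(length)/d(angle) (m) about the named coordinate.

    Positive arm => positive (extension-direction) moment under tension.
    """
    poly._check_range(angles)
    coeffs = poly.coords.get(coordinate)
    if coeffs is None:
        return np.zeros_like(np.asarray(angles.get(coordinate, 0.0), dtype=float))[()]
    dcoeffs = npoly.polyder(np.asarray(coeffs, dtype=float))
    return -npoly.polyval(np.asarray(angles.get(coordinate, 0.0)), dcoeffs)


def mtu_velocity(poly: MTUKinematicsPoly, angles: dict, angular_velocities: dict):
    """MTU lengthening velocity (m/s): sum_c d(length)/d(q_c) * qdot_c."""
    total = 0.0
    for name in poly.coords:
        qdot = np.asarray(angular_velocities.get(name, 0.0))
        total = total + (-moment_arm(poly, angles, name)) * qdot
    return total


def scale_max_isometric_force(volume_cm3, l_opt_cm, specific_tension=60.0):
    """Maximum isometric force (N) from physiological cross-sectional area:
    specific_tension * volume / optimal fibre length."""
    if np.any(np.asarray(volume_cm3) <= 0) or np.any(np.asarray(l_opt_cm) <= 0) \
            or specific_tension <= 0:
        raise ValueError("volume, fibre length and specific tension must be positive")
    return specific_tension * np.asarray(volume_cm3) / np.asarray(l_opt_cm)


@dataclass
class MTU:
    """One muscle-tendon unit: Hill parameters, polynomial kinematics and
    (derived) group label."""

    params: MTUParameters
    kinematics: MTUKinematicsPoly
    volume_cm3: float
    group: str | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "kinematics": {
                "constant": self.kinematics.constant,
                "coords": {k: list(map(float, v))
                           for k, v in self.kinematics.coords.items()},
                "valid_range": {k: list(v)
                                for k, v in self.kinematics.valid_range.items()},
            },
            "volume_cm3": self.volume_cm3,
            "group": self.group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MTU":
        kin = MTUKinematicsPoly(
            constant=d["kinematics"]["constant"],
            coords={k: np.asarray(v, dtype=float)
                    for k, v in d["kinematics"]["coords"].items()},
            valid_range={k: tuple(v)
                         for k, v in d["kinematics"]["valid_range"].items()},
        )
        return cls(params=MTUParameters.from_dict(d["params"]),
                   kinematics=kin, volume_cm3=d["volume_cm3"],
                   group=d.get("group"))


@dataclass
class LimbModel:
    """Right-leg model: named coordinates, a static default pose, and MTUs."""

    coordinates: list
    mtus: list
    default_pose: dict = field(default_factory=lambda: dict(DEFAULT_POSE))
    knee_coordinate: str = "knee"
    name: str = "synthetic-right-leg"

    @property
    def n_mtus(self) -> int:
        return len(self.mtus)

    def pose(self, knee_q) -> dict:
        angles = dict(self.default_pose)
        angles[self.knee_coordinate] = knee_q
        return angles

    def to_json(self, path=None) -> str:
        doc = {
            "name": self.name,
            "coordinates": list(self.coordinates),
            "knee_coordinate": self.knee_coordinate,
            "default_pose": {k: float(v) for k, v in self.default_pose.items()},
            "mtus": [m.to_dict() for m in self.mtus],
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LimbModel":
        if isinstance(source, (str, bytes)) and "{" in str(source):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            coordinates=list(doc["coordinates"]),
            mtus=[MTU.from_dict(m) for m in doc["mtus"]],
            default_pose={k: float(v) for k, v in doc["default_pose"].items()},
            knee_coordinate=doc["knee_coordinate"],
            name=doc["name"],
        )

    def moment_arms_csv(self, path, n_points: int = 19) -> None:
        """Export knee moment arms vs knee flexion angle for inspection."""
        import pandas as pd

        flex_deg = np.linspace(90.0, 0.0, n_points)
        q = knee_q_from_flexion_deg(flex_deg)
        rows = {"flexion_deg": flex_deg}
        for m in self.mtus:
            rows[m.params.name] = [
                float(moment_arm(m.kinematics, self.pose(qi), self.knee_coordinate))
                for qi in q]
        pd.DataFrame(rows).to_csv(path, index=False)


def classify_muscle_groups(model: LimbModel, n_samples: int = 19) -> dict:
    """Label every MTU by the sign of its mean knee moment arm over the
    90 -> 0 deg flexion range: > +1 mm extensor, < -1 mm flexor, else
    non-knee. Depends only on geometry."""
    qs = knee_q_from_flexion_deg(np.linspace(90.0, 0.0, n_samples))
    labels = {}
    for m in model.mtus:
        arms = [float(moment_arm(m.kinematics, model.pose(q), model.knee_coordinate))
                for q in qs]
        mean_arm = float(np.mean(arms))
        if mean_arm > _GROUP_ARM_THRESHOLD:
            labels[m.params.name] = KNEE_EXTENSOR
        elif mean_arm < -_GROUP_ARM_THRESHOLD:
            labels[m.params.name] = KNEE_FLEXOR
        else:
            labels[m.params.name] = NON_KNEE
        m.group = labels[m.params.name]
    return labels


def net_joint_moment(tendon_forces, model: LimbModel, angles: dict,
                     coordinate: str) -> float:
    """Net moment (N*m) about a coordinate: sum of moment arm * force."""
    forces = np.asarray(tendon_forces, dtype=float)
    if len(forces) != model.n_mtus:
        raise ValueError(
            f"expected {model.n_mtus} forces, got {len(forces)}")
    total = 0.0
    for f, m in zip(forces, model.mtus):
        total += float(moment_arm(m.kinematics, angles, coordinate)) * f
    return float(total)


# ---------------------------------------------------------------------------
# default synthetic model
# ---------------------------------------------------------------------------

_SPECIFIC_TENSION = 60.0  # N/cm^2
_VMAX_PER_OFL = 10.0      # max shortening velocity = 10 optimal fibre lengths/s
_BASELINE_K_TENDON = 35.0


def _solve_reference_length(l_opt, alpha_opt, l_slack, l_tilde_target):
    """MTU length at which the slack-tendon fibre sits at l_tilde_target."""
    h = l_opt * math.sin(alpha_opt)
    l_fib = l_tilde_target * l_opt
    return l_slack + math.sqrt(max(l_fib**2 - h**2, 1e-10))


def build_default_model(n_extensors: int = 6, n_flexors: int = 9,
                        n_non_knee: int = 25, seed: int = 0) -> LimbModel:
    """Deterministic synthetic right-leg model (default 40 MTUs).

    Knee extensors operate on the ascending limb / plateau (normalized
    fibre length falling from ~1.15 toward ~0.7 over the 90 -> 0 deg
    motion) and knee flexors on the plateau / descending limb (rising from
    ~0.85 toward ~1.25). Non-knee muscles act about the static hip/ankle
    coordinates and sit near optimal length in the seated pose. Moment-arm
    magnitudes follow documented plausible ranges (extensors 3.5-4.5 cm,
    flexors 2.5-3.5 cm); the geometry is a synthetic stand-in, not a fitted
    anatomical dataset.
    """
    if min(n_extensors, n_flexors, n_non_knee) < 1:
        raise ValueError("each muscle group needs at least one MTU")
    rng = np.random.default_rng(seed)
    q_hi = math.pi / 2
    mtus = []

    def _make(name, arm0, arm_slope, l_opt, alpha_opt, slack_ratio,
              l_tilde_start, volume, knee=True, hip_arm=0.0):
        l_slack = slack_ratio * l_opt
        coords = {}
        if knee:
            # arm(q) = arm0 + arm_slope*(q - pi/4): length = const - int(arm)
            coords["knee"] = np.array([
                0.0,
                -(arm0 - arm_slope * math.pi / 4),
                -arm_slope / 2.0,
            ])
        if hip_arm != 0.0:
            coords["hip"] = np.array([0.0, -hip_arm])
        l_ref = _solve_reference_length(l_opt, alpha_opt, l_slack, l_tilde_start)
        # anchor the length constant so length at the *starting* pose is l_ref
        start_pose = dict(DEFAULT_POSE)
        start_pose["knee"] = 0.0
        offset = sum(npoly.polyval(start_pose.get(k, 0.0), c)
                     for k, c in coords.items())
        kin = MTUKinematicsPoly(
            constant=l_ref - float(offset),
            coords=coords,
            valid_range={"knee": (-0.2, q_hi + 0.2)} if knee else {},
        )
        f_max = float(scale_max_isometric_force(volume, l_opt * 100.0,
                                                _SPECIFIC_TENSION))
        params = MTUParameters(
            name=name, f_max=f_max, l_opt=l_opt, alpha_opt=alpha_opt,
            v_max=_VMAX_PER_OFL * l_opt, k_tendon=_BASELINE_K_TENDON,
            l_tendon_slack=l_slack, volume_fraction=0.0)
        return MTU(params=params, kinematics=kin, volume_cm3=volume)

    for i in range(n_extensors):
        l_opt = rng.uniform(0.13, 0.17)
        mtus.append(_make(
            name=f"ext{i:02d}",
            arm0=rng.uniform(0.037, 0.044),
            arm_slope=rng.uniform(-0.008, 0.008),
            l_opt=l_opt,
            alpha_opt=rng.uniform(0.06, 0.22),
            slack_ratio=rng.uniform(0.9, 1.4),
            l_tilde_start=rng.uniform(1.08, 1.18),
            volume=rng.uniform(400.0, 650.0),
        ))
    for i in range(n_flexors):
        l_opt = rng.uniform(0.11, 0.15)
        mtus.append(_make(
            name=f"flx{i:02d}",
            arm0=-rng.uniform(0.027, 0.034),
            arm_slope=rng.uniform(-0.006, 0.006),
            l_opt=l_opt,
            alpha_opt=rng.uniform(0.06, 0.20),
            slack_ratio=rng.uniform(1.2, 1.8),
            l_tilde_start=rng.uniform(0.82, 0.90),
            volume=rng.uniform(150.0, 300.0),
        ))
    for i in range(n_non_knee):
        l_opt = rng.uniform(0.07, 0.13)
        # same-sign hip arms: non-knee passive forces cannot cancel each
        # other at the hip, so strong fibre-length perturbations saturate
        # the hip reserve rather than self-balancing
        sign = 1.0
        mtus.append(_make(
            name=f"nk{i:02d}",
            arm0=0.0, arm_slope=0.0,
            l_opt=l_opt,
            alpha_opt=rng.uniform(0.06, 0.25),
            slack_ratio=rng.uniform(1.0, 1.6),
            l_tilde_start=rng.uniform(0.95, 1.05),
            volume=rng.uniform(60.0, 350.0),
            knee=False,
            hip_arm=sign * rng.uniform(0.02, 0.04),
        ))

    total_volume = sum(m.volume_cm3 for m in mtus)
    for m in mtus:
        m.params = MTUParameters(
            **{**m.params.to_dict(),
               "volume_fraction": m.volume_cm3 / total_volume})

    model = LimbModel(coordinates=["hip", "knee", "ankle"], mtus=mtus)
    classify_muscle_groups(model)
    return model
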