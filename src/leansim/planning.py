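"""CNS motor planning: reference lean trajectory and target geometry.

The planned lean angle follows the minimum-jerk-style polynomial

    theta_ref(t) = theta_0 + (theta_0 - theta_f) * (A1*tau^4 - A2*tau^5 - A3*tau^3),
    tau = (t - t_r) / t_f

With the default coefficients A1=15, A2=6, A3=10 the bracket equals -1 at
tau=1, so theta_ref moves from theta_0 to theta_f with zero endpoint
velocity and acceleration and a bell-shaped velocity profile (the bracket
is minus the classic minimum-jerk polynomial 10 tau^3 - 15 tau^4 + 6 tau^5).

Targets of the limit-of-stability protocol sit at 30% of the theoretical
lean limit:  d = scale * H_CoM * tan(theta_limit), applied independently in
the anterior-posterior (AP) and medio-lateral (ML) directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default bell-shape coefficients (minimum-jerk-consistent choice).
DEFAULT_A = (15.0, 6.0, 10.0)

#: Theoretical lean-limit angles (deg) per target, AP and ML components.
#: Targets 1-5 lean forward, 6-8 backward (signed AP); diagonal pairs
#: (2,3), (4,5), (6,7) mirror each other in ML.
TARGET_LIMIT_ANGLES_DEG: dict[int, tuple[float, float]] = {
    1: (6.25, 0.0),
    2: (4.5, 6.0),
    3: (4.5, -6.0),
    4: (1.7, 8.0),
    5: (1.7, -8.0),
    6: (-4.4, 6.0),
    7: (-4.4, -6.0),
    8: (-4.4, 0.0),
}

DEFAULT_SCALE_FRACTION = 0.3


@dataclass(frozen=True)
class PlanningParams:
    """Temporal and angular parameters of one planned lean."""

    t_r: float  # s, reaction time
    t_f: float  # s, reaching time
    t_b: float  # s, return time
    t_APA: float  # s, APA (feedforward blending) duration
    theta_0: float = 0.0  # deg
    theta_f: float = 0.0  # deg
    A1: float = DEFAULT_A[0]
    A2: float = DEFAULT_A[1]
    A3: float = DEFAULT_A[2]
    hold: float = 0.0  # s, pause at the target before the return

    def __post_init__(self):
        for name in ("t_r", "t_f", "t_b"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"PlanningParams.{name} must be > 0")
        if not 0 < self.t_APA <= self.t_f:
            raise ValidationError("PlanningParams.t_APA must satisfy 0 < t_APA <= t_f")
        if self.hold < 0:
            raise ValidationError("PlanningParams.hold must be >= 0")


@dataclass(frozen=True)
class TargetRecord:
    target_id: int
    ap_limit_angle: float  # deg, signed (+ forward)
    ml_limit_angle: float  # deg, signed
    ap_distance: float  # m
    ml_distance: float  # m

    @property
    def distance(self) -> float:
        return math.hypot(self.ap_distance, self.ml_distance)

    @property
    def unit_vector(self) -> tuple[float, float]:
        d = self.distance
        if d == 0:
            raise ValidationError(f"target {self.target_id} has zero distance")
        return self.ap_distance / d, self.ml_distance / d


@dataclass(frozen=True)
class TargetLayout:
    """The eight-target layout of the limit-of-stability protocol."""

    H_CoM: float
    scale_fraction: float
    targets: dict[int, TargetRecord] = field(default_factory=dict)

    def __getitem__(self, target_id: int) -> TargetRecord:
        try:
            return self.targets[target_id]
        except KeyError:
            raise ValidationError(f"unknown target id {target_id}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target_id": t.target_id,
                "ap_limit_angle_deg": t.ap_limit_angle,
                "ml_limit_angle_deg": t.ml_limit_angle,
                "ap_distance_m": t.ap_distance,
                "ml_distance_m": t.ml_distance,
            }
            for t in self.targets.values()
        ]
        return pd.DataFrame(rows).sort_values("target_id").reset_index(drop=True)


def _bracket(params: PlanningParams, tau):
    """The trajectory bracket A1*tau^4 - A2*tau^5 - A3*tau^3 and derivatives."""
    a1, a2, a3 = params.A1, params.A2, params.A3
    b = a1 * tau**4 - a2 * tau**5 - a3 * tau**3
    db = 4 * a1 * tau**3 - 5 * a2 * tau**4 - 3 * a3 * tau**2
    ddb = 12 * a1 * tau**2 - 20 * a2 * tau**3 - 6 * a3 * tau
    return b, db, ddb


def plan_reference(params: PlanningParams, t):
    """Reference lean angle, velocity, acceleration at time(s) ``t``.

    ``t`` is measured from target onset.  Phases: flat at theta_0 until
    t_r; polynomial reach over t_f; optional hold at theta_f; mirrored
    polynomial return over t_b; flat at theta_0 afterwards.  Accepts a
    scalar or an array; returns (theta_ref, dtheta_ref, ddtheta_ref) in
    deg, deg/s, deg/s².
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    th = np.full_like(t, params.theta_0)
    dth = np.zeros_like(t)
    ddth = np.zeros_like(t)

    t1 = params.t_r
    t2 = t1 + params.t_f
    t3 = t2 + params.hold
    t4 = t3 + params.t_b
    amp = params.theta_0 - params.theta_f

    m = (t > t1) & (t <= t2)
    if m.any():
        tau = (t[m] - t1) / params.t_f
        b, db, ddb = _bracket(params, tau)
        th[m] = params.theta_0 + amp * b
        dth[m] = amp * db / params.t_f
        ddth[m] = amp * ddb / params.t_f**2

    m = (t > t2) & (t <= t3)
    th[m] = params.theta_f

    m = (t > t3) & (t <= t4)
    if m.any():
        tau = (t[m] - t3) / params.t_b
        b, db, ddb = _bracket(params, tau)
        # mirrored profile: theta_f back to theta_0 over t_b
        th[m] = params.theta_f - amp * b
        dth[m] = -amp * db / params.t_b
        ddth[m] = -amp * ddb / params.t_b**2

    if scalar:
        return float(th[0]), float(dth[0]), float(ddth[0])
    return th, dth, ddth


def target_layout(H_CoM: float, scale_fraction: float = DEFAULT_SCALE_FRACTION) -> TargetLayout:
    """Place the 8 targets at ``scale_fraction`` of the theoretical limits."""
    if not H_CoM > 0:
        raise ValidationError(f"H_CoM={H_CoM} must be > 0")
    targets = {}
    for tid, (ap, ml) in TARGET_LIMIT_ANGLES_DEG.items():
        targets[tid] = TargetRecord(
            target_id=tid,
            ap_limit_angle=ap,
            ml_limit_angle=ml,
            ap_distance=scale_fraction * H_CoM * math.tan(math.radians(ap)),
            ml_distance=scale_fraction * H_CoM * math.tan(math.radians(ml)),
        )
    return TargetLayout(H_CoM=H_CoM, scale_fraction=scale_fraction, targets=targets)


def theta_target_from_distance(d: float, H_CoM: float) -> float:
    """Lean angle (deg) whose static COP projection covers distance ``d``."""
    if not H_CoM > 0:
        raise ValidationError(f"H_CoM={H_CoM} must be > 0")
    return math.degrees(math.atan2(d, H_CoM))
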