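"""Feedback, feedforward, and blended ankle torque commands.

Three torque sources act at the ankle:

* PI feedback on the lean angle error,
  tau_FB = K_P*(theta_ref - theta) + K_I*(dtheta_ref - dtheta)  [gains per deg],
* an inverse-model feedforward driven by the planned trajectory,
  tau_FF = K_FF*(J_B*ddtheta_ref - m*g*L_COM*theta_ref)  [theta_ref in rad],
* intrinsic ankle impedance tau_AIS (see :mod:`leansim.plant`).

During the APA window (t_r < t < t_r + t_APA after target onset) the
feedforward and feedback channels are cross-faded with the weight
alpha = (t - t_r)/t_APA.  Two conventions exist for which channel alpha
weights:

* ``"narrative"`` (default): tau = (1-alpha)*tau_FF + alpha*tau_FB + tau_AIS
  -- control shifts smoothly from feedforward to feedback.  Because the
  planned trajectory starts from rest, tau_FF vanishes at the window start,
  so the total torque is continuous at BOTH window edges.
* ``"printed"``: tau = alpha*tau_FF + (1-alpha)*tau_FB + tau_AIS -- purely
  feedback at APA onset, purely feedforward at APA end.  The hand-over back
  to feedback at the window end is then discontinuous, which injects a
  single-sample COP spike proportional to K_FF (the COP carries the
  acceleration directly); with healthy-scale K_FF this spike dwarfs the
  genuine APA.  Kept as an option for comparison.

Outside the window the command is tau_FB + tau_AIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .plant import DEG, RAD, Anthropometry, BodyState, PlantParams
from .planning import PlanningParams

#: Velocity-error feedback gain, fixed across subjects (N·m per deg/s).
DEFAULT_K_I = 5.0

BLEND_DIRECTIONS = ("narrative", "printed")
DEFAULT_BLEND_DIRECTION = "narrative"


@dataclass(frozen=True)
class ControlGains:
    """Subject-specific controller gains (per-degree units)."""

    K_P: float  # N·m/deg
    K_FF: float  # dimensionless
    K_I: float = DEFAULT_K_I  # N·m/(deg/s)

    def __post_init__(self):
        if not self.K_P > 0:
            raise ValidationError("ControlGains.K_P must be > 0")
        if self.K_I < 0 or self.K_FF < 0:
            raise ValidationError("ControlGains.K_I and K_FF must be >= 0")

    def validate_stable(self, anthro: Anthropometry, plant: PlantParams) -> None:
        """Closed-loop static stability: (K_P + K_A) per rad must exceed m*g*L."""
        if (self.K_P + plant.K_A) * RAD <= anthro.mgl:
            raise ValidationError(
                f"K_P={self.K_P} N·m/deg too small for static stability "
                f"(needs > {min_stable_kp(anthro, plant):.2f} N·m/deg)"
            )


def min_stable_kp(anthro: Anthropometry, plant: PlantParams) -> float:
    """Smallest K_P (N·m/deg) giving positive closed-loop static stiffness."""
    return max((anthro.mgl / RAD) - plant.K_A, 0.0)


@dataclass(frozen=True)
class ControlCommand:
    """One sample of the blended torque command and its components."""

    tau_FB: float
    tau_FF: float
    tau_AIS: float
    alpha: float
    tau_total: float


def feedback_torque(
    gains: ControlGains,
    theta_ref: float,
    theta_ref_dot: float,
    state: BodyState,
) -> float:
    """PI feedback torque on the angle/velocity tracking error (N·m)."""
    return gains.K_P * (theta_ref - state.theta) + gains.K_I * (
        theta_ref_dot - state.theta_dot
    )


def feedforward_torque(
    K_FF: float,
    anthro: Anthropometry,
    theta_ref: float,
    theta_ref_ddot: float,
) -> float:
    """Inverse-model feedforward torque (N·m).

    Time-domain realization of K_FF*(J_B s^2 - m g L_COM) applied to the
    reference: the second derivative comes analytically from the planner,
    never from numeric differentiation.
    """
    return K_FF * (
        anthro.J_B * theta_ref_ddot * DEG - anthro.mgl * theta_ref * DEG
    )


def blend_weights(
    t: float,
    params: PlanningParams,
    blend_direction: str = DEFAULT_BLEND_DIRECTION,
):
    """(w_FF, w_FB, alpha) at time ``t`` after target onset."""
    if params.t_APA <= 0:
        raise ValidationError("t_APA must be > 0")
    if blend_direction not in BLEND_DIRECTIONS:
        raise ValidationError(f"blend_direction must be one of {BLEND_DIRECTIONS}")
    alpha = (t - params.t_r) / params.t_APA
    alpha = min(max(alpha, 0.0), 1.0)
    in_window = params.t_r < t < params.t_r + params.t_APA
    if not in_window:
        return 0.0, 1.0, alpha
    if blend_direction == "printed":
        return alpha, 1.0 - alpha, alpha
    return 1.0 - alpha, alpha, alpha


def blend_torque(
    t: float,
    params: PlanningParams,
    tau_FF: float,
    tau_FB: float,
    tau_AIS: float,
    blend_direction: str = DEFAULT_BLEND_DIRECTION,
) -> ControlCommand:
    """Cross-fade feedforward and feedback torque during the APA window."""
    if not all(map(math.isfinite, (tau_FF, tau_FB, tau_AIS))):
        raise ValidationError("torque components must be finite")
    w_ff, w_fb, alpha = blend_weights(t, params, blend_direction)
    total = w_ff * tau_FF + w_fb * tau_FB + tau_AIS
    return ControlCommand(
        tau_FB=tau_FB, tau_FF=tau_FF, tau_AIS=tau_AIS, alpha=alpha, tau_total=total
    )
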