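"""Single inverted-pendulum body model about the ankle.

The body is modelled as a rigid segment rotating about the ankle joint
(ankle strategy).  The equation of motion is

    J_B * theta_ddot = m * g * L_COM * sin(theta) + tau_total

with ``theta`` the lean angle from vertical, positive toward the task
direction.  Intrinsic ankle impedance contributes a passive torque
``tau_AIS = -(K_A*theta + B_A*theta_dot)``; because the intrinsic stiffness
is sub-critical (``K_A < m*g*L_COM`` in rad units) quiet stance is unstable
without active control.

Controller-facing angles are degrees (the identified gains are per-degree);
all internal dynamics use radians.  The conversion lives at the boundaries
of this module and nowhere else.

The center of pressure is obtained from the linearized single-pendulum
ZMP relation

    COP = L_COM * theta - (J_B / (m*g)) * theta_ddot        [m, theta in rad]

which reduces to the COM ground projection in static conditions and makes
any acceleration toward the target push the COP the opposite way -- the
mechanism behind the anticipatory postural adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ValidationError

G = 9.81
DEG = math.pi / 180.0  # rad per degree
RAD = 180.0 / math.pi  # degree per rad

#: Default ankle-to-COM height as a fraction of stature (anthropometric
#: convention for the COM height of a standing adult).
DEFAULT_COM_COEFF = 0.5527

#: Default intrinsic ankle stiffness/damping as fractions of the gravity
#: stiffness m*g*L_COM (per-rad, converted to per-degree at construction).
#: Sub-critical on purpose: passive stance alone must be unstable.
DEFAULT_KA_FRACTION = 0.15
DEFAULT_BA_FRACTION = 0.05


@dataclass(frozen=True)
class Anthropometry:
    """Subject segment parameters for the single-pendulum model.

    L_COM (the ankle-to-COM height) is identified with the COM height used
    for target placement.  J_B is the moment of inertia about the ankle.
    """

    mass: float  # kg
    height: float  # m
    L_COM: float  # m
    J_B: float  # kg m^2
    g: float = G  # m/s^2

    def __post_init__(self):
        for name in ("mass", "height", "L_COM", "J_B"):
            if not (getattr(self, name) > 0 and math.isfinite(getattr(self, name))):
                raise ValidationError(f"Anthropometry.{name} must be strictly positive")
        if not self.L_COM < self.height:
            raise ValidationError("Anthropometry.L_COM must be below stature")
        if self.g != G:
            raise ValidationError("Anthropometry.g is fixed at 9.81 m/s^2")

    @property
    def mgl(self) -> float:
        """Gravity stiffness m*g*L_COM in N·m/rad."""
        return self.mass * self.g * self.L_COM


@dataclass(frozen=True)
class PlantParams:
    """Intrinsic ankle impedance; gains are per-degree like the controller."""

    K_A: float  # N·m/deg
    B_A: float  # N·m/(deg/s)
    linearized: bool = False  # sin(theta) -> theta

    def __post_init__(self):
        if self.K_A < 0 or self.B_A < 0:
            raise ValidationError("intrinsic stiffness/damping must be >= 0")

    def validate_subcritical(self, anthro: Anthropometry) -> None:
        """Passive stance must be unstable: K_A (per rad) < m*g*L_COM."""
        if self.K_A * RAD >= anthro.mgl:
            raise ValidationError(
                f"intrinsic stiffness K_A={self.K_A} N·m/deg is super-critical "
                f"(>= {anthro.mgl / RAD:.2f} N·m/deg); passive stance would be stable"
            )


@dataclass(frozen=True)
class BodyState:
    """Lean angle state along the task direction (degrees at the interface)."""

    theta: float  # deg, positive toward the target
    theta_dot: float  # deg/s
    t: float = 0.0  # s

    def __post_init__(self):
        if not all(map(math.isfinite, (self.theta, self.theta_dot, self.t))):
            raise ValidationError("BodyState fields must be finite")
        if abs(self.theta) >= 90.0:
            raise ValidationError("BodyState.theta must satisfy |theta| < 90 deg")


def derive_anthropometry(
    height: float,
    mass: float,
    com_coeff: float = DEFAULT_COM_COEFF,
    J_B: float | None = None,
) -> Anthropometry:
    """Build an :class:`Anthropometry` from stature and mass.

    L_COM = com_coeff * height; J_B defaults to the point-mass value
    m * L_COM**2 unless overridden.
    """
    if not 1.2 < height < 2.2:
        raise ValidationError(f"height={height} m outside the plausible range (1.2, 2.2)")
    if not 30.0 < mass < 150.0:
        raise ValidationError(f"mass={mass} kg outside the plausible range (30, 150)")
    if not 0 < com_coeff < 1:
        raise ValidationError(f"com_coeff={com_coeff} must lie in (0, 1)")
    L = com_coeff * height
    J = mass * L * L if J_B is None else float(J_B)
    return Anthropometry(mass=mass, height=height, L_COM=L, J_B=J)


def default_plant(anthro: Anthropometry, linearized: bool = False) -> PlantParams:
    """Intrinsic impedance scaled to gravity stiffness (sub-critical)."""
    return PlantParams(
        K_A=DEFAULT_KA_FRACTION * anthro.mgl / RAD,
        B_A=DEFAULT_BA_FRACTION * anthro.mgl / RAD,
        linearized=linearized,
    )


def intrinsic_torque(state: BodyState, plant: PlantParams) -> float:
    """Passive ankle torque tau_AIS = -(K_A*theta + B_A*theta_dot), N·m."""
    return -(plant.K_A * state.theta + plant.B_A * state.theta_dot)


def _accel(theta_rad: float, tau_total: float, anthro: Anthropometry, linearized: bool) -> float:
    grav = theta_rad if linearized else math.sin(theta_rad)
    return (anthro.mgl * grav + tau_total) / anthro.J_B


def pendulum_step(
    state: BodyState,
    tau_total: float,
    anthro: Anthropometry,
    dt: float,
    plant: PlantParams,
) -> BodyState:
    """Advance the pendulum one fixed RK4 step under constant total torque.

    The intrinsic torque is NOT added here; ``tau_total`` is the full torque
    applied at the ankle (the closed-loop simulator composes it from the
    controller and :func:`intrinsic_torque`).
    """
    if not 0 < dt <= 0.01:
        raise ValidationError(f"dt={dt} s must lie in (0, 0.01]")
    if not math.isfinite(tau_total):
        raise ValidationError("tau_total must be finite")
    th = state.theta * DEG
    om = state.theta_dot * DEG
    lin = plant.linearized

    def f(y0, y1):
        return y1, _accel(y0, tau_total, anthro, lin)

    k1 = f(th, om)
    k2 = f(th + 0.5 * dt * k1[0], om + 0.5 * dt * k1[1])
    k3 = f(th + 0.5 * dt * k2[0], om + 0.5 * dt * k2[1])
    k4 = f(th + dt * k3[0], om + dt * k3[1])
    th_new = th + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    om_new = om + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return replace(state, theta=th_new * RAD, theta_dot=om_new * RAD, t=state.t + dt)


def cop_from_motion(theta: float, theta_ddot: float, anthro: Anthropometry) -> float:
    """COP displacement (cm) from lean angle (deg) and angular accel (deg/s²).

    Linearized ZMP relation COP = L_COM*theta - (J_B/(m g))*theta_ddot with
    angles converted to radians.  Static case: COP equals the linearized COM
    ground projection.
    """
    th = theta * DEG
    thdd = theta_ddot * DEG
    cop_m = anthro.L_COM * th - (anthro.J_B / (anthro.mass * anthro.g)) * thdd
    return cop_m * 100.0
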