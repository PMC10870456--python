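"""Closed-loop simulation of one voluntary-lean trial.

The planner drives both controllers; the blended torque acts on the
inverted-pendulum plant; the linearized ZMP relation maps body motion to
COP.  Integration is fixed-step RK4 at dt = 1/1600 s (20 steps per output
sample), with the reference evaluated analytically on a half-step grid so
RK4 substages see exact mid-step values.  Output is downsampled to the
80 Hz force-plate rate.  Optional white measurement noise (cm) is added to
the emitted COP channels only -- the dynamics are noiseless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .control import DEFAULT_BLEND_DIRECTION, ControlGains, feedforward_torque
from .errors import SimulationDivergedError, ValidationError
from .plant import DEG, RAD, Anthropometry, PlantParams
from .planning import PlanningParams, TargetRecord
from .trial import COPTrial

DEFAULT_DT = 1.0 / 1600.0
DEFAULT_OUT_HZ = 80.0
DEFAULT_PREP_S = 5.0
DEFAULT_TAIL_S = 2.0
THETA_CAP_DEG = 45.0


@dataclass(frozen=True)
class SimConfig:
    """Numerical and protocol settings for one simulated trial."""

    prep_s: float = DEFAULT_PREP_S  # quiet stance before target onset
    tail_s: float = DEFAULT_TAIL_S  # settling time appended after the return
    dt: float = DEFAULT_DT
    out_hz: float = DEFAULT_OUT_HZ
    blend_direction: str = DEFAULT_BLEND_DIRECTION
    noise_sd_cm: float = 0.0
    seed: int | None = None
    theta_cap_deg: float = THETA_CAP_DEG

    def __post_init__(self):
        if not 0 < self.dt <= 0.01:
            raise ValidationError("SimConfig.dt must lie in (0, 0.01]")
        ratio = 1.0 / (self.out_hz * self.dt)
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                f"dt={self.dt} must divide the output period 1/{self.out_hz} s evenly"
            )
        if self.prep_s < 5.0:
            raise ValidationError("preparation must provide >= 5 s of baseline")
        if self.noise_sd_cm < 0:
            raise ValidationError("noise_sd_cm must be >= 0")

    @property
    def steps_per_sample(self) -> int:
        return round(1.0 / (self.out_hz * self.dt))


@dataclass
class SimResult:
    """A simulated trial plus the simulator's full-rate internal state."""

    trial: COPTrial
    t_fine: np.ndarray  # s, full integration grid
    theta_deg: np.ndarray
    omega_deg: np.ndarray
    acc_deg: np.ndarray
    cop_fine_cm: np.ndarray  # scalar COP along the task direction, noiseless
    cop_out_cm: np.ndarray  # scalar COP at out_hz, noiseless
    tau_fb: np.ndarray  # N·m, full grid
    tau_ff: np.ndarray  # unweighted feedforward torque
    tau_ais: np.ndarray
    tau_total: np.ndarray
    w_ff: np.ndarray
    w_fb: np.ndarray
    alpha: np.ndarray
    params: PlanningParams = None
    gains: ControlGains = None
    anthro: Anthropometry = None
    config: SimConfig = None


@njit(cache=False)
def _rk4_loop(th0, om0, n_steps, dt, theta_ref, dtheta_ref, tau_ff, w_ff, w_fb,
              kp, ki, ka, ba, mgl, J, linearized, theta_cap):
    """Fixed-step RK4 of the closed loop.  Reference arrays live on the
    half-step grid (2*n_steps + 1 points); gains are per-rad SI."""
    n = n_steps + 1
    theta = np.empty(n)
    omega = np.empty(n)
    acc = np.empty(n)
    tfb_out = np.empty(n)
    tais_out = np.empty(n)
    ttot_out = np.empty(n)
    th = th0
    om = om0
    diverged = -1
    for i in range(n):
        k = 2 * i
        # record torque decomposition and acceleration at the sample instant
        e = theta_ref[k] - th
        de = dtheta_ref[k] - om
        tfb = kp * e + ki * de
        tais = -(ka * th + ba * om)
        tau = w_ff[k] * tau_ff[k] + w_fb[k] * tfb + tais
        grav = th if linearized else math.sin(th)
        a = (mgl * grav + tau) / J
        theta[i] = th
        omega[i] = om
        acc[i] = a
        tfb_out[i] = tfb
        tais_out[i] = tais
        ttot_out[i] = tau
        if abs(th) > theta_cap:
            diverged = i
            for j in range(i + 1, n):
                theta[j] = th
                omega[j] = om
                acc[j] = a
                tfb_out[j] = tfb
                tais_out[j] = tais
                ttot_out[j] = tau
            break
        if i == n_steps:
            break
        # RK4 stages; stage s uses half-grid index k (start), k+1 (mid), k+2 (end)
        k1t = om
        k1o = a
        th2 = th + 0.5 * dt * k1t
        om2 = om + 0.5 * dt * k1o
        e = theta_ref[k + 1] - th2
        de = dtheta_ref[k + 1] - om2
        tau = w_ff[k + 1] * tau_ff[k + 1] + w_fb[k + 1] * (kp * e + ki * de) - (ka * th2 + ba * om2)
        grav = th2 if linearized else math.sin(th2)
        k2t = om2
        k2o = (mgl * grav + tau) / J
        th3 = th + 0.5 * dt * k2t
        om3 = om + 0.5 * dt * k2o
        e = theta_ref[k + 1] - th3
        de = dtheta_ref[k + 1] - om3
        tau = w_ff[k + 1] * tau_ff[k + 1] + w_fb[k + 1] * (kp * e + ki * de) - (ka * th3 + ba * om3)
        grav = th3 if linearized else math.sin(th3)
        k3t = om3
        k3o = (mgl * grav + tau) / J
        th4 = th + dt * k3t
        om4 = om + dt * k3o
        e = theta_ref[k + 2] - th4
        de = dtheta_ref[k + 2] - om4
        tau = w_ff[k + 2] * tau_ff[k + 2] + w_fb[k + 2] * (kp * e + ki * de) - (ka * th4 + ba * om4)
        grav = th4 if linearized else math.sin(th4)
        k4t = om4
        k4o = (mgl * grav + tau) / J
        th = th + dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
        om = om + dt / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o)
    return theta, omega, acc, tfb_out, tais_out, ttot_out, diverged


def _blend_weight_arrays(t_rel, params: PlanningParams, blend_direction: str):
    alpha = np.clip((t_rel - params.t_r) / params.t_APA, 0.0, 1.0)
    in_window = (t_rel > params.t_r) & (t_rel < params.t_r + params.t_APA)
    if blend_direction == "printed":
        w_ff = np.where(in_window, alpha, 0.0)
    elif blend_direction == "narrative":
        w_ff = np.where(in_window, 1.0 - alpha, 0.0)
    else:
        raise ValidationError(f"unknown blend_direction {blend_direction!r}")
    w_fb = np.where(in_window, 1.0 - w_ff, 1.0)
    return w_ff, w_fb, alpha


def simulate_trial(
    anthro: Anthropometry,
    plant: PlantParams,
    params: PlanningParams,
    gains: ControlGains,
    target: TargetRecord | None = None,
    config: SimConfig = SimConfig(),
    metadata: dict | None = None,
) -> SimResult:
    """Run the closed loop and emit an 80 Hz COP trial.

    ``target`` fixes the planar direction and target id of the output; when
    omitted the lean is emitted along +AP with target id 1.  Deterministic
    given config (noise uses the explicit seed).
    """
    plant.validate_subcritical(anthro)
    gains.validate_stable(anthro, plant)

    spo = config.steps_per_sample
    duration = config.prep_s + params.t_r + params.t_f + params.hold + params.t_b + config.tail_s
    n_out = int(math.ceil(duration * config.out_hz)) + 1
    n_steps = (n_out - 1) * spo

    # half-step grid, clock relative to target onset
    t_half = np.arange(2 * n_steps + 1) * (config.dt / 2.0) - config.prep_s
    th_ref, dth_ref, ddth_ref = (np.asarray(a) for a in _plan_ref_clamped(params, t_half))
    tau_ff_half = feedforward_torque(gains.K_FF, anthro, th_ref, ddth_ref)
    w_ff_half, w_fb_half, alpha_half = _blend_weight_arrays(t_half, params, config.blend_direction)

    theta, omega, acc, tfb, tais, ttot, div = _rk4_loop(
        params.theta_0 * DEG,
        0.0,
        n_steps,
        config.dt,
        th_ref * DEG,
        dth_ref * DEG,
        tau_ff_half,
        w_ff_half,
        w_fb_half,
        gains.K_P * RAD,
        gains.K_I * RAD,
        plant.K_A * RAD,
        plant.B_A * RAD,
        anthro.mgl,
        anthro.J_B,
        plant.linearized,
        config.theta_cap_deg * DEG,
    )
    if div >= 0:
        raise SimulationDivergedError(
            f"closed loop diverged (|theta| > {config.theta_cap_deg} deg) at "
            f"t={div * config.dt - config.prep_s:.3f} s after onset with "
            f"K_P={gains.K_P}, K_FF={gains.K_FF}",
            k_p=gains.K_P,
            k_ff=gains.K_FF,
            t=div * config.dt,
        )

    cop_fine = (anthro.L_COM * theta - (anthro.J_B / (anthro.mass * anthro.g)) * acc) * 100.0
    cop_out = cop_fine[::spo].copy()
    t_out = np.arange(n_out) / config.out_hz

    if target is None:
        u_ap, u_ml = 1.0, 0.0
        target_id = 1
    else:
        u_ap, u_ml = target.unit_vector
        target_id = target.target_id

    cop_ap = cop_out * u_ap
    cop_ml = cop_out * u_ml
    if config.noise_sd_cm > 0:
        rng = np.random.default_rng(config.seed)
        cop_ap = cop_ap + rng.normal(0.0, config.noise_sd_cm, n_out)
        cop_ml = cop_ml + rng.normal(0.0, config.noise_sd_cm, n_out)

    meta = dict(metadata or {})
    meta.setdefault("sampling_hz", config.out_hz)
    trial = COPTrial(
        time=t_out,
        cop_ap=cop_ap,
        cop_ml=cop_ml,
        target_onset=config.prep_s,
        target_id=target_id,
        sampling_hz=config.out_hz,
        metadata=meta,
    )
    full = slice(None, None, 2)
    return SimResult(
        trial=trial,
        t_fine=t_half[full] + config.prep_s,
        theta_deg=theta * RAD,
        omega_deg=omega * RAD,
        acc_deg=acc * RAD,
        cop_fine_cm=cop_fine,
        cop_out_cm=cop_out,
        tau_fb=tfb,
        tau_ff=tau_ff_half[full],
        tau_ais=tais,
        tau_total=ttot,
        w_ff=w_ff_half[full],
        w_fb=w_fb_half[full],
        alpha=alpha_half[full],
        params=params,
        gains=gains,
        anthro=anthro,
        config=config,
    )


def _plan_ref_clamped(params: PlanningParams, t_rel):
    """Planner output with the pre-onset phase clamped to theta_0."""
    from .planning import plan_reference

    th, dth, ddth = plan_reference(params, np.maximum(t_rel, 0.0))
    return th, dth, ddth
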