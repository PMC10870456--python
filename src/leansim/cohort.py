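"""Synthetic cohort generation emulating the study population.

Two groups (Parkinson's disease and age-matched healthy adults, 24 each in
the study) lean toward 8 targets, 4 repetitions per target.  Per-direction
group means of the temporal parameters and control gains reproduce the
published group tables; between-subject spread is not published and is
modelled as truncated normals with a configurable coefficient of variation
(default 15%).  Clinical scores (UPDRS, FRT -- measured in the patient
group only) are generated through a Gaussian copula against subject-level
gain factors so the downstream rank correlations have the configured sign
and strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .control import ControlGains, min_stable_kp
from .errors import ValidationError
from .identify import DEFAULT_KFF_BOUNDS, DEFAULT_KP_BOUNDS, STABILITY_MARGIN
from .plant import Anthropometry, PlantParams, default_plant, derive_anthropometry
from .planning import PlanningParams, TargetLayout, target_layout, theta_target_from_distance
from .simulate import SimConfig, simulate_trial
from .trial import COPTrial

DIRECTIONS = tuple(range(1, 9))

# Published per-direction group means (targets T1..T8).
GROUP_MEANS = {
    "PD": {
        "t_r": (0.9, 0.88, 0.93, 0.92, 1.05, 1.48, 1.38, 1.25),
        "t_APA": (0.36, 0.38, 0.36, 0.41, 0.33, 0.53, 0.45, 0.35),
        "t_f": (2.50, 2.83, 2.61, 2.05, 2.60, 3.07, 2.71, 2.84),
        "t_b": (2.34, 2.85, 2.95, 2.6, 2.67, 2.80, 2.76, 2.19),
        "t_total": (5.74, 6.57, 6.61, 5.59, 6.31, 7.35, 6.86, 5.95),
        "apa_size": (0.63, 0.52, 0.71, 0.67, 0.54, 0.51, 0.49, 0.38),
        "lean_max": (4.32, 4.49, 4.51, 4.69, 4.46, 4.11, 3.988, 2.60),
        "K_P": (61.73, 86.20, 81.27, 91.30, 99.32, 103.01, 105.93, 104.60),
        "K_FF": (4.16, 4.09, 5.18, 4.90, 4.12, 4.57, 4.56, 5.14),
    },
    "H": {
        "t_r": (0.35, 0.35, 0.4, 0.41, 0.32, 0.3, 0.34, 0.53),
        "t_APA": (0.46, 0.48, 0.58, 0.52, 0.43, 0.60, 0.50, 0.49),
        "t_f": (2.00, 2.14, 1.91, 2.08, 1.90, 2.25, 2.60, 2.01),
        "t_b": (1.51, 1.46, 1.74, 1.51, 1.50, 1.48, 1.59, 1.49),
        "t_total": (3.88, 3.95, 4.06, 4.00, 3.73, 4.02, 4.53, 4.04),
        "apa_size": (1.58, 1.46, 1.42, 1.59, 1.59, 1.55, 1.42, 1.07),
        "lean_max": (5.00, 6.14, 6.46, 6.73, 6.68, 6.25, 6.34, 4.25),
        "K_P": (42.40, 33.08, 29.80, 33.90, 30.30, 29.22, 30.81, 51.20),
        "K_FF": (14.95, 14.88, 15.64, 14.80, 15.10, 15.34, 14.72, 17.8),
    },
}

# Demography: (mean, SD) per group.
DEMOGRAPHY = {
    "PD": {"age": (61.5, 9.6), "height_cm": (164.5, 8.4), "mass": (68.5, 11.5)},
    "H": {"age": (54.9, 7.4), "height_cm": (175.6, 8.8), "mass": (77.28, 12.7)},
}

# Clinical scores, patient group only: (mean, SD).
CLINICAL = {"UPDRS": (26.14, 4.4), "FRT": (31.5, 10.2)}


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings; the defaults ARE the study conditions."""

    n_per_group: int = 24
    cv: float = 0.15  # between-subject coefficient of variation
    seed: int = 0
    within_subject_corr: float = 0.7  # share of a gain's spread from a subject factor
    rho_kp_updrs: float = 0.6
    rho_kp_frt: float = -0.6
    rho_kff_updrs: float = -0.6
    rho_kff_frt: float = 0.0
    groups: tuple[str, ...] = ("PD", "H")
    directions: tuple[int, ...] = DIRECTIONS

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        for name in ("within_subject_corr", "rho_kp_updrs", "rho_kp_frt",
                     "rho_kff_updrs", "rho_kff_frt"):
            if abs(getattr(self, name)) > 1:
                raise ValidationError(f"{name} must have magnitude <= 1")
        bad = set(self.directions) - set(DIRECTIONS)
        if bad:
            raise ValidationError(f"unknown directions {sorted(bad)}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    anthro: Anthropometry
    plant: PlantParams
    age: float
    clinical: dict  # UPDRS/FRT (NaN for healthy)
    params: dict[int, PlanningParams]  # per direction
    gains: dict[int, ControlGains]  # per direction


def _trunc_draw(rng, mean, sd, lo, hi, size=None):
    """Truncated-normal draw; degenerate SD returns the (clipped) mean."""
    if hi <= lo:
        raise ValidationError(f"infeasible truncation bounds [{lo}, {hi}]")
    if sd <= 0:
        val = np.clip(mean, lo, hi)
        return np.full(size, val) if size is not None else float(val)
    if (lo - mean) / sd > 6 or (hi - mean) / sd < -6:
        raise ValidationError(
            f"truncation [{lo}, {hi}] excludes mean {mean} +/- 6 SD"
        )
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draw = truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return draw if size is not None else float(draw)


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[SubjectRecord]:
    """Draw a full two-group cohort; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    w = spec.within_subject_corr
    w_resid = math.sqrt(max(1.0 - w * w, 0.0))
    for group in spec.groups:
        demo = DEMOGRAPHY[group]
        means = GROUP_MEANS[group]
        for i in range(spec.n_per_group):
            height = _trunc_draw(rng, demo["height_cm"][0] / 100, demo["height_cm"][1] / 100, 1.2, 2.2)
            mass = _trunc_draw(rng, demo["mass"][0], demo["mass"][1], 30.0, 150.0)
            age = _trunc_draw(rng, demo["age"][0], demo["age"][1], 18.0, 95.0)
            anthro = derive_anthropometry(height=height, mass=mass)
            plant = default_plant(anthro)
            kp_floor = max(
                DEFAULT_KP_BOUNDS[0], min_stable_kp(anthro, plant) * STABILITY_MARGIN
            )

            z_kp = rng.standard_normal()
            z_kff = rng.standard_normal()
            params = {}
            gains = {}
            for d in spec.directions:
                j = d - 1
                t_f = _trunc_draw(rng, means["t_f"][j], spec.cv * means["t_f"][j], 0.3, 10.0)
                t_apa_mean = means["t_APA"][j]
                t_apa = _trunc_draw(
                    rng, t_apa_mean, spec.cv * t_apa_mean, 0.05, min(t_f, 2.0)
                )
                params[d] = PlanningParams(
                    t_r=_trunc_draw(rng, means["t_r"][j], spec.cv * means["t_r"][j], 0.05, 5.0),
                    t_f=t_f,
                    t_b=_trunc_draw(rng, means["t_b"][j], spec.cv * means["t_b"][j], 0.3, 10.0),
                    t_APA=t_apa,
                )
                kp_mean, kff_mean = means["K_P"][j], means["K_FF"][j]
                z1 = w * z_kp + w_resid * rng.standard_normal()
                z2 = w * z_kff + w_resid * rng.standard_normal()
                kp = np.clip(
                    kp_mean + spec.cv * kp_mean * z1, kp_floor, DEFAULT_KP_BOUNDS[1]
                )
                kff = np.clip(
                    kff_mean + spec.cv * kff_mean * z2, *DEFAULT_KFF_BOUNDS
                )
                gains[d] = ControlGains(K_P=float(kp), K_FF=float(kff))

            clinical = {"UPDRS": math.nan, "FRT": math.nan}
            if group == "PD":
                # Gaussian copula against the subject-level gain factors.
                for score, (rho1, rho2) in {
                    "UPDRS": (spec.rho_kp_updrs, spec.rho_kff_updrs),
                    "FRT": (spec.rho_kp_frt, spec.rho_kff_frt),
                }.items():
                    resid = math.sqrt(max(1.0 - rho1**2 - rho2**2, 0.0))
                    z = rho1 * z_kp + rho2 * z_kff + resid * rng.standard_normal()
                    mean, sd = CLINICAL[score]
                    clinical[score] = max(mean + sd * z, 0.0)

            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}{i + 1:03d}",
                    group=group,
                    anthro=anthro,
                    plant=plant,
                    age=age,
                    clinical=clinical,
                    params=params,
                    gains=gains,
                )
            )
    return subjects


def generate_trials(
    subject: SubjectRecord,
    layout: TargetLayout | None = None,
    noise_sd_cm: float = 0.05,
    seed: int = 0,
    repetitions: int = 4,
    sim_config: SimConfig = SimConfig(),
    directions: tuple[int, ...] | None = None,
) -> list[COPTrial]:
    """Forward-simulate every target x repetition for one subject.

    Measurement noise is seeded per trial (spawned deterministically from
    ``seed``); noise SD 0 makes repetitions identical.
    """
    if layout is None:
        layout = target_layout(subject.anthro.L_COM)
    directions = directions or tuple(sorted(subject.params))
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(directions) * repetitions
    )
    trials = []
    k = 0
    for d in directions:
        rec = layout[d]
        theta_f = theta_target_from_distance(rec.distance, layout.H_CoM)
        params = replace(subject.params[d], theta_f=theta_f)
        for rep in range(repetitions):
            cfg = replace(
                sim_config, noise_sd_cm=noise_sd_cm, seed=int(child_seeds[k] % 2**31)
            )
            k += 1
            res = simulate_trial(
                subject.anthro,
                subject.plant,
                params,
                subject.gains[d],
                target=rec,
                config=cfg,
                metadata={
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "repetition": rep + 1,
                    "synthetic": True,
                    "true_K_P": subject.gains[d].K_P,
                    "true_K_FF": subject.gains[d].K_FF,
                    "true_t_r": params.t_r,
                    "true_t_f": params.t_f,
                    "true_t_b": params.t_b,
                    "true_t_APA": params.t_APA,
                    "true_theta_f": theta_f,
                },
            )
            trials.append(res.trial)
    return trials


def cohort_gain_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format table of per-subject, per-direction generated parameters."""
    rows = []
    for s in subjects:
        for d, g in s.gains.items():
            p = s.params[d]
            rows.append(
                {
                    "subject": s.subject_id,
                    "group": s.group,
                    "target_id": d,
                    "K_P": g.K_P,
                    "K_FF": g.K_FF,
                    "t_r": p.t_r,
                    "t_APA": p.t_APA,
                    "t_f": p.t_f,
                    "t_b": p.t_b,
                    "UPDRS": s.clinical["UPDRS"],
                    "FRT": s.clinical["FRT"],
                }
            )
    return pd.DataFrame(rows)
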