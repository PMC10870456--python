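"""Shared fixtures: group-mean subjects and cached noiseless simulations."""

from __future__ import annotations

import pytest

from leansim import (
    ControlGains,
    PlanningParams,
    default_plant,
    derive_anthropometry,
    simulate_trial,
    target_layout,
    theta_target_from_distance,
)

# Group-mean subjects (healthy / patient) and their target-1 task.


@pytest.fixture(scope="session")
def healthy_anthro():
    return derive_anthropometry(height=1.756, mass=77.28)


@pytest.fixture(scope="session")
def healthy_plant(healthy_anthro):
    return default_plant(healthy_anthro)


@pytest.fixture(scope="session")
def healthy_layout(healthy_anthro):
    return target_layout(healthy_anthro.L_COM)


@pytest.fixture(scope="session")
def healthy_params_t1(healthy_layout):
    theta_f = theta_target_from_distance(
        healthy_layout[1].distance, healthy_layout.H_CoM
    )
    return PlanningParams(t_r=0.35, t_f=2.00, t_b=1.51, t_APA=0.46, theta_f=theta_f)


@pytest.fixture(scope="session")
def healthy_gains():
    return ControlGains(K_P=42.40, K_FF=14.95)


@pytest.fixture(scope="session")
def pd_anthro():
    return derive_anthropometry(height=1.645, mass=68.5)


@pytest.fixture(scope="session")
def pd_plant(pd_anthro):
    return default_plant(pd_anthro)


@pytest.fixture(scope="session")
def pd_layout(pd_anthro):
    return target_layout(pd_anthro.L_COM)


@pytest.fixture(scope="session")
def pd_params_t1(pd_layout):
    theta_f = theta_target_from_distance(pd_layout[1].distance, pd_layout.H_CoM)
    return PlanningParams(t_r=0.90, t_f=2.50, t_b=2.34, t_APA=0.36, theta_f=theta_f)


@pytest.fixture(scope="session")
def pd_gains():
    return ControlGains(K_P=61.73, K_FF=4.16)


@pytest.fixture(scope="session")
def healthy_sim(healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains, healthy_layout):
    """Noiseless healthy group-mean trial toward target 1 (cached)."""
    return simulate_trial(
        healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains,
        target=healthy_layout[1],
    )


@pytest.fixture(scope="session")
def pd_sim(pd_anthro, pd_plant, pd_params_t1, pd_gains, pd_layout):
    """Noiseless patient group-mean trial toward target 1 (cached)."""
    return simulate_trial(
        pd_anthro, pd_plant, pd_params_t1, pd_gains, target=pd_layout[1]
    )
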