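import numpy as np
import pytest

import oligocea as o
from oligocea.params import model_config_from_dict
from oligocea.survival import ProbSchedule


@pytest.fixture(scope="session")
def reference():
    """Packaged reference model plus its seeded synthetic trial curves."""
    return o.make_reference_config()


def flat_schedule(p, n_cycles, sd=0.0, cycle_length=3.0, endpoint="OS", arm="arm"):
    """Schedule with constant per-cycle probability (and sd)."""
    return ProbSchedule(
        endpoint=endpoint, arm=arm, cycle_length=cycle_length,
        means=np.full(n_cycles, float(p)), sds=np.full(n_cycles, float(sd)),
        observed_horizon=n_cycles * cycle_length,
    )


def _toy_arm(name, uncertain):
    """Three-state arm: Alive -> Progression -> Death."""
    def est(mean, sd0, family):
        return {"mean": mean, "sd": sd0 if uncertain else 0.0} | (
            {"family": family} if uncertain else {})

    return {
        "name": name,
        "initial_state": "Alive",
        "states": [
            {"name": "Alive", "progression_from_pfs": True,
             "cost": est(1000.0, 250.0, "gamma"),
             "utility": est(0.8, 0.08, "beta")},
            {"name": "Progression",
             "cost": est(2000.0, 500.0, "gamma"),
             "utility": est(0.5, 0.05, "beta")},
            {"name": "Death", "absorbing": True},
        ],
    }


def toy_config_dict(uncertain=False, twin=False):
    """Minimal two-arm configuration for engine and PSA contract tests.

    ``twin=True`` gives both arms the same label and structure, so every
    parameter and schedule draw is shared and increments must vanish.
    """
    label_i = "Arm" if twin else "New"
    label_c = "Arm" if twin else "Std"
    return {
        "settings": {
            "cycle_length_months": 3, "horizon_years": 5,
            "discount_rate": 0.015, "psa_iterations": 100, "seed": 7,
            "wtp_grid": {"start": 0, "stop": 100000, "step": 10000},
        },
        "arms": {
            "intervention": _toy_arm(label_i, uncertain),
            "comparator": _toy_arm(label_c, uncertain),
        },
    }


@pytest.fixture
def toy_config():
    return model_config_from_dict(toy_config_dict(uncertain=False))


@pytest.fixture
def toy_config_uncertain():
    return model_config_from_dict(toy_config_dict(uncertain=True))


@pytest.fixture
def twin_config_uncertain():
    return model_config_from_dict(toy_config_dict(uncertain=True, twin=True))


def toy_schedules(config, p_death_i=0.05, p_pfs_i=0.12, p_death_c=0.08,
                  p_pfs_c=0.20, sd=0.0):
    n = config.settings.n_cycles
    c = config.settings.cycle_length
    return {
        "intervention": {
            "os": flat_schedule(p_death_i, n, sd, c, "OS", config.intervention.name),
            "pfs": flat_schedule(p_pfs_i, n, sd, c, "PFS", config.intervention.name),
        },
        "comparator": {
            "os": flat_schedule(p_death_c, n, sd, c, "OS", config.comparator.name),
            "pfs": flat_schedule(p_pfs_c, n, sd, c, "PFS", config.comparator.name),
        },
    }
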