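import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def cheap_cohort():
    """Small fast cohort (level-0 planners, deterministic choices)."""
    from trustgame.cohort import CohortConfig, generate_cohort
    cfg = CohortConfig(n_subjects=40, seed=7, tom_values=(0,), tom_probs=(1.0,),
                       plan_values=(1,), plan_probs=(1.0,), beta_values=(1.0,),
                       awareness_values=(2,))
    return generate_cohort(cfg)


@pytest.fixture()
def example_pairs():
    """Mixed 10-round game: generous, fair and unfair trustee actions."""
    return [(10, 10.0), (15, 22.5), (20, 30.0), (20, 10.0), (5, 2.5),
            (0, 0.0), (10, 5.0), (15, 15.0), (20, 40.0), (10, 15.0)]


@pytest.fixture()
def example_traj(example_pairs):
    from trustgame.game import GameTrajectory
    return GameTrajectory.from_actions("sub01", "T1", example_pairs)
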