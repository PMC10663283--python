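import numpy as np
import pytest

from actspace import (ChainConfig, HMatrix, PolytopeSpec, TaskSpec,
                      build_task_wrenches, build_trajectory_polytope,
                      generate_synthetic_h, hit_and_run, make_planar_toy)


def box_spec(n, labels=None):
    """The unit box [0,1]^n with no equality or inequality rows."""
    labels = labels or tuple((f"m{i + 1}", 0) for i in range(n))
    return PolytopeSpec(
        eq_matrix=np.zeros((0, n)), eq_rhs=np.zeros(0),
        ineq_matrix=np.zeros((0, n)), ineq_rhs=np.zeros(0),
        lower=np.zeros(n), upper=np.ones(n), var_labels=labels,
    )


@pytest.fixture(scope="session")
def toy():
    """Analytic planar fixture: H=[[1,1]], constant unit wrench."""
    return make_planar_toy()


@pytest.fixture(scope="session")
def segment_spec(toy):
    from actspace import build_moment_polytope
    model, _ = toy
    return build_moment_polytope(model, [1.0])


@pytest.fixture(scope="session")
def square_spec():
    return box_spec(2)


@pytest.fixture(scope="session")
def cube_spec():
    return box_spec(3)


@pytest.fixture(scope="session")
def triangle_spec():
    """{x >= 0, y >= 0, x + y <= 1}: full-dimensional in the plane."""
    return PolytopeSpec(
        eq_matrix=np.zeros((0, 2)), eq_rhs=np.zeros(0),
        ineq_matrix=np.array([[1.0, 1.0]]), ineq_rhs=np.array([1.0]),
        lower=np.zeros(2), upper=np.ones(2),
        var_labels=(("m1", 0), ("m2", 0)),
    )


@pytest.fixture(scope="session")
def simplex3_spec():
    """Four activations summing to 2 inside the box: a 3-D chart fixture."""
    return PolytopeSpec(
        eq_matrix=np.ones((1, 4)), eq_rhs=np.array([2.0]),
        ineq_matrix=np.zeros((0, 4)), ineq_rhs=np.zeros(0),
        lower=np.zeros(4), upper=np.ones(4),
        var_labels=tuple((f"m{i + 1}", 0) for i in range(4)),
    )


@pytest.fixture(scope="session")
def synth_model():
    """A 7-muscle, 4-wrench synthetic model feasible for the default task."""
    return generate_synthetic_h(7, 4, rng_seed=11)


@pytest.fixture(scope="session")
def default_task():
    return TaskSpec()


@pytest.fixture(scope="session")
def synth_seq(synth_model, default_task):
    return build_task_wrenches(default_task, synth_model)


@pytest.fixture(scope="session")
def traj_spec_012(synth_model, synth_seq):
    return build_trajectory_polytope(synth_model, synth_seq, 0.12)


@pytest.fixture(scope="session")
def unseeded_store_012(traj_spec_012):
    """A modest unseeded run at delta=0.12, reused across analysis tests."""
    return hit_and_run(
        traj_spec_012,
        ChainConfig(n_samples=600, burn_in=500, thin=5, rng_seed=101),
        extra_meta={"delta": 0.12, "stage": "unseeded"},
    )
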