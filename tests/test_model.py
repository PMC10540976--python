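"""Architecture, constraints, scaling and parameter bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnn.model import (
    Dataset,
    Dimensions,
    ExperimentalCondition,
    MiRNN,
    MiRNNParams,
    ScalingTransform,
    Trajectory,
    count_params,
    fit_scaling,
    init_params,
    LEAKY_SLOPE,
)


@pytest.mark.parametrize(
    "dims, expected",
    [
        # 25 gut species + 4 metabolites, 16 hidden units, no controls
        (Dimensions(n_s=25, n_m=4, n_u=0, n_h=16), 1245),
        # one scalar per parameter block
        (Dimensions(n_s=1, n_m=0, n_u=0, n_h=1), 6),
        # 9 + 3 + 15 + 9 + 3 + 3, cross-checked by flattening the record
        (Dimensions(n_s=2, n_m=1, n_u=1, n_h=3), 42),
    ],
)
def test_count_params(dims, expected):
    assert count_params(dims) == expected
    assert init_params(dims, 0).flatten().shape == (expected,)


def test_flatten_unflatten_roundtrip(small_dims, small_params):
    theta = small_params.flatten()
    again = MiRNNParams.unflatten(theta, small_dims).flatten()
    assert np.array_equal(theta, again)
    with pytest.raises(ValueError):
        MiRNNParams.unflatten(theta[:-1], small_dims)


def test_dimension_validation():
    with pytest.raises(ValueError):
        Dimensions(n_s=0)
    with pytest.raises(ValueError):
        Dimensions(n_s=1, n_h=0)
    with pytest.raises(ValueError):
        Dimensions(n_s=1, n_m=-1)


def test_step_matches_scalar_oracle(small_dims, small_params, small_model):
    """One step equals a hand-rolled scalar-loop computation."""
    from mirnn.model import CommunityState

    rng = np.random.default_rng(0)
    s = np.array([0.3, 0.0])
    m = np.array([0.5])
    h = rng.normal(size=small_dims.n_h)
    u_prev, u_curr = np.array([0.2]), np.array([0.7])
    state = CommunityState(s=s, m=m, h=h)
    out = small_model.step(small_params, state, u_prev, u_curr, mode="inference")

    # scalar loops
    p = small_params
    x = np.concatenate([s, m, u_prev, u_curr])
    pre = np.zeros(small_dims.n_h)
    for j in range(small_dims.n_h):
        acc = p.b_hh[j]
        for i in range(small_dims.n_h):
            acc += h[i] * p.W_hh[i, j]
        for k in range(len(x)):
            acc += x[k] * p.W_ih[k, j]
        pre[j] = acc
    h_new = np.array([v if v > 0 else LEAKY_SLOPE * v for v in pre])
    o = np.zeros(small_dims.n_y)
    for l in range(small_dims.n_y):
        acc = p.b_ho[l]
        for j in range(small_dims.n_h):
            acc += h_new[j] * p.W_ho[j, l]
        o[l] = acc
    s_exp = np.array([o[0] * (s[0] > 0), o[1] * (s[1] > 0)])
    s_exp = np.maximum(s_exp, 0.0)
    m_exp = np.maximum(o[2:], 0.0)
    assert np.allclose(out.h, h_new, atol=1e-14)
    assert np.allclose(out.s, s_exp, atol=1e-14)
    assert np.allclose(out.m, m_exp, atol=1e-14)


def test_step_absent_species_and_zero_params(small_dims, small_model):
    from mirnn.model import CommunityState

    # absent species output exactly zero regardless of parameters
    params = init_params(small_dims, 11)
    state = CommunityState(s=np.zeros(2), m=np.array([0.5]), h=np.ones(3))
    out = small_model.step(params, state, [0.1], [0.2], mode="training")
    assert np.all(out.s == 0.0)
    # all-zero parameters, inference mode: everything is exactly zero
    zero = MiRNNParams.unflatten(np.zeros(count_params(small_dims)), small_dims)
    state = CommunityState(s=np.array([0.5, 0.5]), m=np.array([0.5]), h=np.zeros(3))
    out = small_model.step(zero, state, [1.0], [1.0], mode="inference")
    assert np.all(out.s == 0.0) and np.all(out.m == 0.0) and np.all(out.h == 0.0)


def test_step_errors(small_dims, small_params, small_model):
    from mirnn.model import CommunityState

    with pytest.raises(ValueError):
        small_model.step(
            small_params,
            CommunityState(s=np.zeros(3), m=np.zeros(1), h=np.zeros(3)),
            [0.0],
            [0.0],
        )
    with pytest.raises(FloatingPointError):
        small_model.step(
            small_params,
            CommunityState(s=np.array([np.nan, 0.0]), m=np.zeros(1), h=np.zeros(3)),
            [0.0],
            [0.0],
        )
    with pytest.raises(ValueError):
        small_model.step(
            small_params,
            CommunityState(s=np.zeros(2), m=np.zeros(1), h=np.zeros(3)),
            [0.0],
            [0.0],
            mode="banana",
        )


def test_trajectory_constraint_and_nonnegativity(small_dims, small_condition):
    """Absent species stay exactly absent; inference outputs are non-negative."""
    model = MiRNN(small_dims)
    cond = ExperimentalCondition(
        s0=np.array([0.8, 0.0]),
        m0=small_condition.m0,
        controls=small_condition.controls,
        times=small_condition.times,
    )
    for seed in range(5):
        params = init_params(small_dims, seed)
        for mode in ("training", "inference"):
            traj = model.predict_trajectory(params, cond, mode=mode)
            assert np.all(traj.values[:, 1] == 0.0)  # exact, not approximate
        traj = model.predict_trajectory(params, cond, mode="inference")
        assert np.all(traj.values >= 0.0)


def test_single_step_rollout_equals_step(small_dims, small_params, small_model):
    from mirnn.model import CommunityState

    cond = ExperimentalCondition(
        s0=[0.4, 0.2], m0=[0.1], controls=np.array([[0.3], [0.9]]), times=[0.0, 1.0]
    )
    traj = small_model.predict_trajectory(small_params, cond, mode="inference")
    state = CommunityState(
        s=np.asarray(cond.s0), m=np.asarray(cond.m0), h=small_params.h_0.copy()
    )
    out = small_model.step(small_params, state, [0.3], [0.9], mode="inference")
    assert np.allclose(traj.values[1], np.concatenate([out.s, out.m]))


def test_inference_rollout_equals_chained_steps(small_dims, small_params, small_condition):
    """Autoregressive rollout is exactly n_tau chained step evaluations."""
    from mirnn.model import CommunityState

    model = MiRNN(small_dims)
    traj = model.predict_trajectory(small_params, small_condition, mode="inference")
    state = CommunityState(
        s=np.asarray(small_condition.s0, dtype=float),
        m=np.asarray(small_condition.m0, dtype=float),
        h=small_params.h_0.copy(),
    )
    for t in range(1, small_condition.n_tau + 1):
        state = model.step(
            small_params,
            state,
            small_condition.controls[t - 1],
            small_condition.controls[t],
            mode="inference",
        )
        assert np.allclose(traj.values[t], np.concatenate([state.s, state.m]), atol=1e-14)


def test_unconstrained_agrees_when_all_species_positive(small_dims, small_condition):
    """With every species strictly positive along the trajectory, the
    constrained and unconstrained models coincide exactly."""
    params = init_params(small_dims, 2)
    # shrink weights and bias outputs upward so predictions stay strictly positive
    params.W_hh *= 0.1
    params.W_ih *= 0.1
    params.W_ho *= 0.1
    params.b_ho[:] = 0.5
    con = MiRNN(small_dims, constrained=True)
    unc = MiRNN(small_dims, constrained=False)
    t1 = con.predict_trajectory(params, small_condition, mode="inference")
    t2 = unc.predict_trajectory(params, small_condition, mode="inference")
    assert np.all(t1.values[1:, :2] > 0)
    assert np.array_equal(t1.values, t2.values)


def test_batch_rollout_matches_single(small_dims, small_params):
    rng = np.random.default_rng(4)
    model = MiRNN(small_dims)
    conds = [
        ExperimentalCondition(
            s0=rng.uniform(0, 1, 2) * (rng.random(2) > 0.4),
            m0=rng.uniform(0, 1, 1),
            controls=rng.uniform(0, 1, (4, 1)),
            times=np.arange(4.0),
        )
        for _ in range(6)
    ]
    for mode in ("training", "inference"):
        batch = model.predict_batch(small_params, conds, mode=mode)
        for i, c in enumerate(conds):
            single = model.predict_trajectory(small_params, c, mode=mode).values
            assert np.allclose(batch[i], single, atol=1e-14)


def test_jacobian_matches_finite_differences(small_dims, small_params, small_condition):
    """Exact forward-mode Jacobian agrees with central finite differences."""
    model = MiRNN(small_dims)
    theta = small_params.flatten()
    values, jac = model.rollout_with_jacobian(small_params, small_condition, "training")
    eps = 1e-6
    for k in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        vp = model.predict_trajectory(
            MiRNNParams.unflatten(tp, small_dims), small_condition, "training"
        ).values[1:]
        vm = model.predict_trajectory(
            MiRNNParams.unflatten(tm, small_dims), small_condition, "training"
        ).values[1:]
        fd = (vp - vm) / (2 * eps)
        assert np.allclose(jac[:, :, k], fd, atol=1e-4, rtol=1e-4)


def test_batch_jacobian_matches_single(small_dims, small_params):
    rng = np.random.default_rng(9)
    model = MiRNN(small_dims)
    conds = [
        ExperimentalCondition(
            s0=rng.uniform(0, 1, 2) * (rng.random(2) > 0.4),
            m0=rng.uniform(0, 1, 1),
            controls=rng.uniform(0, 1, (4, 1)),
            times=np.arange(4.0),
        )
        for _ in range(5)
    ]
    for mode in ("training", "inference"):
        vb, jb = model.rollout_with_jacobian_batch(small_params, conds, mode)
        for i, c in enumerate(conds):
            v1, j1 = model.rollout_with_jacobian(small_params, c, mode)
            assert np.allclose(vb[i], v1, atol=1e-13)
            assert np.allclose(jb[i], j1, atol=1e-13)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def _toy_dataset():
    conds = []
    rng = np.random.default_rng(5)
    trajs = []
    for i in range(3):
        c = ExperimentalCondition(
            s0=[1.0, 0.0], m0=[0.5], controls=rng.uniform(0, 2, (3, 1)),
            times=[0, 1, 2], condition_id=f"c{i}",
        )
        values = rng.uniform(0, 4, (3, 3))
        values[:, 1] = 0.0  # an all-zero feature
        trajs.append(Trajectory(c, values))
    return Dataset(trajs)


def test_fit_scaling_maxima_match_brute_force():
    ds = _toy_dataset()
    tf = fit_scaling(ds)
    stacked = np.vstack([tr.values for tr in ds])
    assert np.array_equal(tf.max_values, stacked.max(axis=0))
    us = np.vstack([tr.condition.controls for tr in ds])
    assert np.array_equal(tf.control_max, np.abs(us).max(axis=0))


def test_scaling_zero_preservation_and_inverse():
    ds = _toy_dataset()
    tf = fit_scaling(ds)
    scaled = ds.scaled(tf)
    # all-zero feature stays exactly zero and in [0, 1] overall
    for tr in scaled:
        assert np.all(tr.values[:, 1] == 0.0)
        assert tr.values.max() <= 1.0 + 1e-12
    # apply then invert is the identity
    y = np.array([0.0, 0.0, 3.0])
    assert np.allclose(tf.invert(tf.apply(y)), y)


def test_scaling_simple_column():
    tf = ScalingTransform(max_values=np.array([4.0]))
    assert np.allclose(tf.apply(np.array([[0.0], [2.0], [4.0]])).ravel(), [0, 0.5, 1])


def test_fit_scaling_errors():
    with pytest.raises(ValueError):
        fit_scaling(Dataset([]))
    ds = _toy_dataset()
    ds.trajectories[0].values[0, 0] = -1.0
    with pytest.raises(ValueError):
        fit_scaling(ds)


@given(st.integers(min_value=0, max_value=2**32 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_init_params_reproducible(seed):
    dims = Dimensions(n_s=2, n_m=1, n_u=0, n_h=2)
    a = init_params(dims, seed).flatten()
    b = init_params(dims, seed).flatten()
    assert np.array_equal(a, b)


def test_init_params_seeds_differ(small_dims):
    assert not np.array_equal(
        init_params(small_dims, 0).flatten(), init_params(small_dims, 1).flatten()
    )


def test_condition_time_validation():
    with pytest.raises(ValueError):
        ExperimentalCondition(s0=[1.0], m0=[], controls=np.zeros((3, 0)),
                              times=[0.0, 1.0, 3.0])  # non-uniform
    with pytest.raises(ValueError):
        ExperimentalCondition(s0=[1.0], m0=[], controls=np.zeros((2, 0)),
                              times=[1.0, 0.0])  # decreasing
    with pytest.raises(ValueError):
        ExperimentalCondition(s0=[1.0], m0=[], controls=np.zeros((2, 0)),
                              times=[0.0])  # single point
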