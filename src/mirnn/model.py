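"""Physically constrained recurrent dynamics model for microbial communities.

The model (MiRNN) is a discrete-time autoregressive recurrent network that maps
the community state at one sampling time to the next,

    h_t = LeakyReLU(W_hh h_{t-1} + W_ih [s_{t-1}, m_{t-1}, u_{t-1}, u_t] + b_hh)
    o_t = W_ho h_t + b_ho

where ``s`` are species abundances, ``m`` metabolite concentrations, ``u``
control inputs and ``h`` a latent state.  Two physical constraints distinguish
it from a plain RNN:

* **absence preservation** — the species part of ``o_t`` is multiplied by the
  indicator ``1[s_{t-1} > 0]``, so a species absent at one time point can never
  spontaneously appear at the next;
* **non-negativity** — at inference time a ReLU is applied to the output, so
  abundances and concentrations are never negative.  During training the ReLU
  is suppressed so that negative raw predictions are penalised by the loss.

All data are scaled to [0, 1] by dividing each feature by its maximum over the
training data (:class:`ScalingTransform`); max-scaling, unlike standardising,
preserves exact zeros, which the absence constraint requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Dimensions",
    "MiRNNParams",
    "CommunityState",
    "ScalingTransform",
    "ExperimentalCondition",
    "Trajectory",
    "Dataset",
    "MiRNN",
    "count_params",
    "init_params",
    "fit_scaling",
    "LEAKY_SLOPE",
]

# negative slope of the hidden-layer LeakyReLU
LEAKY_SLOPE = 0.01


@dataclass(frozen=True)
class Dimensions:
    """Model dimensions.

    n_s, n_m, n_u: numbers of species, metabolites and control inputs.
    n_h: latent-state size.  n_y = n_s + n_m is the observed-output size.
    """

    n_s: int
    n_m: int = 0
    n_u: int = 0
    n_h: int = 16

    def __post_init__(self) -> None:
        for name in ("n_s", "n_m", "n_u", "n_h"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_s < 1:
            raise ValueError("need at least one species")
        if self.n_h < 1:
            raise ValueError("need at least one latent unit")

    @property
    def n_y(self) -> int:
        return self.n_s + self.n_m

    @property
    def n_x(self) -> int:
        """Input size of the recurrence: state plus controls at t-1 and t."""
        return self.n_s + self.n_m + 2 * self.n_u


def count_params(dims: Dimensions) -> int:
    """Total number of free parameters n_theta.

    Blocks: W_hh (n_h*n_h), b_hh (n_h), W_ih (n_x*n_h), W_ho (n_h*n_y),
    b_ho (n_y), h_0 (n_h).
    """
    n_h, n_y, n_x = dims.n_h, dims.n_y, dims.n_x
    return n_h * n_h + n_h + n_x * n_h + n_h * n_y + n_y + n_h


@dataclass
class MiRNNParams:
    """Full parameter set theta = {W_hh, b_hh, W_ih, W_ho, b_ho, h_0}.

    Shapes follow the convention that pre-activations are computed as
    ``h @ W_hh + x @ W_ih + b_hh`` and outputs as ``h @ W_ho + b_ho``.
    """

    W_hh: np.ndarray  # (n_h, n_h)
    b_hh: np.ndarray  # (n_h,)
    W_ih: np.ndarray  # (n_x, n_h)
    W_ho: np.ndarray  # (n_h, n_y)
    b_ho: np.ndarray  # (n_y,)
    h_0: np.ndarray  # (n_h,)

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [
                self.W_hh.ravel(),
                self.b_hh.ravel(),
                self.W_ih.ravel(),
                self.W_ho.ravel(),
                self.b_ho.ravel(),
                self.h_0.ravel(),
            ]
        )

    @staticmethod
    def unflatten(theta: np.ndarray, dims: Dimensions) -> "MiRNNParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (count_params(dims),):
            raise ValueError(
                f"expected flat vector of length {count_params(dims)}, got {theta.shape}"
            )
        n_h, n_y, n_x = dims.n_h, dims.n_y, dims.n_x
        i = 0

        def take(shape):
            nonlocal i
            size = int(np.prod(shape))
            block = theta[i : i + size].reshape(shape)
            i += size
            return block

        return MiRNNParams(
            W_hh=take((n_h, n_h)),
            b_hh=take((n_h,)),
            W_ih=take((n_x, n_h)),
            W_ho=take((n_h, n_y)),
            b_ho=take((n_y,)),
            h_0=take((n_h,)),
        )


def init_params(dims: Dimensions, seed: int | np.random.Generator = 0) -> MiRNNParams:
    """Reproducible small random initialisation.

    Weight matrices are drawn N(0, 1/fan_in); biases and the shared initial
    latent state start at zero.  The same seed yields identical parameters.
    """
    rng = np.random.default_rng(seed)
    n_h, n_y, n_x = dims.n_h, dims.n_y, dims.n_x
    return MiRNNParams(
        W_hh=rng.normal(0.0, 1.0 / np.sqrt(n_h), size=(n_h, n_h)),
        b_hh=np.zeros(n_h),
        W_ih=rng.normal(0.0, 1.0 / np.sqrt(max(n_x, 1)), size=(n_x, n_h)),
        W_ho=rng.normal(0.0, 1.0 / np.sqrt(n_h), size=(n_h, n_y)),
        b_ho=np.zeros(n_y),
        h_0=np.zeros(n_h),
    )


@dataclass
class CommunityState:
    """State of the community at one time point (scaled units)."""

    s: np.ndarray  # (n_s,) species abundances
    m: np.ndarray  # (n_m,) metabolite concentrations
    h: np.ndarray  # (n_h,) latent state

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([self.s, self.m])


@dataclass
class ScalingTransform:
    """Per-feature max-scaling fitted on training data.

    Maps 0 to 0 exactly for every feature.  Features whose training maximum is
    zero are constant-zero and get divisor 1 so the transform is well defined.
    ``max_values`` covers the n_y observed outputs; ``control_max`` (optional)
    covers the n_u controls.
    """

    max_values: np.ndarray
    control_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.max_values = np.asarray(self.max_values, dtype=float)
        if self.control_max is not None:
            self.control_max = np.asarray(self.control_max, dtype=float)

    @staticmethod
    def _divisor(mx: np.ndarray) -> np.ndarray:
        return np.where(mx > 0, mx, 1.0)

    def apply(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) / self._divisor(self.max_values)

    def invert(self, y_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(y_scaled, dtype=float) * self._divisor(self.max_values)

    def apply_controls(self, u: np.ndarray) -> np.ndarray:
        if self.control_max is None:
            return np.asarray(u, dtype=float)
        return np.asarray(u, dtype=float) / self._divisor(self.control_max)

    def apply_condition(self, condition: "ExperimentalCondition") -> "ExperimentalCondition":
        """Scale a condition's initial state and controls."""
        n_s = len(condition.s0)
        y0 = self.apply(np.concatenate([condition.s0, condition.m0]))
        return replace(
            condition,
            s0=y0[:n_s],
            m0=y0[n_s:],
            controls=self.apply_controls(condition.controls),
        )


@dataclass(frozen=True)
class ExperimentalCondition:
    """One experimental condition q_i: initial state, controls and time grid.

    ``controls`` has a row for each of the n_tau+1 grid times (u_0 .. u_ntau);
    the model consumes u_{t-1} and u_t at every step.  Times must be uniformly
    spaced (discrete-time model contract).
    """

    s0: np.ndarray
    m0: np.ndarray
    controls: np.ndarray  # (n_tau+1, n_u)
    times: np.ndarray  # (n_tau+1,)
    condition_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "s0", np.atleast_1d(np.asarray(self.s0, dtype=float)))
        object.__setattr__(self, "m0", np.atleast_1d(np.asarray(self.m0, dtype=float)))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        u = np.asarray(self.controls, dtype=float)
        if u.ndim == 1:
            u = u[:, None] if u.size else u.reshape(len(self.times), 0)
        object.__setattr__(self, "controls", u)
        dt = np.diff(self.times)
        if len(dt) == 0:
            raise ValueError("need at least two time points")
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        if self.controls.shape[0] != len(self.times):
            raise ValueError("controls must have one row per time point")

    @property
    def n_tau(self) -> int:
        return len(self.times) - 1


@dataclass
class Trajectory:
    """Observed or predicted state sequence for one condition.

    ``values`` is (n_tau+1, n_y); row 0 is the (known) initial state.
    """

    condition: ExperimentalCondition
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean output mask: species present at t=0, plus all metabolites.

        Species absent at inoculation are excluded from likelihoods and
        performance evaluation.
        """
        n_s = len(self.condition.s0)
        mask = np.ones(self.values.shape[1], dtype=bool)
        mask[:n_s] = self.condition.s0 > 0
        return mask


@dataclass
class Dataset:
    """A design paired with its observations: a list of trajectories."""

    trajectories: list[Trajectory]
    species_names: list[str] = field(default_factory=list)
    metabolite_names: list[str] = field(default_factory=list)
    control_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return Dataset(
                [self.trajectories[j] for j in i],
                self.species_names,
                self.metabolite_names,
                self.control_names,
            )
        return self.trajectories[i]

    def scaled(self, transform: ScalingTransform) -> "Dataset":
        """Return a copy with outputs and controls scaled by ``transform``."""
        out = []
        for tr in self.trajectories:
            c = tr.condition
            n_s = len(c.s0)
            y0 = transform.apply(np.concatenate([c.s0, c.m0]))
            cond = replace(
                c,
                s0=y0[:n_s],
                m0=y0[n_s:],
                controls=transform.apply_controls(c.controls),
            )
            out.append(Trajectory(cond, transform.apply(tr.values)))
        return Dataset(out, self.species_names, self.metabolite_names, self.control_names)


def fit_scaling(dataset: Dataset) -> ScalingTransform:
    """Per-feature maxima over every condition and time point of ``dataset``.

    Must be fitted on the training split only.  Raises on negative raw
    measurements (abundances and concentrations are non-negative quantities).
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit scaling on an empty dataset")
    ys = np.vstack([tr.values for tr in dataset])
    if np.any(ys < 0):
        raise ValueError("negative raw measurements in dataset")
    max_values = ys.max(axis=0)
    n_u = dataset.trajectories[0].condition.controls.shape[1]
    control_max = None
    if n_u:
        us = np.vstack([tr.condition.controls for tr in dataset])
        control_max = np.abs(us).max(axis=0)
    return ScalingTransform(max_values=max_values, control_max=control_max)


def _leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


class MiRNN:
    """The constrained recurrent model.

    Parameters
    ----------
    dims : Dimensions
    constrained : bool
        If False, the absence-preserving species mask is disabled (the plain
        unconstrained-RNN ablation); the ReLU output activation is kept.
    """

    def __init__(self, dims: Dimensions, constrained: bool = True):
        self.dims = dims
        self.constrained = constrained

    # -- single step ------------------------------------------------------

    def step(
        self,
        params: MiRNNParams,
        state: CommunityState,
        u_prev: np.ndarray,
        u_curr: np.ndarray,
        mode: str = "inference",
    ) -> CommunityState:
        """Advance the community state by one sampling interval.

        In ``training`` mode the output ReLU is suppressed so that negative
        raw predictions incur loss; the absence mask applies in both modes.
        """
        if mode not in ("training", "inference"):
            raise ValueError(f"unknown mode {mode!r}")
        d = self.dims
        u_prev = np.asarray(u_prev, dtype=float).reshape(d.n_u)
        u_curr = np.asarray(u_curr, dtype=float).reshape(d.n_u)
        if state.s.shape != (d.n_s,) or state.m.shape != (d.n_m,) or state.h.shape != (d.n_h,):
            raise ValueError("state dimensions do not match model dimensions")
        x = np.concatenate([state.s, state.m, u_prev, u_curr])
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(state.h))):
            raise FloatingPointError("non-finite model inputs")
        s, m, h = self._step_core(params, x, state.h)
        if self.constrained:
            s *= state.s > 0
        if mode == "inference":
            s = np.maximum(s, 0.0)
            m = np.maximum(m, 0.0)
        return CommunityState(s=s, m=m, h=h)

    def _step_core(self, params: MiRNNParams, x: np.ndarray, h: np.ndarray):
        """Raw recurrence: no mask, no output activation."""
        h = _leaky_relu(h @ params.W_hh + x @ params.W_ih + params.b_hh)
        o = h @ params.W_ho + params.b_ho
        return o[: self.dims.n_s].copy(), o[self.dims.n_s :].copy(), h

    # -- rollout ----------------------------------------------------------

    def predict_trajectory(
        self,
        params: MiRNNParams,
        condition: ExperimentalCondition,
        mode: str = "inference",
    ) -> Trajectory:
        """Autoregressive rollout over the condition's time grid.

        Each predicted state is fed forward as the input to the next step; the
        latent state is initialised to the learned ``params.h_0``.

        In inference mode the absence mask is fully recursive (a species
        predicted extinct stays extinct).  In training mode, where outputs are
        unrectified and may transiently go negative, the mask is pinned to the
        initial presence pattern: for species absent at t = 0 the two
        definitions coincide exactly, and pinning keeps the training objective
        continuous in the parameters (a hard requirement for Newton's method).
        """
        d = self.dims
        if mode not in ("training", "inference"):
            raise ValueError(f"unknown mode {mode!r}")
        s = np.asarray(condition.s0, dtype=float).copy()
        m = np.asarray(condition.m0, dtype=float).copy()
        h = params.h_0.copy()
        init_present = s > 0
        values = np.empty((condition.n_tau + 1, d.n_y))
        values[0] = np.concatenate([s, m])
        for t in range(1, condition.n_tau + 1):
            x = np.concatenate([s, m, condition.controls[t - 1], condition.controls[t]])
            mask = init_present if mode == "training" else s > 0
            s, m, h = self._step_core(params, x, h)
            if self.constrained:
                s *= mask
            if mode == "inference":
                s = np.maximum(s, 0.0)
                m = np.maximum(m, 0.0)
            values[t] = np.concatenate([s, m])
        return Trajectory(condition, values)

    def predict_batch(
        self,
        params: MiRNNParams,
        conditions: list[ExperimentalCondition],
        mode: str = "inference",
    ) -> np.ndarray:
        """Vectorised rollout over many conditions sharing a time grid.

        Returns an array of shape (n_conditions, n_tau+1, n_y).
        """
        d = self.dims
        n_tau = conditions[0].n_tau
        if any(c.n_tau != n_tau for c in conditions):
            raise ValueError("batched conditions must share a time grid length")
        n = len(conditions)
        s = np.stack([c.s0 for c in conditions]).astype(float)
        m = np.stack([c.m0 for c in conditions]).astype(float)
        u = np.stack([c.controls for c in conditions]).astype(float)
        h = np.broadcast_to(params.h_0, (n, d.n_h)).copy()
        init_present = s > 0
        out = np.empty((n, n_tau + 1, d.n_y))
        out[:, 0] = np.concatenate([s, m], axis=1)
        for t in range(1, n_tau + 1):
            x = np.concatenate([s, m, u[:, t - 1], u[:, t]], axis=1)
            mask = init_present if mode == "training" else s > 0
            h = _leaky_relu(h @ params.W_hh + x @ params.W_ih + params.b_hh)
            o = h @ params.W_ho + params.b_ho
            s, m = o[:, : d.n_s], o[:, d.n_s :]
            if self.constrained:
                s = s * mask
            if mode == "inference":
                s = np.maximum(s, 0.0)
                m = np.maximum(m, 0.0)
            out[:, t] = np.concatenate([s, m], axis=1)
        return out

    # -- rollout with exact parameter Jacobian ----------------------------

    def rollout_with_jacobian_batch(
        self,
        params: MiRNNParams,
        conditions: list[ExperimentalCondition],
        mode: str = "training",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`rollout_with_jacobian` over many conditions.

        All conditions must share a time-grid length.  Returns ``(values,
        jac)`` with shapes (n, n_tau+1, n_y) and (n, n_tau, n_y, n_theta).
        """
        d = self.dims
        n_th = count_params(d)
        n_h, n_y, n_x, n_s = d.n_h, d.n_y, d.n_x, d.n_s
        o_Whh = 0
        o_bhh = o_Whh + n_h * n_h
        o_Wih = o_bhh + n_h
        o_Who = o_Wih + n_x * n_h
        o_bho = o_Who + n_h * n_y
        o_h0 = o_bho + n_y

        n_tau = conditions[0].n_tau
        if any(c.n_tau != n_tau for c in conditions):
            raise ValueError("batched conditions must share a time grid length")
        b = len(conditions)
        s = np.stack([c.s0 for c in conditions]).astype(float)
        m = np.stack([c.m0 for c in conditions]).astype(float)
        u = np.stack([c.controls for c in conditions]).astype(float)
        h = np.broadcast_to(params.h_0, (b, n_h)).copy()
        init_present = s > 0
        J_y = np.zeros((b, n_y, n_th))
        J_h = np.zeros((b, n_h, n_th))
        J_h[:, :, o_h0 : o_h0 + n_h] = np.eye(n_h)

        values = np.empty((b, n_tau + 1, n_y))
        values[:, 0] = np.concatenate([s, m], axis=1)
        jac = np.empty((b, n_tau, n_y, n_th))
        jj_h = np.arange(n_h)
        jj_y = np.arange(n_y)

        for t in range(1, n_tau + 1):
            x = np.concatenate([s, m, u[:, t - 1], u[:, t]], axis=1)
            pre = h @ params.W_hh + x @ params.W_ih + params.b_hh
            J_pre = np.matmul(params.W_hh.T, J_h)
            J_pre += np.matmul(params.W_ih[:n_y].T, J_y)
            # direct parameter contributions; the last-axis slices reshape as
            # views, and the paired advanced index hits block-diagonal entries
            Dw = J_pre[:, :, o_Whh : o_Whh + n_h * n_h].reshape(b, n_h, n_h, n_h)
            Dw[:, jj_h, :, jj_h] += h
            Dx = J_pre[:, :, o_Wih : o_Wih + n_x * n_h].reshape(b, n_h, n_x, n_h)
            Dx[:, jj_h, :, jj_h] += x
            Db = J_pre[:, :, o_bhh : o_bhh + n_h]
            Db[:, jj_h, jj_h] += 1.0
            act = np.where(pre > 0, 1.0, LEAKY_SLOPE)
            h = _leaky_relu(pre)
            J_h = act[:, :, None] * J_pre
            o = h @ params.W_ho + params.b_ho
            J_o = np.matmul(params.W_ho.T, J_h)
            Do = J_o[:, :, o_Who : o_Who + n_h * n_y].reshape(b, n_y, n_h, n_y)
            Do[:, jj_y, :, jj_y] += h
            Dbo = J_o[:, :, o_bho : o_bho + n_y]
            Dbo[:, jj_y, jj_y] += 1.0
            s_new, m_new = o[:, :n_s].copy(), o[:, n_s:].copy()
            if self.constrained:
                mask = (init_present if mode == "training" else s > 0).astype(float)
                s_new *= mask
                J_o[:, :n_s] *= mask[:, :, None]
            if mode == "inference":
                pos = np.concatenate([s_new, m_new], axis=1) > 0
                s_new = np.maximum(s_new, 0.0)
                m_new = np.maximum(m_new, 0.0)
                J_o *= pos[:, :, None]
            s, m = s_new, m_new
            J_y = J_o
            values[:, t] = np.concatenate([s, m], axis=1)
            jac[:, t - 1] = J_y
        return values, jac

    def rollout_with_jacobian(
        self,
        params: MiRNNParams,
        condition: ExperimentalCondition,
        mode: str = "training",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Rollout plus the exact Jacobian of the outputs w.r.t. theta.

        Forward-mode differentiation through the recurrence.  Returns
        ``(values, jac)`` with ``values`` of shape (n_tau+1, n_y) and ``jac``
        of shape (n_tau, n_y, n_theta) for the predicted steps t = 1..n_tau.

        The absence indicator is treated as locally constant (its derivative
        is zero almost everywhere); in training mode the output ReLU is
        suppressed, matching the objective the Jacobian serves.
        """
        d = self.dims
        n_th = count_params(d)
        n_h, n_y, n_x, n_s = d.n_h, d.n_y, d.n_x, d.n_s
        # flat-parameter column offsets per block
        o_Whh = 0
        o_bhh = o_Whh + n_h * n_h
        o_Wih = o_bhh + n_h
        o_Who = o_Wih + n_x * n_h
        o_bho = o_Who + n_h * n_y
        o_h0 = o_bho + n_y

        s = np.asarray(condition.s0, dtype=float).copy()
        m = np.asarray(condition.m0, dtype=float).copy()
        h = params.h_0.copy()
        init_present = s > 0
        J_y = np.zeros((n_y, n_th))  # d[s,m]/dtheta
        J_h = np.zeros((n_h, n_th))
        J_h[:, o_h0 : o_h0 + n_h] = np.eye(n_h)

        values = np.empty((condition.n_tau + 1, n_y))
        values[0] = np.concatenate([s, m])
        jac = np.empty((condition.n_tau, n_y, n_th))
        eye_h = np.eye(n_h)
        eye_y = np.eye(n_y)

        for t in range(1, condition.n_tau + 1):
            u_prev = condition.controls[t - 1]
            u_curr = condition.controls[t]
            x = np.concatenate([s, m, u_prev, u_curr])
            pre = h @ params.W_hh + x @ params.W_ih + params.b_hh
            # J_x: controls are data, so only the state rows carry derivatives
            J_pre = params.W_hh.T @ J_h + params.W_ih[:n_y].T @ J_y
            J_pre[:, o_Whh : o_Whh + n_h * n_h] += np.kron(h, eye_h)
            J_pre[:, o_Wih : o_Wih + n_x * n_h] += np.kron(x, eye_h)
            J_pre[:, o_bhh : o_bhh + n_h] += eye_h
            act = np.where(pre > 0, 1.0, LEAKY_SLOPE)
            h = _leaky_relu(pre)
            J_h = act[:, None] * J_pre
            o = h @ params.W_ho + params.b_ho
            J_o = params.W_ho.T @ J_h
            J_o[:, o_Who : o_Who + n_h * n_y] += np.kron(h, eye_y)
            J_o[:, o_bho : o_bho + n_y] += eye_y
            s_new, m_new = o[:n_s].copy(), o[n_s:].copy()
            J_new = J_o
            if self.constrained:
                mask = (init_present if mode == "training" else s > 0).astype(float)
                s_new *= mask
                J_new = J_o.copy()
                J_new[:n_s] *= mask[:, None]
            if mode == "inference":
                pos = np.concatenate([s_new, m_new]) > 0
                s_new = np.maximum(s_new, 0.0)
                m_new = np.maximum(m_new, 0.0)
                J_new = J_new * pos[:, None]
            s, m = s_new, m_new
            J_y = J_new
            values[t] = np.concatenate([s, m])
            jac[t - 1] = J_y
        return values, jac
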