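"""Laplace-approximate Bayesian training of the community dynamics model.

Parameters are estimated by maximum a posteriori (MAP) under a Gaussian
likelihood with noise covariance Sigma_y and a zero-mean Gaussian prior with
diagonal precision alpha,

    E(theta) = 1/2 sum_i r_i(theta)^T Sigma_y^{-1} r_i(theta)
             + 1/2 theta^T diag(alpha) theta,

minimised by Newton's method with the Gauss-Newton Hessian

    H = diag(alpha) + sum_i G_i^T Sigma_y^{-1} G_i,

where G_i is the sensitivity matrix (Jacobian of the rolled-out outputs with
respect to the flattened parameters).  The posterior is approximated as
N(theta_MAP, H^{-1}) and the linearised posterior predictive for a condition q
is N(M(theta_MAP, q), Sigma_y + G H^{-1} G^T), the sum of aleatory
(measurement) and epistemic (parameter) uncertainty.

The machinery is written against a small observation-model interface so that
the same code fits the recurrent network and, in tests, models that are linear
in theta (for which every quantity has a closed form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .model import (
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
)

__all__ = [
    "FitResult",
    "PosteriorState",
    "PredictiveDistribution",
    "MiRNNObservations",
    "LinearObservations",
    "neg_log_posterior",
    "fit_map",
    "sensitivity",
    "laplace_hessian",
    "posterior_predictive",
    "estimate_sigma_y_em",
    "heldout_loglik",
    "log_evidence",
    "optimize_alpha",
    "fit_posterior",
]

logger = logging.getLogger(__name__)


def _as_precision_diag(alpha, n_params: int) -> np.ndarray:
    """Prior precision diagonal: Sigma_theta(alpha)^{-1} = diag(alpha)."""
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 0:
        a = np.full(n_params, float(a))
    if a.shape != (n_params,):
        raise ValueError("alpha must be a scalar or a vector of length n_params")
    if np.any(a <= 0):
        raise ValueError("prior precision alpha must be positive")
    return a


# ---------------------------------------------------------------------------
# observation models
# ---------------------------------------------------------------------------


class MiRNNObservations:
    """Adapter exposing a scaled dataset to the Gaussian regression machinery.

    One observation block per condition and predicted time step.  For the
    constrained model, only the observed outputs enter (species present at
    t = 0 plus all metabolites): the excluded residual and sensitivity rows
    are identically zero, so the restriction is exact and merely drops dead
    rows.  For the unconstrained ablation all outputs enter, including the
    zero observations of absent species — otherwise those output channels
    would act as unpenalised auxiliary latent state feeding back through the
    autoregression.  ``mask_absent`` overrides the default per variant.
    """

    def __init__(
        self,
        model: MiRNN,
        dataset: Dataset,
        sigma_y: np.ndarray,
        mask_absent: bool | None = None,
    ):
        self.model = model
        self.dataset = dataset
        self.n_params = count_params(model.dims)
        self.mask_absent = model.constrained if mask_absent is None else mask_absent
        self.set_sigma_y(sigma_y)

    def set_sigma_y(self, sigma_y: np.ndarray) -> None:
        sigma_y = np.asarray(sigma_y, dtype=float)
        n_y = self.model.dims.n_y
        if sigma_y.ndim == 1:
            sigma_y = np.diag(sigma_y)
        if sigma_y.shape != (n_y, n_y):
            raise ValueError("sigma_y must be n_y x n_y")
        self.sigma_y = sigma_y
        # cache cholesky factors of the masked covariance per mask pattern
        self._chol_cache: dict[bytes, np.ndarray] = {}
        self._masks = []
        self._n_rows = 0
        for tr in self.dataset:
            mask = (
                tr.observed_mask
                if self.mask_absent
                else np.ones(tr.values.shape[1], dtype=bool)
            )
            self._masks.append(mask)
            self._n_rows += int(mask.sum()) * tr.condition.n_tau
        # fast paths: diagonal noise whitens by division; identical masks and
        # time grids allow fully vectorised residual stacking
        off = self.sigma_y - np.diag(np.diag(self.sigma_y))
        self._wdiag = (
            1.0 / np.sqrt(np.diag(self.sigma_y)) if not np.any(off) else None
        )
        self._uniform = (
            len(self._masks) > 0
            and all(np.array_equal(m, self._masks[0]) for m in self._masks)
            and len({tr.condition.n_tau for tr in self.dataset}) == 1
        )
        if self._uniform:
            self._Y = np.stack([tr.values for tr in self.dataset])

    def _chol(self, mask: np.ndarray) -> np.ndarray:
        key = mask.tobytes()
        L = self._chol_cache.get(key)
        if L is None:
            sub = self.sigma_y[np.ix_(mask, mask)]
            try:
                L = linalg.cholesky(sub, lower=True)
            except linalg.LinAlgError as e:  # pragma: no cover - defensive
                raise np.linalg.LinAlgError(f"sigma_y not positive definite: {e}")
            self._chol_cache[key] = L
        return L

    @property
    def n_rows(self) -> int:
        return self._n_rows

    def _grouped(self):
        """Condition indices grouped by shared time-grid length (batched rollouts)."""
        groups: dict[int, list[int]] = {}
        for i, tr in enumerate(self.dataset):
            groups.setdefault(tr.condition.n_tau, []).append(i)
        return groups

    def _rollouts(self, params: MiRNNParams, with_jac: bool):
        """Training-mode values (and Jacobians) for every condition."""
        n = len(self.dataset.trajectories)
        values = [None] * n
        jacs = [None] * n
        for _, idxs in self._grouped().items():
            conds = [self.dataset.trajectories[i].condition for i in idxs]
            if with_jac:
                vals, jac = self.model.rollout_with_jacobian_batch(
                    params, conds, mode="training"
                )
            else:
                vals = self.model.predict_batch(params, conds, mode="training")
                jac = None
            for pos, i in enumerate(idxs):
                values[i] = vals[pos]
                if with_jac:
                    jacs[i] = jac[pos]
        return values, jacs

    def whitened(self, theta: np.ndarray, with_jac: bool = True):
        """Whitened residuals (y - M(theta)) and Jacobians d M / d theta.

        Returns ``(r, J)`` stacked over all blocks; J is None when
        ``with_jac`` is False.  Whitening by L^{-1} (Sigma = L L^T) turns the
        data term of the objective into 1/2 ||r||^2.
        """
        params = MiRNNParams.unflatten(theta, self.model.dims)
        if self._uniform and self._wdiag is not None and len(self.dataset) > 0:
            # vectorised fast path: diagonal noise, shared mask and time grid
            conds = [tr.condition for tr in self.dataset]
            mask = self._masks[0]
            w = self._wdiag[mask]
            if with_jac:
                vals, jac = self.model.rollout_with_jacobian_batch(
                    params, conds, mode="training"
                )
            else:
                vals = self.model.predict_batch(params, conds, mode="training")
            resid = (self._Y[:, 1:, :] - vals[:, 1:, :])[:, :, mask] * w
            r = resid.reshape(-1)
            if not with_jac:
                return r, None
            J = (jac[:, :, mask, :] * w[None, None, :, None]).reshape(-1, self.n_params)
            return r, J

        values_all, jacs_all = self._rollouts(params, with_jac)
        rs, Js = [], []
        for tr, mask, values, jac in zip(self.dataset, self._masks, values_all, jacs_all):
            resid = tr.values[1:, mask] - values[1:, mask]  # (n_tau, k)
            if self._wdiag is not None:
                w = self._wdiag[mask]
                rs.append((resid * w).ravel())
                if with_jac:
                    Js.append(
                        (jac[:, mask, :] * w[None, :, None]).reshape(-1, self.n_params)
                    )
                continue
            L = self._chol(mask)
            rs.append(linalg.solve_triangular(L, resid.T, lower=True).T.ravel())
            if with_jac:
                k = int(mask.sum())
                Jm = jac[:, mask, :]  # (n_tau, k, n_theta)
                Jw = linalg.solve_triangular(
                    L, Jm.transpose(1, 0, 2).reshape(k, -1), lower=True
                )
                # note residual = y - M, so the residual Jacobian is -Jw
                Js.append(
                    Jw.reshape(k, values.shape[0] - 1, self.n_params)
                    .transpose(1, 0, 2)
                    .reshape(-1, self.n_params)
                )
        r = np.concatenate(rs) if rs else np.zeros(0)
        J = (np.vstack(Js) if Js else np.zeros((0, self.n_params))) if with_jac else None
        return r, J

    def log_noise_norm(self) -> float:
        """Sum over rows of the Gaussian normaliser: -(N/2)ln 2pi - 1/2 sum ln det Sigma."""
        total = -0.5 * self._n_rows * np.log(2 * np.pi)
        for tr, mask in zip(self.dataset, self._masks):
            L = self._chol(mask)
            total -= tr.condition.n_tau * np.sum(np.log(np.diag(L)))
        return total

    def residual_moments(self, theta: np.ndarray, H_inv: np.ndarray | None):
        """Per-output second moments of residuals plus the epistemic term.

        Returns (sums, counts) over the n_y outputs, where ``sums[j]`` is
        sum over observed entries of r^2 + [G H^{-1} G^T]_{jj}.  Used by the
        EM update of the noise covariance.
        """
        params = MiRNNParams.unflatten(theta, self.model.dims)
        n_y = self.model.dims.n_y
        sums = np.zeros(n_y)
        counts = np.zeros(n_y)
        values_all, jacs_all = self._rollouts(params, with_jac=H_inv is not None)
        for tr, mask, values, jac in zip(self.dataset, self._masks, values_all, jacs_all):
            resid = tr.values[1:] - values[1:]
            for t in range(resid.shape[0]):
                r2 = resid[t] ** 2
                if H_inv is not None:
                    G = jac[t]
                    r2 = r2 + np.einsum("ij,jk,ik->i", G, H_inv, G)
                sums[mask] += r2[mask]
                counts[mask] += 1
        return sums, counts


class LinearObservations:
    """Observation model linear in theta: y = G theta + eps, eps ~ N(0, Sigma).

    Exact Bayesian linear regression is available in closed form for this
    model, which makes it the reference oracle for the MAP/Laplace machinery.
    """

    def __init__(self, G: np.ndarray, y: np.ndarray, sigma: np.ndarray):
        self.G = np.asarray(G, dtype=float)
        self.y = np.asarray(y, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if sigma.ndim == 1:
            sigma = np.diag(sigma)
        self.sigma = sigma
        self._L = linalg.cholesky(sigma, lower=True)
        self.n_params = self.G.shape[1]
        self.n_rows = self.G.shape[0]

    def whitened(self, theta: np.ndarray, with_jac: bool = True):
        r = linalg.solve_triangular(self._L, self.y - self.G @ theta, lower=True)
        J = linalg.solve_triangular(self._L, self.G, lower=True) if with_jac else None
        return r, J

    def log_noise_norm(self) -> float:
        return -0.5 * self.n_rows * np.log(2 * np.pi) - np.sum(np.log(np.diag(self._L)))


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """MAP fit with convergence diagnostics (never a silent success)."""

    theta: np.ndarray
    objective: float
    grad_norm: float
    n_iter: int
    converged: bool
    message: str = ""


def neg_log_posterior(theta: np.ndarray, observations, alpha) -> float:
    """The MAP objective: 1/2 sum r^T Sigma^{-1} r + 1/2 theta^T diag(alpha) theta."""
    theta = np.asarray(theta, dtype=float)
    a = _as_precision_diag(alpha, observations.n_params)
    r, _ = observations.whitened(theta, with_jac=False)
    return 0.5 * float(r @ r) + 0.5 * float(theta @ (a * theta))


def _grad_and_gn(theta, observations, alpha):
    a = _as_precision_diag(alpha, observations.n_params)
    r, J = observations.whitened(theta, with_jac=True)
    obj = 0.5 * float(r @ r) + 0.5 * float(theta @ (a * theta))
    grad = -J.T @ r + a * theta
    H = J.T @ J
    H[np.diag_indices_from(H)] += a
    return obj, grad, H


def fit_map(
    observations,
    alpha,
    theta0: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
    ftol: float = 1e-10,
) -> FitResult:
    """Newton's method on the MAP objective with the Gauss-Newton Hessian.

    Backtracking (Armijo) line search on the objective guarantees monotone
    descent; the Gauss-Newton Hessian is positive definite thanks to the
    diagonal prior precision, so every step is a descent direction.
    Convergence is declared when the gradient infinity-norm drops below
    ``tol`` or, because the LeakyReLU activations make the objective
    piecewise smooth (the gradient can oscillate between kink branches at a
    nonsmooth minimiser), when the relative objective decrease stays below
    ``ftol`` for three consecutive iterations.  Deterministic given the
    initial point.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    obj, grad, H = _grad_and_gn(theta, observations, alpha)
    gnorm = float(np.max(np.abs(grad))) if grad.size else 0.0
    n_iter = 0
    c1 = 1e-4
    lam = 0.0  # Levenberg-Marquardt damping, raised only when a step stalls
    n_flat = 0
    for n_iter in range(1, max_iter + 1):
        if gnorm <= tol:
            return FitResult(theta, obj, gnorm, n_iter - 1, True, "gradient tolerance met")
        if n_flat >= 3:
            return FitResult(
                theta, obj, gnorm, n_iter - 1, True,
                "objective stationary (piecewise-smooth kink)",
            )
        improved = False
        for _ in range(12):  # escalate damping until a descent step succeeds
            Hd = H if lam == 0 else H + lam * np.eye(len(theta))
            try:
                cf = linalg.cho_factor(Hd, lower=True)
                step = linalg.cho_solve(cf, -grad)
            except linalg.LinAlgError:
                lam = max(lam * 10, 1e-6)
                continue
            slope = float(grad @ step)
            if slope >= 0:
                lam = max(lam * 10, 1e-6)
                continue
            t = 1.0
            for _ in range(30):
                cand = theta + t * step
                cand_obj = neg_log_posterior(cand, observations, alpha)
                if cand_obj <= obj + c1 * t * slope:
                    improved = True
                    break
                t *= 0.5
            if improved:
                theta = cand
                n_flat = n_flat + 1 if obj - cand_obj <= ftol * (1 + abs(obj)) else 0
                obj = cand_obj
                lam = lam / 10 if lam > 1e-10 else 0.0
                break
            lam = max(lam * 10, 1e-6)
        if not improved:
            return FitResult(
                theta, obj, gnorm, n_iter, gnorm <= tol,
                "no descent step found (damped Gauss-Newton stalled)",
            )
        _, grad, H = _grad_and_gn(theta, observations, alpha)
        gnorm = float(np.max(np.abs(grad))) if grad.size else 0.0
    converged = gnorm <= tol
    msg = "gradient tolerance met" if converged else f"max_iter reached (|grad|={gnorm:.2e})"
    if not converged:
        logger.warning("MAP fit did not converge: %s", msg)
    return FitResult(theta, obj, gnorm, n_iter, converged, msg)


# ---------------------------------------------------------------------------
# sensitivities, Hessian, predictive
# ---------------------------------------------------------------------------


def sensitivity(
    model: MiRNN, theta_map: np.ndarray, condition: ExperimentalCondition
) -> np.ndarray:
    """Sensitivity matrix G: Jacobian of the training-mode rollout outputs
    with respect to the flattened parameters, stacked over the condition's
    predicted time points.  Shape (n_tau * n_y, n_theta)."""
    params = MiRNNParams.unflatten(theta_map, model.dims)
    _, jac = model.rollout_with_jacobian(params, condition, mode="training")
    G = jac.reshape(-1, jac.shape[-1])
    if not np.all(np.isfinite(G)):
        raise FloatingPointError("non-finite sensitivity matrix")
    return G


def laplace_hessian(observations, theta_map: np.ndarray, alpha) -> np.ndarray:
    """Gauss-Newton Hessian H = diag(alpha) + sum_i G_i^T Sigma_y^{-1} G_i."""
    _, _, H = _grad_and_gn(np.asarray(theta_map, dtype=float), observations, alpha)
    return H


@dataclass
class PosteriorState:
    """Laplace posterior: MAP estimate, Gauss-Newton Hessian and hyperparameters."""

    theta_map: np.ndarray
    hessian: np.ndarray
    alpha: np.ndarray | float
    sigma_y: np.ndarray
    scaling: ScalingTransform
    dims: Dimensions
    constrained: bool = True
    fit: FitResult | None = None

    @property
    def model(self) -> MiRNN:
        return MiRNN(self.dims, constrained=self.constrained)

    @property
    def params(self) -> MiRNNParams:
        return MiRNNParams.unflatten(self.theta_map, self.dims)

    def hessian_inv(self) -> np.ndarray:
        cf = linalg.cho_factor(self.hessian, lower=True)
        return linalg.cho_solve(cf, np.eye(self.hessian.shape[0]))


@dataclass
class PredictiveDistribution:
    """Linearised posterior predictive for one condition.

    ``mean`` is the inference-mode rollout at theta_MAP, shape (n_tau+1, n_y);
    ``cov`` holds Sigma_y + G_t H^{-1} G_t^T per predicted step, shape
    (n_tau, n_y, n_y); ``sigma_y`` is the aleatory part alone.
    """

    condition: ExperimentalCondition
    mean: np.ndarray
    cov: np.ndarray
    sigma_y: np.ndarray


def posterior_predictive(
    posterior: PosteriorState, condition: ExperimentalCondition
) -> PredictiveDistribution:
    """Mean and covariance of the linearised predictive (scaled units)."""
    model = posterior.model
    params = posterior.params
    mean = model.predict_trajectory(params, condition, mode="inference").values
    _, jac = model.rollout_with_jacobian(params, condition, mode="training")
    H_inv = posterior.hessian_inv()
    covs = np.empty((jac.shape[0], mean.shape[1], mean.shape[1]))
    for t in range(jac.shape[0]):
        G = jac[t]
        covs[t] = posterior.sigma_y + G @ H_inv @ G.T
    return PredictiveDistribution(condition, mean, covs, posterior.sigma_y)


def heldout_loglik(
    predictions: list[PredictiveDistribution],
    observations: list[Trajectory],
    covariance_mode: str = "predicted",
) -> float:
    """Sum of Gaussian log-densities of held-out observations.

    ``covariance_mode='predicted'`` uses each prediction's condition-dependent
    covariance (aleatory + epistemic); ``'fixed'`` uses the constant Sigma_y
    (aleatory only) as the null model.  Only observed outputs (species present
    at t = 0, all metabolites) enter.
    """
    if covariance_mode not in ("predicted", "fixed"):
        raise ValueError(f"unknown covariance_mode {covariance_mode!r}")
    total = 0.0
    for pred, tr in zip(predictions, observations):
        mask = tr.observed_mask
        for t in range(1, tr.values.shape[0]):
            cov = pred.cov[t - 1] if covariance_mode == "predicted" else pred.sigma_y
            sub = cov[np.ix_(mask, mask)]
            r = tr.values[t, mask] - pred.mean[t, mask]
            L = linalg.cholesky(sub, lower=True)
            z = linalg.solve_triangular(L, r, lower=True)
            total += (
                -0.5 * float(z @ z)
                - np.sum(np.log(np.diag(L)))
                - 0.5 * len(r) * np.log(2 * np.pi)
            )
    return total


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------


def log_evidence(observations, theta_map: np.ndarray, alpha) -> float:
    """Laplace approximation of the log marginal likelihood log p(D | alpha).

    log p = -E(theta_MAP) - 1/2 log det H + 1/2 sum log alpha + noise norm.
    Exact for models linear in theta.
    """
    a = _as_precision_diag(alpha, observations.n_params)
    obj, _, H = _grad_and_gn(np.asarray(theta_map, dtype=float), observations, alpha)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("Hessian not positive definite")
    return -obj - 0.5 * logdet + 0.5 * float(np.sum(np.log(a))) + observations.log_noise_norm()


def optimize_alpha(
    observations,
    grid,
    theta0: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[float, list[dict]]:
    """Select the prior precision maximising the Laplace evidence over a grid.

    Fits are warm-started along the grid.  Returns the best alpha and the
    per-grid-point table of evidence values.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    table = []
    theta = np.asarray(theta0, dtype=float)
    for a in grid:
        res = fit_map(observations, a, theta, tol=tol, max_iter=max_iter)
        theta = res.theta
        ev = log_evidence(observations, res.theta, a)
        table.append({"alpha": a, "evidence": ev, "converged": res.converged})
    best = max(table, key=lambda row: row["evidence"])
    return best["alpha"], table


def estimate_sigma_y_em(
    observations: MiRNNObservations,
    alpha,
    theta_init: np.ndarray,
    n_em_iter: int = 5,
    tol: float = 1e-3,
    floor: float = 1e-8,
    fit_tol: float = 1e-5,
    fit_max_iter: int = 500,
) -> tuple[np.ndarray, FitResult]:
    """Expectation-maximisation estimate of the diagonal noise covariance.

    Alternates (i) refitting theta_MAP at the current Sigma_y with (ii)
    updating the diagonal of Sigma_y from residual second moments plus the
    linearised epistemic term diag(G H^{-1} G^T), until ``n_em_iter``
    iterations or relative change below ``tol``.  Diagonal entries are floored
    to keep the matrix positive definite.
    """
    theta = np.asarray(theta_init, dtype=float)
    sigma_diag = np.diag(observations.sigma_y).copy()
    res = None
    for _ in range(n_em_iter):
        res = fit_map(observations, alpha, theta, tol=fit_tol, max_iter=fit_max_iter)
        theta = res.theta
        H = laplace_hessian(observations, theta, alpha)
        cf = linalg.cho_factor(H, lower=True)
        H_inv = linalg.cho_solve(cf, np.eye(H.shape[0]))
        sums, counts = observations.residual_moments(theta, H_inv)
        new_diag = np.where(counts > 0, sums / np.maximum(counts, 1), sigma_diag)
        if np.any(new_diag < floor):
            logger.warning("noise variance floored at %g for %d outputs",
                           floor, int(np.sum(new_diag < floor)))
        new_diag = np.maximum(new_diag, floor)
        rel = np.max(np.abs(new_diag - sigma_diag) / np.maximum(sigma_diag, floor))
        sigma_diag = new_diag
        observations.set_sigma_y(np.diag(sigma_diag))
        if rel < tol:
            break
    # final refit so theta_MAP is consistent with the returned covariance
    res = fit_map(observations, alpha, theta, tol=fit_tol, max_iter=fit_max_iter)
    return np.diag(sigma_diag), res


# ---------------------------------------------------------------------------
# high-level pipeline
# ---------------------------------------------------------------------------


DEFAULT_ALPHA_GRID = (0.1, 1.0, 10.0, 100.0)


def fit_posterior(
    dataset: Dataset,
    dims: Dimensions,
    constrained: bool = True,
    alpha=1.0,
    sigma_y: np.ndarray | float = 1e-2,
    scaling: ScalingTransform | None = None,
    theta0: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = 1,
    em_iters: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    alpha_grid=DEFAULT_ALPHA_GRID,
) -> PosteriorState:
    """Fit scaling, MAP estimate and Laplace posterior on raw (unscaled) data.

    ``alpha`` may be a number (or per-parameter vector) of prior precisions,
    or the string ``"evidence"``, in which case the scalar precision is
    selected from ``alpha_grid`` by maximising the Laplace evidence on the
    training data (fits are warm-started along the grid).  ``sigma_y`` may be
    a scalar variance (isotropic initial guess), a diagonal vector or a full
    matrix, all in scaled units.  With ``em_iters > 0`` the noise covariance
    is re-estimated by EM.  ``n_restarts > 1`` restarts the MAP fit from
    additional seeded initialisations and keeps the lowest objective.
    """
    if scaling is None:
        scaling = fit_scaling(dataset)
    scaled = dataset.scaled(scaling)
    model = MiRNN(dims, constrained=constrained)
    sy = np.asarray(sigma_y, dtype=float)
    if sy.ndim == 0:
        sy = np.full(dims.n_y, float(sy))
    obs = MiRNNObservations(model, scaled, sy)

    inits = []
    if theta0 is not None:
        inits.append(np.asarray(theta0, dtype=float))
    rng = np.random.default_rng(seed)
    while len(inits) < n_restarts or not inits:
        inits.append(init_params(dims, rng.integers(2**31)).flatten())

    if isinstance(alpha, str):
        if alpha != "evidence":
            raise ValueError(f"unknown alpha mode {alpha!r}")
        alpha, _ = optimize_alpha(obs, alpha_grid, inits[0], tol=tol, max_iter=max_iter)

    best = None
    if len(inits) == 1 and em_iters > 0:
        theta_start = inits[0]  # EM refits anyway; skip the redundant pre-fit
    else:
        for th0 in inits:
            res = fit_map(obs, alpha, th0, tol=tol, max_iter=max_iter)
            if best is None or res.objective < best.objective:
                best = res
        theta_start = best.theta
    if em_iters > 0:
        _, best = estimate_sigma_y_em(
            obs, alpha, theta_start, n_em_iter=em_iters,
            fit_tol=tol, fit_max_iter=max_iter,
        )
    H = laplace_hessian(obs, best.theta, alpha)
    return PosteriorState(
        theta_map=best.theta,
        hessian=H,
        alpha=alpha,
        sigma_y=obs.sigma_y,
        scaling=scaling,
        dims=dims,
        constrained=constrained,
        fit=best,
    )
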