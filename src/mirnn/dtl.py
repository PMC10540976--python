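"""Closed-loop design-test-learn (DTL) orchestration and model evaluation.

Each cycle fits the Laplace posterior on all data collected so far, selects a
batch of new experimental conditions under one of four strategies (random,
explore, exploit, explore_exploit), "tests" them by simulating the ground-
truth bioreactor with measurement noise, appends the observations, and records
evaluation metrics (Pearson R and RMSE of predicted end-point product
concentration over the entire enumerated design space against the noiseless
ground truth) together with the best profit found so far.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bioreactor
from .bioreactor import BioreactorParams, profit, simulate
from .design import AcquisitionConfig, DesignSpace, strategy_scores
from .inference import PosteriorState, fit_posterior
from .model import Dataset, Dimensions, MiRNN, Trajectory

__all__ = [
    "DtlConfig",
    "DtlCycleRecord",
    "DtlHistory",
    "run_dtl",
    "evaluate_model",
    "ground_truth_endpoints",
    "crossvalidate",
    "summarize_cv",
]


@dataclass
class DtlConfig:
    """Loop and model settings for one DTL run."""

    n_init: int = 5
    batch_size: int = 5
    n_cycles: int = 5
    n_h: int = 16
    alpha: float | str = "evidence"  # scalar, or evidence-maximising grid search
    sigma0: float = 1e-2  # initial isotropic noise variance (scaled units)
    em_iters: int = 1
    fit_tol: float = 1e-4
    fit_max_iter: int = 60
    noise_pct: float = 0.05
    warm_start: bool = True
    evaluate: bool = True
    acquisition: AcquisitionConfig | None = None

    def make_acquisition(self) -> AcquisitionConfig:
        if self.acquisition is not None:
            return self.acquisition
        return AcquisitionConfig(batch_size=self.batch_size)


@dataclass
class DtlCycleRecord:
    cycle: int
    selected_indices: list[int]
    selected_ids: list[str]
    observed_profits: list[float]
    true_profits: list[float]
    best_profit: float
    pearson_r: float
    rmse: float
    w_I_trace: list[float]
    fit_converged: bool


@dataclass
class DtlHistory:
    strategy: str
    seed: int
    cycles: list[DtlCycleRecord] = field(default_factory=list)
    tested_indices: list[int] = field(default_factory=list)
    exhausted: bool = False
    posterior: PosteriorState | None = None

    @property
    def n_tested(self) -> int:
        return len(self.tested_indices)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cycle": c.cycle,
                    "n_tested": sum(
                        len(r.selected_indices) for r in self.cycles if r.cycle <= c.cycle
                    ),
                    "best_profit": c.best_profit,
                    "pearson_r": c.pearson_r,
                    "rmse": c.rmse,
                }
                for c in self.cycles
            ]
        )


def ground_truth_endpoints(
    params: BioreactorParams, space: DesignSpace, V0: float = 1.0
) -> pd.DataFrame:
    """Noiseless end-point product concentration and profit per configuration."""
    rows = []
    for cond, meta, cid in zip(space.conditions, space.metadata, space.ids):
        traj = simulate(
            params,
            meta["feed_design"],
            V0=meta.get("V0", V0),
            s0=cond.s0,
            t_grid=cond.times,
            noise_pct=0.0,
        )
        rows.append(
            {
                "candidate_id": cid,
                "m_end": traj.m_true[-1],
                "V_end": traj.V[-1],
                "profit": profit(traj, true_values=True),
            }
        )
    return pd.DataFrame(rows)


def evaluate_model(
    posterior: PosteriorState,
    space: DesignSpace,
    truth_endpoints: pd.DataFrame,
) -> tuple[float, float]:
    """Pearson R and RMSE of predicted vs true end-point product concentration
    over the whole design space (noise-free ground truth).

    Returns (nan, rmse) when the predictions have zero variance, where the
    correlation is undefined.
    """
    model = posterior.model
    scaled_conditions = [posterior.scaling.apply_condition(c) for c in space.conditions]
    preds = model.predict_batch(posterior.params, scaled_conditions, mode="inference")
    m_idx = posterior.dims.n_s  # first metabolite column
    m_scale = posterior.scaling.max_values[m_idx]
    m_pred = preds[:, -1, m_idx] * (m_scale if m_scale > 0 else 1.0)
    m_true = truth_endpoints["m_end"].to_numpy()
    rmse = float(np.sqrt(np.mean((m_pred - m_true) ** 2)))
    if np.std(m_pred) == 0 or np.std(m_true) == 0:
        return float("nan"), rmse
    r = float(stats.pearsonr(m_pred, m_true)[0])
    return r, rmse


def _observe(
    params: BioreactorParams,
    space: DesignSpace,
    indices: list[int],
    noise_pct: float,
    rng: np.random.Generator,
) -> tuple[list[Trajectory], list[float], list[float]]:
    """Simulate selected configurations as experiments (noise on)."""
    trajectories, obs_profits, true_profits = [], [], []
    for i in indices:
        cond = space.conditions[i]
        meta = space.metadata[i]
        traj = simulate(
            params,
            meta["feed_design"],
            V0=meta.get("V0", 1.0),
            s0=cond.s0,
            t_grid=cond.times,
            noise_pct=noise_pct,
            seed=rng,
        )
        values = np.column_stack([traj.s, traj.m])
        trajectories.append(Trajectory(cond, values))
        obs_profits.append(profit(traj))
        true_profits.append(profit(traj, true_values=True))
    return trajectories, obs_profits, true_profits


def _candidate_profits_and_sensitivities(
    posterior: PosteriorState,
    space: DesignSpace,
    need_eig: bool,
):
    """Predicted profit per candidate and (optionally) stacked sensitivities."""
    model = posterior.model
    dims = posterior.dims
    scaling = posterior.scaling
    scaled_conditions = [scaling.apply_condition(c) for c in space.conditions]
    preds = model.predict_batch(posterior.params, scaled_conditions, mode="inference")
    m_idx = dims.n_s
    m_scale = scaling.max_values[m_idx]
    m_end = preds[:, -1, m_idx] * (m_scale if m_scale > 0 else 1.0)
    profits = np.array(
        [m * meta["V_end"] for m, meta in zip(m_end, space.metadata)]
    )
    G_stack = None
    if need_eig:
        _, jac = model.rollout_with_jacobian_batch(
            posterior.params, scaled_conditions, mode="training"
        )
        n, n_tau, n_y, n_th = jac.shape
        G_stack = jac.reshape(n, n_tau * n_y, n_th)
    return profits, G_stack


def run_dtl(
    ground_truth: BioreactorParams,
    space: DesignSpace,
    strategy: str,
    config: DtlConfig | None = None,
    seed: int = 0,
    truth_endpoints: pd.DataFrame | None = None,
) -> DtlHistory:
    """Run a sequential design campaign against the simulated ground truth.

    Cycle 0 trains on ``n_init`` randomly chosen configurations; every later
    cycle selects ``batch_size`` new configurations by ``strategy``, simulates
    them with measurement noise, appends the data and refits.  Previously
    tested configurations are excluded from selection.  Deterministic given
    the seed.
    """
    config = config or DtlConfig()
    if config.n_init + config.n_cycles * config.batch_size > len(space):
        raise ValueError("design space too small for the requested campaign")
    rng = np.random.default_rng(seed)
    dims = Dimensions(
        n_s=ground_truth.n_s,
        n_m=1,
        n_u=space.conditions[0].controls.shape[1],
        n_h=config.n_h,
    )
    if config.evaluate and truth_endpoints is None:
        truth_endpoints = ground_truth_endpoints(ground_truth, space)

    history = DtlHistory(strategy=strategy, seed=seed)
    init_idx = [int(i) for i in rng.choice(len(space), size=config.n_init, replace=False)]
    trajs, obs_p, true_p = _observe(ground_truth, space, init_idx, config.noise_pct, rng)
    data = Dataset(list(trajs))
    history.tested_indices.extend(init_idx)
    best = max(obs_p)

    theta0 = None
    posterior = None

    def refit():
        nonlocal theta0, posterior
        posterior = fit_posterior(
            data,
            dims,
            alpha=config.alpha,
            sigma_y=config.sigma0,
            theta0=theta0 if config.warm_start else None,
            seed=seed,
            em_iters=config.em_iters,
            tol=config.fit_tol,
            max_iter=config.fit_max_iter,
        )
        theta0 = posterior.theta_map

    refit()
    r, rmse = (
        evaluate_model(posterior, space, truth_endpoints)
        if config.evaluate
        else (float("nan"), float("nan"))
    )
    history.cycles.append(
        DtlCycleRecord(
            cycle=0,
            selected_indices=init_idx,
            selected_ids=[space.ids[i] for i in init_idx],
            observed_profits=obs_p,
            true_profits=true_p,
            best_profit=best,
            pearson_r=r,
            rmse=rmse,
            w_I_trace=[],
            fit_converged=posterior.fit.converged,
        )
    )

    acq = config.make_acquisition()
    for cycle in range(1, config.n_cycles + 1):
        need_eig = strategy in ("explore", "explore_exploit")
        profits, G_stack = _candidate_profits_and_sensitivities(posterior, space, need_eig)
        design = strategy_scores(
            strategy,
            profits,
            G_stack,
            posterior.hessian if need_eig else None,
            posterior.sigma_y if need_eig else None,
            acq,
            seed=rng,
            exclude=history.tested_indices,
        )
        idx = design.indices
        trajs, obs_p, true_p = _observe(ground_truth, space, idx, config.noise_pct, rng)
        data = Dataset(data.trajectories + list(trajs))
        history.tested_indices.extend(idx)
        best = max(best, max(obs_p))
        refit()
        r, rmse = (
            evaluate_model(posterior, space, truth_endpoints)
            if config.evaluate
            else (float("nan"), float("nan"))
        )
        history.cycles.append(
            DtlCycleRecord(
                cycle=cycle,
                selected_indices=idx,
                selected_ids=[space.ids[i] for i in idx],
                observed_profits=obs_p,
                true_profits=true_p,
                best_profit=best,
                pearson_r=r,
                rmse=rmse,
                w_I_trace=[rec["w_I"] for rec in design.records],
                fit_converged=posterior.fit.converged,
            )
        )
    history.posterior = posterior
    return history


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def crossvalidate(
    dataset: Dataset,
    k_folds: int = 10,
    n_trials: int = 5,
    model_variant: str = "constrained",
    seed: int = 0,
    n_h: int = 16,
    alpha: float = 1.0,
    sigma0: float = 1e-2,
    em_iters: int = 1,
    fit_tol: float = 1e-4,
    fit_max_iter: int = 60,
) -> pd.DataFrame:
    """Repeated k-fold cross-validation with per-species metrics.

    One experimental condition (community) is the partition unit.  Each trial
    randomly partitions the conditions into ``k_folds`` folds; each fold is
    predicted by a model trained on the others, so every condition is tested
    exactly once per trial.  Predictions are evaluated only for species
    initially present, pooling all of a species' test observations within a
    trial into one Pearson R and RMSE (original units).

    Returns a tidy table with columns (trial, species, pearson_r, rmse, n_obs).
    """
    if model_variant not in ("constrained", "unconstrained"):
        raise ValueError(f"unknown model_variant {model_variant!r}")
    n_cond = len(dataset)
    if k_folds > n_cond:
        raise ValueError("more folds than conditions")
    first = dataset.trajectories[0]
    n_s = len(first.condition.s0)
    n_m = len(first.condition.m0)
    n_u = first.condition.controls.shape[1]
    dims = Dimensions(n_s=n_s, n_m=n_m, n_u=n_u, n_h=n_h)
    constrained = model_variant == "constrained"
    rng = np.random.default_rng(seed)

    rows = []
    for trial in range(n_trials):
        order = rng.permutation(n_cond)
        folds = np.array_split(order, k_folds)
        if any(len(f) == 0 for f in folds):
            raise ValueError("a fold received no test conditions")
        # per-species pooled predictions/observations across folds
        preds: dict[int, list[float]] = {j: [] for j in range(n_s)}
        obs: dict[int, list[float]] = {j: [] for j in range(n_s)}
        for fold in folds:
            test_idx = set(int(i) for i in fold)
            train = dataset[[i for i in range(n_cond) if i not in test_idx]]
            posterior = fit_posterior(
                train,
                dims,
                constrained=constrained,
                alpha=alpha,
                sigma_y=sigma0,
                seed=seed,
                em_iters=em_iters,
                tol=fit_tol,
                max_iter=fit_max_iter,
            )
            model = MiRNN(dims, constrained=constrained)
            test = dataset[[int(i) for i in sorted(test_idx)]].scaled(posterior.scaling)
            for tr_scaled, i in zip(test, sorted(test_idx)):
                pred = model.predict_trajectory(
                    posterior.params, tr_scaled.condition, mode="inference"
                ).values
                pred_orig = posterior.scaling.invert(pred)
                truth = dataset.trajectories[i].values
                present = np.where(dataset.trajectories[i].condition.s0 > 0)[0]
                for j in present:
                    preds[j].extend(pred_orig[1:, j])
                    obs[j].extend(truth[1:, j])
        for j in range(n_s):
            p = np.asarray(preds[j])
            o = np.asarray(obs[j])
            if len(o) < 2 or np.std(o) == 0 or np.std(p) == 0:
                r = float("nan")
            else:
                r = float(stats.pearsonr(p, o)[0])
            rows.append(
                {
                    "trial": trial,
                    "species": j,
                    "pearson_r": r,
                    "rmse": float(np.sqrt(np.mean((p - o) ** 2))) if len(o) else float("nan"),
                    "n_obs": len(o),
                }
            )
    return pd.DataFrame(rows)


def summarize_cv(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial median and interquartile range of the per-species metrics."""
    def iqr(x):
        q = np.nanpercentile(x, [25, 75])
        return q[1] - q[0]

    return (
        table.groupby("trial")
        .agg(
            median_r=("pearson_r", "median"),
            iqr_r=("pearson_r", iqr),
            median_rmse=("rmse", "median"),
            iqr_rmse=("rmse", iqr),
        )
        .reset_index()
    )
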