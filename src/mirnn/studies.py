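"""Reference studies: sparsity cross-validation, strategy comparison, calibration.

These presets reproduce, at desk scale, the three headline behaviours of the
framework on fully synthetic ground truths:

* **sparsity study** — the absence-preserving constraint improves held-out
  per-species correlation on sparse community data (random 5-of-20 species
  subsets) compared to the unconstrained ablation;
* **strategy study** — in a closed-loop campaign on a fed-batch bioreactor
  ground truth, combined exploration + exploitation finds higher product than
  random sampling, while pure exploration learns the most accurate model after
  the first designed batch;
* **calibration study** — condition-dependent predictive covariance (aleatory
  + epistemic) assigns higher likelihood to held-out data than the fixed noise
  covariance alone.

Problem sizes here are the package's desk-scale defaults (documented in
docs/methods.md); the generators themselves default to the full study sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bioreactor import (
    default_feed_catalog,
    enumerate_feed_designs,
    build_design_space,
    generate_sparse_communities,
    sample_ecosystem,
    simulate,
)
from .dtl import DtlConfig, crossvalidate, ground_truth_endpoints, run_dtl
from .inference import fit_posterior, heldout_loglik, posterior_predictive
from .model import Dataset, Dimensions, Trajectory

__all__ = [
    "run_sparsity_study",
    "run_strategy_study",
    "run_calibration_study",
]


def run_sparsity_study(
    subset_size: int = 5,
    n_total_species: int = 20,
    n_r: int = 10,
    n_communities: int = 30,
    k_folds: int = 5,
    n_trials: int = 3,
    n_h: int = 8,
    seed: int = 0,
    fit_max_iter: int = 50,
) -> dict:
    """Constrained vs unconstrained cross-validated prediction of sparse
    community dynamics.

    Returns per-variant CV tables and the pooled per-species median Pearson R.
    """
    dataset, _ = generate_sparse_communities(
        n_total_species=n_total_species,
        subset_size=subset_size,
        n_communities=n_communities,
        seed=seed,
    )
    out = {"tables": {}}
    for variant in ("constrained", "unconstrained"):
        table = crossvalidate(
            dataset,
            k_folds=k_folds,
            n_trials=n_trials,
            model_variant=variant,
            seed=seed,
            n_h=n_h,
            fit_max_iter=fit_max_iter,
        )
        out["tables"][variant] = table
        out[f"median_r_{variant}"] = float(np.nanmedian(table["pearson_r"]))
        out[f"median_rmse_{variant}"] = float(np.nanmedian(table["rmse"]))
    return out


def run_strategy_study(
    n_replicates: int = 10,
    n_cycles: int = 3,
    n_init: int = 5,
    batch_size: int = 5,
    n_s: int = 5,
    n_r: int = 7,
    n_profiles: int = 20,
    n_h: int = 8,
    seed: int = 0,
    strategies: tuple[str, ...] = ("random", "explore", "exploit", "explore_exploit"),
    fit_max_iter: int = 50,
) -> dict:
    """Closed-loop campaign comparison across sampling strategies.

    The design space is the full 7-resource x 20-profile enumeration (2,540
    configurations).  One ground-truth ecosystem is shared by all replicates;
    each replicate starts from a different random initial design (seeded).
    The random and explore_exploit strategies run all ``n_cycles`` (they carry
    the best-profit comparison); explore and exploit run a single cycle, which
    is all the post-first-design model-accuracy comparison needs.  Returns the
    per-replicate table and per-strategy medians of the best observed profit
    and of the model R after the first designed batch.
    """
    ecosystem = sample_ecosystem(n_s=n_s, n_r=n_r, seed=seed)
    catalog = default_feed_catalog(n_profiles=n_profiles, seed=seed)
    space = build_design_space(ecosystem, enumerate_feed_designs(n_r, catalog))
    truth = ground_truth_endpoints(ecosystem, space)
    rows = []
    for strategy in strategies:
        cycles = n_cycles if strategy in ("random", "explore_exploit") else 1
        config = DtlConfig(
            n_init=n_init, batch_size=batch_size, n_cycles=cycles, n_h=n_h,
            fit_max_iter=fit_max_iter,
        )
        for rep in range(n_replicates):
            hist = run_dtl(
                ecosystem,
                space,
                strategy,
                config=config,
                seed=(seed * 1000 + rep) % 2**31,
                truth_endpoints=truth,
            )
            rows.append(
                {
                    "strategy": strategy,
                    "replicate": rep,
                    "best_profit": hist.cycles[-1].best_profit,
                    "r_after_cycle1": hist.cycles[1].pearson_r,
                    "rmse_after_cycle1": hist.cycles[1].rmse,
                    "n_tested": hist.n_tested,
                }
            )
    table = pd.DataFrame(rows)
    med = table.groupby("strategy").median(numeric_only=True)
    return {
        "table": table,
        "median_best_profit": med["best_profit"].to_dict(),
        "median_r_after_cycle1": med["r_after_cycle1"].to_dict(),
        "max_true_profit": float(truth["profit"].max()),
    }


def run_calibration_study(
    n_seeds: int = 5,
    n_train: int = 20,
    n_test: int = 10,
    n_s: int = 5,
    n_r: int = 5,
    n_profiles: int = 10,
    n_h: int = 8,
    seed: int = 0,
) -> dict:
    """Held-out log-likelihood: predicted vs fixed covariance.

    For each seed, a fresh ecosystem and a random train/test split of feed
    configurations; the model is fit with one EM pass for the noise covariance
    and held-out log-likelihood is scored under the condition-dependent
    predictive covariance and under the fixed noise covariance.
    """
    diffs, pred_lls, fixed_lls = [], [], []
    for k in range(n_seeds):
        s = seed + k
        rng = np.random.default_rng(s)
        ecosystem = sample_ecosystem(n_s=n_s, n_r=n_r, seed=s)
        catalog = default_feed_catalog(n_profiles=n_profiles, seed=s)
        space = build_design_space(ecosystem, enumerate_feed_designs(n_r, catalog))
        idx = rng.choice(len(space), size=n_train + n_test, replace=False)
        train_idx, test_idx = idx[:n_train], idx[n_train:]

        def observe(indices):
            trajs = []
            for i in indices:
                cond = space.conditions[i]
                meta = space.metadata[i]
                traj = simulate(
                    ecosystem,
                    meta["feed_design"],
                    s0=cond.s0,
                    t_grid=cond.times,
                    noise_pct=0.05,
                    seed=rng,
                )
                trajs.append(Trajectory(cond, np.column_stack([traj.s, traj.m])))
            return Dataset(trajs)

        train, test = observe(train_idx), observe(test_idx)
        dims = Dimensions(
            n_s=n_s, n_m=1, n_u=space.conditions[0].controls.shape[1], n_h=n_h
        )
        posterior = fit_posterior(
            train, dims, alpha="evidence", sigma_y=1e-2, seed=s, em_iters=2,
            tol=1e-4, max_iter=60,
        )
        test_scaled = test.scaled(posterior.scaling)
        preds = [posterior_predictive(posterior, tr.condition) for tr in test_scaled]
        ll_pred = heldout_loglik(preds, list(test_scaled), "predicted")
        ll_fixed = heldout_loglik(preds, list(test_scaled), "fixed")
        pred_lls.append(ll_pred)
        fixed_lls.append(ll_fixed)
        diffs.append(ll_pred - ll_fixed)
    return {
        "loglik_predicted": pred_lls,
        "loglik_fixed": fixed_lls,
        "median_diff": float(np.median(diffs)),
        "median_predicted": float(np.median(pred_lls)),
        "median_fixed": float(np.median(fixed_lls)),
    }
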