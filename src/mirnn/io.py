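"""File formats: long-format trajectory tables, parameter and posterior archives.

Trajectory datasets are exchanged as long-format delimited text with columns
(condition_id, time_h, variable_kind, variable_name, value), where
variable_kind is one of species/metabolite/control.  Parameters are serialized
as a flat vector plus a dimensions header (JSON); posteriors as a compressed
numpy archive with a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorState
from .model import (
    Dataset,
    Dimensions,
    ExperimentalCondition,
    MiRNNParams,
    ScalingTransform,
    Trajectory,
    count_params,
)

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "params_to_json",
    "params_from_json",
    "save_posterior",
    "load_posterior",
]

KINDS = ("species", "metabolite", "control")


def write_trajectories(dataset: Dataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset as a long-format table (header mandatory)."""
    rows = []
    for tr in dataset:
        c = tr.condition
        n_s = len(c.s0)
        names = (
            dataset.species_names or [f"s{i+1}" for i in range(n_s)],
            dataset.metabolite_names or [f"m{i+1}" for i in range(len(c.m0))],
            dataset.control_names or [f"u{i+1}" for i in range(c.controls.shape[1])],
        )
        for t_i, t in enumerate(c.times):
            for j, name in enumerate(names[0]):
                rows.append((c.condition_id, t, "species", name, tr.values[t_i, j]))
            for j, name in enumerate(names[1]):
                rows.append((c.condition_id, t, "metabolite", name, tr.values[t_i, n_s + j]))
            for j, name in enumerate(names[2]):
                rows.append((c.condition_id, t, "control", name, c.controls[t_i, j]))
    df = pd.DataFrame(rows, columns=["condition_id", "time_h", "variable_kind",
                                     "variable_name", "value"])
    df.to_csv(path, sep=sep, index=False)


def read_trajectories(path: str | Path, sep: str = "\t") -> Dataset:
    """Read a long-format trajectory table back into a dataset.

    Validates kinds and uniform time spacing per condition (the condition
    constructor enforces the latter).
    """
    df = pd.read_csv(path, sep=sep)
    required = {"condition_id", "time_h", "variable_kind", "variable_name", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(df["variable_kind"].unique()) - set(KINDS)
    if bad:
        raise ValueError(f"unknown variable kinds: {sorted(bad)}")

    def names_of(kind):
        sub = df[df["variable_kind"] == kind]
        return list(dict.fromkeys(sub["variable_name"]))

    s_names, m_names, u_names = (names_of(k) for k in KINDS)
    trajectories = []
    for cid, grp in df.groupby("condition_id", sort=False):
        times = np.sort(grp["time_h"].unique())
        piv = grp.pivot_table(
            index="time_h", columns="variable_name", values="value", sort=True
        )
        ym_names = s_names + m_names
        values = (
            np.column_stack([piv[n].to_numpy() for n in ym_names])
            if ym_names
            else np.zeros((len(times), 0))
        )
        controls = (
            np.column_stack([piv[n].to_numpy() for n in u_names])
            if u_names
            else np.zeros((len(times), 0))
        )
        cond = ExperimentalCondition(
            s0=values[0, : len(s_names)],
            m0=values[0, len(s_names) :],
            controls=controls,
            times=times,
            condition_id=str(cid),
        )
        trajectories.append(Trajectory(cond, values))
    return Dataset(trajectories, s_names, m_names, u_names)


def params_to_json(params: MiRNNParams, dims: Dimensions, path: str | Path) -> None:
    payload = {
        "dimensions": {"n_s": dims.n_s, "n_m": dims.n_m, "n_u": dims.n_u, "n_h": dims.n_h},
        "n_theta": count_params(dims),
        "theta": params.flatten().tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def params_from_json(path: str | Path) -> tuple[MiRNNParams, Dimensions]:
    payload = json.loads(Path(path).read_text())
    d = payload["dimensions"]
    dims = Dimensions(n_s=d["n_s"], n_m=d["n_m"], n_u=d["n_u"], n_h=d["n_h"])
    theta = np.asarray(payload["theta"], dtype=float)
    return MiRNNParams.unflatten(theta, dims), dims


def save_posterior(posterior: PosteriorState, path: str | Path) -> None:
    """Single-archive posterior: theta_MAP, H, alpha, Sigma_y, scaling, dims."""
    header = {
        "dimensions": {
            "n_s": posterior.dims.n_s,
            "n_m": posterior.dims.n_m,
            "n_u": posterior.dims.n_u,
            "n_h": posterior.dims.n_h,
        },
        "constrained": posterior.constrained,
    }
    np.savez_compressed(
        path,
        header=json.dumps(header),
        theta_map=posterior.theta_map,
        hessian=posterior.hessian,
        alpha=np.asarray(posterior.alpha, dtype=float),
        sigma_y=posterior.sigma_y,
        max_values=posterior.scaling.max_values,
        control_max=(
            posterior.scaling.control_max
            if posterior.scaling.control_max is not None
            else np.zeros(0)
        ),
    )


def load_posterior(path: str | Path) -> PosteriorState:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        d = header["dimensions"]
        dims = Dimensions(n_s=d["n_s"], n_m=d["n_m"], n_u=d["n_u"], n_h=d["n_h"])
        control_max = z["control_max"]
        scaling = ScalingTransform(
            max_values=z["max_values"],
            control_max=control_max if control_max.size else None,
        )
        alpha = z["alpha"]
        return PosteriorState(
            theta_map=z["theta_map"],
            hessian=z["hessian"],
            alpha=float(alpha) if alpha.ndim == 0 else alpha,
            sigma_y=z["sigma_y"],
            scaling=scaling,
            dims=dims,
            constrained=bool(header["constrained"]),
        )
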