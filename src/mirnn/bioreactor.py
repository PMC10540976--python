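"""Ground-truth fed-batch consumer-resource bioreactor simulator.

Species compete for a shared pool of resources in a fed-batch reactor (inflow
feed, no outflow).  With reactor volume V, resource concentrations r, species
abundances s, product concentration m and feed rate u(t):

    dV/dt = u
    dr/dt = r . (-s^T C - d) + (u/V) (r_f - r)
    ds/dt = s . (C r - g) - (u/V) s
    dm/dt = y_ms^T max(0, ds/dt) - k_d m - (u/V) m

where C[i, j] is the rate at which species i consumes resource j, d resource
degradation rates, g minimum growth rates, y_ms growth-associated product
yields, k_d the product decay rate and r_f the feed resource concentrations.
Feed dilutes everything; the product is only made while its producer grows.

Random ecosystems are sampled by drawing a sparse species-resource dependency
matrix (each species depends on a resource with probability p_s/r), row-
normalising it into concentration parameters, and drawing consumption rates
around them.  A single species - the one depending on the fewest resources -
produces the target metabolite with yield 0.5, so that the best feed is a
specific resource subset rather than simply all resources.

Recorded observations are corrupted with 5% multiplicative Gaussian noise and
clipped at zero, mimicking measurement variation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .design import DesignSpace
from .model import Dataset, ExperimentalCondition, Trajectory

__all__ = [
    "BioreactorParams",
    "FeedDesign",
    "ReactorTrajectory",
    "sample_ecosystem",
    "simulate",
    "default_feed_catalog",
    "enumerate_feed_designs",
    "enumerate_design_space",
    "build_design_space",
    "feed_volume",
    "profit",
    "generate_sparse_communities",
    "DEFAULT_T_GRID",
]

logger = logging.getLogger(__name__)

# 130 h batch with observations every 26 h (5 measurements after t=0)
DEFAULT_T_GRID = np.linspace(0.0, 130.0, 6)


@dataclass
class BioreactorParams:
    """Ground-truth ecosystem parameters."""

    C: np.ndarray  # (n_s, n_r) consumption rates, >= 0
    d: np.ndarray  # (n_r,) resource degradation rates (1/h)
    g: np.ndarray  # (n_s,) minimum growth rates (1/h)
    y_ms: np.ndarray  # (n_s,) product yield coefficients
    k_d: float  # product decay rate (1/h)
    r_f: np.ndarray  # (n_r,) feed resource concentrations (g/L)
    p_sr: float  # species-resource dependency probability used to sample C
    theta_conc: np.ndarray | None = None  # (n_s, n_r) concentration parameters
    seed: int | None = None

    @property
    def n_s(self) -> int:
        return self.C.shape[0]

    @property
    def n_r(self) -> int:
        return self.C.shape[1]


@dataclass(frozen=True)
class FeedDesign:
    """A feed configuration: which resources are fed and at what rate profile.

    ``rates`` holds the piecewise-constant feed rate (L/h) on equal intervals
    spanning the batch horizon.
    """

    resource_mask: tuple[int, ...]
    rates: tuple[float, ...]
    profile_id: int = -1

    def __post_init__(self) -> None:
        if not any(self.resource_mask):
            raise ValueError("the empty resource subset is excluded from the design space")

    @property
    def bitmask(self) -> int:
        return int(sum(b << i for i, b in enumerate(self.resource_mask)))

    @property
    def design_id(self) -> str:
        return f"r{self.bitmask:03d}_p{self.profile_id:02d}"


@dataclass
class ReactorTrajectory:
    """Simulated reactor states at the sampling grid.

    ``s``/``m`` carry the recorded (possibly noise-corrupted) observations;
    ``s_true``/``m_true`` the noiseless states.  Volume and resources are not
    measured and stay noiseless.
    """

    times: np.ndarray
    V: np.ndarray
    r: np.ndarray  # (n_t, n_r)
    s: np.ndarray  # (n_t, n_s)
    m: np.ndarray  # (n_t,)
    s_true: np.ndarray = field(default=None)  # type: ignore[assignment]
    m_true: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.s_true is None:
            self.s_true = self.s.copy()
        if self.m_true is None:
            self.m_true = self.m.copy()


def sample_ecosystem(
    n_s: int = 5,
    n_r: int = 7,
    p_sr: float = 0.6,
    seed: int = 0,
    r_f_conc: float = 1.0,
) -> BioreactorParams:
    """Sample a random ground-truth ecosystem.

    Dependencies Theta'_ij ~ Uniform(0,1) with probability ``p_sr`` (else 0);
    rows are renormalised to sum to one and consumption rates drawn
    C_ij ~ Normal(Theta_ij, Theta_ij/10), truncated at zero.  A species whose
    row is entirely zero is resampled (and the event logged).  Degradation and
    maintenance rates are 0.01/h, product decay 0.005/h; the species with the
    fewest resource dependencies is the sole producer with yield 0.5.
    """
    if n_s < 1 or n_r < 1:
        raise ValueError("need at least one species and one resource")
    if not (0 < p_sr <= 1):
        raise ValueError("p_sr must be in (0, 1]")
    rng = np.random.default_rng(seed)
    theta_raw = np.zeros((n_s, n_r))
    for i in range(n_s):
        row = rng.uniform(0, 1, n_r) * (rng.uniform(0, 1, n_r) < p_sr)
        while not np.any(row > 0):
            logger.info("resampling all-zero dependency row for species %d", i)
            row = rng.uniform(0, 1, n_r) * (rng.uniform(0, 1, n_r) < p_sr)
        theta_raw[i] = row
    theta = theta_raw / theta_raw.sum(axis=1, keepdims=True)
    C = np.maximum(rng.normal(theta, theta / 10.0), 0.0)
    n_dep = (theta > 0).sum(axis=1)
    producer = int(np.argmin(n_dep))
    y_ms = np.zeros(n_s)
    y_ms[producer] = 0.5
    return BioreactorParams(
        C=C,
        d=np.full(n_r, 0.01),
        g=np.full(n_s, 0.01),
        y_ms=y_ms,
        k_d=0.005,
        r_f=np.full(n_r, float(r_f_conc)),
        p_sr=p_sr,
        theta_conc=theta,
        seed=seed,
    )


def _rhs(params: BioreactorParams, r_feed: np.ndarray, u: float):
    n_r, n_s = params.n_r, params.n_s

    def f(t, y):
        V = y[0]
        r = y[1 : 1 + n_r]
        s = y[1 + n_r : 1 + n_r + n_s]
        m = y[-1]
        dil = u / V
        dr = r * (-(s @ params.C) - params.d) + dil * (r_feed - r)
        ds = s * (params.C @ r - params.g) - dil * s
        dm = params.y_ms @ np.maximum(ds, 0.0) - params.k_d * m - dil * m
        return np.concatenate([[u], dr, ds, [dm]])

    return f


def simulate(
    params: BioreactorParams,
    design: FeedDesign | None,
    V0: float = 1.0,
    s0: np.ndarray | float = 0.01,
    t_grid: np.ndarray | None = None,
    noise_pct: float = 0.05,
    seed: int | np.random.Generator | None = None,
    r0: np.ndarray | float = 0.0,
    m0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> ReactorTrajectory:
    """Integrate the fed-batch equations and record states at ``t_grid``.

    ``design=None`` means batch operation (u = 0, nothing fed); then ``r0``
    must supply the initial resources.  The feed rate is piecewise constant on
    ``len(design.rates)`` equal intervals, so integration proceeds segment by
    segment with the state floored at zero between segments.  Recorded species
    and product observations are multiplied by (1 + eps), eps ~ N(0,
    ``noise_pct``), then clipped at zero; ``noise_pct=0`` gives the noiseless
    ground truth.
    """
    if V0 <= 0:
        raise ValueError("V0 must be positive")
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    n_r, n_s = params.n_r, params.n_s
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), (n_s,)).copy()
    r0 = np.broadcast_to(np.asarray(r0, dtype=float), (n_r,)).copy()

    if design is None:
        rates = np.zeros(1)
        r_feed = np.zeros(n_r)
    else:
        rates = np.asarray(design.rates, dtype=float)
        r_feed = params.r_f * np.asarray(design.resource_mask, dtype=float)

    t0, t_end = t_grid[0], t_grid[-1]
    edges = np.linspace(t0, t_end, len(rates) + 1)
    y = np.concatenate([[V0], r0, s0, [m0]])
    out = np.empty((len(t_grid), len(y)))
    out[0] = y
    rec_i = 1
    for k in range(len(rates)):
        a, b = edges[k], edges[k + 1]
        t_rec = t_grid[(t_grid > a + 1e-12) & (t_grid <= b + 1e-12)]
        t_eval = np.unique(np.append(t_rec, b))  # always land on the segment end
        sol = solve_ivp(
            _rhs(params, r_feed, float(rates[k])),
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            did = design.design_id if design is not None else "batch"
            raise RuntimeError(f"integration failed for design {did}: {sol.message}")
        if len(t_rec):
            out[rec_i : rec_i + len(t_rec)] = sol.y[:, : len(t_rec)].T
            rec_i += len(t_rec)
        y = np.maximum(sol.y[:, -1], 0.0)
        y[0] = sol.y[0, -1]  # volume is never clipped

    V = out[:, 0]
    r = np.maximum(out[:, 1 : 1 + n_r], 0.0)
    s_true = np.maximum(out[:, 1 + n_r : 1 + n_r + n_s], 0.0)
    m_true = np.maximum(out[:, -1], 0.0)
    s_obs, m_obs = s_true.copy(), m_true.copy()
    if noise_pct > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        s_obs[1:] = np.maximum(s_true[1:] * (1 + rng.normal(0, noise_pct, s_true[1:].shape)), 0.0)
        m_obs[1:] = np.maximum(m_true[1:] * (1 + rng.normal(0, noise_pct, m_true[1:].shape)), 0.0)
    return ReactorTrajectory(
        times=t_grid, V=V, r=r, s=s_obs, m=m_obs, s_true=s_true, m_true=m_true
    )


def profit(trajectory: ReactorTrajectory, true_values: bool = False) -> float:
    """Total product at the end of the batch: m(T) * V(T), in grams."""
    m_end = trajectory.m_true[-1] if true_values else trajectory.m[-1]
    return float(m_end * trajectory.V[-1])


# ---------------------------------------------------------------------------
# design-space enumeration
# ---------------------------------------------------------------------------


def default_feed_catalog(
    n_profiles: int = 20,
    rates: tuple[float, ...] = (0.0, 0.005, 0.01),
    n_intervals: int = 5,
    seed: int = 0,
) -> list[tuple[float, ...]]:
    """Catalog of piecewise-constant feed-rate profiles.

    All rate combinations on ``n_intervals`` equal intervals are enumerated
    (the all-zero profile excluded, since an empty feed defeats fed-batch
    operation) and a seeded permutation picks ``n_profiles`` distinct ones.
    Deterministic given the seed; user-overridable wherever a catalog is
    accepted.
    """
    all_profiles = [
        p for p in itertools.product(rates, repeat=n_intervals) if any(x > 0 for x in p)
    ]
    if n_profiles > len(all_profiles):
        raise ValueError(f"only {len(all_profiles)} distinct profiles available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_profiles))
    return [all_profiles[i] for i in order[:n_profiles]]


def enumerate_feed_designs(
    n_r: int, feed_profile_catalog: list[tuple[float, ...]]
) -> list[FeedDesign]:
    """All (2^n_r - 1) non-empty resource subsets x catalog profiles.

    Deterministic ordering: subset bitmask ascending, then profile index.
    """
    if not feed_profile_catalog:
        raise ValueError("feed profile catalog must be non-empty")
    designs = []
    for bitmask in range(1, 2**n_r):
        mask = tuple((bitmask >> i) & 1 for i in range(n_r))
        for p_idx, rates in enumerate(feed_profile_catalog):
            designs.append(FeedDesign(resource_mask=mask, rates=tuple(rates), profile_id=p_idx))
    return designs


def feed_volume(design: FeedDesign, V0: float, t_grid: np.ndarray) -> np.ndarray:
    """Reactor volume at the grid times (deterministic: V = V0 + integral of u)."""
    t_grid = np.asarray(t_grid, dtype=float)
    edges = np.linspace(t_grid[0], t_grid[-1], len(design.rates) + 1)
    rates = np.asarray(design.rates, dtype=float)
    V = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        dt_in = np.clip(t - edges[:-1], 0.0, np.diff(edges))
        V[i] = V0 + float(rates @ dt_in)
    return V


def _rate_at_grid(design: FeedDesign, t_grid: np.ndarray) -> np.ndarray:
    """Feed rate at each grid time: the rate of the interval starting there
    (the final grid point carries the last interval's rate)."""
    t_grid = np.asarray(t_grid, dtype=float)
    edges = np.linspace(t_grid[0], t_grid[-1], len(design.rates) + 1)
    idx = np.clip(np.searchsorted(edges, t_grid, side="right") - 1, 0, len(design.rates) - 1)
    return np.asarray(design.rates, dtype=float)[idx]


def build_design_space(
    params: BioreactorParams,
    designs: list[FeedDesign],
    t_grid: np.ndarray | None = None,
    V0: float = 1.0,
    s0: np.ndarray | float = 0.01,
) -> DesignSpace:
    """Wrap feed designs as model-facing experimental conditions.

    Controls per grid time are [feed resource concentrations (n_r, static),
    feed rate u_t], so the model sees both the static resource selection and
    the dynamic feed rate.  Initial resources are zero: the feed is the sole
    source of resources in the fed-batch study.
    """
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    n_s = params.n_s
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), (n_s,)).copy()
    conditions, metadata, ids = [], [], []
    for d in designs:
        feed_conc = params.r_f * np.asarray(d.resource_mask, dtype=float)
        u = _rate_at_grid(d, t_grid)
        controls = np.column_stack([np.tile(feed_conc, (len(t_grid), 1)), u])
        conditions.append(
            ExperimentalCondition(
                s0=s0,
                m0=np.zeros(1),
                controls=controls,
                times=t_grid,
                condition_id=d.design_id,
            )
        )
        metadata.append(
            {
                "feed_design": d,
                "bitmask": d.bitmask,
                "profile_id": d.profile_id,
                "V_end": float(feed_volume(d, V0, t_grid)[-1]),
                "V0": V0,
            }
        )
        ids.append(d.design_id)
    return DesignSpace(conditions=conditions, metadata=metadata, ids=ids)


def enumerate_design_space(
    n_r: int,
    feed_profile_catalog: list[tuple[float, ...]],
    params: BioreactorParams | None = None,
    t_grid: np.ndarray | None = None,
    V0: float = 1.0,
    s0: np.ndarray | float = 0.01,
    n_s: int = 5,
) -> DesignSpace:
    """Enumerate the full resource-subset x feed-profile design space.

    With 7 resources and 20 profiles this yields 20 x (2^7 - 1) = 2540
    configurations.  If ``params`` is omitted a default ecosystem is sampled
    only to supply feed concentrations (r_f); pass the actual ground truth
    when simulating.
    """
    if params is None:
        params = sample_ecosystem(n_s=n_s, n_r=n_r)
    if params.n_r != n_r:
        raise ValueError("params.n_r does not match n_r")
    designs = enumerate_feed_designs(n_r, feed_profile_catalog)
    return build_design_space(params, designs, t_grid=t_grid, V0=V0, s0=s0)


# ---------------------------------------------------------------------------
# sparse-community dataset generation
# ---------------------------------------------------------------------------


def generate_sparse_communities(
    n_total_species: int = 20,
    subset_size: int = 5,
    n_communities: int = 50,
    t_grid: np.ndarray | None = None,
    seed: int = 0,
    params: BioreactorParams | None = None,
    n_r: int = 10,
    noise_pct: float = 0.05,
    s0_abundance: float = 0.01,
    r0: float = 1.0,
    include_metabolite: bool = False,
) -> tuple[Dataset, BioreactorParams]:
    """Simulated communities assembling random species subsets (batch mode).

    Samples ``n_communities`` distinct subsets of ``subset_size`` of the
    ``n_total_species`` species, simulates each in batch operation (u = 0,
    initial resources ``r0``) from equal initial abundances, and records
    noise-corrupted species abundances at the grid times.  Species absent at
    t = 0 are identically zero at every time point.  Returns the dataset and
    the ground-truth ecosystem.
    """
    from math import comb

    if subset_size > n_total_species:
        raise ValueError("subset_size exceeds the number of species")
    if n_communities > comb(n_total_species, subset_size):
        raise ValueError("requested distinct subsets exceed the number available")
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    if params is None:
        params = sample_ecosystem(
            n_s=n_total_species, n_r=n_r, seed=int(rng.integers(2**31))
        )
    subsets: list[tuple[int, ...]] = []
    seen = set()
    while len(subsets) < n_communities:
        sub = tuple(sorted(rng.choice(n_total_species, size=subset_size, replace=False)))
        if sub not in seen:
            seen.add(sub)
            subsets.append(sub)

    trajectories = []
    n_y_cols = n_total_species + (1 if include_metabolite else 0)
    for k, sub in enumerate(subsets):
        s0 = np.zeros(n_total_species)
        s0[list(sub)] = s0_abundance
        traj = simulate(
            params,
            design=None,
            V0=1.0,
            s0=s0,
            t_grid=t_grid,
            noise_pct=noise_pct,
            seed=rng,
            r0=r0,
        )
        values = np.empty((len(t_grid), n_y_cols))
        values[:, :n_total_species] = traj.s
        if include_metabolite:
            values[:, -1] = traj.m
        cond = ExperimentalCondition(
            s0=s0,
            m0=np.zeros(1 if include_metabolite else 0),
            controls=np.zeros((len(t_grid), 0)),
            times=t_grid,
            condition_id=f"community_{k:03d}",
        )
        trajectories.append(Trajectory(cond, values))
    names = [f"s{i+1}" for i in range(n_total_species)]
    dataset = Dataset(
        trajectories,
        species_names=names,
        metabolite_names=["product"] if include_metabolite else [],
    )
    return dataset, params
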