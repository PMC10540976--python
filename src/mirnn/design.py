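"""Batch Bayesian experimental design for the community dynamics model.

The expected information gain (EIG) of a prospective design with conditions
q_1..q_n, given the current Gauss-Newton posterior precision H, is the
log-determinant difference

    EIG = ln det(H + sum_i G_i^T Sigma_y^{-1} G_i) - ln det(H),

equal (exactly) to a sum of small-determinant terms

    EIG = sum_i ln det(I + Sigma_y^{-1} G_i A_{i-1}^{-1} G_i^T),
    A_i = A_{i-1} + G_i^T Sigma_y^{-1} G_i,   A_0 = H,

with A_i^{-1} maintained by the Woodbury identity.  The fast form never
factorises an n_theta x n_theta matrix beyond the one initial inversion of H,
which is reused across candidate evaluations.

Designs are selected greedily: the first condition maximises the predicted
profit, and each subsequent condition maximises

    f = profit + w_I * (incremental EIG),

where the exploration weight w_I starts small and is escalated multiplicatively
whenever the maximiser is a condition already in the batch, forcing novelty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "AcquisitionConfig",
    "DesignSpace",
    "Design",
    "woodbury_update",
    "eig_direct",
    "eig_fast",
    "fim_logdet",
    "acquisition_score",
    "greedy_select",
    "strategy_scores",
    "STRATEGIES",
]

STRATEGIES = ("random", "explore", "exploit", "explore_exploit")


@dataclass
class AcquisitionConfig:
    """Knobs of the combined profit + information acquisition.

    ``w_I_init`` is the initial exploration weight (kept small so the first
    escalations stay profit-dominated), ``w_I_factor`` the multiplicative
    escalation step applied whenever the acquisition argmax is already in the
    batch, and ``batch_size`` the number of conditions per design.
    """

    batch_size: int = 5
    w_I_init: float = 1e-4
    w_I_factor: float = 10.0
    max_escalations: int = 60

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.w_I_init < 0:
            raise ValueError("w_I_init must be >= 0")
        if self.w_I_factor <= 1:
            raise ValueError("w_I_factor must be > 1")


@dataclass
class DesignSpace:
    """Ordered collection of candidate experimental conditions Q."""

    conditions: list  # ExperimentalCondition candidates
    metadata: list[dict] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.metadata:
            self.metadata = [{} for _ in self.conditions]
        if not self.ids:
            self.ids = [
                getattr(c, "condition_id", "") or f"cand_{i}"
                for i, c in enumerate(self.conditions)
            ]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("candidate identifiers must be unique")
        if not (len(self.conditions) == len(self.metadata) == len(self.ids)):
            raise ValueError("conditions, metadata and ids must align")

    def __len__(self) -> int:
        return len(self.conditions)


@dataclass
class Design:
    """An ordered selection from a design space, with per-pick diagnostics."""

    indices: list[int]
    records: list[dict]  # rank, candidate_index, profit_pred, eig_increment, w_I


# ---------------------------------------------------------------------------
# information-gain primitives
# ---------------------------------------------------------------------------


def _expand_cov(sigma_y: np.ndarray, rows: int) -> np.ndarray:
    """Noise covariance for a G block of ``rows`` rows.

    A block stacking k measurement times of an n_y-output condition gets the
    block-diagonal covariance kron(I_k, Sigma_y)."""
    sigma_y = np.asarray(sigma_y, dtype=float)
    if sigma_y.ndim == 1:
        sigma_y = np.diag(sigma_y)
    n_y = sigma_y.shape[0]
    if rows == n_y:
        return sigma_y
    if rows % n_y:
        raise ValueError(f"G with {rows} rows incompatible with n_y={n_y}")
    return np.kron(np.eye(rows // n_y), sigma_y)


def woodbury_update(A_inv: np.ndarray, G: np.ndarray, sigma_y: np.ndarray) -> np.ndarray:
    """Rank-k downdate: returns (A + G^T Sigma_y^{-1} G)^{-1}.

    Only an n_y x n_y (or k n_y x k n_y) system is solved; A itself is never
    formed or factorised.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if np.allclose(G, 0):
        return A_inv.copy()
    S = _expand_cov(sigma_y, G.shape[0])
    W = A_inv @ G.T  # (n_theta, rows)
    K = S + G @ W
    cf = linalg.cho_factor(K, lower=True)
    out = A_inv - W @ linalg.cho_solve(cf, W.T)
    return 0.5 * (out + out.T)


def eig_direct(H: np.ndarray, G_list, sigma_y: np.ndarray) -> float:
    """Dense log-determinant form of the EIG; the oracle for ``eig_fast``."""
    H = np.asarray(H, dtype=float)
    sign0, logdet0 = np.linalg.slogdet(H)
    if sign0 <= 0:
        raise np.linalg.LinAlgError("H must be positive definite")
    A = H.copy()
    for G in G_list:
        G = np.atleast_2d(np.asarray(G, dtype=float))
        S = _expand_cov(sigma_y, G.shape[0])
        A += G.T @ np.linalg.solve(S, G)
    sign1, logdet1 = np.linalg.slogdet(A)
    if sign1 <= 0:
        raise np.linalg.LinAlgError("updated precision not positive definite")
    return float(logdet1 - logdet0)


def eig_fast(
    H: np.ndarray,
    G_list,
    sigma_y: np.ndarray,
    H_inv: np.ndarray | None = None,
) -> float:
    """Fast EIG as a sum of n_y-sized log-determinants with Woodbury updates.

    ``H_inv`` may be supplied to reuse the one expensive inversion of H across
    many candidate evaluations.
    """
    if H_inv is None:
        cf = linalg.cho_factor(np.asarray(H, dtype=float), lower=True)
        H_inv = linalg.cho_solve(cf, np.eye(H.shape[0]))
    A_inv = H_inv
    total = 0.0
    first = True
    for G in G_list:
        G = np.atleast_2d(np.asarray(G, dtype=float))
        S = _expand_cov(sigma_y, G.shape[0])
        M = G @ A_inv @ G.T
        sign, logdet = np.linalg.slogdet(np.eye(G.shape[0]) + np.linalg.solve(S, M))
        if sign <= 0:
            raise np.linalg.LinAlgError("EIG term not positive definite")
        total += float(logdet)
        # Woodbury update of the running inverse (copy-on-first to keep H_inv intact)
        if first:
            A_inv = A_inv.copy()
            first = False
        if not np.allclose(G, 0):
            K = S + M
            cf = linalg.cho_factor(K, lower=True)
            W = A_inv @ G.T
            A_inv -= W @ linalg.cho_solve(cf, W.T)
    return total


def fim_logdet(G_list, sigma_y: np.ndarray) -> float:
    """Log-determinant of the summed Fisher information matrix.

    Returns ``-inf`` (a documented sentinel, not an exception) when the
    stacked information matrix is rank deficient, e.g. when the total number
    of output rows is smaller than n_theta.
    """
    G_list = [np.atleast_2d(np.asarray(G, dtype=float)) for G in G_list]
    if not G_list:
        return float("-inf")
    n_theta = G_list[0].shape[1]
    if sum(G.shape[0] for G in G_list) < n_theta:
        return float("-inf")
    F = np.zeros((n_theta, n_theta))
    for G in G_list:
        S = _expand_cov(sigma_y, G.shape[0])
        F += G.T @ np.linalg.solve(S, G)
    sign, logdet = np.linalg.slogdet(F)
    if sign <= 0:
        return float("-inf")
    return float(logdet)


def acquisition_score(profit: float, eig: float, w_I: float) -> float:
    """Combined acquisition f = profit + w_I * EIG."""
    if not (np.isfinite(profit) and np.isfinite(eig) and np.isfinite(w_I)):
        raise ValueError("acquisition inputs must be finite")
    return float(profit) + float(w_I) * float(eig)


# ---------------------------------------------------------------------------
# greedy batch selection
# ---------------------------------------------------------------------------


class _EigTracker:
    """Incremental EIG of every candidate given the conditions picked so far.

    Maintains M_c = G_c A^{-1} G_c^T for all candidates, updating them after
    each pick with the Woodbury identity; A^{-1} itself is updated once per
    pick.  All candidate G blocks must share a row count R.
    """

    def __init__(self, G_stack: np.ndarray, H: np.ndarray, sigma_y: np.ndarray):
        self.G = np.asarray(G_stack, dtype=float)  # (n_c, R, n_theta)
        n_c, R, _ = self.G.shape
        self.S = _expand_cov(sigma_y, R)
        L = linalg.cholesky(self.S, lower=True)
        self._L_inv = linalg.solve_triangular(L, np.eye(R), lower=True)
        cf = linalg.cho_factor(np.asarray(H, dtype=float), lower=True)
        self.A_inv = linalg.cho_solve(cf, np.eye(H.shape[0]))
        T = (self.G.reshape(n_c * R, -1) @ self.A_inv).reshape(n_c, R, -1)
        self.M = np.matmul(T, self.G.transpose(0, 2, 1))
        self._eye = np.eye(R)

    def increments(self) -> np.ndarray:
        """ln det(I + Sigma^{-1} G_c A^{-1} G_c^T) for every candidate.

        Evaluated as sum log(1 + eig(L^{-1} M_c L^{-T})) with Sigma = L L^T,
        which is symmetric and immune to the extreme conditioning that arises
        when some noise variances sit near their floor; tiny negative
        eigenvalues from accumulated Woodbury round-off are clipped at zero.
        """
        M = 0.5 * (self.M + self.M.transpose(0, 2, 1))
        W = np.matmul(np.matmul(self._L_inv, M), self._L_inv.T)
        w = np.linalg.eigvalsh(0.5 * (W + W.transpose(0, 2, 1)))
        return np.log1p(np.maximum(w, 0.0)).sum(axis=1)

    def pick(self, idx: int) -> None:
        """Condition on candidate ``idx``: update A^{-1} and all M_c."""
        G_s = self.G[idx]
        M_s = 0.5 * (self.M[idx] + self.M[idx].T)
        K = self.S + M_s
        try:
            cf = linalg.cho_factor(K, lower=True)
        except linalg.LinAlgError:
            w, U = np.linalg.eigh(M_s)
            K = self.S + (U * np.maximum(w, 0.0)) @ U.T
            cf = linalg.cho_factor(K, lower=True)
        W = self.A_inv @ G_s.T  # (n_theta, R)
        K_inv_Wt = linalg.cho_solve(cf, W.T)
        n_c, R, _ = self.G.shape
        X = (self.G.reshape(n_c * R, -1) @ W).reshape(n_c, R, R)
        K_inv = linalg.cho_solve(cf, np.eye(R))
        self.M -= np.matmul(np.matmul(X, K_inv), X.transpose(0, 2, 1))
        self.M = 0.5 * (self.M + self.M.transpose(0, 2, 1))
        A_inv = self.A_inv - W @ K_inv_Wt
        self.A_inv = 0.5 * (A_inv + A_inv.T)


def _greedy(
    profits: np.ndarray,
    tracker: _EigTracker | None,
    config: AcquisitionConfig,
    use_profit: bool,
    use_eig: bool,
    exclude: frozenset[int] = frozenset(),
) -> Design:
    n_c = len(profits)
    eligible = np.ones(n_c, dtype=bool)  # not previously tested
    for i in exclude:
        eligible[i] = False
    novel = eligible.copy()  # eligible and not yet picked in this batch
    if int(eligible.sum()) < config.batch_size:
        raise ValueError("batch_size exceeds the number of available candidates")
    base_profit = np.where(eligible, profits, -np.inf)

    indices: list[int] = []
    records: list[dict] = []
    w_I = config.w_I_init

    for rank in range(config.batch_size):
        incs = tracker.increments() if (tracker is not None and use_eig) else None
        if rank == 0:
            # first pick: max predicted profit, or max single-condition EIG
            # when exploring without a profit term
            base = base_profit if use_profit else np.where(novel, incs, -np.inf)
            pick = int(np.argmax(base))
            inc = float(incs[pick]) if incs is not None else 0.0
            w_rec = 0.0 if use_profit else w_I
        elif not use_eig:
            # pure exploitation: profit with within-batch duplicate exclusion
            pick = int(np.argmax(np.where(novel, base_profit, -np.inf)))
            inc, w_rec = 0.0, 0.0
        elif not use_profit:
            # pure exploration: novel candidate with the largest EIG increment
            pick = int(np.argmax(np.where(novel, incs, -np.inf)))
            inc, w_rec = float(incs[pick]), w_I
        else:
            # combined acquisition: candidates already in the batch stay in
            # the argmax; w_I is escalated until a novel candidate wins
            for _ in range(config.max_escalations + 1):
                score = np.where(eligible, base_profit + w_I * incs, -np.inf)
                pick = int(np.argmax(score))
                if novel[pick]:
                    break
                w_I *= config.w_I_factor
            else:
                pick = int(np.argmax(np.where(novel, base_profit + w_I * incs, -np.inf)))
            inc, w_rec = float(incs[pick]), w_I
        indices.append(pick)
        novel[pick] = False
        records.append(
            {
                "rank": rank,
                "candidate_index": pick,
                "profit_pred": float(profits[pick]),
                "eig_increment": inc,
                "w_I": w_rec,
            }
        )
        if tracker is not None and use_eig and rank < config.batch_size - 1:
            tracker.pick(pick)
    return Design(indices=indices, records=records)


def greedy_select(
    profits: np.ndarray,
    G_stack: np.ndarray | None,
    H: np.ndarray,
    sigma_y: np.ndarray,
    config: AcquisitionConfig,
    exclude=(),
) -> Design:
    """Greedy batch selection maximising profit + w_I * incremental EIG.

    The first pick maximises predicted profit; each later pick maximises the
    acquisition with the EIG increment computed against the already-selected
    conditions.  When the maximiser is already selected, w_I is escalated
    until a novel condition wins.  Deterministic; ties break toward the lowest
    candidate index.  ``exclude`` removes previously tested candidates.
    """
    tracker = _EigTracker(G_stack, H, sigma_y) if G_stack is not None else None
    return _greedy(
        np.asarray(profits, dtype=float),
        tracker,
        config,
        use_profit=True,
        use_eig=tracker is not None,
        exclude=frozenset(int(i) for i in exclude),
    )


def strategy_scores(
    strategy: str,
    profits: np.ndarray,
    G_stack: np.ndarray | None,
    H: np.ndarray | None,
    sigma_y: np.ndarray | None,
    config: AcquisitionConfig,
    seed: int | np.random.Generator = 0,
    exclude=(),
) -> Design:
    """Select a batch under one of the four sampling strategies.

    random: seeded uniform sample without replacement; explore: greedy on the
    EIG alone; exploit: greedy on predicted profit with duplicate exclusion;
    explore_exploit: the combined acquisition of :func:`greedy_select`.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    profits = np.asarray(profits, dtype=float)
    excl = frozenset(int(i) for i in exclude)
    if strategy == "random":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        avail = [i for i in range(len(profits)) if i not in excl]
        if len(avail) < config.batch_size:
            raise ValueError("batch_size exceeds the number of available candidates")
        picks = [int(i) for i in rng.choice(avail, size=config.batch_size, replace=False)]
        records = [
            {"rank": r, "candidate_index": p, "profit_pred": float(profits[p]),
             "eig_increment": 0.0, "w_I": 0.0}
            for r, p in enumerate(picks)
        ]
        return Design(indices=picks, records=records)
    if strategy == "exploit":
        return _greedy(profits, None, config, use_profit=True, use_eig=False, exclude=excl)
    tracker = _EigTracker(G_stack, H, sigma_y)
    if strategy == "explore":
        return _greedy(profits, tracker, config, use_profit=False, use_eig=True, exclude=excl)
    return _greedy(profits, tracker, config, use_profit=True, use_eig=True, exclude=excl)
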