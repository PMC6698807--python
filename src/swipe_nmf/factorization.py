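"""Penalized non-negative tri-factorization of one heterogeneous block system.

Every present relation block is decomposed simultaneously,
``R_ij ~ G_i S_ij G_j^T``, with one non-negative membership factor ``G_i``
per segment type and one coupling factor ``S_ij`` per block, minimizing

    f(G, S) = sum_ij || R_ij - G_i S_ij G_j^T ||_F^2  +  trace(G^T Theta G)

over ``G >= 0``.  Signed constraint blocks ``Theta_ii`` reward (negative
entries) or penalize (positive entries) co-clustering of same-type segment
pairs.

The solver alternates an exact least-squares update of every ``S_ij`` with
multiplicative updates of each ``G_i``.  Because ``S`` may carry mixed signs
and ``Theta`` is signed, every term entering the multiplicative ratio is
split into positive and negative parts so numerator and denominator stay
non-negative; this is the standard scheme for penalized tri-factor data
fusion.  Monotone descent of the objective is a tested property, not an
assumption.

A purely attractive zero-diagonal ``Theta`` makes the raw objective
unbounded below: scaling ``G_i`` up while ``S`` compensates leaves every
residual unchanged but drives the trace term to minus infinity, and the
multiplicative iteration follows that ray to overflow.  The solver therefore
anchors each attractive constraint with its degree diagonal
(``L = D - W``, the graph Laplacian), turning the penalty into the
non-negative graph-smoothness form ``sum_pq w_pq ||g_p - g_q||^2`` familiar
from graph-regularized NMF.  This keeps the objective bounded and the
iteration convergent while rewarding exactly the same co-clustering;
:func:`objective` with an explicit constraint matrix still evaluates the
plain trace form.

Rank selection scans a grid of rank fractions ``k`` (each type gets rank
``max(1, round(k * n_i))``), records the reconstruction-error curve, and
picks the ``k`` at its maximum kink (largest discrete second difference,
ties to the smaller ``k``).  Final scores come from an ensemble of
independently initialized runs; the ensemble averages *reconstructions*
(``G_1 S_12 G_2^T``, ``G_1 G_1^T``, ``G_2 G_2^T``), never raw factors, which
are identifiable only up to permutation and scaling.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .core_model import FactorSet, FusionProblem, SegmentType

_EPS = 1e-12

DEFAULT_K_GRID = tuple(round(0.05 * i, 2) for i in range(1, 11))


class NumericalFailure(RuntimeError):
    """Non-finite values appeared during the alternating updates."""

    def __init__(self, message: str, iteration: int):
        super().__init__(f"{message} (iteration {iteration})")
        self.iteration = iteration


@dataclass
class FactorizationConfig:
    """Knobs of the factorization engine.

    ``k_grid`` lists candidate rank fractions; ``tol`` is the relative
    objective change below which iteration stops; ``n_ensemble`` runs with
    distinct initializations are averaged.
    """

    k_grid: Tuple[float, ...] = DEFAULT_K_GRID
    n_ensemble: int = 20
    max_iter: int = 200
    tol: float = 0.01
    min_rank: int = 1
    acol_pool: int = 5

    def __post_init__(self) -> None:
        if any(not (0 < k <= 1) for k in self.k_grid):
            raise ValueError("rank fractions must lie in (0, 1]")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")


def _pos(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _neg(x: np.ndarray) -> np.ndarray:
    return np.maximum(-x, 0.0)


def _split_sparse(m: sp.spmatrix) -> Tuple[sp.csr_matrix, sp.csr_matrix]:
    m = sp.csr_matrix(m)
    return m.maximum(0), (-m).maximum(0)


def laplacian_completed(theta: sp.spmatrix) -> sp.csr_matrix:
    """Anchor an attractive constraint with its degree diagonal.

    For the negative (must-link) part ``-W`` of ``theta`` the result adds
    ``D = diag(W 1)``, so the penalty trace(G' (theta + D) G) equals the
    non-negative graph form sum_pq w_pq ||g_p - g_q||^2 plus the original
    cannot-link terms.  Existing diagonal entries are preserved.
    """
    theta = sp.csr_matrix(theta)
    w_degrees = np.asarray((-theta).maximum(0).sum(axis=1)).ravel()
    return (theta + sp.diags(w_degrees)).tocsr()


def _effective_thetas(
    problem: FusionProblem, stabilize: bool
) -> Dict[SegmentType, sp.csr_matrix]:
    return {
        i: laplacian_completed(con.data) if stabilize else sp.csr_matrix(con.data)
        for i, con in problem.constraints.items()
    }


def init_acol(
    problem: FusionProblem,
    ranks: Dict[SegmentType, int],
    rng: np.random.Generator,
    pool: int = 5,
) -> FactorSet:
    """Random Acol initialization.

    Each column of ``G_i`` is the mean of ``pool`` randomly chosen columns of
    the horizontal concatenation of all relation blocks incident to type
    ``i`` (transposing blocks where type ``i`` indexes columns).  A type with
    no incident relation block falls back to uniform random entries in
    [0, 1).  ``S`` is then set by one exact least-squares update.
    """
    G: Dict[SegmentType, np.ndarray] = {}
    for t in sorted(ranks):
        n_i = problem.catalog.count(t)
        k_i = ranks[t]
        if not (0 < k_i <= n_i):
            raise ValueError(f"rank {k_i} invalid for type {t.name} with n={n_i}")
        blocks = []
        for (a, b), rel in sorted(problem.relations.items()):
            if a == t:
                blocks.append(rel.data)
            if b == t:
                blocks.append(rel.data.T)
        if blocks:
            columns = sp.hstack(blocks, format="csc")
            n_cols = columns.shape[1]
            p = min(pool, n_cols)
            g = np.empty((n_i, k_i))
            for c in range(k_i):
                chosen = rng.choice(n_cols, size=p, replace=False)
                g[:, c] = np.asarray(columns[:, chosen].mean(axis=1)).ravel()
        else:
            g = rng.random((n_i, k_i))
        G[t] = g
    S = _update_s(problem, G)
    return FactorSet(G=G, S=S, ranks=dict(ranks))


def _update_s(
    problem: FusionProblem, G: Dict[SegmentType, np.ndarray]
) -> Dict[Tuple[SegmentType, SegmentType], np.ndarray]:
    """Exact least-squares S given G: S_ij = (Gi'Gi)^+ Gi' R_ij Gj (Gj'Gj)^+."""
    S: Dict[Tuple[SegmentType, SegmentType], np.ndarray] = {}
    pinv_cache: Dict[SegmentType, np.ndarray] = {}

    def pinv_gram(t: SegmentType) -> np.ndarray:
        if t not in pinv_cache:
            g = G[t]
            pinv_cache[t] = np.linalg.pinv(g.T @ g)
        return pinv_cache[t]

    for (i, j), rel in problem.relations.items():
        gi, gj = G[i], G[j]
        middle = gi.T @ (rel.data @ gj)
        S[(i, j)] = pinv_gram(i) @ middle @ pinv_gram(j)
    return S


def objective(
    problem: FusionProblem,
    factors: FactorSet,
    thetas: Optional[Dict[SegmentType, sp.csr_matrix]] = None,
) -> float:
    """Squared Frobenius residual over present R blocks plus the trace penalty.

    ``thetas`` optionally substitutes constraint matrices (the solver passes
    Laplacian-completed ones); by default the problem's own are used.
    """
    if thetas is None:
        thetas = {i: con.data for i, con in problem.constraints.items()}
    total = 0.0
    for (i, j), rel in problem.relations.items():
        approx = factors.G[i] @ factors.S[(i, j)] @ factors.G[j].T
        resid = rel.data.toarray() - approx
        total += float(np.sum(resid * resid))
    for i, theta in thetas.items():
        g = factors.G[i]
        coo = sp.coo_matrix(theta)
        # trace(G' Theta G) = sum_pq theta_pq <g_p, g_q>
        total += float(
            np.sum(coo.data * np.einsum("ij,ij->i", g[coo.row], g[coo.col]))
        )
    return total


def reconstruction_error(problem: FusionProblem, factors: FactorSet) -> float:
    """Residual term only (no trace penalty); used for rank selection."""
    total = 0.0
    for (i, j), rel in problem.relations.items():
        approx = factors.G[i] @ factors.S[(i, j)] @ factors.G[j].T
        resid = rel.data.toarray() - approx
        total += float(np.sum(resid * resid))
    return total


def update_step(
    problem: FusionProblem,
    factors: FactorSet,
    iteration: int = 0,
    thetas: Optional[Dict[SegmentType, sp.csr_matrix]] = None,
) -> FactorSet:
    """One alternating sweep: multiplicative G updates, then exact S update.

    G updates are Gauss-Seidel (each type sees the freshest other factors).
    Ratio entries with zero numerator and denominator are set to 0, and
    denominators are floored at 1e-12.
    """
    if thetas is None:
        thetas = {i: con.data for i, con in problem.constraints.items()}
    G = {t: g.copy() for t, g in factors.G.items()}
    S = factors.S
    for t in sorted(G):
        num = np.zeros_like(G[t])
        den = np.zeros_like(G[t])
        for (a, b), rel in problem.relations.items():
            if a == t:
                s = S[(a, b)]
                lin = rel.data @ (G[b] @ s.T)
                num += _pos(lin)
                den += _neg(lin)
                quad = s @ (G[b].T @ G[b]) @ s.T
                num += G[t] @ _neg(quad)
                den += G[t] @ _pos(quad)
            if b == t:
                s = S[(a, b)]
                lin = rel.data.T @ (G[a] @ s)
                num += _pos(lin)
                den += _neg(lin)
                quad = s.T @ (G[a].T @ G[a]) @ s
                num += G[t] @ _neg(quad)
                den += G[t] @ _pos(quad)
        theta = thetas.get(t)
        if theta is not None:
            theta_pos, theta_neg = _split_sparse(theta)
            num += theta_neg @ G[t]
            den += theta_pos @ G[t]
        ratio = np.where(
            (num == 0.0) & (den == 0.0), 0.0, num / np.maximum(den, _EPS)
        )
        G[t] = G[t] * np.sqrt(ratio)
        if not np.all(np.isfinite(G[t])):
            raise NumericalFailure(
                f"non-finite values in G for type {t.name}", iteration
            )
    S_new = _update_s(problem, G)
    for key, s in S_new.items():
        if not np.all(np.isfinite(s)):
            raise NumericalFailure(f"non-finite values in S for block {key}", iteration)
    return FactorSet(
        G=G, S=S_new, ranks=dict(factors.ranks),
        objective_trace=list(factors.objective_trace),
        initial_objective=factors.initial_objective,
    )


def factorize(
    problem: FusionProblem,
    ranks: Dict[SegmentType, int],
    config: FactorizationConfig,
    rng: np.random.Generator,
    stabilize: bool = True,
) -> FactorSet:
    """Run alternating updates until the relative objective change falls
    below ``config.tol`` or ``config.max_iter`` iterations are reached.

    With ``stabilize`` (the default) attractive constraints are anchored
    with their Laplacian degree diagonal so the minimized objective is
    bounded below; the recorded trace is of the objective being minimized.
    """
    thetas = _effective_thetas(problem, stabilize)
    factors = init_acol(problem, ranks, rng, pool=config.acol_pool)
    f_prev = objective(problem, factors, thetas)
    factors.initial_objective = f_prev
    for it in range(config.max_iter):
        factors = update_step(problem, factors, iteration=it, thetas=thetas)
        f_cur = objective(problem, factors, thetas)
        factors.objective_trace.append(f_cur)
        if abs(f_cur - f_prev) < config.tol * max(1.0, abs(f_prev)):
            break
        f_prev = f_cur
    return factors


def factorize_best(
    problem: FusionProblem,
    ranks: Dict[SegmentType, int],
    config: FactorizationConfig,
    seed: int = 0,
    n_restarts: Optional[int] = None,
) -> FactorSet:
    """Best (lowest final objective) of ``n_restarts`` independently
    initialized runs — multiplicative updates are local, and restarting is
    the method's own answer to local minima (defaults to the ensemble size)."""
    if n_restarts is None:
        n_restarts = config.n_ensemble
    best: Optional[FactorSet] = None
    best_f = np.inf
    for member in range(n_restarts):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, member])
        factors = factorize(problem, ranks, config, rng)
        f = factors.objective_trace[-1] if factors.objective_trace else factors.initial_objective
        if f < best_f:
            best, best_f = factors, f
    assert best is not None
    return best


def ranks_for_fraction(
    problem: FusionProblem, k: float, types: Sequence[SegmentType],
    min_rank: int = 1,
) -> Dict[SegmentType, int]:
    """Per-type integer ranks ``max(min_rank, round(k * n_i))``, capped at n_i."""
    out = {}
    for t in types:
        n = problem.catalog.count(t)
        out[t] = max(min_rank, min(n, int(round(k * n))))
    return out


def select_rank(
    problem: FusionProblem,
    config: FactorizationConfig,
    rng_seed: int,
) -> Tuple[float, List[float]]:
    """Pick the rank fraction at the maximum kink of the error curve.

    Each grid point is evaluated with a single factorization run started from
    the same seed, recording the residual reconstruction error.  The selected
    ``k*`` maximizes the discrete second difference ``e[t-1] - 2 e[t] +
    e[t+1]`` over interior grid points; ties break to the smaller ``k``.
    """
    grid = sorted(config.k_grid)
    if len(grid) < 3:
        raise ValueError("rank-fraction grid needs at least 3 points")
    types = problem.types_present()
    errors: List[float] = []
    for k in grid:
        ranks = ranks_for_fraction(problem, k, types, config.min_rank)
        rng = np.random.default_rng(rng_seed)
        factors = factorize(problem, ranks, config, rng)
        errors.append(reconstruction_error(problem, factors))
    return grid[max_kink_index(errors)], errors


def max_kink_index(errors: Sequence[float]) -> int:
    """Interior index maximizing the discrete second difference
    ``e[t-1] - 2 e[t] + e[t+1]``; ties break to the smaller index."""
    if len(errors) < 3:
        raise ValueError("kink selection needs at least 3 curve points")
    best_t, best_curv = None, -np.inf
    for t in range(1, len(errors) - 1):
        curv = errors[t - 1] - 2 * errors[t] + errors[t + 1]
        if curv > best_curv + 1e-15:
            best_t, best_curv = t, curv
    return best_t


def stable_key(*parts) -> int:
    """Deterministic 31-bit key from strings/ints, for seed derivation."""
    h = 0
    for part in parts:
        h = zlib.crc32(str(part).encode(), h)
    return h & 0x7FFFFFFF


@dataclass
class EnsembleResult:
    """Averaged reconstructions over the ensemble members."""

    ep: Optional[np.ndarray]
    ee: Optional[np.ndarray]
    pp: Optional[np.ndarray]
    ranks: Dict[SegmentType, int]
    member_objectives: List[float]
    n_members: int


def _reconstruct_pair(
    factors: FactorSet, i: SegmentType, j: SegmentType
) -> Optional[np.ndarray]:
    if (i, j) in factors.S:
        return factors.G[i] @ factors.S[(i, j)] @ factors.G[j].T
    if (j, i) in factors.S:
        return (factors.G[j] @ factors.S[(j, i)] @ factors.G[i].T).T
    return None


def ensemble_factorize(
    problem: FusionProblem,
    ranks: Dict[SegmentType, int],
    config: FactorizationConfig,
    seed: int,
    window_key: int = 0,
) -> EnsembleResult:
    """Average reconstructed outputs over ``config.n_ensemble`` seeded runs.

    Member seeds are derived from (seed, window_key, member index) so results
    are reproducible and independent of processing order.  Members that fail
    numerically are dropped; if fewer than half survive (or none), that is an
    error.
    """
    EN, PR = SegmentType.ENHANCER, SegmentType.PROMOTER
    ep_sum = ee_sum = pp_sum = None
    objectives: List[float] = []
    n_ok = 0
    failures = 0
    for member in range(config.n_ensemble):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, window_key, member])
        try:
            factors = factorize(problem, ranks, config, rng)
        except NumericalFailure:
            failures += 1
            continue
        n_ok += 1
        objectives.append(
            factors.objective_trace[-1]
            if factors.objective_trace
            else factors.initial_objective
        )
        ep = _reconstruct_pair(factors, EN, PR)
        ee = factors.G[EN] @ factors.G[EN].T if EN in factors.G else None
        pp = factors.G[PR] @ factors.G[PR].T if PR in factors.G else None
        if ep is not None:
            ep_sum = ep if ep_sum is None else ep_sum + ep
        if ee is not None:
            ee_sum = ee if ee_sum is None else ee_sum + ee
        if pp is not None:
            pp_sum = pp if pp_sum is None else pp_sum + pp
    if n_ok == 0:
        raise NumericalFailure("all ensemble members failed", config.max_iter)
    if failures and n_ok < config.n_ensemble / 2:
        raise NumericalFailure(
            f"only {n_ok}/{config.n_ensemble} ensemble members survived",
            config.max_iter,
        )
    if failures:
        warnings.warn(
            f"{failures}/{config.n_ensemble} ensemble members failed; "
            "averaging the survivors"
        )
    return EnsembleResult(
        ep=None if ep_sum is None else ep_sum / n_ok,
        ee=None if ee_sum is None else ee_sum / n_ok,
        pp=None if pp_sum is None else pp_sum / n_ok,
        ranks=dict(ranks),
        member_objectives=objectives,
        n_members=n_ok,
    )
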