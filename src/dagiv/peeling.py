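"""Peeling: recover the ancestral relation graph from the reduced form.

A primary variable is a leaf (no children) exactly when some instrument's
row of V has its sole nonzero at that variable's column.  The algorithm
repeatedly identifies all current leaves with their instruments, links each
leaf to the previously peeled columns its instruments all load on, removes
the leaves, and recurses on the remaining columns.  The collected edges
determine the ancestral relations up to transitive closure; candidate
intervention edges attach X_l to Y_j whenever V loads X_l on Y_j or on any
estimated ancestor of Y_j.

Peeling is a pure function of the estimated V -- it never touches Y or X.
When no single-nonzero row exists the everyone-instrumented condition is
violated and a ``NoLeafFoundError`` is raised (an opt-in greedy fallback
picks the row whose second-largest magnitude is smallest and treats the
smaller entries as zero; it is always logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .graph import AncestralRelationGraph, transitive_closure
from .simulate import DataSet
from .sparse_regression import TuningConfig, default_gamma_grid, default_tau

logger = logging.getLogger(__name__)

__all__ = [
    "NoLeafFoundError",
    "PeelingTrace",
    "find_leaf_instruments",
    "peel",
    "estimate_coefficients",
]


class NoLeafFoundError(RuntimeError):
    """No row of V has a single nonzero among the active columns."""

    def __init__(self, active_cols):
        self.active_cols = sorted(active_cols)
        super().__init__(
            "no leaf found among active columns "
            f"{self.active_cols}: some primary variable lacks an instrument "
            "(observational data W = 0 always ends here)"
        )


@dataclass(frozen=True)
class PeelingTrace:
    """Per-round leaves with their instruments, and the induced order.

    ``rounds[r]`` maps each leaf found in round r to its instrument rows;
    ``peel_order`` lists variables leaves-first (a reverse topological
    order of the estimated graph).
    """

    rounds: tuple[dict[int, frozenset[int]], ...]
    peel_order: tuple[int, ...]

    def __post_init__(self) -> None:
        seen: list[int] = []
        for rnd in self.rounds:
            for leaf, instruments in rnd.items():
                seen.append(leaf)
                if len(instruments) == 0:
                    raise ValueError(f"leaf {leaf} recorded without instruments")
        if sorted(seen) != sorted(set(seen)) or tuple(seen) != self.peel_order:
            raise ValueError("inconsistent peeling trace")


def find_leaf_instruments(
    V_hat: np.ndarray, active_cols: set[int]
) -> dict[int, set[int]]:
    """Columns holding the sole nonzero of some row, restricted to active.

    Returns {leaf column j: {rows l with their single nonzero at j}}, all
    1-based.  Empty result means no identifiable leaf.
    """
    if not active_cols:
        raise ValueError("active_cols must be non-empty")
    act = np.array(sorted(active_cols)) - 1
    sub = V_hat[:, act] != 0
    counts = sub.sum(axis=1)
    leaves: dict[int, set[int]] = {}
    for l in np.nonzero(counts == 1)[0]:
        j = int(act[np.nonzero(sub[l])[0][0]]) + 1
        leaves.setdefault(j, set()).add(int(l) + 1)
    return leaves


def peel(
    V_hat: np.ndarray, *, greedy_fallback: bool = False
) -> tuple[AncestralRelationGraph, PeelingTrace]:
    """Reconstruct the ancestral relation graph from V.

    Iterates leaf identification and removal; a leaf k links to a
    previously peeled column j iff every instrument row of k loads on j.
    The ancestral set is the transitive closure of the collected links.
    """
    V_hat = np.asarray(V_hat, float)
    q, p = V_hat.shape
    if p < 1:
        raise ValueError("V_hat needs at least one column")
    active = set(range(1, p + 1))
    peeled: list[int] = []
    rounds: list[dict[int, frozenset[int]]] = []
    edges: set[tuple[int, int]] = set()
    while active:
        leaves = find_leaf_instruments(V_hat, active)
        if not leaves:
            if not greedy_fallback:
                raise NoLeafFoundError(active)
            leaves = _greedy_leaf(V_hat, active)
        rnd: dict[int, frozenset[int]] = {}
        for k in sorted(leaves):
            instruments = leaves[k]
            rnd[k] = frozenset(instruments)
            for j in peeled:
                if all(V_hat[l - 1, j - 1] != 0 for l in instruments):
                    edges.add((k, j))
        # leaves of one round are peeled simultaneously, ascending order
        for k in sorted(rnd):
            peeled.append(k)
            active.discard(k)
        rounds.append(rnd)
    closure = transitive_closure(edges, p)
    anc = {j: {k for k, jj in closure if jj == j} for j in range(1, p + 1)}
    cand: set[tuple[int, int]] = set()
    nz_rows = {j: set(np.nonzero(V_hat[:, j - 1])[0] + 1) for j in range(1, p + 1)}
    for j in range(1, p + 1):
        for k in anc[j] | {j}:
            for l in nz_rows[k]:
                cand.add((int(l), j))
    arg = AncestralRelationGraph(p, q, frozenset(closure), frozenset(cand))
    return arg, PeelingTrace(tuple(rounds), tuple(peeled))


def _greedy_leaf(V_hat: np.ndarray, active: set[int]) -> dict[int, set[int]]:
    """Fallback leaf pick: row with the smallest second-largest magnitude."""
    act = np.array(sorted(active)) - 1
    sub = np.abs(V_hat[:, act])
    rows = np.nonzero(sub.sum(axis=1) > 0)[0]
    if rows.size == 0:
        raise NoLeafFoundError(active)
    second = np.sort(sub[rows], axis=1)[:, -2] if len(act) > 1 else np.zeros(rows.size)
    l = rows[int(np.argmin(second))]
    j = int(act[int(np.argmax(sub[l]))]) + 1
    logger.warning(
        "greedy fallback: treating row %d as instrument of column %d "
        "(second-largest |entry| %.3g set to zero)", l + 1, j, float(np.min(second))
    )
    return {j: {int(l) + 1}}


def estimate_coefficients(
    data: DataSet,
    arg: AncestralRelationGraph,
    kappa_prime: int | dict[int, int] | None = None,
    config: TuningConfig | None = None,
    kappa_prime_grid: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> tuple[np.ndarray, np.ndarray, dict[int, int | None]]:
    """Estimate (U, W) column-wise given the ancestral relation graph.

    For each node j, Y_j is regressed on its estimated ancestors (sparsity
    at most kappa'_j, via the same DC machinery; the intervention columns
    are never penalized) and its candidate interventions.  Entries outside
    the graph are exactly zero.  When ``kappa_prime`` is None the per-node
    bound is chosen by BIC over ``kappa_prime_grid``; the chosen value is
    returned per node (None for nodes without ancestor candidates).
    """
    config = config or TuningConfig()
    Y, X, n = data.Y, data.X, data.n
    p, q = arg.p, arg.q
    U_hat = np.zeros((p, p))
    W_hat = np.zeros((q, p))
    chosen: dict[int, int | None] = {}
    for j in range(1, p + 1):
        an = sorted(arg.ancestors(j))
        inset = sorted(arg.candidate_interventions(j))
        y = Y[:, j - 1]
        Z = np.column_stack(
            [Y[:, [k - 1 for k in an]].reshape(n, -1), X[:, [l - 1 for l in inset]].reshape(n, -1)]
        )
        n_an, n_in = len(an), len(inset)
        if Z.shape[1] >= n:
            raise ValueError(
                f"node {j}: {Z.shape[1]} regressors for {n} samples; "
                "the candidate sets exceed the sample size"
            )
        if n_an == 0:
            chosen[j] = None
            if n_in:
                beta = np.linalg.lstsq(Z, y, rcond=None)[0]
                W_hat[[l - 1 for l in inset], j - 1] = beta
            continue
        G, c, yty = Z.T @ Z, Z.T @ y, float(y @ y)
        tau = default_tau(y, n, max(q, 2), config.tau_scale)
        gg = default_gamma_grid(c[:n_an] if n_an else c, n, tau,
                                config.n_gammas, config.gamma_min_ratio)
        max_iter = config.resolved_max_dc_iter(n_an)
        if kappa_prime is not None:
            kp = kappa_prime[j] if isinstance(kappa_prime, dict) else int(kappa_prime)
            kp = min(kp, n_an)
            fit = _dc_penalized_subset(G, c, yty, n, kp, tau, gg, config.tol, max_iter, n_an)
            chosen[j] = kp
        else:
            best = None
            cache: dict[int, tuple] = {}
            for g in sorted(set(kappa_prime_grid)):
                kp = min(g, n_an)
                if kp not in cache:
                    cache[kp] = _dc_penalized_subset(
                        G, c, yty, n, kp, tau, gg, config.tol, max_iter, n_an
                    )
                cand = cache[kp]
                bic = n * math.log(max(cand[1], 1e-300) / n) + kp * math.log(n)
                # recorded choice is the grid value; ties go to the smaller
                if best is None or bic < best[0] - 1e-9:
                    best = (bic, cand, g)
            fit, chosen[j] = best[1], best[2]
        beta, _ = fit
        for i, k in enumerate(an):
            U_hat[k - 1, j - 1] = beta[i]
        for i, l in enumerate(inset):
            W_hat[l - 1, j - 1] = beta[n_an + i]
    return U_hat, W_hat, chosen


def _dc_penalized_subset(G, c, yty, n, kappa, tau, gamma_grid, tol, max_dc_iter, n_pen):
    """DC/L0 where only the first ``n_pen`` coordinates are penalized.

    Runs the same DC iterations with the penalty weights forced to zero on
    the unpenalized block, projects only the penalized block, and refits
    OLS on the selected-plus-unpenalized columns.  Returns (beta, RSS) with
    beta over all columns of G.
    """
    from ._cd import cd_weighted_lasso
    from .sparse_regression import _ols_refit, l0_project

    d = G.shape[0]
    free = np.arange(n_pen, d)
    best = None
    v = np.zeros(d)
    for gamma in gamma_grid:
        lam = n * gamma * tau
        for _ in range(max_dc_iter):
            w = (np.abs(v) <= tau).astype(float)
            w[free] = 0.0
            v_new = v.copy()
            cd_weighted_lasso(G, c, lam, w, v_new, 2000, 1e-12)
            change = float(np.max(np.abs(v_new - v))) if d else 0.0
            v = v_new
            if change <= tol:
                break
        pen_part = v[:n_pen]
        if np.count_nonzero(pen_part) > kappa:
            pen_part = l0_project(pen_part, kappa)
        support = np.concatenate([np.nonzero(pen_part)[0], free]).astype(int)
        beta_s, rss = _ols_refit(G, c, yty, support, n)
        nnz = int(np.count_nonzero(pen_part))
        bic = n * math.log(max(rss, 1e-300) / n) + nnz * math.log(n)
        if best is None or bic < best[0] - 1e-12:
            beta = np.zeros(d)
            beta[support] = beta_s
            best = (bic, (beta, rss))
    return best[1]
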