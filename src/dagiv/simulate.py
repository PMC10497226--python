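"""Seeded synthetic data for the interventional Gaussian SEM.

Data follow the linear structural equation model

    Y = U^T Y + W^T X + eps,   eps ~ N(0, Diag(sigma_1^2 .. sigma_p^2)),

with U (p x p) the directed effects among primary variables (acyclic
support), W (q x p) the intervention effects, and X drawn from a Gaussian
with AR(0.5) covariance by default.  The standard benchmark designs are
provided: random upper-triangular Bernoulli(1/p) graphs, hub graphs, and
three intervention layouts --

* Setup A: each Y_j has its own instrument X_j, plus p-1 two-target
  invalid instruments and inactive interventions (everyone instrumented);
* Setup B: only Y_p retains a valid instrument (the everyone-instrumented
  condition fails);
* Setup C: W = (I, 0)^T, instruments only.

All randomness flows through a single integer seed via independent
``numpy`` SeedSequence substreams, so adding a consumer never shifts
earlier draws and every dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import InterventionDAG, topological_order

__all__ = [
    "SEMParameters",
    "DataSet",
    "random_graph_U",
    "hub_graph_U",
    "intervention_W",
    "default_sigma2",
    "ar_covariance",
    "sample_dataset",
    "implied_V",
    "substream",
]

# substream ids: keep draw order stable when consumers are added
_STREAM_X = 0
_STREAM_EPS = 1
STREAM_PERTURB = 3


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for (seed, key...) -- counter-style seeding."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def random_graph_U(p: int, seed: int, weight: float = 1.0) -> np.ndarray:
    """Random sparse DAG: upper off-diagonal entries iid Bernoulli(1/p).

    Edge weights default to 1; ``weight`` rescales every edge, which is how
    weak-signal alternatives are realized in the power studies.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = substream(seed, 7)
    U = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    U[iu] = (rng.random(len(iu[0])) < 1.0 / p) * weight
    return U


def hub_graph_U(p: int, weight: float = 1.0) -> np.ndarray:
    """Hub DAG: node 1 points to odd nodes 3,5,..., node 2 to even 4,6,...

    Edges are U[1, 2j+1] = U[2, 2j+2] = 1 for j = 1 .. floor(p/2) - 2
    (1-based), so nodes 1 and 2 have dense out-neighborhoods.
    """
    nedges = p // 2 - 2
    if p < 6 or nedges < 1:
        raise ValueError("hub graph needs p >= 6")
    U = np.zeros((p, p))
    for j in range(1, nedges + 1):
        U[0, 2 * j] = weight      # 1 -> 2j+1
        U[1, 2 * j + 1] = weight  # 2 -> 2j+2
    return U


def intervention_W(setup: str, p: int, q: int) -> np.ndarray:
    """Intervention coefficient matrix for Setup A, B or C.

    W stacks [A; B; 0] with A, B p x p.  Setup A: A = I, B_jj = B_j,j+1 = 1
    for j < p.  Setup B additionally sets A_j,j+1 = 1 for j < p, destroying
    all instruments except X_p.  Setup C: W = (I, 0)^T.
    """
    setup = setup.upper()
    if setup in ("A", "B"):
        if q < 2 * p:
            raise ValueError(f"setup {setup} needs q >= 2p, got q={q}, p={p}")
        A = np.eye(p)
        B = np.zeros((p, p))
        for j in range(p - 1):
            B[j, j] = 1.0
            B[j, j + 1] = 1.0
            if setup == "B":
                A[j, j + 1] = 1.0
        W = np.zeros((q, p))
        W[:p] = A
        W[p : 2 * p] = B
        return W
    if setup == "C":
        if q < p:
            raise ValueError(f"setup C needs q >= p, got q={q}, p={p}")
        W = np.zeros((q, p))
        W[:p] = np.eye(p)
        return W
    raise ValueError(f"unknown setup {setup!r}")


def default_sigma2(p: int) -> np.ndarray:
    """Error variances equally spaced from 0.5 to 1 (0.5 when p = 1)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if p == 1:
        return np.array([0.5])
    return np.linspace(0.5, 1.0, p)


def ar_covariance(q: int, rho: float = 0.5) -> np.ndarray:
    idx = np.arange(q)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class SEMParameters:
    """(U, W, sigma^2) of the interventional SEM, with derived quantities."""

    U: np.ndarray
    W: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, float)
        W = np.asarray(self.W, float)
        s2 = np.asarray(self.sigma2, float)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "sigma2", s2)
        p = U.shape[0]
        if U.shape != (p, p):
            raise ValueError("U must be square")
        if W.shape[1] != p:
            raise ValueError("W must be q x p")
        if s2.shape != (p,) or np.any(s2 <= 0):
            raise ValueError("sigma2 must be a length-p positive vector")
        if self.topological_order() is None:
            raise ValueError("support of U contains a directed cycle")

    @property
    def p(self) -> int:
        return self.U.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[0]

    def topological_order(self) -> list[int] | None:
        edges = {(int(k) + 1, int(j) + 1) for k, j in zip(*np.nonzero(self.U))}
        return topological_order(edges, self.p)

    def dag(self) -> InterventionDAG:
        pe = {(int(k) + 1, int(j) + 1) for k, j in zip(*np.nonzero(self.U))}
        ie = {(int(l) + 1, int(j) + 1) for l, j in zip(*np.nonzero(self.W))}
        return InterventionDAG(self.p, self.q, frozenset(pe), frozenset(ie))

    def omega(self) -> np.ndarray:
        """Precision of the reduced-form errors: (I-U) Sigma^-1 (I-U^T)."""
        I = np.eye(self.p)
        return (I - self.U) @ np.diag(1.0 / self.sigma2) @ (I - self.U.T)


def implied_V(params: SEMParameters) -> np.ndarray:
    """Reduced-form coefficient matrix V = W (I - U)^{-1}.

    Solved along a topological order (back-substitution on the permuted
    triangular system), never by explicit inversion.  V_.j's support is the
    set of interventions acting on Y_j or any of its ancestors, barring
    exact path cancellation.
    """
    order = params.topological_order()
    assert order is not None
    perm = np.array(order) - 1
    p, U, W = params.p, params.U, params.W
    # In topological order, I - U becomes upper triangular: solve V (I-U) = W
    # column by column: V_.j = W_.j + sum_{k in PA(j)} U_kj V_.k
    V = np.zeros_like(W)
    for j in perm:
        V[:, j] = W[:, j]
        parents = np.nonzero(U[:, j])[0]
        for k in parents:
            V[:, j] = V[:, j] + U[k, j] * V[:, k]
    return V


@dataclass(frozen=True)
class DataSet:
    """n observations of the p primary and q intervention variables."""

    Y: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, float)
        X = np.asarray(self.X, float)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "X", X)
        if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
            raise ValueError("Y and X must be 2-d with equal row counts")
        if not (np.isfinite(Y).all() and np.isfinite(X).all()):
            raise ValueError("Y and X must be finite (no missing values)")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def q(self) -> int:
        return self.X.shape[1]


def sample_dataset(
    params: SEMParameters,
    n: int,
    seed: int,
    x_cov: np.ndarray | None = None,
) -> tuple[DataSet, np.ndarray]:
    """Draw (Y, X) from the SEM; also return the error matrix for oracles.

    X rows are iid N(0, x_cov) (default AR(0.5)); errors are iid
    N(0, Diag(sigma^2)); Y is solved exactly along a topological order:
    Y_j = sum_k U_kj Y_k + (X W)_j + eps_j.
    """
    if x_cov is None:
        x_cov = ar_covariance(params.q)
    x_cov = np.asarray(x_cov, float)
    try:
        chol = np.linalg.cholesky(x_cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("x_cov must be positive definite") from exc
    X = substream(seed, _STREAM_X).standard_normal((n, params.q)) @ chol.T
    e = substream(seed, _STREAM_EPS).standard_normal((n, params.p)) * np.sqrt(
        params.sigma2
    )
    drive = X @ params.W + e
    Y = np.zeros((n, params.p))
    order = params.topological_order()
    assert order is not None
    for j1 in order:
        j = j1 - 1
        Y[:, j] = drive[:, j]
        for k in np.nonzero(params.U[:, j])[0]:
            Y[:, j] += params.U[k, j] * Y[:, k]
    return DataSet(Y, X), e
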