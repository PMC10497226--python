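"""Monte-Carlo harness: rejection-rate curves, SHD, BIC-selection tables.

Each scenario fixes a graph kind (random or hub), an intervention layout
(Setup A/B/C), dimensions, a grid of sample sizes and hypothesized-edge
signal strengths, and the test method(s).  Replicates are independently
seeded from the scenario seed, so results are invariant to the number of
worker processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .graph import HypothesisSpec
from .inference import test_edges, test_pathway
from .peeling import NoLeafFoundError, estimate_coefficients, peel
from .simulate import (
    SEMParameters,
    default_sigma2,
    hub_graph_U,
    intervention_W,
    random_graph_U,
    sample_dataset,
)
from .sparse_regression import TuningConfig, fit_V

__all__ = ["ScenarioSpec", "MonteCarloResult", "shd", "rejection_rate", "selection_frequency"]


def shd(U_hat: np.ndarray, U_true: np.ndarray) -> int:
    """Structural Hamming distance: count of support disagreements."""
    U_hat = np.asarray(U_hat)
    U_true = np.asarray(U_true)
    if U_hat.shape != U_true.shape:
        raise ValueError(f"shape mismatch {U_hat.shape} vs {U_true.shape}")
    return int(np.sum((U_hat != 0) != (U_true != 0)))


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario cell grid.

    ``signal_grid`` holds the common coefficient placed on every
    hypothesized edge (0 encodes the null); ``hypothesis`` names the edges
    under test.
    """

    p: int
    q: int
    graph: str = "random"            # random | hub
    setup: str = "A"                 # A | B | C
    n_grid: tuple[int, ...] = (500,)
    signal_grid: tuple[float, ...] = (0.0,)
    hypothesis: HypothesisSpec = field(
        default_factory=lambda: HypothesisSpec(((1, 2),))
    )
    methods: tuple[str, ...] = ("dp",)
    replicates: int = 200
    M: int = 200
    alpha: float = 0.05
    seed: int = 0
    tuning: TuningConfig | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0) and self.alpha != 1.0:
            raise ValueError("alpha must be in (0, 1] ")
        if min(self.p, self.q, self.replicates, self.M, *self.n_grid) < 1:
            raise ValueError("all counts must be positive")


@dataclass(frozen=True)
class MonteCarloResult:
    """Tidy per-replicate records plus a per-cell summary."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby(["n", "signal", "method"], as_index=False).agg(
            rate=("reject", "mean"), replicates=("reject", "size")
        )
        g["se"] = np.sqrt(g["rate"] * (1 - g["rate"]) / g["replicates"])
        return g


def _truth(spec: ScenarioSpec, signal: float, rep_seed: int) -> SEMParameters:
    if spec.graph == "random":
        U = random_graph_U(spec.p, rep_seed)
    elif spec.graph == "hub":
        U = hub_graph_U(spec.p)
    else:
        raise ValueError(f"unknown graph kind {spec.graph!r}")
    for k, j in spec.hypothesis.edges:
        U[k - 1, j - 1] = signal
    W = intervention_W(spec.setup, spec.p, spec.q)
    return SEMParameters(U, W, default_sigma2(spec.p))


def _one_rejection_cell(spec: ScenarioSpec, n: int, signal: float, r: int):
    rep_seed = int(np.random.SeedSequence(spec.seed, spawn_key=(n, r)).generate_state(1)[0] % (2**31))
    params = _truth(spec, signal, rep_seed)
    data, _ = sample_dataset(params, n, rep_seed)
    rows = []
    for method in spec.methods:
        try:
            if spec.hypothesis.mode == "pathway":
                rep = test_pathway(data, spec.hypothesis, M=spec.M,
                                   seed=rep_seed, config=spec.tuning)
            else:
                rep = test_edges(
                    data, spec.hypothesis, M=spec.M, alpha=spec.alpha,
                    seed=rep_seed, method=method, config=spec.tuning,
                    oracle_graph=params.dag() if method == "oracle" else None,
                )
            rows.append({"n": n, "signal": signal, "method": method, "rep": r,
                         "pvalue": rep.pvalue, "reject": rep.pvalue < spec.alpha,
                         "error": ""})
        except (NoLeafFoundError, RuntimeError) as exc:  # reported, not fatal
            rows.append({"n": n, "signal": signal, "method": method, "rep": r,
                         "pvalue": np.nan, "reject": False, "error": str(exc)})
    return rows


def rejection_rate(spec: ScenarioSpec, n_jobs: int = 1) -> MonteCarloResult:
    """Empirical rejection rate of the configured test per scenario cell."""
    tasks = [
        (n, signal, r)
        for n in spec.n_grid
        for signal in spec.signal_grid
        for r in range(spec.replicates)
    ]
    chunks = Parallel(n_jobs=n_jobs)(
        delayed(_one_rejection_cell)(spec, n, s, r) for n, s, r in tasks
    )
    records = pd.DataFrame([row for chunk in chunks for row in chunk])
    return MonteCarloResult(records)


def selection_frequency(
    spec: ScenarioSpec, kappa_grid: tuple[int, ...] = (1, 2, 3, 4, 5), n_jobs: int = 1
) -> pd.DataFrame:
    """Frequency of the per-node BIC choice of the coefficient-step sparsity.

    For each replicate the structure is learned, the coefficient step runs
    with its per-node sparsity bound chosen by BIC over ``kappa_grid``
    (nodes without ancestor candidates make no choice), and the modal
    per-node choice is recorded.  Returns one row per grid value with its
    modal frequency across replicates and a binomial standard error, plus
    the pooled per-node frequencies.
    """
    def one(r: int):
        rep_seed = int(np.random.SeedSequence(spec.seed, spawn_key=(11, r)).generate_state(1)[0] % (2**31))
        params = _truth(spec, 0.0, rep_seed)
        data, _ = sample_dataset(params, spec.n_grid[0], rep_seed)
        fit = fit_V(data, spec.tuning or TuningConfig())
        arg, _ = peel(fit.V_hat, greedy_fallback=True)
        _, _, chosen = estimate_coefficients(data, arg, kappa_prime=None,
                                             kappa_prime_grid=kappa_grid)
        choices = [v for v in chosen.values() if v is not None]
        if not choices:
            return None, []
        vals, counts = np.unique(choices, return_counts=True)
        modal = int(vals[np.argmax(counts)])  # argmax ties -> smaller value
        return modal, choices

    out = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(spec.replicates))
    modal = [m for m, _ in out if m is not None]
    pooled = [c for _, cs in out for c in cs]
    rows = []
    R = len(modal)
    for k in sorted(set(kappa_grid)):
        f = float(np.mean([m == k for m in modal])) if R else np.nan
        rows.append({
            "kappa": k,
            "modal_frequency": f,
            "modal_se": float(np.sqrt(f * (1 - f) / R)) if R else np.nan,
            "node_frequency": float(np.mean([c == k for c in pooled])) if pooled else np.nan,
            "replicates": R,
        })
    return pd.DataFrame(rows)
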