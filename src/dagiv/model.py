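"""Model/Results facade over the learning and inference machinery.

``InterventionSEM`` wraps an observed data pair (Y, X) the way a
statsmodels model wraps its endog/exog: construct once, ``fit()`` to run
the nodewise reduced-form regressions, the peeling reconstruction and the
coefficient step, and use the returned ``InterventionSEMResults`` for
summaries and hypothesis tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import AncestralRelationGraph, HypothesisSpec
from .inference import DPTestReport, test_edges as _test_edges, dp_pvalue_pathway
from .peeling import PeelingTrace, estimate_coefficients, peel
from .simulate import DataSet
from .sparse_regression import TuningConfig, VEstimate, fit_V

__all__ = ["InterventionSEM", "InterventionSEMResults"]


class InterventionSEM:
    """Gaussian DAG with additive unspecified interventions.

    Parameters
    ----------
    Y : (n, p) array of primary variables (e.g. expression levels)
    X : (n, q) array of intervention variables (e.g. genotypes)
    ynames, xnames : optional column names carried into reports
    """

    def __init__(self, Y, X, ynames=None, xnames=None):
        self.data = DataSet(np.asarray(Y, float), np.asarray(X, float))
        self.ynames = list(ynames) if ynames is not None else [
            f"Y{j}" for j in range(1, self.data.p + 1)
        ]
        self.xnames = list(xnames) if xnames is not None else [
            f"X{l}" for l in range(1, self.data.q + 1)
        ]
        if len(self.ynames) != self.data.p or len(self.xnames) != self.data.q:
            raise ValueError("name lengths do not match data dimensions")

    @classmethod
    def from_dataframes(cls, Y: pd.DataFrame, X: pd.DataFrame) -> "InterventionSEM":
        return cls(Y.to_numpy(float), X.to_numpy(float),
                   ynames=list(Y.columns), xnames=list(X.columns))

    def fit(
        self,
        kappa=None,
        kappa_prime=None,
        tau_scale: float = 1.0,
        config: TuningConfig | None = None,
        greedy_fallback: bool = False,
    ) -> "InterventionSEMResults":
        """Learn the graph and estimate the coefficients.

        ``kappa`` bounds the per-column sparsity of the reduced-form step
        (BIC-selected over 1..5 when omitted); ``kappa_prime`` bounds the
        directed-effect step (BIC over 1..5 when omitted).
        """
        if config is None:
            config = TuningConfig(kappa=kappa, tau_scale=tau_scale)
        v_est = fit_V(self.data, config)
        arg, trace = peel(v_est.V_hat, greedy_fallback=greedy_fallback)
        U_hat, W_hat, chosen = estimate_coefficients(
            self.data, arg, kappa_prime=kappa_prime, config=config
        )
        # residual variances on the graph's own regressor sets
        sigma2 = np.empty(self.data.p)
        for j in range(1, self.data.p + 1):
            cols_y = [k - 1 for k in sorted(arg.ancestors(j))]
            cols_x = [l - 1 for l in sorted(arg.candidate_interventions(j))]
            Z = np.column_stack([
                self.data.Y[:, cols_y].reshape(self.data.n, -1),
                self.data.X[:, cols_x].reshape(self.data.n, -1),
            ])
            y = self.data.Y[:, j - 1]
            if Z.shape[1]:
                beta = np.linalg.lstsq(Z, y, rcond=None)[0]
                resid = y - Z @ beta
            else:
                resid = y
            dof = max(self.data.n - Z.shape[1], 1)
            sigma2[j - 1] = float(resid @ resid) / dof
        return InterventionSEMResults(self, v_est, arg, trace, U_hat, W_hat,
                                      chosen, sigma2)


@dataclass
class InterventionSEMResults:
    """Learned graph and coefficient estimates, with tests attached."""

    model: InterventionSEM
    v_estimate: VEstimate
    arg: AncestralRelationGraph
    trace: PeelingTrace
    U_hat: np.ndarray
    W_hat: np.ndarray
    kappa_prime_chosen: dict
    sigma2_hat: np.ndarray

    @property
    def directed_edges(self) -> list[tuple[str, str]]:
        names = self.model.ynames
        return [(names[k - 1], names[j - 1])
                for k, j in zip(*[(a + 1).tolist() for a in np.nonzero(self.U_hat)])]

    def test_edges(self, edges, *, M: int = 1000, alpha: float = 0.05,
                   seed: int = 0, method: str = "dp",
                   oracle_graph=None) -> DPTestReport:
        """Simultaneous directed-edge test (null: all edges absent)."""
        h = HypothesisSpec(tuple(edges), mode="edge")
        return _test_edges(
            self.model.data, h, M=M, alpha=alpha, seed=seed, method=method,
            config=self.v_estimate.config, oracle_graph=oracle_graph,
            _prefit=(self.v_estimate, self.arg) if method != "oracle" else None,
        )

    def test_pathway(self, nodes, *, M: int = 1000, seed: int = 0) -> DPTestReport:
        """Directed-pathway test (null: some edge on the path absent)."""
        h = HypothesisSpec.from_path(nodes)
        return dp_pvalue_pathway(self.model.data, self.arg, h,
                                 self.v_estimate, M, seed)

    def summary(self) -> str:
        p, q, n = self.model.data.p, self.model.data.q, self.model.data.n
        lines = [
            "Interventional Gaussian DAG — peeling fit",
            "=" * 45,
            f"observations: {n}    primary: {p}    interventions: {q}",
            f"ancestral relations: {len(self.arg.ancestral_edges)}"
            f"    candidate interventions: {len(self.arg.candidate_intervention_edges)}",
            f"directed edges recovered: {int(np.count_nonzero(self.U_hat))}",
            f"peeling rounds: {len(self.trace.rounds)}",
            "",
            "edge          coefficient",
            "-" * 30,
        ]
        ks, js = np.nonzero(self.U_hat)
        for k, j in zip(ks, js):
            lines.append(
                f"{self.model.ynames[k]} -> {self.model.ynames[j]:<8}"
                f"{self.U_hat[k, j]: .4f}"
            )
        if ks.size == 0:
            lines.append("(none)")
        lines += ["", "sigma^2: " +
                  np.array2string(self.sigma2_hat, precision=3, separator=", ")]
        return "\n".join(lines)
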