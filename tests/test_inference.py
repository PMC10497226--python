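"""Likelihood-ratio construction, DP replication, p-value rules."""

import numpy as np
import pytest
from scipy import stats

from dagiv.graph import HypothesisSpec, arg_of_dag
from dagiv.inference import (
    DPReplicate,
    DPTestReport,
    DegreesOfFreedomError,
    NoValidReplicatesError,
    _holm_bonferroni,
    asymptotic_pvalue,
    build_context,
    dp_pvalue_edges,
    dp_pvalue_pathway,
    dp_replicate,
    likelihood_ratio,
    test_edges as run_edge_test,
    test_pathway as run_path_test,
)
from dagiv.simulate import DataSet, sample_dataset
from dagiv.sparse_regression import TuningConfig, fit_V
from tests.conftest import random_dag_params


@pytest.fixture(scope="module")
def chain_fit(chain_params):
    data, _ = sample_dataset(chain_params, 600, seed=31)
    fit = fit_V(data)
    from dagiv.peeling import peel

    arg, _ = peel(fit.V_hat)
    return chain_params, data, fit, arg


class TestBuildContext:
    def test_sigma_estimates_close_to_truth(self, chain_params):
        arg = arg_of_dag(chain_params.dag())
        h = HypothesisSpec(((1, 6),))
        vals = []
        for r in range(60):
            data, _ = sample_dataset(chain_params, 2000, seed=800 + r)
            ctx = build_context(data, arg, h)
            vals.append(ctx.sigma2_hat)
        mean = np.mean(vals, axis=0)
        assert np.allclose(mean, chain_params.sigma2, rtol=0.10)

    def test_nodes_without_hypothesized_parents_excluded(self, chain_fit):
        params, data, fit, arg = chain_fit
        ctx = build_context(data, arg, HypothesisSpec(((1, 6),)))
        assert ctx.contributing == (6,)
        assert ctx.hyp_parents[3] == ()

    def test_degenerate_hypothesis_rejected(self, chain_fit):
        params, data, fit, arg = chain_fit
        with pytest.raises(ValueError):
            build_context(data, arg, HypothesisSpec(((6, 1),)))

    def test_dof_error_when_saturated(self, chain_params):
        data, _ = sample_dataset(chain_params, 12, seed=5)
        arg = arg_of_dag(chain_params.dag())
        with pytest.raises(DegreesOfFreedomError):
            build_context(data, arg, HypothesisSpec(((1, 6),)))

    def test_collinear_design_warns(self, chain_params):
        data, _ = sample_dataset(chain_params, 300, seed=6)
        X = data.X.copy()
        X[:, 1] = X[:, 0]  # exact collinearity among interventions
        data2 = DataSet(data.Y, X)
        arg = arg_of_dag(chain_params.dag())
        with pytest.warns(UserWarning, match="collinear"):
            build_context(data2, arg, HypothesisSpec(((1, 6),)))


class TestLikelihoodRatio:
    def test_rss_and_projection_forms_agree(self, chain_fit):
        params, data, fit, arg = chain_fit
        for edges in [((1, 6),), ((1, 6), (2, 6)), ((1, 4), (2, 5))]:
            ctx = build_context(data, arg, HypothesisSpec(edges))
            a = likelihood_ratio(ctx, data, form="projection")
            b = likelihood_ratio(ctx, data, form="rss")
            assert a == pytest.approx(b, rel=1e-8)

    def test_spanned_hypothesized_parent_gives_zero(self):
        # when the hypothesized parent column lies in the span of the
        # remaining regressors, P_A = P_B and Lr = 0 exactly
        params = random_dag_params(4, 8, 44)
        data, _ = sample_dataset(params, 400, seed=44)
        arg = arg_of_dag(params.dag())
        h = HypothesisSpec(((1, 4),))
        Y = data.Y.copy()
        assert 4 in arg.candidate_interventions(4)  # X4 instruments Y4 in Setup A
        Y[:, 0] = data.X[:, 3]  # Y1 := X4, already a regressor of node 4
        with pytest.warns(UserWarning, match="collinear"):
            ctx = build_context(DataSet(Y, data.X), arg, h)
            lr = likelihood_ratio(ctx, DataSet(Y, data.X))
        assert lr == pytest.approx(0.0, abs=1e-8)

    def test_nonnegative(self, chain_fit):
        params, data, fit, arg = chain_fit
        ctx = build_context(data, arg, HypothesisSpec(((2, 6),)))
        assert likelihood_ratio(ctx, data) >= 0.0

    def test_null_calibration_chi2_mean(self, chain_params):
        # oracle graph, |D| = 1: mean of 2 Lr is close to 1
        arg = arg_of_dag(chain_params.dag())
        h = HypothesisSpec(((1, 6),))
        vals = []
        for r in range(400):
            data, _ = sample_dataset(chain_params, 400, seed=2000 + r)
            ctx = build_context(data, arg, h)
            vals.append(2 * likelihood_ratio(ctx, data))
        assert abs(np.mean(vals) - 1.0) < 0.15


class TestDPReplication:
    def test_replicate_reproducible(self, chain_fit):
        params, data, fit, arg = chain_fit
        ctx = build_context(data, arg, HypothesisSpec(((1, 6),)))
        r1 = dp_replicate(data, ctx, fit, seed=9, m=3)
        r2 = dp_replicate(data, ctx, fit, seed=9, m=3)
        assert r1.valid == r2.valid and r1.lr_star == r2.lr_star

    def test_replicate_independent_of_M(self, chain_fit):
        # stream keyed by (seed, m): same m regardless of how many others run
        params, data, fit, arg = chain_fit
        ctx = build_context(data, arg, HypothesisSpec(((1, 6),)))
        solo = dp_replicate(data, ctx, fit, seed=9, m=7)
        among = [dp_replicate(data, ctx, fit, seed=9, m=m) for m in range(8)][7]
        assert solo.lr_star == among.lr_star

    def test_perturbation_kept_on_request(self, chain_fit):
        params, data, fit, arg = chain_fit
        ctx = build_context(data, arg, HypothesisSpec(((1, 6),)))
        rep = dp_replicate(data, ctx, fit, seed=9, m=0, keep_perturbation=True)
        assert rep.perturbation is not None and rep.perturbation.shape == data.Y.shape

    def test_null_replicates_follow_chi2(self, chain_fit):
        params, data, fit, arg = chain_fit
        ctx = build_context(data, arg, HypothesisSpec(((1, 6),)))
        stars = []
        for m in range(300):
            rep = dp_replicate(data, ctx, fit, seed=77, m=m)
            if rep.valid:
                stars.append(2 * float(rep.lr_star))
        assert len(stars) > 250
        ks = stats.kstest(stars, stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.01


class TestPvalues:
    def mk(self, lrs, valid=None):
        valid = valid or [True] * len(lrs)
        return [DPReplicate(v, l) for v, l in zip(valid, lrs)]

    def test_counting_rule(self):
        rep = dp_pvalue_edges(2.0, self.mk([1.0, 2.5, 3.0, 0.5]))
        assert rep.pvalue == 0.5

    def test_zero_statistic_gives_one(self):
        rep = dp_pvalue_edges(0.0, self.mk([0.3, 1.0, 2.0]))
        assert rep.pvalue == 1.0

    def test_invalid_replicates_excluded(self):
        rep = dp_pvalue_edges(2.0, self.mk([1.0, 5.0, 9.0], [True, False, True]))
        assert rep.M_valid == 2 and rep.pvalue == 0.5

    def test_no_valid_replicates_raises(self):
        with pytest.raises(NoValidReplicatesError):
            dp_pvalue_edges(1.0, self.mk([1.0], [False]))

    def test_all_valid_equals_plain_rank(self):
        lrs = [0.1, 0.9, 1.7, 2.4, 5.0]
        rep = dp_pvalue_edges(1.0, self.mk(lrs))
        assert rep.pvalue == np.mean([l >= 1.0 for l in lrs])

    def test_report_bounds_enforced(self):
        with pytest.raises(ValueError):
            DPTestReport(lr=1.0, pvalue=1.5, M_total=1, M_valid=1,
                         classification=None, method="dp")


class TestAsymptoticPvalue:
    def test_chi2_95th_percentile(self):
        assert asymptotic_pvalue(3.841 / 2, 1) == pytest.approx(0.05, abs=1e-3)

    def test_normal_regime_center(self):
        assert asymptotic_pvalue(25.0, 50, regime="large") == pytest.approx(0.5)

    def test_zero_statistic(self):
        assert asymptotic_pvalue(0.0, 3) == 1.0

    def test_auto_switches(self):
        small = asymptotic_pvalue(30.0, 51)
        assert small == pytest.approx(asymptotic_pvalue(30.0, 51, regime="large"))


class TestHolm:
    def test_adjustment_monotone_and_capped(self):
        adj = _holm_bonferroni([0.01, 0.04, 0.3])
        assert adj == pytest.approx([0.03, 0.08, 0.3])
        assert _holm_bonferroni([0.9, 0.8]) == pytest.approx([1.0, 1.0])


class TestEndToEnd:
    def test_degenerate_edge_pvalue_one(self, chain_fit):
        params, data, fit, arg = chain_fit
        rep = run_edge_test(data, HypothesisSpec(((6, 1),)), M=10, seed=0)
        assert rep.pvalue == 1.0 and rep.classification.degenerate

    def test_true_edge_rejected(self, chain_params):
        data, _ = sample_dataset(chain_params, 800, seed=55)
        rep = run_edge_test(data, HypothesisSpec(((1, 2),)), M=80, seed=2)
        assert rep.pvalue < 0.05

    def test_oracle_method(self, chain_params):
        data, _ = sample_dataset(chain_params, 600, seed=56)
        rep = run_edge_test(data, HypothesisSpec(((1, 6),)), method="oracle",
                         oracle_graph=chain_params.dag())
        assert 0 <= rep.pvalue <= 1 and rep.method == "oracle"

    def test_irregular_decomposition(self):
        # hypothesis whose nondegenerate edges jointly close a cycle with
        # the learned ancestral relations -> Holm-combined single edges
        params = random_dag_params(5, 10, 77)
        U = params.U.copy()
        U[:] = 0
        U[2, 3] = 0.9  # 3 -> 4 (1-based)
        params2 = type(params)(U, params.W, params.sigma2)
        data, _ = sample_dataset(params2, 800, seed=77)
        h = HypothesisSpec(((4, 5), (5, 3)))
        rep = run_edge_test(data, h, M=60, seed=1)
        if rep.per_edge:
            assert rep.classification is not None
            assert not rep.classification.regular
            assert all("pvalue_holm" in d for d in rep.per_edge)
            assert rep.pvalue == pytest.approx(min(d["pvalue_holm"] for d in rep.per_edge))


class TestPathway:
    def test_max_rule_and_singleton_equivalence(self, chain_params):
        data, _ = sample_dataset(chain_params, 700, seed=66)
        fit = fit_V(data)
        from dagiv.peeling import peel

        arg, _ = peel(fit.V_hat)
        h1 = HypothesisSpec(((1, 2),), mode="pathway")
        pathway = dp_pvalue_pathway(data, arg, h1, fit, M=50, seed=4)
        edge = run_edge_test(data, HypothesisSpec(((1, 2),)), M=50, seed=4,
                          _prefit=(fit, arg))
        assert pathway.pvalue == pytest.approx(edge.pvalue)

    def test_degenerate_subedge_gives_one(self, chain_params):
        data, _ = sample_dataset(chain_params, 500, seed=67)
        h = HypothesisSpec.from_path([2, 1, 3])  # 2->1 reverses a chain edge
        rep = run_path_test(data, h, M=20, seed=5)
        assert rep.pvalue == 1.0

    def test_present_path_detected(self, chain_params):
        data, _ = sample_dataset(chain_params, 900, seed=68)
        rep = run_path_test(data, HypothesisSpec.from_path([1, 2, 3]), M=80, seed=6)
        assert rep.pvalue < 0.05
        assert len(rep.per_edge) == 2
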