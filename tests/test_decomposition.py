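import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from gapdecomp import (
    AssemblyError,
    Block,
    DesignMatrix,
    LogitFit,
    ModelSpec,
    ValidationError,
    aggregate_decomposition,
    assign_wealth_groups,
    build_design_matrix,
    decomposition_report,
    detailed_decomposition_single,
    example_config,
    fit_linear_probability,
    fit_logit,
    generate_population,
    match_samples,
    matched_explained,
    replicate_detailed_decomposition,
    run_decomposition,
)


def fixed_fit(beta, columns, column_blocks, benchmark="nonpoor", link="logit"):
    """LogitFit with printed coefficients — the benchmark for toy oracles."""
    beta = np.asarray(beta, dtype=float)
    return LogitFit(
        benchmark=benchmark,
        beta=beta,
        vcov=np.eye(beta.size),
        columns=columns,
        column_blocks=column_blocks,
        n_obs=0,
        n_clusters=0,
        loglik=0.0,
        converged=True,
        link=link,
    )


def toy_dm(X, y=None, weights=None, column_blocks=None):
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    blocks = column_blocks or ["(intercept)"] + [f"b{j}" for j in range(1, k)]
    return DesignMatrix(
        values=X,
        columns=list(blocks),
        column_blocks=list(blocks),
        row_ids=np.arange(n),
        y=np.zeros(n) if y is None else np.asarray(y, dtype=float),
        weights=np.ones(n) if weights is None else np.asarray(weights, dtype=float),
        psu=np.array([f"c{i}" for i in range(n)]),
    )


def fitted_toy(seed=0, n=120, households=40):
    """Small synthetic dataset with real fits for integration-style tests."""
    cfg = example_config(n_strata=3, psus_per_stratum=4, households_per_psu=households,
                         seed=seed)
    micro = assign_wealth_groups(generate_population(cfg))
    spec = cfg.model_spec()
    dm = build_design_matrix(micro, spec)
    dm_poor, dm_np = dm.split_groups()
    fits = {
        "poor": fit_logit(dm_poor, "poor"),
        "nonpoor": fit_logit(dm_np, "nonpoor"),
        "pooled": fit_logit(dm, "pooled"),
    }
    return dm_poor, dm_np, fits


class TestAggregate:
    def test_identical_groups_decompose_to_zero(self):
        dm_poor, _, fits = fitted_toy()
        agg = aggregate_decomposition(fits["poor"], dm_poor, dm_poor)
        assert agg.gap == 0.0
        assert abs(agg.explained) < 1e-15
        assert abs(agg.unexplained) < 1e-15

    def test_six_row_direct_sum_oracle(self):
        beta = np.array([0.25, -1.5, 2.0])
        Xp = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0]], dtype=float)
        Xnp = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)
        wp = np.array([1.0, 2.0, 1.0])
        wnp = np.array([1.0, 1.0, 3.0])
        yp = np.array([0.0, 1.0, 0.0])
        ynp = np.array([1.0, 1.0, 0.0])
        cols = ["(intercept)", "a", "b"]
        fit = fixed_fit(beta, cols, cols)
        agg = aggregate_decomposition(fit, toy_dm(Xp, yp, wp), toy_dm(Xnp, ynp, wnp))
        # brute-force direct summation over all rows
        explained = sum(
            w * expit(x @ beta) for x, w in zip(Xnp, wnp / wnp.sum())
        ) - sum(w * expit(x @ beta) for x, w in zip(Xp, wp / wp.sum()))
        gap = np.average(ynp, weights=wnp) - np.average(yp, weights=wp)
        assert abs(agg.explained - explained) < 1e-12
        assert abs(agg.gap - gap) < 1e-12
        assert abs(agg.explained + agg.unexplained - agg.gap) < 1e-12

    def test_identity_link_matches_linear_blinder_oaxaca(self):
        dm_poor, dm_np, _ = fitted_toy(seed=6)
        fit = fit_linear_probability(dm_np, "nonpoor")
        agg = aggregate_decomposition(fit, dm_poor, dm_np)
        xbar_p = np.average(dm_poor.values, axis=0, weights=dm_poor.weights)
        xbar_np = np.average(dm_np.values, axis=0, weights=dm_np.weights)
        closed_form = float(fit.beta @ (xbar_np - xbar_p))
        assert abs(agg.explained - closed_form) < 1e-10

    def test_nonconverged_fit_rejected(self):
        dm_poor, dm_np, fits = fitted_toy()
        bad = fits["nonpoor"]
        bad.converged = False
        with pytest.raises(Exception, match="converge"):
            aggregate_decomposition(bad, dm_poor, dm_np)

    def test_second_bracket_cross_check_passes_on_real_fits(self):
        dm_poor, dm_np, fits = fitted_toy(seed=2)
        agg = aggregate_decomposition(
            fits["nonpoor"], dm_poor, dm_np,
            fit_poor=fits["poor"], fit_nonpoor=fits["nonpoor"], check_tol=1e-9,
        )
        assert abs(agg.explained + agg.unexplained - agg.gap) < 1e-15


class TestMatching:
    def test_equal_sizes_no_subsampling(self):
        dm_poor, dm_np, fits = fitted_toy()
        n = min(dm_poor.n_obs, dm_np.n_obs)
        sub = dm_np.subset(np.arange(dm_np.n_obs) < n)
        m = match_samples(dm_poor.subset(np.arange(dm_poor.n_obs) < n), sub,
                          fits["pooled"], seed=0)
        assert sorted(m.poor_pos) == list(range(n))
        assert sorted(m.counterpart_pos) == list(range(n))

    def test_seed_determinism(self):
        dm_poor, dm_np, fits = fitted_toy()
        a = match_samples(dm_poor, dm_np, fits["pooled"], seed=11)
        b = match_samples(dm_poor, dm_np, fits["pooled"], seed=11)
        c = match_samples(dm_poor, dm_np, fits["pooled"], seed=12)
        assert np.array_equal(a.poor_pos, b.poor_pos)
        assert np.array_equal(a.counterpart_pos, b.counterpart_pos)
        assert not (
            np.array_equal(a.poor_pos, c.poor_pos)
            and np.array_equal(a.counterpart_pos, c.counterpart_pos)
        )

    def test_4v6_hand_enumerated_pairing(self):
        beta = np.array([0.0, 1.0])
        cols = ["(intercept)", "x"]
        fit = fixed_fit(beta, cols, cols)
        Xp = np.array([[1, 0.4], [1, -1.0], [1, 2.0], [1, 0.0]])
        Xnp = np.array([[1, 1.5], [1, -0.5], [1, 0.7], [1, -2.0], [1, 3.0], [1, 0.1]])
        seed = 5
        m = match_samples(toy_dm(Xp), toy_dm(Xnp), fit, seed=seed)
        assert m.n_pairs == 4
        # replay the seeded stream: one subsample draw, then two tiebreak shuffles
        rng = np.random.default_rng(seed)
        sel = rng.choice(6, size=4, replace=False)
        expected_poor = np.argsort(Xp[:, 1], kind="stable")
        expected_np = sel[np.argsort(Xnp[sel, 1], kind="stable")]
        assert np.array_equal(m.poor_pos, expected_poor)
        assert np.array_equal(m.counterpart_pos, expected_np)
        # ranks non-decreasing along the pair list on both sides
        assert (np.diff(Xp[m.poor_pos, 1]) >= 0).all()
        assert (np.diff(Xnp[m.counterpart_pos, 1]) >= 0).all()

    def test_larger_poor_group_is_subsampled(self):
        dm_poor, dm_np, fits = fitted_toy()
        big, small = (dm_poor, dm_np) if dm_poor.n_obs > dm_np.n_obs else (dm_np, dm_poor)
        m = match_samples(big, small, fits["pooled"], seed=0)
        assert m.n_pairs == small.n_obs

    def test_nonconverged_ranking_fit_rejected(self):
        dm_poor, dm_np, fits = fitted_toy()
        fits["pooled"].converged = False
        with pytest.raises(Exception, match="converge"):
            match_samples(dm_poor, dm_np, fits["pooled"], seed=0)


class TestDetailedSingle:
    def _two_block_setup(self):
        beta = np.array([-0.2, 1.1, -0.8])
        cols = ["(intercept)", "a", "b"]
        fit = fixed_fit(beta, cols, cols)
        Xp = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]], dtype=float)
        Xnp = np.array([[1, 1, 0], [1, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        wp = np.array([1.0, 2.0, 1.0, 0.5])
        dmp = toy_dm(Xp, weights=wp, column_blocks=cols)
        dmn = toy_dm(Xnp, column_blocks=cols)
        match = match_samples(dmp, dmn, fit, seed=0)
        return beta, fit, dmp, dmn, match

    def test_single_block_equals_matched_explained(self):
        beta = np.array([0.3, 0.9])
        cols = ["(intercept)", "a"]
        fit = fixed_fit(beta, cols, cols)
        dmp = toy_dm(np.array([[1, 0], [1, 1], [1, 0]], dtype=float), column_blocks=cols)
        dmn = toy_dm(np.array([[1, 1], [1, 1], [1, 0]], dtype=float), column_blocks=cols)
        match = match_samples(dmp, dmn, fit, seed=1)
        contrib = detailed_decomposition_single(match, dmp, dmn, fit, ["a"])
        assert abs(contrib["a"] - matched_explained(match, dmp, dmn, fit)) < 1e-15

    def test_inert_block_contributes_zero(self):
        beta, fit, dmp, dmn, match = self._two_block_setup()
        fit_inert = fixed_fit([beta[0], beta[1], 0.0], fit.columns, fit.column_blocks)
        contrib = detailed_decomposition_single(match, dmp, dmn, fit_inert, ["a", "b"])
        assert contrib["b"] == 0.0

    def test_switch_state_oracle_both_orderings(self):
        beta, fit, dmp, dmn, match = self._two_block_setup()
        Xp = dmp.values[match.poor_pos]
        Xn = dmn.values[match.counterpart_pos]
        w = dmp.weights[match.poor_pos]
        w = w / w.sum()

        # brute-force enumeration of the four switch states per pair
        def F(a_from_np, b_from_np):
            X = Xp.copy()
            if a_from_np:
                X[:, 1] = Xn[:, 1]
            if b_from_np:
                X[:, 2] = Xn[:, 2]
            return float(w @ expit(X @ beta))

        for ordering, expected in (
            (["a", "b"], {"a": F(1, 0) - F(0, 0), "b": F(1, 1) - F(1, 0)}),
            (["b", "a"], {"b": F(0, 1) - F(0, 0), "a": F(1, 1) - F(0, 1)}),
        ):
            contrib = detailed_decomposition_single(match, dmp, dmn, fit, ordering)
            for blk in ("a", "b"):
                assert abs(contrib[blk] - expected[blk]) < 1e-12
            total = matched_explained(match, dmp, dmn, fit)
            assert abs(contrib.sum() - total) < 1e-12

    def test_bad_ordering_rejected(self):
        beta, fit, dmp, dmn, match = self._two_block_setup()
        with pytest.raises(ValidationError, match="permutation"):
            detailed_decomposition_single(match, dmp, dmn, fit, ["a", "a"])


@settings(max_examples=30, deadline=None)
@given(st.permutations(["distance", "mother_edu", "partner_edu", "tv", "birth_order", "religion"]))
def test_telescoping_for_any_ordering(ordering):
    dm_poor, dm_np, fits = _CACHED_TOY
    match = match_samples(dm_poor, dm_np, fits["pooled"], seed=3)
    contrib = detailed_decomposition_single(match, dm_poor, dm_np, fits["nonpoor"], list(ordering))
    total = matched_explained(match, dm_poor, dm_np, fits["nonpoor"])
    assert abs(contrib.sum() - total) < 1e-10


class TestReplication:
    def test_r1_identity_ordering_equals_single(self):
        dm_poor, dm_np, fits = fitted_toy(seed=1)
        blocks = dm_poor.blocks
        det = replicate_detailed_decomposition(
            dm_poor, dm_np, fits["nonpoor"], fits["pooled"], R=1, root_seed=77,
            orderings=[blocks],
        )
        child = np.random.SeedSequence(77).spawn(1)[0]
        match_seed = int(child.spawn(2)[0].generate_state(1)[0])
        match = match_samples(dm_poor, dm_np, fits["pooled"], match_seed)
        single = detailed_decomposition_single(match, dm_poor, dm_np, fits["nonpoor"], blocks)
        np.testing.assert_allclose(det.contribution_mean.to_numpy(), single.to_numpy(), atol=0)

    def test_identity_link_contributions_are_ordering_free(self):
        # equal-size groups, uniform weights: no subsampling variation, and the
        # linear limit makes per-block contributions the closed-form quantities
        dm_poor, dm_np, _ = fitted_toy(seed=4)
        n = min(dm_poor.n_obs, dm_np.n_obs)
        dmp = dm_poor.subset(np.arange(dm_poor.n_obs) < n)
        dmn = dm_np.subset(np.arange(dm_np.n_obs) < n)
        dmp.weights = np.ones(n)
        dmn.weights = np.ones(n)
        # mild coefficients keep every switch-state prediction inside [0, 1],
        # so the identity link is exactly linear (no clipping)
        rng = np.random.default_rng(0)
        beta = np.concatenate([[0.5], rng.uniform(-0.03, 0.03, dmp.n_cols - 1)])
        fit = fixed_fit(beta, dmp.columns, dmp.column_blocks, link="identity")
        det_a = replicate_detailed_decomposition(dmp, dmn, fit, fit, R=3, root_seed=1)
        det_b = replicate_detailed_decomposition(dmp, dmn, fit, fit, R=3, root_seed=99)
        for blk in dmp.blocks:
            cols = dmp.block_columns(blk)
            closed = float(
                fit.beta[cols] @ (dmn.values[:, cols].mean(0) - dmp.values[:, cols].mean(0))
            )
            assert abs(det_a.contribution_mean[blk] - closed) < 1e-10
            assert abs(det_b.contribution_mean[blk] - closed) < 1e-10
            assert det_a.contribution_se[blk] < 1e-10

    def test_self_consistency_across_root_seeds(self):
        dm_poor, dm_np, fits = fitted_toy(seed=8, households=30)
        R = 200
        a = replicate_detailed_decomposition(dm_poor, dm_np, fits["nonpoor"], fits["pooled"],
                                             R=R, root_seed=1)
        b = replicate_detailed_decomposition(dm_poor, dm_np, fits["nonpoor"], fits["pooled"],
                                             R=R, root_seed=2)
        for blk in dm_poor.blocks:
            combined = np.hypot(a.contribution_se[blk], b.contribution_se[blk]) / np.sqrt(R)
            diff = abs(a.contribution_mean[blk] - b.contribution_mean[blk])
            assert diff < 4 * max(combined, 1e-12), blk

    def test_ordering_average_variance_shrinks_with_r(self):
        dm_poor, dm_np, fits = fitted_toy(seed=9, households=30)
        means = {R: [] for R in (10, 100)}
        for R in means:
            for root in range(6):
                det = replicate_detailed_decomposition(
                    dm_poor, dm_np, fits["nonpoor"], fits["pooled"], R=R, root_seed=root
                )
                means[R].append(det.contribution_mean.to_numpy())
        var10 = np.var(np.array(means[10]), axis=0).sum()
        var100 = np.var(np.array(means[100]), axis=0).sum()
        assert var100 < var10

    def test_invalid_r(self):
        dm_poor, dm_np, fits = fitted_toy()
        with pytest.raises(ValidationError, match="R"):
            replicate_detailed_decomposition(dm_poor, dm_np, fits["nonpoor"], fits["pooled"], R=0)

    def test_percent_of_gap_definition(self):
        dm_poor, dm_np, fits = fitted_toy(seed=3)
        det = replicate_detailed_decomposition(dm_poor, dm_np, fits["nonpoor"], fits["pooled"],
                                               R=5, root_seed=0)
        np.testing.assert_allclose(
            det.percent_of_gap.to_numpy(),
            100.0 * det.contribution_mean.to_numpy() / det.gap,
            atol=1e-12,
        )


class TestReferenceInvariance:
    def test_detailed_contributions_invariant_to_reference_swap(self):
        cfg = example_config(n_strata=3, psus_per_stratum=4, households_per_psu=40, seed=13)
        micro = assign_wealth_groups(generate_population(cfg))
        spec_a = cfg.model_spec()
        spec_b = spec_a.with_reference("mother_edu", "higher").with_reference("religion", "islam")
        results = {}
        for key, spec in (("a", spec_a), ("b", spec_b)):
            dm = build_design_matrix(micro, spec)
            dmp, dmn = dm.split_groups()
            fit_np = fit_logit(dmn, "nonpoor")
            fit_pool = fit_logit(dm, "pooled")
            results[key] = replicate_detailed_decomposition(
                dmp, dmn, fit_np, fit_pool, R=3, root_seed=5
            )
        for blk in results["a"].blocks:
            assert abs(
                results["a"].contribution_mean[blk] - results["b"].contribution_mean[blk]
            ) < 1e-8, blk


class TestReport:
    def test_full_pipeline_report_plumbing(self):
        cfg = example_config(n_strata=3, psus_per_stratum=4, households_per_psu=40, seed=2)
        micro = generate_population(cfg)
        result = run_decomposition(micro, cfg.model_spec(), R=3, seed=4)
        rep = result.report
        for bench, agg in rep.aggregate.items():
            assert abs(agg.explained + agg.unexplained - agg.gap) < 1e-12
            d = rep.to_dict()[bench]
            assert d["explained"] == agg.explained
            assert d["gap"] == agg.gap
        frame = rep.to_frame()
        totals = frame[frame["block"] == "total_explained"]
        assert set(totals["benchmark"]) == set(rep.aggregate)

    def test_explained_share_ratio_contract(self):
        from gapdecomp import AggregateDecomposition

        agg = AggregateDecomposition("nonpoor", 0.746, 0.41, 0.336, 0.234, 0.102)
        assert round(agg.explained_pct, 1) == 69.6

    def test_benchmark_mismatch_raises(self):
        dm_poor, dm_np, fits = fitted_toy(seed=1)
        agg = aggregate_decomposition(fits["nonpoor"], dm_poor, dm_np)
        det = replicate_detailed_decomposition(dm_poor, dm_np, fits["poor"], fits["pooled"],
                                               R=2, root_seed=0)
        with pytest.raises(AssemblyError):
            decomposition_report({"nonpoor": agg}, {"nonpoor": det})

    def test_corrupted_contributions_raise(self):
        dm_poor, dm_np, fits = fitted_toy(seed=1)
        agg = aggregate_decomposition(fits["nonpoor"], dm_poor, dm_np)
        det = replicate_detailed_decomposition(dm_poor, dm_np, fits["nonpoor"], fits["pooled"],
                                               R=2, root_seed=0)
        det.draws.iloc[0, 0] += 0.5  # break telescoping
        with pytest.raises(AssemblyError, match="telescop|sum"):
            decomposition_report({"nonpoor": agg}, {"nonpoor": det})


_CACHED_TOY = fitted_toy(seed=7)
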