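"""Conditional-logit (MaxDiff) estimation: oracles, invariants, recovery."""

import itertools

import numpy as np
import pytest

from bwsprefs import (
    MaxDiffModel,
    build_questionnaire,
    compare_subgroups,
    default_profile,
    fit_by_subgroup,
    fit_maxdiff,
    generate_bibd,
    maxdiff_loglik,
    simulate_study,
)
from bwsprefs.items import generic_catalog
from bwsprefs.model import ConvergenceWarning, SeparationWarning
from bwsprefs.simulate import UtilityProfile

from conftest import random_scripted_picks, scripted_dataset


def enumeration_loglik(beta, dataset):
    """Brute-force MaxDiff log-likelihood: normalize over all ordered pairs."""
    ids = dataset.questionnaire.item_ids
    u = {iid: b for iid, b in zip(ids, beta)}
    total = 0.0
    for resp in dataset.responses:
        for bi, (best, worst) in resp.picks.items():
            members = [ids[i] for i in dataset.design.blocks[bi]]
            denom = sum(
                np.exp(u[i] - u[j])
                for i, j in itertools.permutations(members, 2)
            )
            total += np.log(np.exp(u[best] - u[worst]) / denom)
    return total


@pytest.fixture()
def block4_dataset():
    """One respondent, one complete block of four items."""
    q = build_questionnaire(generate_bibd(4, 4), 0, generic_catalog(4))
    ids = q.item_ids
    return scripted_dataset(q, [{0: (ids[0], ids[3])}])


class TestLoglik:
    def test_uniform_null_is_log_one_twelfth(self, block4_dataset):
        ll = maxdiff_loglik(np.zeros(4), block4_dataset)
        assert ll == pytest.approx(np.log(1 / 12), abs=1e-12)

    def test_shift_invariance(self, tiny_questionnaire):
        rng = np.random.default_rng(17)
        ds = scripted_dataset(
            tiny_questionnaire,
            [random_scripted_picks(tiny_questionnaire, rng) for _ in range(2)],
        )
        beta = np.array([0.5, -0.2, -0.3])
        for c in (1.0, -3.7, 250.0):
            assert maxdiff_loglik(beta + c, ds) == pytest.approx(
                maxdiff_loglik(beta, ds), abs=1e-10
            )

    def test_matches_pair_enumeration_oracle(self, tiny_questionnaire):
        ids = tiny_questionnaire.item_ids
        picks = [
            {0: (ids[0], ids[1]), 1: (ids[0], ids[2]), 2: (ids[1], ids[2])},
            {0: (ids[2], ids[0]), 1: (ids[1], ids[0]), 2: (ids[0], ids[2])},
        ]
        ds = scripted_dataset(tiny_questionnaire, picks)
        beta = np.array([0.5, -0.2, -0.3])
        assert maxdiff_loglik(beta, ds) == pytest.approx(
            enumeration_loglik(beta, ds), abs=1e-10
        )

    def test_dict_interface_and_length_check(self, block4_dataset):
        ids = block4_dataset.questionnaire.item_ids
        by_id = maxdiff_loglik({i: 0.1 for i in ids}, block4_dataset)
        by_arr = maxdiff_loglik(np.full(4, 0.1), block4_dataset)
        assert by_id == by_arr
        with pytest.raises(ValueError, match="length"):
            maxdiff_loglik(np.zeros(3), block4_dataset)

    def test_analytic_gradient_matches_finite_differences(self, tiny_questionnaire):
        rng = np.random.default_rng(4)
        ds = scripted_dataset(
            tiny_questionnaire,
            [random_scripted_picks(tiny_questionnaire, rng) for _ in range(3)],
        )
        for likelihood in ("maxdiff", "sequential"):
            model = MaxDiffModel(ds, likelihood=likelihood)
            beta = np.array([0.4, 0.1, -0.5])
            g = model.score(beta)
            eps = 1e-6
            for m in range(3):
                step = np.zeros(3)
                step[m] = eps
                fd = (model.loglike(beta + step) - model.loglike(beta - step)) / (2 * eps)
                assert g[m] == pytest.approx(fd, abs=1e-6)

    def test_sequential_equals_maxdiff_at_zero(self, block4_dataset):
        # with all utilities 0 both likelihoods give each block log(1/(k*(k-1)))
        md = MaxDiffModel(block4_dataset, likelihood="maxdiff")
        seq = MaxDiffModel(block4_dataset, likelihood="sequential")
        assert md.loglike(np.zeros(4)) == pytest.approx(seq.loglike(np.zeros(4)),
                                                        abs=1e-12)


class TestFit:
    def test_optimum_matches_dense_grid_search(self, tiny_questionnaire):
        ids = tiny_questionnaire.item_ids
        picks = [
            {0: (ids[0], ids[1]), 1: (ids[0], ids[2]), 2: (ids[1], ids[2])},
            {0: (ids[0], ids[2]), 1: (ids[1], ids[2]), 2: (ids[0], ids[1])},
        ]
        ds = scripted_dataset(tiny_questionnaire, picks)
        res = fit_maxdiff(ds)
        # dense grid over the 2-dimensional centered parameter space,
        # with the denominator computed by explicit pair enumeration
        step = 0.005
        grid = np.arange(-2.0, 2.0 + 1e-9, step)
        b1, b2 = np.meshgrid(grid, grid, indexing="ij")
        B = np.stack([b1.ravel(), b2.ravel(), -b1.ravel() - b2.ravel()], axis=1)
        denom = np.zeros(len(B))
        for i, j in itertools.permutations(range(3), 2):
            denom += np.exp(B[:, i] - B[:, j])
        ll = np.zeros(len(B))
        for resp in ds.responses:
            for _, (best, worst) in resp.picks.items():
                bi, wi = ids.index(best), ids.index(worst)
                ll += B[:, bi] - B[:, wi] - np.log(denom)
        argmax = int(np.argmax(ll))
        assert res.llf >= ll[argmax] - 1e-9
        assert res.params[ids[0]] == pytest.approx(B[argmax, 0], abs=1e-3 + step)
        assert res.params[ids[1]] == pytest.approx(B[argmax, 1], abs=1e-3 + step)

    def test_effects_coding_sums_to_zero(self, overall_fit):
        assert abs(overall_fit.params.sum()) < 1e-8
        assert overall_fit.converged

    def test_symmetric_data_gives_zero_betas_and_tiebreak_ranks(self):
        q = build_questionnaire(generate_bibd(4, 4), 0, generic_catalog(4))
        ids = q.item_ids
        picks = [
            {0: (ids[i], ids[j])} for i in range(4) for j in range(4) if i != j
        ]
        ds = scripted_dataset(q, picks)
        res = fit_maxdiff(ds)
        assert np.allclose(res.params.values, 0.0, atol=1e-6)
        ranked = res.ranks.sort_values()
        assert list(ranked.index) == sorted(ids)

    def test_parameter_recovery_within_three_se(self):
        """At n=5000 under the matched generative model every estimate is
        within 3 standard errors of the truth."""
        q = build_questionnaire(generate_bibd(13, 4), 0)
        profile = default_profile("overall", heterogeneity_sd=0.0)
        ds = simulate_study(q, {"overall": 5000}, {"overall": profile},
                            master_seed=77)
        res = fit_maxdiff(ds)
        truth = profile.utilities_for(res.params.index)
        z = (res.params.values - truth) / res.bse.values
        assert np.all(np.abs(z) < 3)

    def test_ci_contains_beta_and_halfwidths_shrink_as_root_n(self):
        q = build_questionnaire(generate_bibd(13, 4), 0)
        profile = default_profile("overall")
        widths = {}
        for n in (50, 200, 800):
            ds = simulate_study(q, {"overall": n}, {"overall": profile},
                                master_seed=1000 + n)
            res = fit_maxdiff(ds)
            ci = res.conf_int()
            assert (ci["ci_low"] <= res.params).all()
            assert (res.params <= ci["ci_high"]).all()
            widths[n] = float((ci["ci_high"] - ci["ci_low"]).mean())
        # quadrupling n should roughly halve the interval
        assert widths[200] / widths[800] == pytest.approx(2.0, rel=0.25)
        assert widths[50] / widths[200] == pytest.approx(2.0, rel=0.25)

    def test_hessian_ses_match_finite_difference_ses(self, tiny_questionnaire):
        rng = np.random.default_rng(21)
        ds = scripted_dataset(
            tiny_questionnaire,
            [random_scripted_picks(tiny_questionnaire, rng) for _ in range(6)],
        )
        res = fit_maxdiff(ds)
        model = MaxDiffModel(ds)
        T = model._reduction()
        beta = res.params.values
        eps = 1e-5
        H = np.zeros((model.v, model.v))
        for m in range(model.v):
            step = np.zeros(model.v)
            step[m] = eps
            H[:, m] = (model.score(beta + step) - model.score(beta - step)) / (2 * eps)
        cov = T @ np.linalg.inv(-(T.T @ H @ T)) @ T.T
        se_fd = np.sqrt(np.diag(cov))
        assert np.allclose(se_fd, res.bse.values, rtol=0.01)

    def test_nonconvergence_is_flagged_not_silent(self, included):
        with pytest.warns(ConvergenceWarning):
            res = fit_maxdiff(included, maxiter=1)
        assert not res.converged

    def test_separation_is_warned_per_item(self):
        q = build_questionnaire(generate_bibd(4, 4), 0, generic_catalog(4))
        ids = q.item_ids
        picks = [{0: (ids[0], ids[3])}, {0: (ids[0], ids[2])}]
        ds = scripted_dataset(q, picks)
        with pytest.warns(SeparationWarning, match=ids[0]):
            MaxDiffModel(ds).fit()

    def test_sequential_alternative_fits_and_is_centered(self, included):
        res = fit_maxdiff(included, likelihood="sequential")
        assert abs(res.params.sum()) < 1e-8
        assert res.converged
        # both likelihoods should broadly agree on the ranking
        res_md = fit_maxdiff(included)
        assert res.ranks["adl"] == res_md.ranks["adl"] == 1


def test_matches_statsmodels_conditional_logit(questionnaire13):
    """Reference-coded refit via statsmodels reproduces the utilities.

    The MaxDiff pair likelihood is a conditional logit over the k*(k-1)
    ordered pairs of a block, with pair covariates e_best - e_worst.  A
    fixed-effects ConditionalLogit on that expansion is an independent
    implementation of the same estimator (up to the identification shift).
    """
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    profile = default_profile("overall")
    ds = simulate_study(questionnaire13, {"overall": 40},
                        {"overall": profile}, master_seed=12)
    ours = fit_maxdiff(ds)
    ids = list(ours.params.index)

    rows, chosen, groups = [], [], []
    gid = 0
    for resp in ds.responses:
        for bi, (best, worst) in resp.picks.items():
            members = [ids.index(i) for i in
                       (ds.questionnaire.item_ids[j]
                        for j in ds.design.blocks[bi])]
            bidx, widx = ids.index(best), ids.index(worst)
            for i, j in itertools.permutations(members, 2):
                x = np.zeros(len(ids))
                x[i] += 1.0
                x[j] -= 1.0
                rows.append(x[:-1])  # reference coding: drop the last item
                chosen.append(1 if (i, j) == (bidx, widx) else 0)
                groups.append(gid)
            gid += 1
    fit_sm = ConditionalLogit(np.array(chosen), np.array(rows),
                              groups=np.array(groups)).fit(
        method="bfgs", gtol=1e-8, disp=False)
    ours_ref = ours.params.values - ours.params.values[-1]
    assert np.allclose(ours_ref[:-1], fit_sm.params, atol=1e-3)


class TestSubgroups:
    def test_study_emulation_strata_fits(self, included):
        by = fit_by_subgroup(included)
        assert {p: r.n_respondents for p, r in by.items()} == {
            "pre_op": 36, "short_post": 55, "long_post": 62
        }
        for r in by.values():
            assert abs(r.params.sum()) < 1e-8

    def test_single_phase_equals_overall_fit(self, questionnaire13):
        profile = default_profile("overall")
        ds = simulate_study(questionnaire13, {"pre_op": 10},
                            {"pre_op": profile}, master_seed=2)
        by = fit_by_subgroup(ds)
        assert list(by) == ["pre_op"]
        overall = fit_maxdiff(ds)
        assert np.allclose(by["pre_op"].params.values, overall.params.values,
                           atol=1e-6)

    def test_empty_subgroup_named(self, included):
        trimmed = included.subset(
            [r for r in included.responses if r.phase != "pre_op"][:20]
        )
        by = fit_by_subgroup(trimmed)
        assert "pre_op" not in by  # absent stratum simply not fitted
        with pytest.raises(ValueError, match="empty|no responses"):
            fit_by_subgroup(included.subset([]))

    def test_compare_subgroups_shapes_and_errors(self, included):
        by = fit_by_subgroup(included)
        table = compare_subgroups(by, top_m=4)
        assert table.top.shape == (4, 3)
        assert table.trajectories.shape == (13, 3)
        assert set(table.phases) == {"pre_op", "short_post", "long_post"}
        with pytest.raises(ValueError, match="at least two"):
            compare_subgroups({"pre_op": by["pre_op"]})
        with pytest.raises(ValueError, match="top_m"):
            compare_subgroups(by, top_m=14)

    def test_identical_subgroups_give_identical_columns(self, included):
        res = fit_maxdiff(included)
        table = compare_subgroups({"a": res, "b": res})
        assert (table.top["a"] == table.top["b"]).all()
        assert np.allclose(table.trajectories["a"], table.trajectories["b"])


def test_results_frame_and_summary(overall_fit):
    df = overall_fit.to_frame()
    assert list(df.columns) == ["subgroup", "item_id", "beta", "se", "ci_low",
                                "ci_high", "rank", "n", "loglik", "converged"]
    assert sorted(df["rank"]) == list(range(1, 14))
    assert (df["ci_low"] <= df["beta"]).all() and (df["beta"] <= df["ci_high"]).all()
    recs = overall_fit.to_records()
    assert len(recs) == 13 and recs[0].subgroup == "overall"
    text = overall_fit.summary()
    assert "adl" in text and "log-likelihood" in text


def test_forest_plot_smoke(overall_fit):
    mpl = pytest.importorskip("matplotlib")
    mpl.use("Agg")
    ax = overall_fit.plot_forest()
    assert ax.get_xlabel() == "standardized score (beta)"
    assert len(ax.get_yticklabels()) == 13
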