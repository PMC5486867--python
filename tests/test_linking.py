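import dataclasses

import numpy as np
import pytest

from linkedlmm.design import build_design
from linkedlmm.linking import (
    compare_models,
    covariate_removal_shift,
    decompose,
    fit_linked_sequential,
    joint_fit,
    reliability_simulation,
)
from linkedlmm.lmm import fit_lmm
from linkedlmm.simdata import (
    SimConfig,
    generate_corpus,
    slim_duration_spec,
    slim_location_spec,
)


class TestDecomposition:
    def test_identity_machine_precision(self, tiny_fit1):
        d = decompose(tiny_fit1)
        np.testing.assert_allclose(d.xhat + d.resid, tiny_fit1.design.y,
                                   rtol=0, atol=1e-12)

    def test_residuals_sum_to_zero(self, tiny_fit1):
        d = decompose(tiny_fit1)
        assert abs(d.resid.sum()) < 1e-8 * len(d.resid)

    def test_prediction_residual_near_orthogonality(self, tiny_fit1):
        d = decompose(tiny_fit1)
        assert abs(d.rho) < 0.1


class TestSequentialLinking:
    def test_mode_none_vs_observed_df(self, tiny_corpus):
        lf_none = fit_linked_sequential(tiny_corpus.table, None,
                                        slim_duration_spec(), mode="none")
        lf_obs = fit_linked_sequential(tiny_corpus.table, None,
                                       slim_duration_spec(), mode="observed")
        assert lf_obs.fit2.df - lf_none.fit2.df == 2

    def test_observed_mode_ignores_first_model(self, tiny_corpus, tiny_fit1):
        a = fit_linked_sequential(tiny_corpus.table, slim_location_spec(),
                                  slim_duration_spec(), mode="observed")
        b = fit_linked_sequential(tiny_corpus.table, None,
                                  slim_duration_spec(), mode="observed",
                                  fit1=tiny_fit1)
        np.testing.assert_allclose(a.fit2.beta, b.fit2.beta, rtol=0, atol=0)

    def test_link_table_shape(self, linked_both):
        tab = linked_both.link_table()
        assert len(tab) == 4
        assert set(tab["variable"]) == {"xhat", "resid_loc"}

    def test_recovers_generating_signs(self, linked_both, tiny_config):
        tab = linked_both.link_table().set_index(["variable", "order"])
        assert np.sign(tab.loc[("xhat", "quadratic"), "raw_estimate"]) == \
            np.sign(tiny_config.beta_xhat[1])
        assert np.sign(tab.loc[("resid_loc", "quadratic"), "raw_estimate"]) == \
            np.sign(tiny_config.beta_resid[1])

    def test_unknown_mode(self, tiny_corpus):
        with pytest.raises(ValueError, match="unknown link mode"):
            fit_linked_sequential(tiny_corpus.table, None,
                                  slim_duration_spec(), mode="median")

    def test_zero_variance_link_covariate(self, tiny_corpus):
        df = tiny_corpus.table.data.copy()
        df["rel_loc"] = 0.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_linked_sequential(df, None, slim_duration_spec(),
                                  mode="observed")

    def test_no_dissociation_observed_equivalent_to_both(self):
        # equal linear coefficients and no quadratics on the two legs make
        # the decomposition uninformative: observed and both describe the
        # same signal, so their log-likelihoods differ only by noise fitting
        cfg = SimConfig.reduced(n_subjects=12, n_sentences=20,
                                beta_xhat=(-0.4, 0.0), beta_resid=(-0.4, 0.0))
        corpus = generate_corpus(cfg, 31)
        rep = compare_models(corpus.table, slim_location_spec(),
                             slim_duration_spec(), modes=("observed", "both"))
        rows = rep.rows.set_index("label")
        ll_diff = rows.loc["both", "logLik"] - rows.loc["observed", "logLik"]
        assert -2.0 < ll_diff < 10.0


class TestCompareModels:
    def test_report_contract(self, tiny_corpus):
        rep = compare_models(tiny_corpus.table, slim_location_spec(),
                             slim_duration_spec(),
                             modes=("none", "observed", "both"))
        rows = rep.rows
        assert list(rows["AIC"]) == sorted(rows["AIC"])
        by_label = rows.set_index("label")
        assert by_label.loc["both", "df"] - by_label.loc["observed", "df"] == 2
        for _, r in rows.iterrows():
            assert r["AIC"] == pytest.approx(-2 * r["logLik"] + 2 * r["df"])

    def test_requires_mode(self, tiny_corpus):
        with pytest.raises(ValueError):
            compare_models(tiny_corpus.table, None, slim_duration_spec(),
                           modes=())


class TestJointFit:
    def test_ascent_property_and_agreement(self, tiny_corpus):
        jf = joint_fit(tiny_corpus.table, slim_location_spec(),
                       slim_duration_spec())
        assert jf.joint_loglik >= jf.sequential_loglik - 1e-8
        seq = fit_linked_sequential(tiny_corpus.table, slim_location_spec(),
                                    slim_duration_spec(), mode="both")
        # fixed effects agree within half a joint-fit standard error
        diff = np.abs(jf.fit2.beta - seq.fit2.beta)
        assert np.all(diff <= 0.5 * jf.fit2.se + 1e-12)

    def test_separable_when_unlinked(self):
        # zero link coefficients: the duration data carry no information
        # about the location model, so the joint fit stays at the
        # sequential solution
        cfg = SimConfig.reduced(n_subjects=10, n_sentences=15,
                                beta_xhat=(0.0, 0.0), beta_resid=(0.0, 0.0))
        corpus = generate_corpus(cfg, 13)
        jf = joint_fit(corpus.table, slim_location_spec(), slim_duration_spec())
        seq = fit_linked_sequential(corpus.table, slim_location_spec(),
                                    slim_duration_spec(), mode="both")
        np.testing.assert_allclose(jf.fit1.beta, seq.fit1.beta, atol=1e-4)
        np.testing.assert_allclose(jf.fit2.beta, seq.fit2.beta, atol=1e-3)


class TestReliability:
    def test_determinism(self, tiny_fit1, tiny_corpus):
        kw = dict(n_reps=2, seed=77)
        a = reliability_simulation(tiny_fit1, slim_duration_spec(),
                                   tiny_corpus.table, **kw)
        b = reliability_simulation(tiny_fit1, slim_duration_spec(),
                                   tiny_corpus.table, **kw)
        assert a.summary.equals(b.summary)
        assert a.draws.equals(b.draws)

    def test_means_near_point_estimates(self, tiny_fit1, tiny_corpus,
                                        linked_both):
        res = reliability_simulation(tiny_fit1, slim_duration_spec(),
                                     tiny_corpus.table, n_reps=8, seed=5)
        assert res.n_completed == 8
        orig = linked_both.link_table().set_index(["variable", "order"])
        summ = res.summary.set_index(["variable", "order"])
        for key in orig.index:
            sd = summ.loc[key, "sd"]
            assert abs(summ.loc[key, "mean"] - orig.loc[key, "raw_estimate"]) \
                <= 3.0 * sd

    def test_conditional_variant_runs(self, tiny_fit1, tiny_corpus):
        res = reliability_simulation(tiny_fit1, slim_duration_spec(),
                                     tiny_corpus.table, n_reps=2, seed=3,
                                     conditional=True)
        assert res.n_completed == 2


class TestCovariateRemoval:
    def test_shift_and_monotone_variance(self):
        # launch-site distance drives location but is absent from the
        # duration model, so model 2 cannot re-absorb its contribution:
        # dropping it from model 1 must move the residual-path coefficient
        # (a covariate present in both models would shift its own
        # duration coefficient instead)
        cfg = SimConfig.reduced(n_subjects=20, n_sentences=30)
        corpus = generate_corpus(cfg, 55)
        full, reduced = covariate_removal_shift(
            corpus.table, slim_location_spec(), slim_duration_spec(),
            drop="log2_launch_c",
        )
        # explained variance can only shrink when a covariate is dropped
        assert np.var(full.decomposition.xhat) >= np.var(
            reduced.decomposition.xhat)
        ft = full.link_table().set_index(["variable", "order"])
        rt = reduced.link_table().set_index(["variable", "order"])
        key = ("resid_loc", "linear")
        shift = abs(ft.loc[key, "raw_estimate"] - rt.loc[key, "raw_estimate"])
        assert shift > 2.0 * ft.loc[key, "raw_se"]

    def test_null_covariate_is_noop(self):
        # a covariate with (near-)zero effect on location leaves the link
        # coefficients unchanged
        cfg = SimConfig.reduced(n_subjects=12, n_sentences=20)
        cfg.alpha = dict(cfg.alpha)
        cfg.alpha["log_freq_nm1_c"] = 0.0
        corpus = generate_corpus(cfg, 21)
        full, reduced = covariate_removal_shift(
            corpus.table, slim_location_spec(), slim_duration_spec(),
            drop="log_freq_nm1_c",
        )
        ft = full.link_table().set_index(["variable", "order"])
        rt = reduced.link_table().set_index(["variable", "order"])
        for key in ft.index:
            assert abs(ft.loc[key, "raw_estimate"] - rt.loc[key, "raw_estimate"]) \
                <= 0.5 * ft.loc[key, "raw_se"]

    def test_errors(self, tiny_corpus):
        with pytest.raises(ValueError, match="not in the first model"):
            covariate_removal_shift(tiny_corpus.table, slim_location_spec(),
                                    slim_duration_spec(), drop="nope")
        only = dataclasses.replace(
            slim_location_spec(),
            fixed=slim_location_spec().fixed[:1],
        )
        with pytest.raises(ValueError, match="only covariate"):
            covariate_removal_shift(tiny_corpus.table, only,
                                    slim_duration_spec(),
                                    drop=only.fixed[0].name)
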