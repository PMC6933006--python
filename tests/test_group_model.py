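"""Bayesian regression stack: z-transform, pre-difference model, MLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moveson.bayes import (ModelSpec, PreInterventionDifference,
                           SamplerConfig, SmoothnessMixedLM,
                           fit_pre_difference, ztransform)
from moveson.simulate import gen_clinical_table

FAST = SamplerConfig(n_steps=800)


def _records(n_patients=10, per_patient=12, sd_patient=0.5, sigma=1.0,
             group_effect=0.0, prez_effect=0.0, seed=0):
    """Gaussian records with known effect structure (direct simulation)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        b = rng.normal(0, sd_patient)
        gc = 0.5 if i % 2 == 0 else -0.5
        prez = rng.normal()
        for s in range(per_patient):
            sc = s - (per_patient - 1) / 2
            y = (group_effect * gc + prez_effect * prez + b
                 + rng.normal(0, sigma))
            rows.append({"MedianLC": y, "IDanon": f"P{i:02d}", "Group.c": gc,
                         "Session.c": sc, "pre.z": prez,
                         "MoCap.c": 0.5 if i % 4 < 2 else -0.5})
    return pd.DataFrame(rows)


class TestZTransform:
    def test_standardises_to_zero_mean_unit_sd(self):
        z, _ = ztransform([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_round_trip_with_stored_reference(self):
        x = np.array([3.1, 4.1, 5.9, 2.6])
        z, ref = ztransform(x)
        assert np.allclose(ref.invert(z), x)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="SD"):
            ztransform([2.0, 2.0, 2.0])

    def test_external_reference_applied(self):
        z, _ = ztransform([10.0, 20.0], reference_mean=10.0, reference_sd=5.0)
        assert np.allclose(z, [0.0, 2.0])


class TestPreDifference:
    def test_large_n_recovers_injected_offset(self):
        tab = gen_clinical_table(200, offsets={"ARAT": 1.0}, seed=5)
        res = fit_pre_difference(tab, "ARAT", seed=1)
        # the offset is 1 population SD; z-scoring the pooled sample
        # shrinks it slightly (pooled SD > within-group SD)
        assert res.intervals()["median"] == pytest.approx(1.0, abs=0.15)

    def test_constant_treatment_not_identified(self):
        tab = gen_clinical_table(5, seed=0)
        tab["Treatment"] = 0
        with pytest.raises(ValueError, match="not identified"):
            PreInterventionDifference(tab, "ARAT")

    def test_tail_mass_between_zero_and_one(self):
        tab = gen_clinical_table(20, seed=2)
        res = fit_pre_difference(tab, "BBT", seed=0, n_steps=400)
        assert 0.0 <= res.tail_mass() <= 1.0

    def test_null_interval_coverage_over_replicates(self):
        """90% intervals cover 0 in ~90% of null-table refits."""
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            tab = gen_clinical_table(30, seed=10_000 + rep)
            res = fit_pre_difference(tab, "SIS.1", seed=rep,
                                     n_walkers=12, n_steps=400)
            iv = res.intervals()
            covered += iv["l90"] <= 0.0 <= iv["u90"]
        assert covered >= 85


class TestMixedLM:
    def test_intercept_only_matches_sample_mean(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"MedianLC": rng.normal(0.8, 1.0, 300),
                           "IDanon": [f"P{i % 6}" for i in range(300)]})
        spec = ModelSpec(population_terms=(), varying_terms=("intercept",))
        res = SmoothnessMixedLM(df, spec).fit(seed=0, sampler=FAST)
        est = res.summary().set_index("term").loc["Intercept", "estimate"]
        assert est == pytest.approx(df["MedianLC"].mean(), abs=0.1)

    def test_fixed_seed_reproduces_summaries(self):
        df = _records(seed=1)
        a = SmoothnessMixedLM(df, ModelSpec.ladder(1)).fit(seed=3, sampler=FAST)
        b = SmoothnessMixedLM(df, ModelSpec.ladder(1)).fit(seed=3, sampler=FAST)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_null_group_effect_interval_covers_zero(self):
        df = _records(group_effect=0.0, seed=2)
        res = SmoothnessMixedLM(df, ModelSpec.ladder(1)).fit(seed=0,
                                                             sampler=FAST)
        row = res.summary().set_index("term").loc["Group.c"]
        assert row["conf.low"] <= 0.0 <= row["conf.high"]

    def test_known_group_effect_recovered(self):
        df = _records(n_patients=20, per_patient=20, group_effect=0.7,
                      sd_patient=0.2, seed=5)
        res = SmoothnessMixedLM(df, ModelSpec.ladder(2)).fit(seed=0,
                                                             sampler=FAST)
        row = res.summary().set_index("term").loc["Group.c"]
        assert row["estimate"] == pytest.approx(0.7, abs=0.25)

    def test_shrinkage_toward_population_mean(self):
        # a patient with 1 record is pulled harder toward the grand mean
        # than one with 15 records at the same empirical offset
        rng = np.random.default_rng(6)
        rows = []
        for i in range(12):
            n_i = 1 if i == 0 else 15
            offset = 1.5 if i <= 1 else 0.0
            for _ in range(n_i):
                rows.append({"MedianLC": offset + rng.normal(0, 0.5),
                             "IDanon": f"P{i:02d}",
                             "Group.c": 0.5 if i % 2 else -0.5})
        df = pd.DataFrame(rows)
        res = SmoothnessMixedLM(df, ModelSpec.ladder(1)).fit(seed=0,
                                                             sampler=FAST)
        re = res.random_effects()
        emp = df.groupby("IDanon")["MedianLC"].mean()
        grand = df["MedianLC"].mean()
        for pid in ("P00", "P01"):
            est = re.loc[pid, "intercept"]
            # between the empirical offset and the population mean
            assert min(emp[pid] - grand, 0) - 0.15 <= est <= max(
                emp[pid] - grand, 0) + 0.15
        # sparse patient shrinks proportionally more
        shrink_sparse = 1 - re.loc["P00", "intercept"] / (emp["P00"] - grand)
        shrink_dense = 1 - re.loc["P01", "intercept"] / (emp["P01"] - grand)
        assert shrink_sparse > shrink_dense

    def test_prior_draws_match_student_t_quantiles(self):
        df = _records(seed=0)
        m = SmoothnessMixedLM(df, ModelSpec.ladder(4))
        prior = m.sample_prior(20000, seed=0)
        q = np.quantile(prior["Group.c"], [0.25, 0.5, 0.75])
        expected = stats.t.ppf([0.25, 0.5, 0.75], df=3, scale=3.0)
        assert np.allclose(q, expected, atol=0.12)
        # half-t sd prior: all positive, median matches
        assert (prior["sigma"] > 0).all()
        assert np.median(prior["sigma"]) == pytest.approx(
            stats.t.ppf(0.75, df=3, scale=3.0), abs=0.12)

    def test_lkj_prior_marginal_variance(self):
        # q = 2, eta = 2: density prop. to (1 - r^2), variance = 1/5
        df = _records(seed=0)
        spec = ModelSpec(population_terms=("Group.c", "Session.c"),
                         varying_terms=("intercept", "Session.c"))
        prior = SmoothnessMixedLM(df, spec).sample_prior(20000, seed=1)
        r = prior["cor(intercept,Session.c)"]
        assert r.mean() == pytest.approx(0.0, abs=0.02)
        assert r.var() == pytest.approx(0.2, abs=0.02)

    def test_correlated_three_term_model_runs_with_full_diagnostics(self):
        df = _records(n_patients=12, per_patient=10, prez_effect=0.5, seed=7)
        res = SmoothnessMixedLM(df, ModelSpec.ladder(4)).fit(seed=0,
                                                             sampler=FAST)
        summ = res.summary()
        # R-hat reported for every parameter; interval bounds ordered
        assert summ["rhat"].notna().all()
        assert (summ["conf.low"] <= summ["conf.high"]).all()
        names = set(summ["term"])
        assert {"pre.z", "sd(Session.c)", "cor(intercept,Session.c)"} <= names

    def test_rank_deficient_design_rejected(self):
        df = _records(seed=0)
        df["MoCap.c"] = 0.5  # constant column
        with pytest.raises(ValueError, match="rank"):
            SmoothnessMixedLM(df, ModelSpec.ladder(5))

    def test_non_finite_outcome_rejected(self):
        df = _records(seed=0)
        df.loc[0, "MedianLC"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            SmoothnessMixedLM(df, ModelSpec.ladder(1))

    def test_single_patient_rejected(self):
        df = _records(seed=0)
        df["IDanon"] = "P00"
        with pytest.raises(ValueError, match="2 patients"):
            SmoothnessMixedLM(df, ModelSpec.ladder(1))

    def test_intervals_are_nested(self):
        df = _records(seed=8)
        res = SmoothnessMixedLM(df, ModelSpec.ladder(1)).fit(seed=0,
                                                             sampler=FAST)
        iv = res.intervals("Group.c")
        assert iv["l90"] <= iv["l50"] <= iv["median"] <= iv["u50"] <= iv["u90"]
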