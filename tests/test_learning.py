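"""Mixed-effects learning-curve models: recovery, invariances, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import reachmetrics as rm
from reachmetrics.learning import MixedLearningModel, validate_learning_table

TRUE = dict(Intercept=5.0, logday=8.0, tdcs=1.0, tdcs_x_logday=2.0)


def noiseless_table(**overrides):
    kw = dict(
        beta0=TRUE["Intercept"], beta_day=TRUE["logday"], beta_tdcs=TRUE["tdcs"],
        beta_interaction=TRUE["tdcs_x_logday"], animal_sd=0.0, resid_sd=0.0,
        extra_attempt_mean=0.0, round_counts=False, seed=1,
    )
    kw.update(overrides)
    return rm.gen_learning_table(rm.LearningSimConfig(**kw))


class TestSuccessModel:
    def test_noiseless_exact_coefficient_recovery(self):
        res = rm.fit_success_model(noiseless_table())
        for name, val in TRUE.items():
            assert res.params[name] == pytest.approx(val, abs=1e-8)

    def test_row_permutation_and_relabeling_invariance(self):
        cfg = rm.LearningSimConfig(seed=4)
        tab = rm.gen_learning_table(cfg)
        ref = rm.fit_success_model(tab)
        rng = np.random.default_rng(0)
        shuffled = tab.sample(frac=1.0, random_state=3).reset_index(drop=True)
        relabel = {a: f"subj_{i:03d}" for i, a in
                   enumerate(rng.permutation(tab["animal_id"].unique()))}
        shuffled["animal_id"] = shuffled["animal_id"].map(relabel)
        alt = rm.fit_success_model(shuffled)
        for name in TRUE:
            assert alt.params[name] == pytest.approx(ref.params[name], abs=1e-6)

    def test_missing_days_handled_by_likelihood(self):
        tab = rm.gen_learning_table(rm.LearningSimConfig(seed=5))
        # 3 animals lose days 8-10, as unbalanced cohorts do
        drop = tab["animal_id"].isin(["rat00", "rat05", "rat13"]) & (tab["day"] >= 8)
        res = rm.fit_success_model(tab.loc[~drop])
        assert res.n_obs == len(tab) - int(drop.sum())
        assert np.isfinite(res.params).all()

    def test_scale_preconditions(self):
        tab = rm.gen_learning_table(rm.LearningSimConfig(seed=1))
        one_group = tab[tab["group"] == "anodal"]
        with pytest.raises(ValueError, match="2 animals per group"):
            rm.fit_success_model(one_group)
        one_day = tab[tab["day"] == 1]
        with pytest.raises(ValueError, match="2 training days"):
            rm.fit_success_model(one_day)

    def test_summary_mentions_multiple_comparison_caveat(self):
        res = rm.fit_success_model(rm.gen_learning_table(rm.LearningSimConfig(seed=2)))
        assert "not corrected for multiple comparisons" in res.summary()
        assert f"n_obs={res.n_obs}" in res.summary()


class TestRateModel:
    def test_noiseless_rate_recovery_from_constructed_ratio(self):
        tab = noiseless_table()
        tab["attempts"] = 100
        tab["successes"] = tab["successes"].clip(upper=100)
        res = rm.fit_rate_model(tab)
        for name, val in TRUE.items():
            assert res.params[name] == pytest.approx(val / 100.0, abs=1e-8)

    def test_zero_attempt_rows_dropped_and_counted(self):
        tab = rm.gen_learning_table(rm.LearningSimConfig(seed=6))
        tab.loc[tab.index[:5], ["successes", "attempts"]] = 0
        res = rm.fit_rate_model(tab)
        assert res.n_obs == len(tab) - 5
        assert res.n_dropped == 5


class TestStereotypyModel:
    @staticmethod
    def trial_records(n_animals=8, n_days=5, trials_per_day=6, effect=0.0,
                      noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        groups, paws = {}, {}
        for i in range(n_animals):
            a = f"rat{i:02d}"
            groups[a] = "anodal" if i < n_animals // 2 else "control"
            paws[a] = "right" if i % 4 else "left"
            for d in range(1, n_days + 1):
                for t in range(trials_per_day):
                    mu = 0.5 + 0.05 * np.log(d)
                    if groups[a] == "anodal":
                        mu += effect * np.log(d)
                    rows.append(
                        dict(trial_id=f"{a}d{d}t{t}", animal_id=a, day=d,
                             score=mu + rng.normal(0, noise),
                             success=bool(rng.uniform() < 0.5))
                    )
        return pd.DataFrame(rows), pd.Series(groups), pd.Series(paws)

    def test_constant_scores_zero_slopes(self):
        recs, groups, _ = self.trial_records(noise=0.0, seed=1)
        recs["score"] = 0.7
        res = rm.fit_stereotypy_model(recs, groups)
        assert res.params["logday"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["tdcs_x_logday"] == pytest.approx(0.0, abs=1e-10)

    def test_interaction_sign_recovered(self):
        hits = 0
        for s in range(20):
            recs, groups, _ = self.trial_records(effect=0.08, seed=100 + s)
            res = rm.fit_stereotypy_model(recs, groups)
            hits += res.params["tdcs_x_logday"] > 0
        assert hits >= 19

    def test_paw_subset_bookkeeping(self):
        recs, groups, paws = self.trial_records(seed=2)
        right_animals = set(paws[paws == "right"].index)
        res = rm.fit_stereotypy_model(
            recs, groups, paw="right", paw_by_animal=paws
        )
        assert res.n_obs == int(recs["animal_id"].isin(right_animals).sum())

    def test_success_stratification(self):
        recs, groups, _ = self.trial_records(seed=3)
        res = rm.fit_stereotypy_model(recs, groups, success=False)
        assert res.n_obs == int((~recs["success"]).sum())


class TestMEPModels:
    @staticmethod
    def amplitude_frame(side_effect=2.0, noise=0.0, seed=0, n_animals=10):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_animals):
            a = f"rat{i:02d}"
            grp = "anodal" if i < n_animals // 2 else "control"
            base = rng.normal(-2.0, 0.3)
            for paw in ("trained", "untrained"):
                for hemi in ("contra", "ipsi"):
                    lv = base + (side_effect if hemi == "contra" else 0.0)
                    rows.append(
                        dict(animal_id=a, group=grp, paw=paw, hemisphere=hemi,
                             log_value=lv + rng.normal(0, noise),
                             success=int(rng.integers(5, 30)))
                    )
        return pd.DataFrame(rows)

    def test_side_effect_exact_at_zero_noise(self):
        df = self.amplitude_frame(side_effect=2.0, noise=0.0, seed=1)
        res = rm.fit_mep_model(df, design="side")
        assert res.params["side"] == pytest.approx(2.0, abs=1e-8)

    def test_logdiff_design_null_effects(self):
        df = self.amplitude_frame(side_effect=1.0, noise=0.0, seed=2)
        res = rm.fit_mep_model(df, design="logdiff")
        # contra-ipsi difference identical for every animal and paw
        assert res.params["tdcs"] == pytest.approx(0.0, abs=1e-8)
        assert res.params["trained"] == pytest.approx(0.0, abs=1e-8)
        assert res.params["Intercept"] == pytest.approx(1.0, abs=1e-8)

    def test_success_design_runs(self):
        df = self.amplitude_frame(noise=0.2, seed=3)
        res = rm.fit_mep_model(df, design="success")
        assert {"success", "tdcs"} <= set(res.params.index)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            rm.fit_mep_model(self.amplitude_frame(), design="banana")


class TestSummaryAndValidation:
    def test_success_summary_matches_brute_force(self):
        tab = rm.gen_learning_table(rm.LearningSimConfig(seed=9))
        summ = rm.success_summary(tab)
        for _, row in summ.iterrows():
            vals = tab.loc[
                (tab["group"] == row["group"]) & (tab["day"] == row["day"]),
                "successes",
            ].to_numpy(dtype=float)
            assert row["mean"] == pytest.approx(vals.mean())
            assert row["sem"] == pytest.approx(
                vals.std(ddof=1) / np.sqrt(len(vals))
            )

    def test_identical_animals_zero_sem(self):
        tab = noiseless_table(beta_tdcs=0.0, beta_interaction=0.0)
        summ = rm.success_summary(tab)
        assert np.allclose(summ["sem"], 0.0)

    def test_single_animal_day_flagged(self):
        tab = rm.gen_learning_table(rm.LearningSimConfig(n_animals=4, seed=3))
        keep = ~((tab["group"] == "anodal") & (tab["day"] == 5)
                 & (tab["animal_id"] != "rat00"))
        summ = rm.success_summary(tab.loc[keep])
        row = summ[(summ["group"] == "anodal") & (summ["day"] == 5)].iloc[0]
        assert row["single_animal"] and np.isnan(row["sem"])

    @pytest.mark.parametrize(
        "mutate,msg",
        [
            (lambda t: t.assign(successes=t["attempts"] + 1), "exceed"),
            (lambda t: t.assign(day=0), "day must be"),
            (lambda t: t.assign(group="sham"), "unknown group"),
            (lambda t: t.drop(columns="paw"), "lacks column"),
        ],
    )
    def test_table_invariants_enforced(self, mutate, msg):
        tab = rm.gen_learning_table(rm.LearningSimConfig(n_animals=4, seed=1))
        with pytest.raises(ValueError, match=msg):
            validate_learning_table(mutate(tab))

    def test_random_slope_comparison_runs(self):
        tab = rm.gen_learning_table(rm.LearningSimConfig(seed=11))
        model = MixedLearningModel.from_learning_table(tab)
        cmp = model.compare_random_slope()
        assert cmp["df"] == 2 and 0.0 <= cmp["p"] <= 1.0
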