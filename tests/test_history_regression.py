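import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transdx.bandit_env import MISSING, ChoiceSession, Context, generate_schedule
from transdx.history_regression import (
    bh_fdr,
    build_history_design,
    fit_history_model,
    joint_task_model,
    ridge_logistic,
    stage1_coefficients,
    total_effects,
)
from transdx.rl_models import RLParams, simulate_agent


def make_session(choices, outcomes, context="reward", pid="toy"):
    return ChoiceSession(
        participant_id=pid, context=Context(context),
        choices=np.asarray(choices, dtype=np.int64),
        outcomes=np.asarray(outcomes, dtype=float),
    )


class TestBuildHistoryDesign:
    def test_hand_coded_six_trials(self):
        # trials (1-based): 1 choseX+reward, 2 choseY+reward, 3 choseX+noreward,
        # 4 choseZ+noreward, 5 choseX+reward, 6 choseY+noreward
        s = make_session([0, 1, 0, 2, 0, 1], [1, 1, 0, 0, 1, 0])
        d = build_history_design(s, target_option=0, tau_max=4)
        assert len(d) == 2  # trials 5 and 6
        row5 = d.iloc[0]
        assert row5["trial"] == 5 and row5["y"] == 1.0
        # lags for trial 5: t-1=4 (Z, no reward), t-2=3 (X, no reward),
        # t-3=2 (Y, reward), t-4=1 (X, reward)
        assert (row5["R1"], row5["R2"], row5["R3"], row5["R4"]) == (0.0, 0.0, -1.0, 1.0)
        assert (row5["C1"], row5["C2"], row5["C3"], row5["C4"]) == (-1.0, 1.0, -1.0, 1.0)
        row6 = d.iloc[1]
        assert row6["y"] == 0.0
        # lags for trial 6: t-1=5 (X, reward), t-2=4, t-3=3, t-4=2
        assert (row6["R1"], row6["R2"], row6["R3"], row6["R4"]) == (1.0, 0.0, 0.0, -1.0)

    def test_other_option_rewarded_codes_minus_one(self):
        s = make_session([1, 0, 0, 0, 0], [1, 1, 1, 1, 1])
        d = build_history_design(s, target_option=0, tau_max=4)
        assert d.iloc[0]["R4"] == -1.0  # chose Y and rewarded
        assert d.iloc[0]["C4"] == -1.0

    def test_chose_x_no_reward_codes_zero_and_plus_one(self):
        s = make_session([0, 0, 0, 0, 0], [0, 1, 1, 1, 1])
        d = build_history_design(s, target_option=0, tau_max=4)
        assert d.iloc[0]["R4"] == 0.0
        assert d.iloc[0]["C4"] == 1.0

    def test_full_session_row_count(self, schedule, rl2b_params):
        s = simulate_agent(schedule, "reward", "RL2b", rl2b_params, miss_rate=0.0, seed=0)
        d = build_history_design(s, tau_max=4)
        assert len(d) == 496

    def test_missing_lag_codes_zero(self):
        s = make_session([0, MISSING, 0, 1, 0], [1, 0, 1, 1, 1])
        d = build_history_design(s, target_option=0, tau_max=4)
        assert d.iloc[0]["R3"] == 0.0 and d.iloc[0]["C3"] == 0.0

    def test_missing_current_trial_dropped(self):
        s = make_session([0, 1, 0, 1, MISSING, 0], [1, 1, 1, 1, 0, 1])
        d = build_history_design(s, tau_max=4)
        assert list(d["trial"]) == [6]

    def test_loss_context_success_is_no_loss(self):
        s = make_session([0, 1, 0, 1, 0], [0, -1, 0, 0, 0], context="loss")
        d = build_history_design(s, target_option=0, tau_max=4)
        # t-4 = trial 1: chose X, no-loss -> success -> R=+1
        assert d.iloc[0]["R4"] == 1.0
        # t-3 = trial 2: chose Y, loss -> no success -> R=0
        assert d.iloc[0]["R3"] == 0.0

    def test_short_session_empty_with_warning(self):
        s = make_session([0, 1], [1, 1])
        d = build_history_design(s, tau_max=4)
        assert len(d) == 0

    @pytest.mark.parametrize("tau", [1, 7])
    def test_tau_out_of_range(self, tau):
        s = make_session([0, 1, 0], [1, 1, 1])
        with pytest.raises(ValueError, match="tau_max"):
            build_history_design(s, tau_max=tau)


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_never_below_raw(self, rng):
        p = rng.random(40)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


@pytest.fixture(scope="module")
def small_cohort():
    """40 RL2b agents with gamma tied to a synthetic CIT score."""
    sched = generate_schedule(seed=2, drift_sd=0.1, switch_rate=0.04, bounds=(0.1, 0.9))
    rng = np.random.default_rng(0)
    rows, designs = [], []
    for i in range(40):
        cit = rng.standard_normal()
        p = RLParams(
            alpha=0.45, beta=5.0, gamma=-1.0 + 0.6 * cit,
            alpha_F=0.1, alpha_C=0.5,
        )
        s = simulate_agent(sched, "reward", "RL2b", p, seed=100 + i,
                           participant_id=f"p{i:02d}")
        designs.append(build_history_design(s, tau_max=4))
        rows.append(
            {"participant_id": f"p{i:02d}", "CIT": cit,
             "AD": rng.standard_normal(), "IM": rng.standard_normal(),
             "age": rng.uniform(20, 69), "sex": rng.integers(1, 3),
             "education": rng.integers(1, 8), "ses": rng.integers(1, 11)}
        )
    return designs, pd.DataFrame(rows)


class TestFitHistoryModel:
    def test_total_equals_sum_of_lags(self, small_cohort):
        designs, participants = small_cohort
        res = fit_history_model(designs, participants, tau_max=4)
        coef = res.per_participant
        assert np.allclose(
            coef["total_R"], coef[["R1", "R2", "R3", "R4"]].sum(axis=1)
        )
        # group-level slope of the total equals the sum of per-lag slopes
        eff, tot_tab = res.effects, res.totals
        for term in ("const", "CIT"):
            lag_sum = sum(
                float(eff[(eff["response"] == r) & (eff["term"] == term)]["coef"].iloc[0])
                for r in ("R1", "R2", "R3", "R4")
            )
            tot = float(
                tot_tab[
                    (tot_tab["response"] == "total_R") & (tot_tab["term"] == term)
                ]["coef"].iloc[0]
            )
            assert tot == pytest.approx(lag_sum, abs=1e-8)

    def test_reward_history_positive_choice_negative(self, small_cohort):
        designs, participants = small_cohort
        te = total_effects(fit_history_model(designs, participants))
        assert te["beta_R"] > 0  # reinforcement
        assert te["beta_C"] < 0  # gamma centred at -1: avoid recent choices

    def test_gamma_link_shows_in_choice_interaction(self, small_cohort):
        designs, participants = small_cohort
        te = total_effects(fit_history_model(designs, participants))
        assert te["beta_C:CIT"] > 0

    def test_single_participant_raises(self, small_cohort):
        designs, participants = small_cohort
        with pytest.raises(ValueError, match="2 participants"):
            fit_history_model(designs[:1], participants)

    def test_unknown_estimator(self, small_cohort):
        designs, participants = small_cohort
        with pytest.raises(ValueError, match="estimator"):
            fit_history_model(designs, participants, estimator="bogus")

    def test_laplace_glmm_agrees_on_signs(self, small_cohort):
        designs, participants = small_cohort
        te2 = total_effects(fit_history_model(designs, participants))
        tel = total_effects(
            fit_history_model(designs, participants, estimator="laplace_glmm")
        )
        assert np.sign(tel["beta_R"]) == np.sign(te2["beta_R"])
        assert np.sign(tel["beta_C"]) == np.sign(te2["beta_C"])

    def test_fdr_attached_to_factor_terms(self, small_cohort):
        designs, participants = small_cohort
        res = fit_history_model(designs, participants)
        factor_rows = res.totals[res.totals["term"].isin(("CIT", "AD", "IM"))]
        assert factor_rows["q"].notna().all()
        assert (factor_rows["q"] >= factor_rows["p"] - 1e-12).all()


class TestJointTaskModel:
    def test_sign_flip_on_relabel(self, small_cohort):
        designs, participants = small_cohort
        half = len(designs) // 2
        a = joint_task_model(designs[:half], designs[half:], participants)
        b = joint_task_model(designs[half:], designs[:half], participants)
        for resp in ("total_R", "total_C"):
            for term in ("task", "CIT:task"):
                ca = float(a.query("response == @resp and term == @term")["coef"].iloc[0])
                cb = float(b.query("response == @resp and term == @term")["coef"].iloc[0])
                assert ca == pytest.approx(-cb, abs=1e-8)

    def test_missing_arm_raises(self, small_cohort):
        designs, participants = small_cohort
        with pytest.raises(ValueError, match="both task arms"):
            joint_task_model(designs, [], participants)

    def test_symmetric_arms_no_task_effect(self):
        # same generating process in both arms -> three-way terms ~ 0
        sched = generate_schedule(seed=5, drift_sd=0.1, switch_rate=0.04,
                                  bounds=(0.1, 0.9))
        rng = np.random.default_rng(1)
        rows, d_a, d_b = [], [], []
        for i in range(60):
            cit = rng.standard_normal()
            p = RLParams(alpha=0.45, beta=5.0, gamma=-1.0 + 0.5 * cit,
                         alpha_F=0.1, alpha_C=0.5)
            pid_a, pid_b = f"a{i:02d}", f"b{i:02d}"
            sa = simulate_agent(sched, "reward", "RL2b", p, seed=i, participant_id=pid_a)
            sb = simulate_agent(sched, "reward", "RL2b", p, seed=1000 + i,
                                participant_id=pid_b)
            d_a.append(build_history_design(sa))
            d_b.append(build_history_design(sb))
            for pid in (pid_a, pid_b):
                rows.append({"participant_id": pid, "CIT": cit,
                             "AD": rng.standard_normal(), "IM": rng.standard_normal(),
                             "age": 40.0, "sex": 1 + i % 2, "education": 4, "ses": 5})
        table = joint_task_model(d_a, d_b, pd.DataFrame(rows))
        row = table.query("response == 'total_C' and term == 'CIT:task'")
        coef, se = float(row["coef"].iloc[0]), float(row["se"].iloc[0])
        assert abs(coef) < 3 * se


class TestRidgeLogistic:
    def test_matches_unpenalised_logit_when_weak(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(500), rng.standard_normal((500, 3))])
        eta = X @ np.array([0.2, 0.8, -0.5, 0.1])
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        beta = ridge_logistic(X, y, penalty=1e-6)
        ref = sm.Logit(y, X).fit(disp=0).params
        assert np.allclose(beta, ref, atol=1e-4)

    def test_separation_handled(self):
        X = np.column_stack([np.ones(40), np.r_[np.ones(20), -np.ones(20)]])
        y = np.r_[np.ones(20), np.zeros(20)]
        beta = ridge_logistic(X, y, penalty=1.0)
        assert np.all(np.isfinite(beta))


def test_monotone_link_to_rl_parameters():
    """Higher alpha -> larger reward totals; higher gamma -> larger choice totals."""
    sched = generate_schedule(seed=3, drift_sd=0.1, switch_rate=0.04, bounds=(0.1, 0.9))
    rng = np.random.default_rng(7)
    alphas, gammas, tot_r, tot_c = [], [], [], []
    designs = []
    for i in range(100):
        a = rng.uniform(0.15, 0.8)
        g = rng.uniform(-2.0, 2.0)
        p = RLParams(alpha=a, beta=5.0, gamma=g, alpha_F=0.1, alpha_C=0.5)
        s = simulate_agent(sched, "reward", "RL2b", p, seed=i, participant_id=f"p{i}")
        designs.append(build_history_design(s))
        alphas.append(a)
        gammas.append(g)
    coef = stage1_coefficients(designs, tau_max=4)
    tot_r = coef[["R1", "R2", "R3", "R4"]].sum(axis=1)
    tot_c = coef[["C1", "C2", "C3", "C4"]].sum(axis=1)
    assert stats.spearmanr(alphas, tot_r).statistic > 0.5
    assert stats.spearmanr(gammas, tot_c).statistic > 0.5


@pytest.mark.parametrize("tau_max", [2, 3, 5, 6])
def test_history_length_sensitivity(small_cohort, tau_max):
    """Interaction signs are stable across the 2-6 history-length range."""
    _, participants = small_cohort
    # rebuild designs at this tau from the same generating cohort
    sched = generate_schedule(seed=2, drift_sd=0.1, switch_rate=0.04, bounds=(0.1, 0.9))
    rng = np.random.default_rng(0)
    designs = []
    for i in range(40):
        cit = participants["CIT"].iloc[i]
        p = RLParams(alpha=0.45, beta=5.0, gamma=-1.0 + 0.6 * cit,
                     alpha_F=0.1, alpha_C=0.5)
        s = simulate_agent(sched, "reward", "RL2b", p, seed=100 + i,
                           participant_id=participants["participant_id"].iloc[i])
        designs.append(build_history_design(s, tau_max=tau_max))
        rng.standard_normal(2)  # keep draws aligned with the fixture's stream
    te = total_effects(fit_history_model(designs, participants, tau_max=tau_max))
    assert te["beta_R"] > 0
    assert te["beta_C"] < 0
    assert te["beta_C:CIT"] > 0


def test_two_stage_consistency_with_session_length():
    """Stage-1 estimates converge to a long-session reference as T grows."""
    lag_cols = ["R1", "R2", "R3", "R4", "C1", "C2", "C3", "C4"]

    def coef_at(T, seed, params, penalty=1.0):
        sched = generate_schedule(seed=seed, n_trials=T, drift_sd=0.1,
                                  switch_rate=0.04, bounds=(0.1, 0.9))
        s = simulate_agent(sched, "reward", "RL2b", params, seed=seed,
                           participant_id="p")
        d = build_history_design(s)
        return stage1_coefficients([d], tau_max=4, penalty=penalty)[lag_cols].iloc[0]

    err_short, err_long = [], []
    rng = np.random.default_rng(0)
    for i in range(8):
        p = RLParams(alpha=rng.uniform(0.3, 0.6), beta=5.0,
                     gamma=rng.uniform(-1.5, -0.5), alpha_F=0.1, alpha_C=0.5)
        ref = coef_at(8000, 900 + i, p, penalty=1e-3)
        err_short.append(np.abs(coef_at(200, i, p) - ref).mean())
        err_long.append(np.abs(coef_at(1000, 100 + i, p) - ref).mean())
    assert np.mean(err_long) < np.mean(err_short)
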