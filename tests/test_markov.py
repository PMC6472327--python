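"""Multistate model: matrix exponentials, panel likelihood, fitting, summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvdscreen.cohort import (
    PanelDataset,
    observe_panel,
    simulate_state_path,
    simulate_trajectories,
)
from cvdscreen.markov import (
    IntensityMatrix,
    StateSpace,
    default_descriptive_intensity,
    default_policy_intensity,
    expected_total_occupancy,
    first_passage,
    fit,
    mean_time_to_state,
    next_state_probabilities,
    occupancy,
    panel_log_likelihood,
    sojourn_times,
    transition_probabilities,
)
from .conftest import euler_transition_matrix


def two_state_chain(a: float) -> IntensityMatrix:
    """One transient state decaying to EVENT at rate a (DEATH rate 0)."""
    space = StateSpace(transient=("LOW",))
    return IntensityMatrix.from_rates(space, {("LOW", "EVENT"): a})


def three_state_toy() -> IntensityMatrix:
    space = StateSpace(transient=("LOW", "INT_LOW"))
    return IntensityMatrix.from_rates(
        space,
        {("LOW", "INT_LOW"): 0.3, ("INT_LOW", "LOW"): 0.1,
         ("LOW", "EVENT"): 0.02, ("INT_LOW", "EVENT"): 0.08,
         ("LOW", "DEATH"): 0.01, ("INT_LOW", "DEATH"): 0.02},
    )


def random_valid_Q(seed: int) -> IntensityMatrix:
    rng = np.random.default_rng(seed)
    space = StateSpace.policy()
    rates = {}
    for i in range(space.n):
        for j in range(space.n):
            if space.mask[i, j]:
                rates[(space.states[i], space.states[j])] = rng.uniform(0.01, 0.4)
    return IntensityMatrix.from_rates(space, rates)


class TestIntensityMatrix:
    def test_invariants_enforced(self, policy_space):
        Q = np.zeros((6, 6))
        Q[0, 1], Q[0, 0] = 0.1, -0.1
        IntensityMatrix(Q, policy_space)  # valid
        bad = Q.copy()
        bad[0, 2] = 0.05  # LOW -> INT_HIGH not adjacent
        bad[0, 0] = -0.15
        with pytest.raises(ValueError, match="mask"):
            IntensityMatrix(bad, policy_space)
        bad2 = Q.copy()
        bad2[0, 0] = 0.0
        with pytest.raises(ValueError, match="sum"):
            IntensityMatrix(bad2, policy_space)

    def test_policy_mask_blocks_backward_from_high(self, policy_space):
        i, j = policy_space.index("HIGH"), policy_space.index("INT_HIGH")
        assert not policy_space.mask[i, j]
        desc = StateSpace.descriptive()
        assert desc.mask[desc.index("HIGH"), desc.index("INT_HIGH")]

    def test_json_round_trip(self, policy_Q, tmp_path):
        path = tmp_path / "q.json"
        policy_Q.to_json(path)
        back = IntensityMatrix.from_json(path)
        np.testing.assert_allclose(back.Q, policy_Q.Q)
        assert back.space.transient == policy_Q.space.transient


class TestTransitionProbabilities:
    def test_p0_is_identity(self, policy_Q):
        np.testing.assert_allclose(
            transition_probabilities(policy_Q, 0.0), np.eye(6), atol=1e-14
        )

    @pytest.mark.parametrize("a,t", [(0.2, 1.0), (0.05, 7.5), (1.3, 0.4)])
    def test_two_state_closed_form(self, a, t):
        P = transition_probabilities(two_state_chain(a), t)
        assert P[0, 0] == pytest.approx(np.exp(-a * t), abs=1e-12)
        assert P[0, 1] == pytest.approx(1 - np.exp(-a * t), abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=15)
    def test_chapman_kolmogorov(self, seed):
        Q = random_valid_Q(seed)
        P1, P2, P3 = (transition_probabilities(Q, t) for t in (1.0, 2.0, 3.0))
        np.testing.assert_allclose(P3, P1 @ P2, atol=1e-9)

    def test_rows_sum_to_one(self, policy_Q):
        for t in (0.5, 5.0, 50.0):
            P = transition_probabilities(policy_Q, t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= -1e-12).all()

    def test_negative_time_rejected(self, policy_Q):
        with pytest.raises(ValueError):
            transition_probabilities(policy_Q, -1.0)

    def test_policy_variant_never_leaves_high_downward(self, policy_Q):
        i = policy_Q.space.index("HIGH")
        for t in (0.5, 2.0, 10.0, 40.0):
            P = transition_probabilities(policy_Q, t)
            assert np.abs(P[i, :i]).max() < 1e-14


class TestPanelLikelihood:
    def test_hand_computed_two_observation_chain(self):
        a = 0.2
        Q = two_state_chain(a)
        panel = PanelDataset(pd.DataFrame(
            {"id": [1, 1], "exam_time": [0.0, 4.0],
             "observed_state": ["LOW", "LOW"], "attended": [True, True]}
        ))
        assert panel_log_likelihood(Q, panel) == pytest.approx(-a * 4.0, abs=1e-12)

    def test_exact_absorption_density_closed_form(self):
        # death of a 2-state chain at exact time t has density a*exp(-a t)
        a = 0.2
        Q = two_state_chain(a)
        panel = PanelDataset(pd.DataFrame(
            {"id": [1, 1], "exam_time": [0.0, 4.0],
             "observed_state": ["LOW", "EVENT"], "attended": [True, False]}
        ))
        ll = panel_log_likelihood(Q, panel, exact_death_times=True)
        assert ll == pytest.approx(np.log(a) - a * 4.0, abs=1e-12)
        ll_int = panel_log_likelihood(Q, panel, exact_death_times=False)
        assert ll_int == pytest.approx(np.log(1 - np.exp(-a * 4.0)), abs=1e-12)

    def test_duplicated_dataset_doubles_loglik(self, policy_Q):
        trajs = simulate_trajectories(policy_Q, 50, 20.0, seed=3)
        panel = observe_panel(trajs, [0, 5, 10, 15, 20], rng=4)
        df2 = panel.df.copy()
        df2["id"] = df2["id"] + 1000
        doubled = PanelDataset(pd.concat([panel.df, df2], ignore_index=True))
        assert panel_log_likelihood(policy_Q, doubled) == pytest.approx(
            2 * panel_log_likelihood(policy_Q, panel), rel=1e-12
        )

    def test_matches_discretised_brute_force_oracle(self):
        """Euler-chain oracle (step 1e-3 y) reproduces the likelihood to 3 decimals."""
        Q = three_state_toy()
        panel = PanelDataset(pd.DataFrame({
            "id": [1, 1, 1, 2, 2],
            "exam_time": [0.0, 2.0, 5.0, 0.0, 3.7],
            "observed_state": ["LOW", "INT_LOW", "LOW", "INT_LOW", "EVENT"],
            "attended": [True, True, True, True, False],
        }))
        ll = panel_log_likelihood(Q, panel, exact_death_times=True)
        P2 = euler_transition_matrix(Q.Q, 2.0)
        P3 = euler_transition_matrix(Q.Q, 3.0)
        P37 = euler_transition_matrix(Q.Q, 3.7)
        i, j, e = 0, 1, Q.space.index("EVENT")
        dens = (P37 @ Q.Q)[j, e]
        oracle = np.log(P2[i, j]) + np.log(P3[j, i]) + np.log(dens)
        assert ll == pytest.approx(oracle, abs=1e-3)

    def test_invariant_to_person_order_and_record_splitting(self, policy_Q):
        trajs = simulate_trajectories(policy_Q, 40, 20.0, seed=6)
        panel = observe_panel(trajs, [0, 5, 10, 15, 20], rng=7)
        shuffled = PanelDataset(
            panel.df.sample(frac=1.0, random_state=0).sort_values(["id", "exam_time"])
        )
        assert panel_log_likelihood(policy_Q, shuffled) == pytest.approx(
            panel_log_likelihood(policy_Q, panel), rel=1e-12
        )
        # split each person's record at their second observation: the Markov
        # property makes the likelihood factorise identically
        parts = []
        for pid, g in panel.df.groupby("id"):
            g = g.sort_values("exam_time")
            if len(g) > 2:
                head, tail = g.iloc[:2].copy(), g.iloc[1:].copy()
                tail["id"] = pid + 100000
                parts += [head, tail]
            else:
                parts.append(g)
        split = PanelDataset(pd.concat(parts, ignore_index=True))
        assert panel_log_likelihood(policy_Q, split) == pytest.approx(
            panel_log_likelihood(policy_Q, panel), rel=1e-12
        )

    def test_impossible_transition_gives_minus_inf(self, policy_Q):
        panel = PanelDataset(pd.DataFrame(
            {"id": [1, 1], "exam_time": [0.0, 5.0],
             "observed_state": ["HIGH", "LOW"], "attended": [True, True]}
        ))
        with pytest.warns(UserWarning, match="zero model probability"):
            assert panel_log_likelihood(policy_Q, panel) == -np.inf


class TestFit:
    @pytest.fixture(scope="class")
    def small_panel(self):
        Q = default_policy_intensity()
        trajs = simulate_trajectories(Q, 900, 20.0, seed=11)
        return observe_panel(trajs, [0, 5, 10, 15, 20], rng=12), Q

    def test_truth_start_is_at_least_as_good_as_perturbed(self, small_panel):
        panel, Q = small_panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(panel, Q.space, Q_init=Q, compute_ci=False)
        perturbed = IntensityMatrix(
            np.where(Q.space.mask, Q.Q * 2.5, 0.0)
            - np.diag((np.where(Q.space.mask, Q.Q * 2.5, 0.0)).sum(axis=1)),
            Q.space,
        )
        ll_perturbed_start = panel_log_likelihood(perturbed, panel)
        assert res.log_likelihood >= ll_perturbed_start
        assert res.log_likelihood >= panel_log_likelihood(Q, panel)

    def test_different_inits_reach_same_optimum(self, small_panel):
        """Robustness to initial transition values: 4 significant figures."""
        panel, Q = small_panel
        space = Q.space
        init2 = IntensityMatrix(
            np.where(space.mask, 0.05, 0.0) - np.diag(np.where(space.mask, 0.05, 0.0).sum(axis=1)),
            space,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_a = fit(panel, space, Q_init=Q, compute_ci=False)
            res_b = fit(panel, space, Q_init=init2, compute_ci=False)
        ra, rb = res_a.Q.Q[space.mask], res_b.Q.Q[space.mask]
        np.testing.assert_allclose(ra, rb, rtol=5e-4)
        assert res_a.converged and res_b.converged

    def test_fitted_Q_satisfies_invariants_and_ci_brackets_point(self, small_panel):
        panel, Q = small_panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(panel, Q.space)
        res.Q.validate()  # raises if any invariant is broken
        mask = Q.space.mask
        lo, hi = res.rate_ci_lower[mask], res.rate_ci_upper[mask]
        point = res.Q.Q[mask]
        assert (lo <= point + 1e-12).all() and (point <= hi + 1e-12).all()
        assert np.isfinite(res.log_likelihood)

    def test_unobserved_origin_state_is_pinned_with_warning(self, policy_space):
        panel = PanelDataset(pd.DataFrame({
            "id": [1, 1, 2, 2],
            "exam_time": [0.0, 5.0, 0.0, 5.0],
            "observed_state": ["LOW", "LOW", "LOW", "INT_LOW"],
            "attended": True,
        }))
        with pytest.warns(UserWarning, match="never observed"):
            res = fit(panel, policy_space, compute_ci=False, max_iter=50)
        assert "HIGH" in res.pinned_states


class TestSummaries:
    def test_sojourn_times_inverse_identity(self, policy_Q):
        s = sojourn_times(policy_Q)
        # default rates are stored rounded to 5 decimals, hence the tolerance
        assert s["LOW"] == pytest.approx(8.7, abs=2e-3)
        assert s["INT_HIGH"] == pytest.approx(3.9, abs=2e-3)
        space = StateSpace(transient=("LOW",))
        q = IntensityMatrix.from_rates(space, {("LOW", "EVENT"): 0.25})
        assert sojourn_times(q)["LOW"] == pytest.approx(4.0)
        qz = IntensityMatrix(np.zeros((3, 3)), space)
        assert np.isinf(sojourn_times(qz)["LOW"])

    def test_next_state_probabilities_arithmetic(self):
        space = StateSpace(transient=("LOW", "INT_LOW"))
        q = IntensityMatrix.from_rates(
            space, {("LOW", "INT_LOW"): 0.2, ("LOW", "EVENT"): 0.1, ("LOW", "DEATH"): 0.1}
        )
        with pytest.warns(UserWarning, match="no exit"):
            probs = next_state_probabilities(q)
        row = probs.loc["LOW"]
        assert row["INT_LOW"] == pytest.approx(0.5)
        assert row["EVENT"] == pytest.approx(0.25)
        assert row["DEATH"] == pytest.approx(0.25)
        assert probs.loc["LOW"].sum() == pytest.approx(1.0)

    def test_single_exit_gets_probability_one(self):
        q = two_state_chain(0.3)
        assert next_state_probabilities(q).loc["LOW", "EVENT"] == pytest.approx(1.0)

    def test_next_state_frequencies_match_simulation(self, policy_Q, rng):
        n = 20000
        exits = [
            simulate_state_path(policy_Q, "INT_LOW", 1e9, rng).path[1][1]
            for _ in range(n)
        ]
        freq = pd.Series(exits).value_counts(normalize=True)
        probs = next_state_probabilities(policy_Q).loc["INT_LOW"]
        for s, p in probs[probs > 0].items():
            assert abs(freq.get(s, 0.0) - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_mean_time_forward_chain_is_sum_of_sojourns(self):
        space = StateSpace.policy()
        rates = {("LOW", "INT_LOW"): 1 / 8, ("INT_LOW", "INT_HIGH"): 1 / 6,
                 ("INT_HIGH", "HIGH"): 1 / 4}
        Q = IntensityMatrix.from_rates(space, rates)
        assert mean_time_to_state(Q, "HIGH", "LOW") == pytest.approx(18.0, abs=1e-10)
        assert mean_time_to_state(Q, "HIGH", "HIGH") == 0.0

    def test_first_passage_matches_simulation(self, policy_Q, rng):
        """Conditional mean first-passage time to HIGH vs 50000 Gillespie paths."""
        n = 50000
        hits = []
        for _ in range(n):
            traj = simulate_state_path(policy_Q, "INT_LOW", 1e9, rng)
            t_high = traj.first_entry(["HIGH"])
            if t_high is not None:
                hits.append(t_high)
        hits = np.asarray(hits)
        fp = first_passage(policy_Q, "HIGH").loc["INT_LOW"]
        assert abs(len(hits) / n - fp["p_reach"]) < 3 * np.sqrt(
            fp["p_reach"] * (1 - fp["p_reach"]) / n
        )
        se = hits.std() / np.sqrt(len(hits))
        assert abs(hits.mean() - fp["mean_years_given_reach"]) < 3 * se

    def test_unreachable_target_flagged_infinite(self):
        space = StateSpace.policy()
        Q = IntensityMatrix.from_rates(space, {("LOW", "EVENT"): 0.1,
                                               ("INT_LOW", "INT_HIGH"): 0.2,
                                               ("INT_HIGH", "HIGH"): 0.2})
        with pytest.warns(UserWarning, match="unreachable"):
            fp = first_passage(Q, "HIGH")
        assert np.isinf(fp.loc["LOW", "mean_years_given_reach"])

    def test_occupancy_limits(self, policy_Q):
        pi = [0.54, 0.30, 0.09, 0.07]
        at0 = occupancy(policy_Q, 0.0, pi)
        np.testing.assert_allclose(at0[:4], pi, atol=1e-14)
        late = occupancy(policy_Q, 2000.0, pi)
        assert late[["EVENT", "DEATH"]].sum() == pytest.approx(1.0, abs=1e-9)

    def test_occupancy_matches_empirical_counts(self, policy_Q):
        n = 8000
        trajs = simulate_trajectories(policy_Q, n, 15.0, seed=31)
        for t in (5.0, 10.0):
            states = pd.Series([tr.state_at(t) for tr in trajs])
            emp = states.value_counts(normalize=True)
            exp = occupancy(policy_Q, t, [0.54, 0.30, 0.09, 0.07])
            # 4 SE: twelve cells are checked simultaneously, so a per-cell
            # 3 SE band would reject a correct model ~4% of the time
            for s, p in exp.items():
                if p > 1e-6:
                    assert abs(emp.get(s, 0.0) - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_total_occupancy_exceeds_single_visit_sojourn(self, policy_Q):
        total = expected_total_occupancy(policy_Q, "LOW")
        assert total["LOW"] >= sojourn_times(policy_Q)["LOW"] - 1e-12
        # and equals the Euler-style identity: rows of (-Q_TT)^-1 sum checks
        nt = policy_Q.space.n_transient
        M = np.linalg.inv(-policy_Q.Q[:nt, :nt])
        np.testing.assert_allclose(total.to_numpy(), M[0], atol=1e-12)

    def test_descriptive_variant_high_exit_split(self):
        Q = default_descriptive_intensity()
        probs = next_state_probabilities(Q).loc["HIGH"]
        assert probs["INT_HIGH"] == pytest.approx(0.427, abs=1e-9)
        assert probs["VERY_HIGH"] == pytest.approx(0.472, abs=1e-9)
        assert probs["EVENT"] == pytest.approx(0.045, abs=1e-9)
        assert probs["DEATH"] == pytest.approx(0.056, abs=1e-9)
        assert sojourn_times(Q)["HIGH"] == pytest.approx(6.7, abs=1e-9)
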