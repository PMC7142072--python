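"""Statistical model checking engine: search grids, perturbation,
tunnel checking, SPRT pruning, Monte Carlo match estimation, ranking
and the Spearman correlogram."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pelagia import (ForcingSeries, ParameterSet, Trajectory, check_tunnel,
                     chernoff_n, simulate, sprt_decide)
from pelagia.model import FLUX_NAMES
from pelagia.params import TABLE_SEARCH_VECTORS
from pelagia.scenarios import make_lab_degrowth
from pelagia.smce import (CandidateVector, SearchVector, SMCConfig, SprtTest,
                          correlogram, enumerate_space, estimate_match,
                          evaluate_space, perturb, space_size)
from pelagia.tunnels import TunnelSet


def table_vectors() -> dict:
    return {k: SearchVector(*v) for k, v in TABLE_SEARCH_VECTORS.items()}


# ---------------------------------------------------------------------------
# search space
# ---------------------------------------------------------------------------

class TestSearchSpace:
    def test_inclusive_endpoint_grid(self):
        vec = SearchVector(0.4, 0.1, 1.0)
        np.testing.assert_allclose(vec.values(),
                                   [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])

    @pytest.mark.parametrize("name, count", [
        ("k_p", 9), ("a_max", 6), ("k_a", 8), ("c_re", 21),
        ("spn", 7), ("c_e", 11), ("F_lab", 6)])
    def test_published_bracket_counts(self, name, count):
        assert len(SearchVector(*TABLE_SEARCH_VECTORS[name])) == count

    def test_product_rule(self):
        vecs = {"a": SearchVector(0, 1, 1), "b": SearchVector(0, 1, 2)}
        assert space_size(vecs) == 6
        assert len(list(enumerate_space(vecs))) == 6

    def test_full_grid_size(self):
        assert space_size(table_vectors()) == 4_191_264

    def test_lexicographic_order_and_indices(self):
        vecs = {"spn": SearchVector(0.4, 0.1, 0.6),
                "c_e": SearchVector(0.0, 0.2, 0.2)}
        cands = list(enumerate_space(vecs))
        assert [c.index for c in cands] == list(range(6))
        # spn is canonical-first, so it varies slowest
        assert [c.center["spn"] for c in cands] == pytest.approx(
            [0.4, 0.4, 0.5, 0.5, 0.6, 0.6])

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            space_size({})


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------

class TestPerturb:
    def test_zero_std_returns_central_vector(self, rng):
        cand = CandidateVector(center={"spn": 0.7, "c_e": 0.4},
                               pseudo_std={"spn": 0.0, "c_e": 0.0})
        draw = perturb(cand, rng)
        assert draw["spn"] == 0.7 and draw["c_e"] == 0.4

    def test_uniform_box_statistics(self, rng):
        cand = CandidateVector(center={"spn": 0.7}, pseudo_std={"spn": 0.05})
        draws = perturb(cand, rng, size=100_000)["spn"]
        assert draws.min() == pytest.approx(0.65, abs=1e-3)
        assert draws.max() == pytest.approx(0.75, abs=1e-3)
        assert draws.mean() == pytest.approx(0.7, abs=1e-3)

    def test_nonnegativity_truncation(self, rng):
        cand = CandidateVector(center={"c_e": 0.0}, pseudo_std={"c_e": 0.025})
        draws = perturb(cand, rng, size=10_000)["c_e"]
        assert draws.min() >= 0.0 and draws.max() <= 0.025

    def test_p_max_recomputed_from_drawn_kp(self, rng):
        cand = CandidateVector(center={"k_p": 1.9e-4},
                               pseudo_std={"k_p": 1e-5})
        d = perturb(cand, rng, size=100)
        np.testing.assert_allclose(d["p_max"],
                                   0.1399 * (1 + d["k_p"] / 1.2e-4))

    def test_a_max_capped_at_one(self, rng):
        cand = CandidateVector(center={"a_max": 1.0},
                               pseudo_std={"a_max": 0.05})
        draws = perturb(cand, rng, size=10_000)["a_max"]
        assert draws.max() <= 1.0 and draws.min() >= 0.95


# ---------------------------------------------------------------------------
# tunnel checking
# ---------------------------------------------------------------------------

def flat_trajectory(values, times=None) -> Trajectory:
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None else times
    return Trajectory(t=t, cm=values, bd=values, wm=values,
                      fluxes={k: np.zeros_like(values) for k in FLUX_NAMES})


class TestCheckTunnel:
    def test_midline_trajectory_is_inside_with_zero_distance(self):
        tun = TunnelSet([0, 1, 2], [1.0, 1.5, 2.0], [3.0, 3.5, 4.0])
        traj = flat_trajectory(tun.midline)
        assert check_tunnel(traj, tun) == (True, 0.0)

    def test_single_excursion_of_one_half_width(self):
        n = 4
        tun = TunnelSet(range(n), [0.0] * n, [2.0] * n)  # half-width 1
        vals = np.array([1.0, 1.0, 3.0, 1.0])  # one point 1 half-width out
        inside, dist = check_tunnel(flat_trajectory(vals), tun)
        assert not inside
        assert dist == pytest.approx(1.0 / n)

    def test_degenerate_band_requires_exact_equality(self):
        tun = TunnelSet([0, 1], [2.0, 2.0], [2.0, 2.0])
        assert check_tunnel(flat_trajectory([2.0, 2.0]), tun)[0]
        assert not check_tunnel(flat_trajectory([2.0, 2.0001]), tun)[0]

    def test_interpolation_between_model_steps(self):
        # trajectory linear from 0 to 2 over [0, 2]; tunnel at t=0.5
        traj = flat_trajectory([0.0, 1.0, 2.0])
        tun = TunnelSet([0.5], [0.4], [0.6])
        assert check_tunnel(traj, tun)[0]

    def test_truncated_trajectory_counts_as_outside(self):
        traj = flat_trajectory([1.0, 1.0])  # spans t in [0, 1] only
        tun = TunnelSet([0.0, 5.0], [0.0, 0.0], [2.0, 2.0])
        inside, dist = check_tunnel(traj, tun)
        assert not inside
        assert dist == pytest.approx(0.5)  # one missing point of two


# ---------------------------------------------------------------------------
# SPRT
# ---------------------------------------------------------------------------

class TestSprt:
    def test_all_fail_stream_rejects_at_the_wald_boundary(self):
        gamma, eps, delta = 0.70, 0.05, 0.01
        decision, n = sprt_decide(iter([False] * 1000), gamma, eps, delta)
        assert decision == "reject_below_threshold"
        # closed form: each failure adds ln((1-(g-e))/(1-(g+e))) to the LLR
        inc = math.log((1 - (gamma - eps)) / (1 - (gamma + eps)))
        expected = math.ceil(math.log((1 - delta) / delta) / inc)
        assert n == expected

    def test_all_pass_stream_never_rejects(self):
        decision, n = sprt_decide(iter([True] * 500), 0.70, 0.05, 0.01)
        assert decision == "complete" and n == 500

    def test_rejection_is_sticky(self):
        t = SprtTest(0.7, 0.05, 0.01)
        while t.update(False) == "continue":
            pass
        assert t.update(True) == "reject_below_threshold"

    def test_boundary_parameters_validated(self):
        with pytest.raises(ValueError):
            SprtTest(0.99, 0.05, 0.01)

    def test_chernoff_sample_size(self):
        # the 5% / 1% setting needs ~1060 draws by the Chernoff bound
        assert chernoff_n(0.05, 0.01) == 1060


# ---------------------------------------------------------------------------
# Monte Carlo match estimation through the engine
# ---------------------------------------------------------------------------

def degrowth_scenario_with_band(lo, hi, at_day=10.0, initial_bd=4.5):
    sc = make_lab_degrowth(duration=15.0, initial_bd=initial_bd)
    return sc.with_tunnel(TunnelSet([at_day], [lo], [hi], "bd"))


def toy_candidate(std=1.0) -> CandidateVector:
    # c_e ~ Uniform[0, 2] around center 1; bd(day 10) is strictly
    # decreasing in c_e, so a one-sided band has an analytic pass rate
    return CandidateVector(center={"c_e": 1.0}, pseudo_std={"c_e": std})


def bd_at_day10(c_e: float) -> float:
    sc = make_lab_degrowth(duration=15.0, initial_bd=4.5)
    traj = simulate(4.5, sc.forcing, ParameterSet(c_e=c_e))
    return float(traj.values_at([10.0], "bd")[0])


class TestEstimateMatch:
    def test_infinitely_wide_tunnel_always_matches(self, params):
        sc = degrowth_scenario_with_band(0.0, 1e9)
        r = estimate_match(toy_candidate(), [sc], params,
                           SMCConfig(n_sims=50, rng_seed=1))
        assert r.theta_hat == 1.0
        assert r.decided_by == "monte_carlo"
        assert r.n_used == 50

    def test_unreachable_band_never_matches_and_prunes_early(self, params):
        sc = degrowth_scenario_with_band(100.0, 101.0)
        r = estimate_match(toy_candidate(), [sc], params,
                           SMCConfig(n_sims=500, rng_seed=1))
        assert r.theta_hat == 0.0
        assert r.decided_by == "sprt_reject"
        assert r.n_used < 500

    def test_theta_matches_analytic_pass_probability(self, params):
        # pass iff drawn c_e < 0.3 * 2, i.e. probability 0.3
        threshold = bd_at_day10(0.6)
        sc = degrowth_scenario_with_band(threshold, 1e9)
        cfg = SMCConfig(n_sims=500, rng_seed=7, use_sprt=False)
        r = estimate_match(toy_candidate(), [sc], params, cfg)
        tol = 3 * math.sqrt(0.3 * 0.7 / 500)
        assert abs(r.theta_hat - 0.3) <= tol
        assert r.score["degrowth"] == pytest.approx(1 - r.theta_hat)

    def test_score_complements_theta_when_all_simulations_run(self, params):
        threshold = bd_at_day10(1.0)
        sc = degrowth_scenario_with_band(threshold, 1e9)
        cfg = SMCConfig(n_sims=200, rng_seed=3, use_sprt=False)
        r = estimate_match(toy_candidate(), [sc], params, cfg)
        assert r.n_used == 200
        assert r.score["degrowth"] * r.n_used == pytest.approx(
            (1 - r.theta_hat) * r.n_used)


class TestEvaluateSpace:
    def test_exactly_the_passing_candidate_is_retained(self, params):
        sc = degrowth_scenario_with_band(0.0, 1e9)
        bad_sc = degrowth_scenario_with_band(100.0, 101.0)
        good = CandidateVector(center={"c_e": 0.0}, pseudo_std={"c_e": 0.0},
                               index=0)
        bad = CandidateVector(center={"c_e": 0.0}, pseudo_std={"c_e": 0.0},
                              index=1)
        cfg = SMCConfig(n_sims=50, rng_seed=0)
        res_good = evaluate_space([good], [sc], params, cfg)
        res_bad = evaluate_space([bad], [bad_sc], params, cfg)
        assert res_good[0].retained and not res_bad[0].retained

    def test_results_independent_of_candidate_order(self, params):
        threshold = bd_at_day10(1.0)
        sc = degrowth_scenario_with_band(threshold, 1e9)
        cands = [CandidateVector(center={"c_e": c}, pseudo_std={"c_e": 0.3},
                                 index=i)
                 for i, c in enumerate([0.3, 0.9, 1.5])]
        cfg = SMCConfig(n_sims=60, rng_seed=5)
        fwd = evaluate_space(cands, [sc], params, cfg)
        rev = evaluate_space(cands[::-1], [sc], params, cfg)
        by_index_fwd = {r.candidate.index: r.theta_hat for r in fwd}
        by_index_rev = {r.candidate.index: r.theta_hat for r in rev}
        assert by_index_fwd == by_index_rev

    def test_bit_identical_reruns(self, params):
        threshold = bd_at_day10(1.0)
        sc = degrowth_scenario_with_band(threshold, 1e9)
        cands = [CandidateVector(center={"c_e": 1.0}, pseudo_std={"c_e": 0.5},
                                 index=0)]
        cfg = SMCConfig(n_sims=80, rng_seed=11)
        r1 = evaluate_space(cands, [sc], params, cfg)[0]
        r2 = evaluate_space(cands, [sc], params, cfg)[0]
        assert r1.theta_hat == r2.theta_hat
        assert r1.dist == r2.dist and r1.n_used == r2.n_used

    def test_widening_the_tunnel_never_lowers_theta(self, params):
        threshold = bd_at_day10(0.8)
        cand = toy_candidate()
        cfg = SMCConfig(n_sims=100, rng_seed=2, use_sprt=False)
        thetas = []
        for factor in (1.0, 2.0, 4.0):
            tun = TunnelSet([10.0], [threshold], [2 * 4.5 - threshold], "bd")
            sc = make_lab_degrowth(15.0, 4.5).with_tunnel(tun.widen(factor))
            thetas.append(estimate_match(cand, [sc], params, cfg).theta_hat)
        assert thetas == sorted(thetas)


# ---------------------------------------------------------------------------
# correlogram
# ---------------------------------------------------------------------------

class TestCorrelogram:
    def test_self_correlation_is_one_and_matrix_symmetric(self, rng):
        df = pd.DataFrame({"x": rng.random(10), "y": rng.random(10)})
        corr = correlogram(df)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == corr.loc["y", "x"]

    def test_monotone_transform_has_perfect_rank_correlation(self, rng):
        x = rng.random(20)
        df = pd.DataFrame({"x": x, "y": x ** 3})
        assert correlogram(df).loc["x", "y"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        df = pd.DataFrame(rng.random((5, 3)), columns=list("abc"))
        corr = correlogram(df)
        for i in "abc":
            for j in "abc":
                expected = stats.pearsonr(stats.rankdata(df[i]),
                                          stats.rankdata(df[j]))[0]
                assert corr.loc[i, j] == pytest.approx(expected, rel=1e-12)

    def test_constant_column_reported_missing_not_zero(self, rng):
        df = pd.DataFrame({"x": rng.random(8), "k": np.ones(8)})
        corr = correlogram(df)
        assert np.isnan(corr.loc["x", "k"]) and np.isnan(corr.loc["k", "k"])

    def test_requires_three_rows(self):
        with pytest.raises(ValueError):
            correlogram(pd.DataFrame({"x": [1.0, 2.0]}))
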