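"""4-state CTMC for binary trait pairs: generator structure, pruning
likelihood against enumeration, ML/MCMC behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import ratetrait as rt
from ratetrait.coevolution import (
    DEPENDENT_RATES,
    INDEPENDENT_RATES,
    STATES,
    _transition_matrices,
    build_rate_matrix,
    fit_ml,
    independent_to_dependent,
    pruning_loglik,
    run_mcmc,
    transition_rate_report,
)
from ratetrait.simulate import simulate_binary_pair_ctmc, simulate_species_tree


def random_dependent_rates(rng):
    return {k: float(rng.uniform(0.05, 2.0)) for k in DEPENDENT_RATES}


def enumeration_loglik(tree, tips, Q, pi):
    """Oracle: sum the likelihood over every internal-node state assignment
    using per-branch expm products."""
    order = tree.postorder_branches()
    internal = [b for b in order if tree.children(b)]
    P = {b: expm(Q * tree.duration(b)) for b in order}
    idx = {s: i for i, s in enumerate(STATES)}
    tip_idx = {t: idx[f"{a}{b}"] for t, (a, b) in tips.items()}
    total = 0.0
    for root_state in range(4):
        for assignment in itertools.product(range(4), repeat=len(internal)):
            states = dict(zip(internal, assignment))
            prob = pi[root_state]
            for b in order:
                parent = tree.parent(b)
                s_par = root_state if parent is None else states[parent]
                s_child = states[b] if b in states else tip_idx[b]
                prob *= P[b][s_par, s_child]
            total += prob
    return np.log(total)


def two_state_pruning(tree, tip_states, q01, q10):
    """Oracle: single binary trait pruning likelihood (2-state chain)."""
    Q = np.array([[-q01, q01], [q10, -q10]])
    L = {}
    for b in tree.postorder_branches():
        kids = tree.children(b)
        if not kids:
            v = np.zeros(2)
            v[tip_states[b]] = 1.0
            L[b] = v
        else:
            L[b] = np.prod(
                [expm(Q * tree.duration(c)) @ L[c] for c in kids], axis=0
            )
    root = np.prod(
        [expm(Q * tree.duration(c)) @ L[c] for c in tree.children(None)], axis=0
    )
    with np.errstate(divide="ignore"):
        return np.log(0.5 * root.sum())


class TestRateMatrix:
    def test_zero_rates_give_zero_generator(self):
        Q = build_rate_matrix({k: 0.0 for k in INDEPENDENT_RATES}, "independent")
        assert np.all(Q == 0.0)

    def test_independent_structure(self):
        Q = build_rate_matrix({k: 0.7 for k in INDEPENDENT_RATES}, "independent")
        assert np.allclose(Q.sum(axis=1), 0.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert sorted(off)[:4] == [0.0] * 4  # the four forbidden dual jumps
        for row in range(4):
            vals = [Q[row, c] for c in range(4) if c != row]
            assert sorted(vals) == [0.0, 0.7, 0.7]

    def test_dual_transitions_forbidden(self):
        rng = np.random.default_rng(0)
        Q = build_rate_matrix(random_dependent_rates(rng), "dependent")
        i = {s: k for k, s in enumerate(STATES)}
        for a, b in [("00", "11"), ("11", "00"), ("01", "10"), ("10", "01")]:
            assert Q[i[a], i[b]] == 0.0

    def test_negative_rate_rejected(self):
        params = {k: 0.1 for k in INDEPENDENT_RATES}
        params["qA01"] = -0.1
        with pytest.raises(ValueError, match="negative"):
            build_rate_matrix(params, "independent")

    def test_missing_rate_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_rate_matrix({"qA01": 1.0}, "independent")

    def test_transition_matrices_are_stochastic(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            Q = build_rate_matrix(random_dependent_rates(rng), "dependent")
            P = _transition_matrices(Q, np.array([0.1, 1.0, 10.0]))
            assert np.abs(P.sum(axis=2) - 1.0).max() < 1e-10
            assert P.min() > -1e-12

    def test_expm_matches_series_for_small_qt(self):
        rng = np.random.default_rng(2)
        Q = build_rate_matrix(random_dependent_rates(rng), "dependent")
        t = 1e-3
        P = _transition_matrices(Q, np.array([t]))[0]
        import math

        series = sum(np.linalg.matrix_power(Q * t, k) / math.factorial(k)
                     for k in range(20))
        assert np.abs(P - series).max() < 1e-10


class TestPruning:
    def test_zero_duration_tree_pins_tips_to_root(self, balanced4):
        zero = rt.SpeciesTree.from_newick(
            "((A:0,B:0):0,(C:0,D:0):0);", time_calibrated=True
        )
        Q = build_rate_matrix({k: 1.0 for k in INDEPENDENT_RATES}, "independent")
        tips = {t: (0, 0) for t in "ABCD"}
        assert pruning_loglik(zero, tips, Q) == pytest.approx(np.log(0.25))
        tips["D"] = (1, 1)
        assert pruning_loglik(zero, tips, Q) == -np.inf

    def test_matches_enumeration_oracle(self, balanced4):
        rng = np.random.default_rng(3)
        pi = np.full(4, 0.25)
        for _ in range(5):
            Q = build_rate_matrix(random_dependent_rates(rng), "dependent")
            tips = {t: (int(rng.integers(2)), int(rng.integers(2))) for t in "ABCD"}
            got = pruning_loglik(balanced4, tips, Q, pi)
            want = enumeration_loglik(balanced4, tips, Q, pi)
            assert got == pytest.approx(want, abs=1e-10)

    def test_independent_model_factorizes(self):
        rng = np.random.default_rng(4)
        tree = simulate_species_tree(12, seed=9, target_depth=10.0)
        for _ in range(3):
            params = {k: float(rng.uniform(0.05, 1.0)) for k in INDEPENDENT_RATES}
            Q = build_rate_matrix(params, "independent")
            tips = {
                t: (int(rng.integers(2)), int(rng.integers(2))) for t in tree.taxa
            }
            joint = pruning_loglik(tree, tips, Q)
            la = two_state_pruning(
                tree, {t: s[0] for t, s in tips.items()},
                params["qA01"], params["qA10"],
            )
            lb = two_state_pruning(
                tree, {t: s[1] for t, s in tips.items()},
                params["qB01"], params["qB10"],
            )
            assert joint == pytest.approx(la + lb, abs=1e-8)

    def test_invariant_to_taxon_order_and_rotation(self, balanced4):
        rng = np.random.default_rng(5)
        Q = build_rate_matrix(random_dependent_rates(rng), "dependent")
        tips = {"A": (0, 1), "B": (1, 1), "C": (0, 0), "D": (1, 0)}
        ll = pruning_loglik(balanced4, tips, Q)
        reordered = dict(reversed(list(tips.items())))
        assert pruning_loglik(balanced4, reordered, Q) == pytest.approx(ll, abs=1e-12)
        rotated = rt.SpeciesTree.from_newick(
            "((D:1,C:1):1,(B:1,A:1):1);", time_calibrated=True
        )
        assert pruning_loglik(rotated, tips, Q) == pytest.approx(ll, abs=1e-12)

    def test_missing_tip_marginalized(self, balanced4):
        rng = np.random.default_rng(6)
        Q = build_rate_matrix(random_dependent_rates(rng), "dependent")
        tips = {"A": (0, 1), "B": (1, 1), "C": (0, 0), "D": (np.nan, np.nan)}
        ll = pruning_loglik(balanced4, tips, Q)
        # equals the sum over D's possible states weighted by transition probs,
        # i.e. the likelihood of the tree with D pruned
        pruned = rt.SpeciesTree.from_newick("((A:1,B:1):1,C:2);", time_calibrated=True)
        ll_pruned = pruning_loglik(
            pruned, {k: v for k, v in tips.items() if k != "D"}, Q
        )
        assert ll == pytest.approx(ll_pruned, abs=1e-10)

    def test_requires_time_calibrated_tree(self):
        t = rt.SpeciesTree.from_newick("((A:1,B:1):1,C:2);")
        Q = build_rate_matrix({k: 0.1 for k in INDEPENDENT_RATES}, "independent")
        with pytest.raises(ValueError, match="time-calibrated"):
            pruning_loglik(t, {"A": (0, 0), "B": (0, 0), "C": (0, 0)}, Q)

    def test_root_distribution_must_normalize(self, balanced4):
        Q = build_rate_matrix({k: 0.1 for k in INDEPENDENT_RATES}, "independent")
        with pytest.raises(ValueError, match="sum to 1"):
            pruning_loglik(balanced4, {t: (0, 0) for t in "ABCD"}, Q, np.ones(4))


class TestInference:
    def test_ml_recovers_rates_on_moderate_tree(self):
        tree = simulate_species_tree(150, seed=20, target_depth=100.0)
        truth = dict(qA01=0.05, qA10=0.05, qB01=0.05, qB10=0.05)
        sim = simulate_binary_pair_ctmc(
            tree, Q=build_rate_matrix(truth, "independent"), seed=21
        )
        fit = fit_ml(tree, sim["tips"], "independent", restarts=3, seed=22)
        geo = np.exp(np.mean(np.log(list(fit.rates.values()))))
        assert 0.05 / 3 < geo < 0.05 * 3
        assert fit.converged

    def test_dependent_embeds_independent(self, balanced4):
        rng = np.random.default_rng(23)
        params = {k: float(rng.uniform(0.1, 1.0)) for k in INDEPENDENT_RATES}
        tips = {"A": (0, 1), "B": (1, 1), "C": (0, 0), "D": (1, 0)}
        ll_i = pruning_loglik(balanced4, tips, build_rate_matrix(params, "independent"))
        ll_d = pruning_loglik(
            balanced4, tips,
            build_rate_matrix(independent_to_dependent(params), "dependent"),
        )
        assert ll_i == pytest.approx(ll_d, abs=1e-12)

    def test_mcmc_deterministic_and_diagnosed(self):
        tree = simulate_species_tree(30, seed=24, target_depth=100.0)
        sim = simulate_binary_pair_ctmc(
            tree,
            Q=build_rate_matrix(
                {k: 0.05 for k in INDEPENDENT_RATES}, "independent"
            ),
            seed=25,
        )
        tr1 = run_mcmc(tree, sim["tips"], "independent", iterations=300, seed=26)
        tr2 = run_mcmc(tree, sim["tips"], "independent", iterations=300, seed=26)
        pd.testing.assert_frame_equal(tr1.rates, tr2.rates)
        assert len(tr1.rates) == 300
        assert 0.05 < tr1.acceptance_rate < 0.8
        # posterior mass in a broad bracket (30 taxa identify rates only
        # weakly, so the exponential prior pulls estimates toward its mean)
        pm = tr1.posterior_mean()
        assert (pm > 1e-3).all() and (pm < 5.0).all()

    def test_mcmc_rejects_bad_arguments(self, balanced4):
        tips = {t: (0, 0) for t in "ABCD"}
        with pytest.raises(ValueError, match="iterations"):
            run_mcmc(balanced4, tips, iterations=0)
        with pytest.raises(ValueError, match="prior"):
            run_mcmc(balanced4, tips, prior_mean=0.0, iterations=10)


class TestReport:
    def test_report_structure(self):
        rng = np.random.default_rng(27)
        rates = random_dependent_rates(rng)
        fit = rt.CoevolutionFit(
            model="dependent", rates=rates, loglik=-10.0, converged=True, n_restarts=1
        )
        rep = transition_rate_report(fit)
        assert len(rep) == 8
        assert list(rep.columns)[:5] == [
            "transition", "from_state", "to_state", "changing_trait", "rate_per_Ma",
        ]
        # every transition flips exactly one trait
        for _, row in rep.iterrows():
            diffs = sum(a != b for a, b in zip(row.from_state, row.to_state))
            assert diffs == 1
        assert list(rep["transition"]) == [
            "q00_10", "q00_01", "q01_11", "q01_00",
            "q10_00", "q10_11", "q11_01", "q11_10",
        ]

    def test_report_expands_independent_model(self):
        params = dict(qA01=0.1, qA10=0.2, qB01=0.3, qB10=0.4)
        fit = rt.CoevolutionFit(
            model="independent", rates=params, loglik=-5.0, converged=True, n_restarts=1
        )
        rep = transition_rate_report(fit).set_index("transition")
        assert rep.loc["q00_10", "rate_per_Ma"] == 0.1
        assert rep.loc["q01_11", "rate_per_Ma"] == 0.1
        assert rep.loc["q11_01", "rate_per_Ma"] == 0.2
        assert rep.loc["q10_11", "rate_per_Ma"] == 0.3
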