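import numpy as np
import pandas as pd
import pytest

from spotdecon.dwls import (
    SolverConfig,
    cluster_spots_kmeans,
    dampened_weights,
    deconvolve,
    deconvolve_spot,
    select_damping,
    solve_constrained_wls,
)
from spotdecon.enrichment import binarize
from spotdecon.io import InputContractError


def weighted_objective(S, t, w, f):
    r = S @ f - t
    return float(np.sum(w * r * r))


class TestSolveConstrainedWls:
    def test_noiseless_recovery_full_rank(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(0.1, 5, size=(40, 4))
        f_true = rng.dirichlet(np.ones(4))
        f = solve_constrained_wls(S, S @ f_true)
        assert np.abs(f - f_true).max() < 1e-6

    def test_single_type_returns_one(self):
        S = np.ones((5, 1))
        assert solve_constrained_wls(S, np.array([9, 1, 0, 2, 3.0])) == pytest.approx([1.0])

    def test_beats_random_simplex_search(self):
        rng = np.random.default_rng(42)
        S = rng.uniform(0, 3, size=(40, 4))
        t = rng.uniform(0, 3, size=40)
        w = rng.uniform(0.2, 5, size=40)
        f = solve_constrained_wls(S, t, w)
        candidates = rng.dirichlet(np.ones(4), size=10_000)
        best_random = min(weighted_objective(S, t, w, c) for c in candidates)
        assert weighted_objective(S, t, w, f) <= best_random + 1e-9

    def test_all_zero_spot_gives_uniform(self):
        f = solve_constrained_wls(np.ones((5, 3)), np.zeros(5))
        assert np.allclose(f, 1 / 3)

    def test_rank_deficient_signature_still_on_simplex(self):
        S = np.ones((6, 3))  # identical columns
        f = solve_constrained_wls(S, np.full(6, 2.0))
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert (f >= 0).all()

    def test_gene_permutation_leaves_solution_unchanged(self):
        rng = np.random.default_rng(5)
        S = rng.uniform(0, 4, size=(30, 3))
        t = rng.uniform(0, 4, size=30)
        w = rng.uniform(0.5, 2, size=30)
        perm = rng.permutation(30)
        f1 = solve_constrained_wls(S, t, w)
        f2 = solve_constrained_wls(S[perm], t[perm], w[perm])
        assert np.allclose(f1, f2, atol=1e-8)

    def test_type_permutation_permutes_solution(self):
        rng = np.random.default_rng(6)
        S = rng.uniform(0, 4, size=(30, 4))
        t = rng.uniform(0, 4, size=30)
        perm = np.array([2, 0, 3, 1])
        f1 = solve_constrained_wls(S, t)
        f2 = solve_constrained_wls(S[:, perm], t)
        assert np.allclose(f1[perm], f2, atol=1e-8)


class TestDampenedWeights:
    def test_constant_fitted_values_give_equal_weights(self):
        S = np.ones((7, 2))
        f = np.array([0.5, 0.5])
        w = dampened_weights(S, f, d=8.0)
        assert np.allclose(w, w[0])

    def test_d_one_caps_everything_at_min_weight(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(0.5, 4, size=(20, 3))
        f = rng.dirichlet(np.ones(3))
        w = dampened_weights(S, f, d=1.0)
        assert np.allclose(w, w.min())

    def test_matches_loop_recomputation(self):
        rng = np.random.default_rng(2)
        S = rng.uniform(0, 3, size=(15, 3))
        f = rng.dirichlet(np.ones(3))
        d = 16.0
        w = dampened_weights(S, f, d)
        fitted = S @ f
        raw = np.array([1.0 / max(v**2, 1e-12) for v in fitted])
        expected = np.minimum(raw, d * raw.min())
        assert np.allclose(w, expected)


class TestSelectDamping:
    def test_noiseless_tie_break_returns_smallest(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0.5, 3, size=(40, 3))
        t = S @ rng.dirichlet(np.ones(3))
        cfg = SolverConfig(seed=1)
        assert select_damping(S, t, cfg) == cfg.damping_candidates[0]

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(4)
        S = rng.uniform(0.5, 3, size=(40, 3))
        cfg = SolverConfig(damping_candidates=(8.0,), seed=1)
        assert select_damping(S, S @ np.array([0.3, 0.3, 0.4]), cfg) == 8.0

    def test_count_noise_selects_finite_dampening(self):
        # Poisson counts: low-expression genes carry the largest relative
        # noise, so uncapped inverse-squared-fit weights overweight them and
        # cross-validation should prefer a finite cap most of the time.
        rng = np.random.default_rng(10)
        S = np.vstack(
            [rng.uniform(5, 10, size=(15, 3)), rng.uniform(0.05, 0.3, size=(15, 3))]
        )
        f_true = np.array([0.5, 0.3, 0.2])
        cfg = SolverConfig(cv_folds=3, seed=0)
        hits = 0
        n_runs = 50
        for rep in range(n_runs):
            t = rng.poisson(20.0 * (S @ f_true)) / 20.0
            d = select_damping(S, t, SolverConfig(cv_folds=3, seed=rep))
            if d < cfg.damping_candidates[-1]:
                hits += 1
        assert hits >= 0.8 * n_runs

    def test_too_few_genes_rejected(self):
        with pytest.raises(InputContractError, match="genes"):
            select_damping(np.ones((5, 2)), np.ones(5), SolverConfig(cv_folds=10))


class TestDeconvolveSpot:
    def test_noiseless_converges_within_three_iterations(self):
        rng = np.random.default_rng(8)
        S = rng.uniform(0.5, 4, size=(50, 4))
        f_true = rng.dirichlet(np.ones(4))
        f, info = deconvolve_spot(S, S @ f_true, SolverConfig(seed=0), d=4.0)
        assert np.abs(f - f_true).max() < 1e-6
        assert info["converged"] and info["n_iter"] <= 3

    def test_unit_fixed_weights_reduce_to_plain_ls(self):
        rng = np.random.default_rng(9)
        S = rng.uniform(0, 3, size=(30, 3))
        t = rng.uniform(0, 3, size=30)
        f_fixed, _ = deconvolve_spot(S, t, fixed_weights=np.ones(30))
        assert np.allclose(f_fixed, solve_constrained_wls(S, t), atol=1e-9)

    def test_poisson_mixture_recovery(self):
        # 3 types, 60 markers each at 10x, depth 2000: mean per-type |error| < 0.05
        rng = np.random.default_rng(7)
        n_types, mpt = 3, 60
        profile = np.ones((n_types * mpt + 100, n_types))
        for k in range(n_types):
            profile[k * mpt:(k + 1) * mpt, k] = 10.0
        profile /= profile.sum(axis=0, keepdims=True)
        errors = []
        for _ in range(50):
            f_true = rng.dirichlet(np.ones(n_types))
            t = rng.poisson(2000 * profile @ f_true).astype(float)
            S = profile * 2000
            f, _ = deconvolve_spot(S, t, SolverConfig(seed=0), d=4.0)
            errors.append(np.abs(f - f_true))
        assert np.mean(errors, axis=0).max() < 0.05

    def test_reweighting_objective_monotone_per_iteration(self):
        # each solve minimizes its own weighted objective given the new weights
        rng = np.random.default_rng(11)
        S = rng.uniform(0.2, 4, size=(40, 4))
        t = np.clip(S @ rng.dirichlet(np.ones(4)) + rng.normal(0, 0.3, 40), 0, None)
        d = 16.0
        f = solve_constrained_wls(S, t)
        for _ in range(10):
            w = dampened_weights(S, f, d)
            f_next = solve_constrained_wls(S, t, w)
            assert (weighted_objective(S, t, w, f_next)
                    <= weighted_objective(S, t, w, f) + 1e-9)
            if np.max(np.abs(f_next - f)) < 1e-10:
                break
            f = f_next


def _toy_problem():
    rng = np.random.default_rng(21)
    genes = [f"g{i}" for i in range(60)]
    types = ["A", "B", "C"]
    sig = pd.DataFrame(rng.uniform(0.5, 5, size=(60, 3)), index=genes, columns=types)
    frac = pd.DataFrame(
        [[0.7, 0.3, 0.0], [0.2, 0.8, 0.0], [0.0, 0.5, 0.5], [0.1, 0.2, 0.7]],
        index=[f"s{i}" for i in range(4)], columns=types,
    )
    spots = pd.DataFrame(
        (sig.to_numpy() @ frac.to_numpy().T), index=genes, columns=frac.index
    )
    return sig, frac, spots


class TestDeconvolve:
    def test_identical_spots_in_one_cluster_give_identical_rows(self):
        sig, _, _ = _toy_problem()
        t = sig.to_numpy() @ np.array([0.5, 0.25, 0.25])
        spots = pd.DataFrame({f"s{i}": t for i in range(4)}, index=sig.index)
        comp = deconvolve(spots, sig, cfg=SolverConfig(seed=0))
        assert np.allclose(comp.fractions.to_numpy() - comp.fractions.to_numpy()[0], 0)

    def test_min_frequency_second_round_zeroes_small_types(self):
        sig, _, _ = _toy_problem()
        t = sig.to_numpy() @ np.array([0.97, 0.02, 0.01])
        spots = pd.DataFrame({"s0": t}, index=sig.index)
        comp = deconvolve(spots, sig, cfg=SolverConfig(seed=0, min_frequency=0.02))
        row = comp.fractions.loc["s0"]
        # 0.02 is kept (strict < removes), 0.01 removed exactly
        assert row["C"] == 0.0
        assert row["B"] > 0.0
        assert comp.flags.loc["s0", "rounds"] == 2

    def test_rows_on_simplex_and_masked_types_exactly_zero(self):
        sig, frac, spots = _toy_problem()
        es = pd.DataFrame(
            [[5.0, 5, 5, 5], [5.0, 5, 5, 5], [-3.0, -3, -3, -3]],
            index=sig.columns, columns=spots.columns,
        )
        enr = binarize(es, cutoff=2.0)
        comp = deconvolve(spots, sig, enr=enr, cfg=SolverConfig(seed=0))
        F = comp.fractions
        assert np.allclose(F.sum(axis=1), 1.0, atol=1e-6)
        assert ((F.to_numpy() >= 0) & (F.to_numpy() <= 1)).all()
        assert (F["C"] == 0.0).all()  # masked out everywhere -> exact zero

    def test_spot_mask_level_restricts_each_spot(self):
        sig, frac, spots = _toy_problem()
        es = pd.DataFrame(
            [[5.0, 5, 5, 5], [5.0, 5, 5, 5], [-3.0, -3, 5, 5]],
            index=sig.columns, columns=spots.columns,
        )
        enr = binarize(es, cutoff=2.0)
        comp = deconvolve(spots, sig, enr=enr, cfg=SolverConfig(seed=0), mask_level="spot")
        assert (comp.fractions.loc[["s0", "s1"], "C"] == 0.0).all()

    def test_noiseless_tissue_recovered(self):
        sig, frac, spots = _toy_problem()
        comp = deconvolve(spots, sig, cfg=SolverConfig(seed=0))
        assert np.abs(comp.fractions - frac).to_numpy().max() < 1e-5

    def test_type_permutation_equivariance(self):
        sig, _, spots = _toy_problem()
        comp1 = deconvolve(spots, sig, cfg=SolverConfig(seed=0))
        perm = ["C", "A", "B"]
        comp2 = deconvolve(spots, sig[perm], cfg=SolverConfig(seed=0))
        assert np.allclose(comp1.fractions[perm], comp2.fractions, atol=1e-6)


def test_kmeans_fallback_is_deterministic_and_covers_spots(small_tissue):
    c1 = cluster_spots_kmeans(small_tissue.spot_expr, n_clusters=3, seed=4)
    c2 = cluster_spots_kmeans(small_tissue.spot_expr, n_clusters=3, seed=4)
    assert c1.equals(c2)
    assert set(c1.index) == set(small_tissue.spot_expr.columns)
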