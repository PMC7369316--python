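import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omapop as op
from omapop import mixing
from omapop.design import EXEMPLARS, FORMATS
from conftest import trial_rates_for_unit


def _trial_frame(values_by_cell, n_trials=2):
    """Build a trial-rate frame with identical trials per cell."""
    rows = []
    tid = 0
    for j, f in enumerate(FORMATS):
        for i, e in enumerate(EXEMPLARS):
            for _ in range(n_trials):
                rows.append((tid, f, e, values_by_cell[j, i]))
                tid += 1
    return pd.DataFrame(rows, columns=["trial_id", "format", "exemplar", "rate"])


def _oracle_svd(T):
    """Singular values/vectors from first principles via the Gram matrix."""
    G = T @ T.T
    w, U = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    s = np.sqrt(np.clip(w, 0, None))
    V = np.where(s > 1e-12, 1.0, 0.0)[None, :] * (T.T @ U) / np.where(s > 1e-12, s, 1.0)
    return U, s, V


class TestSplitHalves:
    def test_identical_trials_give_identical_halves(self):
        V = np.arange(28, dtype=float).reshape(4, 7) + 1
        O, Op = mixing.split_half_matrices(_trial_frame(V))
        assert np.allclose(O, Op)
        assert np.allclose(O, V)

    def test_two_trials_per_cell_split_one_and_one(self):
        V = np.ones((4, 7))
        df = _trial_frame(V, n_trials=2)
        # make the two trials of each cell distinct
        df.loc[df.index % 2 == 1, "rate"] += 1.0
        O, Op = mixing.split_half_matrices(df)
        assert np.allclose(O, 1.0) and np.allclose(Op, 2.0)

    def test_random_split_matches_brute_force_recount(self, mult_session):
        df = trial_rates_for_unit(mult_session, mult_session.unit_ids[0])
        O, Op = mixing.split_half_matrices(df, mode="random", seed=5)
        O2, Op2 = mixing.split_half_matrices(df, mode="random", seed=5)
        assert np.allclose(O, O2) and np.allclose(Op, Op2)
        # halves partition every cell: 2 * (O + O') cell sums = full sums
        full = mixing.cell_means(
            df["rate"].to_numpy(),
            df["format"].map({f: i for i, f in enumerate(FORMATS)}).to_numpy(),
            df["exemplar"].map({e: i for i, e in enumerate(EXEMPLARS)}).to_numpy(),
        )
        assert np.allclose((O + Op) / 2, full)

    def test_single_trial_cell_is_an_error(self):
        df = _trial_frame(np.ones((4, 7)), n_trials=1)
        with pytest.raises(ValueError):
            mixing.split_half_matrices(df)

    def test_observed_r2_invariant_to_consistent_relabeling(self, mult_session):
        df = trial_rates_for_unit(mult_session, mult_session.unit_ids[1])
        O, Op = mixing.split_half_matrices(df)
        base = mixing.model_r2(Op, O)
        perm = np.random.default_rng(0).permutation(7)
        assert mixing.model_r2(Op[:, perm], O[:, perm]) == pytest.approx(base)


class TestAdditive:
    def test_zero_mean_additive_input_is_reproduced(self):
        e = np.array([3, -1, 0, 1, -3, 2, -2.0])
        f = np.array([2, -2, 1, -1.0])
        T = e[None, :] + f[:, None]
        E, F, k1, k2, A = mixing.fit_additive(T)
        assert np.allclose(A, T, atol=1e-9)
        assert k1 == pytest.approx(1.0) and k2 == pytest.approx(1.0)

    def test_strong_gain_outer_product_leaves_additive_residual(self):
        g = np.array([0.2, 1.0, 3.0, 8.0])
        e = np.linspace(1, 7, 7)
        T = np.outer(g, e)
        *_, A = mixing.fit_additive(T)
        # independent oracle: direct least squares on the explicit design
        E, F = T.mean(axis=0), T.mean(axis=1)
        X = np.array([[E[i], F[j]] for j in range(4) for i in range(7)])
        k, res, *_ = np.linalg.lstsq(X, T.ravel(), rcond=None)
        assert res[0] > 1.0
        assert np.allclose(A.ravel(), X @ k)

    def test_constant_matrix_predicts_the_constant(self):
        T = np.full((4, 7), 3.5)
        *_, A = mixing.fit_additive(T)
        assert np.allclose(A, 3.5)


class TestMultiplicative:
    def test_rank_one_input_is_reproduced_exactly(self):
        T = np.outer([1.0, 2.0, 0.5, 3.0], np.linspace(1, 4, 7))
        *_, M = mixing.fit_multiplicative(T)
        assert np.allclose(M, T, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_error_equals_eckart_young_bound(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.uniform(0, 10, (4, 7))
        *_, M = mixing.fit_multiplicative(T)
        _, s, _ = _oracle_svd(T)
        err = np.linalg.norm(T - M)
        assert err == pytest.approx(np.sqrt((s[1:] ** 2).sum()), rel=1e-9)
        # no random rank-1 probe does better
        for _ in range(50):
            probe = np.outer(rng.normal(size=4), rng.normal(size=7))
            scale = (T * probe).sum() / max((probe**2).sum(), 1e-12)
            assert np.linalg.norm(T - scale * probe) >= err - 1e-9

    def test_additive_grid_error_matches_oracle_second_singular_values(self):
        T = np.add.outer(np.array([1.0, 4.0, 2.0, 6.0]), np.linspace(0, 6, 7)) + 2
        *_, M = mixing.fit_multiplicative(T)
        _, s, _ = _oracle_svd(T)
        assert np.linalg.norm(T - M) == pytest.approx(np.sqrt((s[1:] ** 2).sum()))

    def test_all_zero_matrix_predicts_zero(self):
        u1, s1, v1, M = mixing.fit_multiplicative(np.zeros((4, 7)))
        assert s1 == 0 and not M.any()


class TestModelR2:
    def test_perfect_and_sign_flipped_predictions(self):
        rng = np.random.default_rng(1)
        O = rng.normal(10, 3, (4, 7))
        assert mixing.model_r2(O, O) == pytest.approx(1.0)
        assert mixing.model_r2(-O, O) == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self):
        rng = np.random.default_rng(2)
        P, O = rng.normal(size=(4, 7)), rng.normal(size=(4, 7))
        p, o = P.ravel(), O.ravel()
        r = ((p - p.mean()) * (o - o.mean())).sum() / np.sqrt(
            ((p - p.mean()) ** 2).sum() * ((o - o.mean()) ** 2).sum()
        )
        assert mixing.model_r2(P, O) == pytest.approx(r**2)

    def test_constant_heldout_matrix_is_undefined(self):
        assert np.isnan(mixing.model_r2(np.eye(4, 7), np.ones((4, 7))))


class TestMannWhitney:
    def test_identical_distributions_give_small_z(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        res = mixing.mann_whitney(x, y)
        assert abs(res["Z"]) < 3 and res["p"] > 0.001

    def test_exact_p_matches_full_enumeration_on_small_lists(self):
        x = np.array([1.2, 3.4, 0.5, 7.7, 2.2])
        y = np.array([2.5, 6.1, 4.4, 8.0, 5.5])
        res = mixing.mann_whitney(x, y)
        # U = number of (x, y) pairs with x > y (scipy convention for x)
        u_manual = sum(xi > yi for xi in x for yi in y)
        assert res["U"] == u_manual
        # exact two-sided p by enumerating all C(10,5) group assignments
        pooled = np.concatenate([x, y])
        us = []
        for comb in itertools.combinations(range(10), 5):
            xs = pooled[list(comb)]
            ys = pooled[[i for i in range(10) if i not in comb]]
            us.append(sum(xi > yi for xi in xs for yi in ys))
        us = np.array(us)
        extreme = np.abs(us - 12.5) >= abs(u_manual - 12.5)
        assert res["p"] == pytest.approx(extreme.mean())


class TestPopulations:
    def _fits(self, cls, seed, n=40):
        pop = op.synthetic.make_population({cls: n}, seed=seed)
        rec = op.generate_main_dataset(pop, seed=seed + 500)
        rows = []
        for u in rec.unit_ids:
            f = mixing.fit_unit(trial_rates_for_unit(rec, u))
            rows.append((f.r2_observed, f.r2_multiplicative, f.r2_additive))
        return pd.DataFrame(
            rows, columns=["r2_observed", "r2_multiplicative", "r2_additive"]
        )

    @pytest.mark.parametrize("cls,winner", [
        ("multiplicative_stable", "r2_multiplicative"),
        ("additive", "r2_additive"),
    ])
    def test_each_generative_class_favors_its_own_model(self, cls, winner):
        other = {"r2_multiplicative": "r2_additive", "r2_additive": "r2_multiplicative"}[winner]
        fits = self._fits(cls, seed=7)
        res = mixing.compare_models_population(fits)
        assert res["medians"][winner] > res["medians"][other]
        assert res["tests"]["r2_multiplicative_vs_r2_additive"]["p"] < 0.05


class TestTimeResolved:
    def test_static_rank_one_tuning_tracks_observed_everywhere(self):
        pop = op.synthetic.make_population({"multiplicative_stable": 10}, seed=9)
        rec = op.generate_main_dataset(pop, seed=901)
        b = op.bin_rates(rec, 0.15, 0.05, (0.4, 1.5))
        res = mixing.time_resolved_comparison(b, rec.trials, n_repeats=5, seed=1)
        s = res["series"]
        # the rank-1 model tracks the split-half reliability ceiling
        # (slightly above it, because the rank-1 projection denoises)
        assert np.all(s["r2_multiplicative"] >= s["r2_observed"] - 0.02)
        assert np.all(s["r2_multiplicative"] - s["r2_observed"] < 0.15)
        late = s["bin_start"] >= 0.8  # dynamic tuning fully expressed
        assert (s.loc[late, "r2_multiplicative"] > s.loc[late, "r2_additive"]).all()

    def test_null_units_produce_no_consecutive_significant_runs(self):
        hits = 0
        for seed in range(5):
            pop = op.synthetic.make_population({"untuned": 10}, seed=seed)
            rec = op.generate_main_dataset(pop, seed=seed + 700)
            b = op.bin_rates(rec, 0.15, 0.05, (0.0, 1.5))
            res = mixing.time_resolved_comparison(b, rec.trials, n_repeats=5, seed=2)
            hits += any(m.any() for m in res["masks"].values())
        assert hits <= 1

    def test_consecutive_runs_mask_thresholds_run_length(self):
        sig = np.array([1, 1, 1, 0, 1, 1, 1, 1, 0, 1], dtype=bool)
        out = mixing.consecutive_runs_mask(sig, 4)
        assert out.tolist() == [0, 0, 0, 0, 1, 1, 1, 1, 0, 0]
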