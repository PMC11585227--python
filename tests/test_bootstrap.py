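import numpy as np
import pytest

from wildrank import (
    IncompleteFactorialData,
    bootstrap_test,
    build_contrast,
    design_meta,
    midranks,
    run_all_tests,
)
from wildrank.bootstrap import (
    WEIGHT_SCHEMES,
    _batch_statistics,
    bootstrap_covariance,
    bootstrap_effects,
    center_ranks,
    draw_weights,
)
from wildrank.ranks import covariance_estimate

from _oracles import oracle_bootstrap_stats
from conftest import random_incomplete


class TestWeightSchemes:
    @pytest.mark.parametrize("scheme", ["rademacher", "mammen", "normal", "poisson"])
    def test_mean_zero_variance_one(self, scheme):
        rng = np.random.default_rng(0)
        w = draw_weights(scheme, rng, 200_000)
        assert w.mean() == pytest.approx(0.0, abs=0.01)
        assert w.var() == pytest.approx(1.0, abs=0.02)

    def test_rademacher_support(self):
        w = draw_weights("rademacher", np.random.default_rng(1), 1000)
        assert set(np.unique(w)) == {-1.0, 1.0}
        assert abs(np.mean(w == 1.0) - 0.5) < 0.06

    def test_mammen_two_point_distribution(self):
        s5 = np.sqrt(5.0)
        w = draw_weights("mammen", np.random.default_rng(2), 100_000)
        lo, hi = -(s5 - 1) / 2, (s5 + 1) / 2
        np.testing.assert_allclose(sorted(np.unique(w)), [lo, hi], atol=1e-12)
        assert np.mean(w == lo) == pytest.approx((s5 + 1) / (2 * s5), abs=0.005)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown weight scheme"):
            draw_weights("bogus", np.random.default_rng(0), 3)


class TestCenteredRanks:
    def test_worked_fixture_first_timepoint(self, worked_example):
        meta = design_meta(worked_example)
        Z = center_ranks(midranks(worked_example), meta)
        # time-1 ranks (1, 2.5, 6, 4.5), mean 3.5 -> (-2.5, -1, 2.5, 1)
        np.testing.assert_allclose(Z[0][:, 0], [-2.5, -1.0, 2.5, 1.0])

    def test_complete_cells_center_to_zero(self, random_dataset):
        meta = design_meta(random_dataset)
        Z = center_ranks(midranks(random_dataset), meta)
        for z in Z:
            np.testing.assert_allclose(z.sum(axis=0), 0.0, atol=1e-9)

    def test_all_tied_cell_is_zero(self):
        data = IncompleteFactorialData(values=[np.full((4, 2), 3.0)], observed=None)
        Z = center_ranks(midranks(data), design_meta(data))
        np.testing.assert_array_equal(Z[0], 0.0)


class TestReplicateBuildingBlocks:
    def test_unit_weights_give_zero_effects_and_original_covariance(
        self, random_dataset
    ):
        meta = design_meta(random_dataset)
        rt = midranks(random_dataset)
        Z = center_ranks(rt, meta)
        for sign in (1.0, -1.0):
            Zs = [sign * z for z in Z]
            np.testing.assert_allclose(bootstrap_effects(Zs, meta), 0.0, atol=1e-12)
            Vb = bootstrap_covariance(Zs, rt.observed, meta).V_hat
            V = covariance_estimate(rt, meta).V_hat
            np.testing.assert_allclose(Vb, V, atol=1e-9)

    def test_alternating_weights_match_hand_summation(self, worked_example):
        meta = design_meta(worked_example)
        rt = midranks(worked_example)
        Z = center_ranks(rt, meta)
        w = np.array([1.0, -1.0, 1.0, -1.0])
        Zs = [w[:, None] * Z[0]]
        p = bootstrap_effects(Zs, meta)
        # time 1: (-2.5 + 1 + 2.5 - 1) / (4 * 7) = 0
        # time 2: ranks (4.5, -, 2.5, 7), mean 14/3; weights (1, ., 1, -1)
        t2 = ((4.5 - 14 / 3) + (2.5 - 14 / 3) - (7 - 14 / 3)) / (3 * 7)
        np.testing.assert_allclose(p, [0.0, t2], atol=1e-12)

    def test_rademacher_diagonal_shrinks_by_replicate_mean(self):
        # complete data: sum (Z* - Zbar*)^2 = sum Z^2 - n Zbar*^2, so the
        # replicate variance equals the original minus a mean-squared term
        rng = np.random.default_rng(8)
        data = IncompleteFactorialData(values=[rng.random((6, 2))], observed=None)
        meta = design_meta(data)
        rt = midranks(data)
        Z = center_ranks(rt, meta)
        w = draw_weights("rademacher", rng, 6)
        Zs = [w[:, None] * Z[0]]
        Vb = bootstrap_covariance(Zs, rt.observed, meta).V_hat
        V = covariance_estimate(rt, meta).V_hat
        zbar = Zs[0].mean(axis=0)
        lam = 6
        correction = 6 * lam * zbar**2 / (meta.N**2 * lam * (lam - 1))
        np.testing.assert_allclose(np.diag(Vb), np.diag(V) - correction, atol=1e-10)
        assert (np.diag(Vb) <= np.diag(V) + 1e-12).all()

    def test_degenerate_all_tied_gives_zero_covariance(self):
        data = IncompleteFactorialData(values=[np.full((5, 2), 1.0)], observed=None)
        meta = design_meta(data)
        rt = midranks(data)
        Zs = [z.copy() for z in center_ranks(rt, meta)]
        np.testing.assert_array_equal(
            bootstrap_covariance(Zs, rt.observed, meta).V_hat, 0.0
        )


class TestBatchEngine:
    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_matches_formula_by_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = random_incomplete(rng, a=2, d=3, n=(5, 6))
        meta = design_meta(data)
        rt = midranks(data)
        Z = center_ranks(rt, meta)
        cs = build_contrast("interaction", 2, 3)
        B = 4
        W = [draw_weights("rademacher", rng, (B, n_i)) for n_i in data.n]
        stats, _ = _batch_statistics(Z, rt.observed, meta, cs, W)
        for b in range(B):
            ow, oa, om = oracle_bootstrap_stats(data, cs.C, [w[b] for w in W])
            assert stats["WTS"][b] == pytest.approx(ow, abs=1e-9)
            assert stats["ATS"][b] == pytest.approx(oa, abs=1e-9)
            assert stats["MATS"][b] == pytest.approx(om, abs=1e-9)

    def test_sign_symmetry_of_replicate_map(self, random_dataset):
        meta = design_meta(random_dataset)
        rt = midranks(random_dataset)
        Z = center_ranks(rt, meta)
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        rng = np.random.default_rng(4)
        W = [draw_weights("rademacher", rng, (3, n_i)) for n_i in random_dataset.n]
        Wneg = [-w for w in W]
        s1, _ = _batch_statistics(Z, rt.observed, meta, cs, W)
        s2, _ = _batch_statistics(Z, rt.observed, meta, cs, Wneg)
        for m in s1:
            np.testing.assert_allclose(s1[m], s2[m], atol=1e-9)

    def test_replicate_effects_center_over_many_replicates(self, random_dataset):
        meta = design_meta(random_dataset)
        rt = midranks(random_dataset)
        Z = center_ranks(rt, meta)
        rng = np.random.default_rng(12)
        B = 4000
        for i, z in enumerate(Z):
            W = draw_weights("rademacher", rng, (B, z.shape[0]))
            p_star = (W @ z) / (meta.N * meta.lambda_dot[i])  # (B, d)
            mean = p_star.mean(axis=0)
            se = p_star.std(axis=0, ddof=1) / np.sqrt(B)
            assert (np.abs(mean) < 4 * np.maximum(se, 1e-12)).all()


class TestBootstrapTest:
    def test_b_equal_one_p_in_zero_one(self, random_dataset):
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        res = bootstrap_test(random_dataset, cs, "ATS", B=1, seed=0)
        assert res.p_bootstrap in (0.0, 1.0)

    def test_same_seed_identical_p(self, random_dataset):
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        r1 = bootstrap_test(random_dataset, cs, "ATS", B=99, seed=7)
        r2 = bootstrap_test(random_dataset, cs, "ATS", B=99, seed=7)
        assert r1.p_bootstrap == r2.p_bootstrap

    def test_subject_permutation_stable_p(self, random_dataset):
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        rng = np.random.default_rng(5)
        perm = [rng.permutation(n) for n in random_dataset.n]
        shuffled = IncompleteFactorialData(
            values=[v[p] for v, p in zip(random_dataset.values, perm)],
            observed=[m[p] for m, p in zip(random_dataset.observed, perm)],
        )
        for method in ("WTS", "ATS", "MATS"):
            r1 = bootstrap_test(random_dataset, cs, method, B=199, seed=3)
            r2 = bootstrap_test(shuffled, cs, method, B=199, seed=3)
            assert r1.p_bootstrap == r2.p_bootstrap

    def test_monotone_transform_same_seed_identical_p(self, random_dataset):
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        transformed = IncompleteFactorialData(
            values=[
                np.where(m, np.exp(v), np.nan)
                for v, m in zip(random_dataset.values, random_dataset.observed)
            ],
            observed=[m.copy() for m in random_dataset.observed],
        )
        for method in ("WTS", "ATS", "MATS"):
            r1 = bootstrap_test(random_dataset, cs, method, B=199, seed=11)
            r2 = bootstrap_test(transformed, cs, method, B=199, seed=11)
            assert r1.p_bootstrap == r2.p_bootstrap

    def test_run_all_tests_shares_replicates_with_single_runs(self, random_dataset):
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        combined = run_all_tests(random_dataset, cs, B=99, seed=2)
        assert set(combined) == {"WTS", "ATS", "MATS"}
        for m, res in combined.items():
            assert res.B == 99 and res.weight_scheme == "rademacher"
            assert 0.0 <= res.p_bootstrap <= 1.0

    def test_invalid_inputs_rejected(self, random_dataset):
        cs = build_contrast("time", random_dataset.a, random_dataset.d)
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_test(random_dataset, cs, "ATS", B=0, seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            bootstrap_test(random_dataset, cs, "XTS", B=9, seed=0)
        bad_cs = build_contrast("time", 1, 2)
        with pytest.raises(ValueError, match="columns"):
            bootstrap_test(random_dataset, bad_cs, "ATS", B=9, seed=0)
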