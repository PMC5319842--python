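"""Point-set model, loss, error ratio, initializations, and searches."""

import numpy as np
import pytest

from conftest import make_dataset
from tpselect.data import TimeGrid
from tpselect.selection import (
    LAMBDA_GRID,
    PointSet,
    SplineScorer,
    error_ratio,
    exhaustive_search,
    greedy_search,
    init_abs_difference,
    init_equal_partition,
    init_max_distance,
    reconstruction_error,
    search_all_inits,
    simulated_annealing_search,
)


def oracle_smooth(x, y, lam, query):
    """Independent penalized natural-spline fit.

    Builds the roughness penalty by Simpson integration of products of the
    second derivatives of scipy's natural-cubic-spline basis (exact: the
    integrand is piecewise quadratic), solves the penalized least squares
    in that basis, and evaluates through scipy.  Shares no code with the
    package's Green--Silverman matrices.
    """
    from scipy.interpolate import CubicSpline

    x = np.asarray(x, float)
    k = x.size
    basis = [CubicSpline(x, np.eye(k)[j], bc_type="natural") for j in range(k)]
    P = np.zeros((k, k))
    for a in range(k - 1):
        lo, hi = x[a], x[a + 1]
        mid, h = 0.5 * (lo + hi), hi - lo
        d2 = np.array([[b(p, 2) for p in (lo, mid, hi)] for b in basis])
        P += (h / 6.0) * (
            np.outer(d2[:, 0], d2[:, 0])
            + 4.0 * np.outer(d2[:, 1], d2[:, 1])
            + np.outer(d2[:, 2], d2[:, 2])
        )
    f = np.linalg.solve(np.eye(k) + lam * P, np.asarray(y, float))
    return CubicSpline(x, f, bc_type="natural")(np.asarray(query, float))


def oracle_score(ds, indices, weights=None):
    """Independent recomputation of the engine's loss.

    Per gene: brute-force LOOCV over the same penalty grid using honest
    per-fold refits of the independent smoother (endpoint folds excluded,
    ties toward the smoother penalty), then prediction at the left-out grid
    times and the squared error against every repeat.
    """
    sel = list(indices)
    out = [i for i in range(ds.grid.n) if i not in set(sel)]
    x = ds.grid.times[sel]
    q = ds.grid.times[out]
    lams = LAMBDA_GRID * float(np.mean(np.diff(x))) ** 3
    means = ds.repeat_means()
    total = 0.0
    w = np.ones(ds.n_genes) if weights is None else np.asarray(weights, float)
    for g in range(ds.n_genes):
        y = means[g, sel]
        cv = np.zeros(lams.size)
        for j, lam in enumerate(lams):
            for i in range(1, len(sel) - 1):
                pred = oracle_smooth(np.delete(x, i), np.delete(y, i), lam, [x[i]])
                cv[j] += float((pred[0] - y[i]) ** 2)
        best = np.flatnonzero(cv <= cv.min() + 1e-12)[-1]
        pred = oracle_smooth(x, y, lams[best], q)
        for t_pos, t_idx in enumerate(out):
            reps = ds.values[g, t_idx]
            reps = reps[np.isfinite(reps)]
            total += w[g] * float(np.sum((pred[t_pos] - reps) ** 2))
    return total


class TestPointSet:
    def test_endpoints_required(self):
        grid = TimeGrid(np.arange(6.0))
        with pytest.raises(ValueError, match="endpoints"):
            PointSet(grid, (1, 2, 3))

    def test_size_bounds(self):
        grid = TimeGrid(np.arange(6.0))
        with pytest.raises(ValueError):
            PointSet(grid, (0, 5))
        with pytest.raises(ValueError):
            PointSet(grid, (0, 1, 2, 3, 4, 5))

    def test_sorted_unique_and_times(self):
        grid = TimeGrid(np.array([0.0, 0.5, 1.0, 2.0, 4.0]))
        ps = PointSet(grid, (4, 0, 2))
        assert ps.indices == (0, 2, 4)
        assert np.allclose(ps.times, [0.0, 1.0, 4.0])
        assert ps.complement == (1, 3)


class TestReconstructionError:
    def test_noiseless_linear_gene_zero_error(self, linear_gene_ds):
        ps = PointSet(linear_gene_ds.grid, (0, 3, 7))
        score = reconstruction_error(linear_gene_ds, ps)
        assert score.total == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_scipy_oracle(self, small_noisy_ds):
        for idx in [(0, 2, 5, 11), (0, 3, 6, 9, 11), (0, 1, 4, 7, 10, 11)]:
            ps = PointSet(small_noisy_ds.grid, idx)
            mine = reconstruction_error(small_noisy_ds, ps).total
            assert mine == pytest.approx(oracle_score(small_noisy_ds, idx), rel=1e-8)

    def test_toy_single_left_out_point_hand_arithmetic(self):
        # one gene on 5 points, repeats equal to their means; omit one point:
        # error must equal sum over repeats of (spline estimate - repeat)^2
        vals = np.array([[0.0, 1.0, 3.0, 2.0, 1.0]])
        ds = make_dataset(np.stack([vals[0], vals[0]], axis=-1)[None, :, :])
        idx = (0, 1, 3, 4)
        score = reconstruction_error(ds, PointSet(ds.grid, idx))
        x = ds.grid.times[list(idx)]
        y = vals[0, list(idx)]
        lams = LAMBDA_GRID * float(np.mean(np.diff(x))) ** 3
        cv = np.zeros(lams.size)
        for j, lam in enumerate(lams):
            for i in (1, 2):
                pred = oracle_smooth(np.delete(x, i), np.delete(y, i), lam, [x[i]])
                cv[j] += float((pred[0] - y[i]) ** 2)
        best = np.flatnonzero(cv <= cv.min() + 1e-12)[-1]
        ehat = float(oracle_smooth(x, y, lams[best], [2.0])[0])
        expected = 2 * (ehat - 3.0) ** 2  # two identical repeats at t=2
        assert score.total == pytest.approx(expected, rel=1e-8)
        assert score.avg_mse == pytest.approx(expected / 2, rel=1e-8)

    def test_unit_weights_equal_unweighted(self, small_noisy_ds):
        ps = PointSet(small_noisy_ds.grid, (0, 4, 8, 11))
        plain = reconstruction_error(small_noisy_ds, ps)
        weighted = reconstruction_error(
            small_noisy_ds, ps, weights=np.ones(small_noisy_ds.n_genes)
        )
        assert plain.total == pytest.approx(weighted.total)

    def test_full_grid_rejected(self, small_noisy_ds):
        scorer = SplineScorer(small_noisy_ds)
        with pytest.raises(ValueError, match="left-out"):
            scorer.score(tuple(range(small_noisy_ds.grid.n)))


class TestErrorRatio:
    def test_identity_is_one(self, small_noisy_ds):
        ps = PointSet(small_noisy_ds.grid, (0, 3, 7, 11))
        assert error_ratio(small_noisy_ds, ps, ps) == pytest.approx(1.0)

    def test_equals_independent_quotient(self, small_noisy_ds):
        a = PointSet(small_noisy_ds.grid, (0, 2, 9, 11))
        b = PointSet(small_noisy_ds.grid, (0, 4, 7, 11))
        ratio = error_ratio(small_noisy_ds, a, b)
        expected = oracle_score(small_noisy_ds, b.indices) / oracle_score(
            small_noisy_ds, a.indices
        )
        assert ratio == pytest.approx(expected, rel=1e-8)

    def test_zero_error_degenerate_cases(self, linear_gene_ds):
        grid = linear_gene_ds.grid
        a = PointSet(grid, (0, 3, 7))
        b = PointSet(grid, (0, 4, 7))
        # both sets reconstruct a line exactly: 0/0 -> 1 by convention
        assert error_ratio(linear_gene_ds, a, b) == 1.0

    def test_mismatched_k_rejected(self, small_noisy_ds):
        a = PointSet(small_noisy_ds.grid, (0, 3, 11))
        b = PointSet(small_noisy_ds.grid, (0, 3, 7, 11))
        with pytest.raises(ValueError):
            error_ratio(small_noisy_ds, a, b)


class TestInitializations:
    def test_equal_partition_midpoint(self):
        grid = TimeGrid(np.arange(11.0))
        assert init_equal_partition(grid, 3).indices == (0, 5, 10)

    def test_equal_partition_uniform_targets(self):
        grid = TimeGrid(np.arange(11.0))
        assert np.allclose(init_equal_partition(grid, 6).times, [0, 2, 4, 6, 8, 10])

    def test_equal_partition_k_n_minus_1_enumeration(self):
        # all points except the interior point farthest from its uniform target
        grid = TimeGrid(np.array([0.0, 0.5, 1.0, 6.0, 9.0, 10.0]))
        ps = init_equal_partition(grid, 5)
        assert ps.k == 5
        assert 0 in ps.indices and 5 in ps.indices
        # targets 2.5, 5, 7.5 pull in 1.0, 6.0, 9.0; then 0.5 beats nothing:
        # the omitted point is the one never nearest an unclaimed target
        assert ps.indices == (0, 2, 3, 4, 5)

    def test_equal_partition_k_range_validated(self):
        grid = TimeGrid(np.arange(5.0))
        for bad_k in (2, 5, 6):
            with pytest.raises(ValueError):
                init_equal_partition(grid, bad_k)

    def test_abs_difference_finds_step(self):
        # single gene with one step between t2 and t3 (0-based) on 6 points
        ds = make_dataset(np.array([[0.0, 0.0, 0.0, 5.0, 5.0, 5.0]]))
        ps = init_abs_difference(ds, 4)
        assert set(ps.indices) == {0, 2, 3, 5}

    def test_abs_difference_scores_by_hand(self):
        profile = np.array([[1.0, 4.0, 2.0, 2.0, 7.0, 0.0]])
        ds = make_dataset(profile)
        # interior scores: t1:|4-1|+|2-4|=5, t2:|2-4|+|0|=2, t3:0+5=5, t4:5+7=12
        # k=5 keeps top 3 = t4, then tie (t1, t3) -> earlier first: t1, t3
        ps = init_abs_difference(ds, 5)
        assert set(ps.indices) == {0, 1, 3, 4, 5}

    def test_abs_difference_flat_falls_back_to_equal(self):
        ds = make_dataset(np.full((3, 11), 2.0))
        assert init_abs_difference(ds, 3).indices == (0, 5, 10)

    def test_abs_difference_gene_order_invariant(self, small_noisy_ds):
        ds = small_noisy_ds
        perm = ds.subset_genes([ds.gene_ids[i] for i in (2, 0, 3, 1)])
        assert init_abs_difference(ds, 5).indices == init_abs_difference(perm, 5).indices

    def test_max_distance_monotone_single_gene(self):
        # values 0,1,2,3,10: farthest from both endpoint values is t3 (3):
        # distances to closest endpoint: 1:min(1,9)=1, 2:2, 3:min(3,7)=3
        ds = make_dataset(np.array([[0.0, 1.0, 2.0, 3.0, 10.0]]))
        assert init_max_distance(ds, 3).indices == (0, 3, 4)

    def test_max_distance_skips_duplicate_profiles(self):
        # time points 1 and 2 are identical columns; both should not be
        # chosen while distinct columns remain
        cols = np.array(
            [[0.0, 5.0, 5.0, 2.0, 8.0, 1.0], [0.0, 5.0, 5.0, 2.0, 8.0, 1.0]]
        )
        ds = make_dataset(cols)
        ps = init_max_distance(ds, 5)
        assert not {1, 2}.issubset(set(ps.indices))

    def test_max_distance_gene_order_invariant(self, small_noisy_ds):
        ds = small_noisy_ds
        perm = ds.subset_genes([ds.gene_ids[i] for i in (3, 1, 0, 2)])
        assert init_max_distance(ds, 5).indices == init_max_distance(perm, 5).indices


class TestGreedySearch:
    def test_fixed_point_terminates_immediately(self):
        ds = make_dataset(np.array([[0.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0, 5.0]]))
        opt = exhaustive_search(ds, 4)
        res = greedy_search(ds, 4, init=opt.point_set)
        assert res.iterations == 1
        assert res.point_set.indices == opt.point_set.indices

    def test_step_profile_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        step = np.array([0.0, 0.0, 0.0, 0.0, 4.0, 4.0, 4.0, 4.0])
        vals = step[None, :, None] + rng.normal(0, 0.2, size=(1, 8, 2))
        ds = make_dataset(vals)
        greedy, _ = search_all_inits(ds, 4)
        brute = exhaustive_search(ds, 4)  # C(6,2)=15 subsets
        assert greedy.final_error == pytest.approx(brute.final_error)

    def test_trace_strictly_decreasing_and_termination_ratio(self, small_noisy_ds):
        res = greedy_search(small_noisy_ds, 5, init="equal")
        assert all(b < a for a, b in zip(res.error_trace, res.error_trace[1:]))
        assert res.converged
        assert res.ratio_trace[-1] >= 1.0

    def test_multi_swap_never_worse(self, small_noisy_ds):
        plain = greedy_search(small_noisy_ds, 5, init="equal")
        multi = greedy_search(small_noisy_ds, 5, init="equal", multi_swap=True)
        assert multi.final_error <= plain.final_error + 1e-12

    def test_result_serialization_round_trip(self, small_noisy_ds):
        import json

        res = greedy_search(small_noisy_ds, 4, init="abs")
        payload = json.loads(res.to_json())
        assert payload["k"] == 4
        assert payload["selected_times"] == [float(t) for t in res.point_set.times]
        assert payload["error_trace"][-1] == pytest.approx(res.final_error)


class TestSimulatedAnnealing:
    def test_zero_temperature_never_accepts_worsening(self, small_noisy_ds):
        from tpselect.selection import AnnealingSchedule

        res = simulated_annealing_search(
            small_noisy_ds,
            4,
            schedule=AnnealingSchedule(t0=1e-300, n_temps=5, proposals_per_temp=20),
            seed=1,
        )
        assert all(b <= a + 1e-12 for a, b in zip(res.error_trace, res.error_trace[1:]))

    def test_seed_reproducibility(self, small_noisy_ds):
        from tpselect.selection import AnnealingSchedule

        sched = AnnealingSchedule(n_temps=5, proposals_per_temp=10)
        a = simulated_annealing_search(small_noisy_ds, 4, schedule=sched, seed=7)
        b = simulated_annealing_search(small_noisy_ds, 4, schedule=sched, seed=7)
        assert a.point_set.indices == b.point_set.indices
        assert a.error_trace == b.error_trace

    def test_invalid_schedule_rejected(self):
        from tpselect.selection import AnnealingSchedule

        with pytest.raises(ValueError):
            AnnealingSchedule(t0=-1.0)
        with pytest.raises(ValueError):
            AnnealingSchedule(cooling=1.5)

    def test_sa_competitive_with_greedy_on_toy_instances(self):
        """SA (best-ever) is never worse than its initialization and at
        least matches greedy on half of small random instances."""
        from tpselect.selection import AnnealingSchedule
        from tpselect.synthetic import SyntheticConfig, generate_dataset

        sched = AnnealingSchedule(n_temps=12, proposals_per_temp=10, cooling=0.85)
        not_worse_than_init = 0
        at_least_greedy = 0
        n_inst = 60
        for seed in range(n_inst):
            cfg = SyntheticConfig(
                n_genes=4,
                grid=TimeGrid(np.arange(10.0)),
                n_clusters=2,
                n_repeats=2,
                noise_sd=0.3,
                transitions_per_cluster=1,
                seed=seed,
            )
            ds, _ = generate_dataset(cfg)
            scorer = SplineScorer(ds)
            init_err = scorer.score(
                init_abs_difference(ds, 4).indices
            ).total
            sa = simulated_annealing_search(
                ds, 4, init="abs", schedule=sched, seed=seed, scorer=scorer
            )
            greedy = greedy_search(ds, 4, init="abs", scorer=scorer)
            if sa.final_error <= init_err + 1e-12:
                not_worse_than_init += 1
            if sa.final_error <= greedy.final_error + 1e-12:
                at_least_greedy += 1
        assert not_worse_than_init == n_inst
        assert at_least_greedy >= n_inst // 2


class TestExhaustiveSearch:
    def test_k_n_minus_1_equals_direct_omission_loop(self, small_noisy_ds):
        ds = small_noisy_ds
        n = ds.grid.n
        scorer = SplineScorer(ds)
        direct = min(
            scorer.score(tuple(i for i in range(n) if i != omit)).total
            for omit in range(1, n - 1)
        )
        assert exhaustive_search(ds, n - 1).final_error == pytest.approx(direct)

    def test_symmetric_profile_symmetric_or_mirrored_optimum(self):
        sym = np.array([0.0, 1.0, 3.0, 4.0, 3.0, 1.0, 0.0])
        ds = make_dataset(np.stack([sym, sym], axis=-1)[None, :, :])
        res = exhaustive_search(ds, 4)
        idx = np.array(res.point_set.indices)
        mirrored = tuple(sorted(6 - idx))
        scorer = SplineScorer(ds)
        assert scorer.score(mirrored).total == pytest.approx(res.final_error)

    def test_dominates_greedy_and_init(self, small_noisy_ds):
        scorer = SplineScorer(small_noisy_ds)
        greedy = greedy_search(small_noisy_ds, 5, init="equal", scorer=scorer)
        init_err = scorer.score(init_equal_partition(small_noisy_ds.grid, 5).indices)
        brute = exhaustive_search(small_noisy_ds, 5, scorer=scorer)
        assert brute.final_error <= greedy.final_error + 1e-12
        assert greedy.final_error <= init_err.total + 1e-12

    def test_cap_enforced(self, small_noisy_ds):
        with pytest.raises(ValueError, match="cap"):
            exhaustive_search(small_noisy_ds, 6, cap=10)
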