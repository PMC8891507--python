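"""Reliability metrics: centroids, density/wDSC, profiles, ICC, CV, correlations."""

import numpy as np
import pandas as pd
import pytest

from tractreli.metrics import (
    TractDensityMap,
    assign_endpoints_to_parcels,
    average_centroid,
    centroid_distance,
    density_map,
    icc_absolute,
    map_scalar_along,
    metric_correlations,
    pairwise_wdsc_mean,
    streamline_cv,
    tract_centroid,
    tract_profile,
    wdsc,
)


def straight(n=20, y=0.0, z=0.0, x0=0.0, x1=19.0):
    return np.stack([np.linspace(x0, x1, n), np.full(n, y), np.full(n, z)], axis=1)


def sparse_map(shape, affine, voxel_fracs, n=1):
    """Hand-built density map from {flat_index: fraction}."""
    idx = np.array(sorted(voxel_fracs), dtype=int)
    fr = np.array([voxel_fracs[i] for i in idx], dtype=float)
    return TractDensityMap(shape, np.asarray(affine, float), idx, fr, n)


GRID = ((4, 4, 4), np.eye(4))


class TestCentroids:
    def test_average_of_identical_centroids(self):
        c = straight()
        assert np.allclose(average_centroid([c, c, c]), c)

    def test_two_offset_subjects_average_midway(self):
        c = straight()
        avg = average_centroid([c + [0, 0, 1], c - [0, 0, 1]])
        assert np.allclose(avg, c)

    def test_centroid_distance_zero_for_self(self):
        c = straight()
        assert centroid_distance(c, c) == 0.0

    def test_offset_subjects_distance_one(self):
        c = straight()
        subs = [c + [0, 0, 1.0], c - [0, 0, 1.0]]
        avg = average_centroid(subs)
        for s in subs:
            assert centroid_distance(s, avg) == pytest.approx(1.0)

    def test_distance_flip_invariant(self):
        c = straight()
        assert centroid_distance(c[::-1], c + [0, 2, 0]) == pytest.approx(2.0)

    def test_average_shrinks_like_inverse_sqrt_k(self):
        # Monte Carlo: per-point deviation of the k-subject average from the
        # truth scales ~ sigma/sqrt(k)
        rng = np.random.default_rng(0)
        c = straight()
        sigma = 1.0
        for k, reps in [(4, 200), (16, 200)]:
            devs = []
            for _ in range(reps):
                subs = c[None] + rng.normal(0, sigma, size=(k, 1, 3))
                devs.append(np.linalg.norm(average_centroid(subs) - c, axis=1).mean())
            # the average of k subjects has per-point noise N(0, sigma^2/k I3),
            # whose expected norm is 2*sqrt(2/pi)*sigma/sqrt(k) ~ 1.5958 sigma/sqrt(k)
            assert np.mean(devs) == pytest.approx(
                1.5957691 * sigma / np.sqrt(k), rel=0.15
            )

    def test_tract_centroid_empty_errors(self):
        with pytest.raises(ValueError):
            tract_centroid(np.empty((0, 20, 3)))


class TestDensityMap:
    def test_single_streamline_hits_traversed_row(self):
        s = np.array([[0.0, 1, 1], [3.0, 1, 1]])
        m = density_map([s], (4, 4, 4), np.eye(4))
        dense = m.to_dense()
        assert np.all(dense[:, 1, 1] == 1.0)
        dense[:, 1, 1] = 0
        assert np.all(dense == 0)

    def test_two_streamline_hand_count(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])  # voxels (0,0,0),(1,0,0)
        b = np.array([[1.0, 0, 0], [2.0, 0, 0]])  # voxels (1,0,0),(2,0,0)
        m = density_map([a, b], (4, 4, 4), np.eye(4))
        d = m.to_dense()
        assert d[1, 0, 0] == 1.0
        assert d[0, 0, 0] == 0.5 and d[2, 0, 0] == 0.5

    def test_duplicates_leave_fractions_unchanged(self):
        s = np.array([[0.0, 1, 1], [3.0, 1, 1]])
        m1 = density_map([s], *GRID)
        m2 = density_map([s, s.copy()], *GRID)
        assert np.array_equal(m1.indices, m2.indices)
        assert np.allclose(m1.fractions, m2.fractions)

    def test_outside_points_ignored(self, caplog):
        s = np.array([[-10.0, 1, 1], [3.0, 1, 1]])
        m = density_map([s], (4, 4, 4), np.eye(4))
        assert np.all(m.to_dense()[:, 1, 1] == 1.0)


class TestWdsc:
    def test_identical_nonempty_is_one(self):
        m = sparse_map(*GRID, {3: 0.5, 7: 1.0})
        assert wdsc(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = sparse_map(*GRID, {0: 1.0})
        b = sparse_map(*GRID, {5: 1.0})
        assert wdsc(a, b) == 0.0

    def test_ab_bc_half(self):
        a = sparse_map(*GRID, {0: 1.0, 1: 1.0})
        b = sparse_map(*GRID, {1: 1.0, 2: 1.0})
        assert wdsc(a, b) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "fa,fb",
        [
            ({0: 0.2, 1: 0.8, 2: 0.4}, {1: 0.5, 2: 0.9, 3: 0.1}),
            ({0: 1.0, 4: 0.25}, {0: 0.5, 4: 0.75, 9: 0.3}),
        ],
    )
    def test_weighted_cases_match_independent_summation(self, fa, fb):
        a, b = sparse_map(*GRID, fa), sparse_map(*GRID, fb)
        common = set(fa) & set(fb)
        expected = (sum(fa[v] for v in common) + sum(fb[v] for v in common)) / (
            sum(fa.values()) + sum(fb.values())
        )
        assert wdsc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_range(self):
        a = sparse_map(*GRID, {0: 0.3, 1: 0.9})
        b = sparse_map(*GRID, {1: 0.4, 2: 0.2})
        assert wdsc(a, b) == wdsc(b, a)
        assert 0 <= wdsc(a, b) <= 1

    def test_erosion_never_increases(self):
        fa = {0: 0.5, 1: 0.7, 2: 0.3}
        fb = {1: 0.6, 2: 0.8, 3: 0.2}
        full = wdsc(sparse_map(*GRID, fa), sparse_map(*GRID, fb))
        fa2 = dict(fa)
        del fa2[1]  # remove an intersection voxel
        eroded = wdsc(sparse_map(*GRID, fa2), sparse_map(*GRID, fb))
        assert eroded <= full

    def test_empty_maps_return_zero(self):
        e = sparse_map(*GRID, {})
        assert wdsc(e, e) == 0.0

    def test_mismatched_grids_error(self):
        a = sparse_map(*GRID, {0: 1.0})
        b = sparse_map((5, 5, 5), np.eye(4), {0: 1.0})
        with pytest.raises(ValueError):
            wdsc(a, b)

    def test_pairwise_mean_enumerates_pairs(self):
        a = sparse_map(*GRID, {0: 1.0, 1: 1.0})
        b = sparse_map(*GRID, {1: 1.0, 2: 1.0})
        # pairs: (a,a)=1, (a,b)=0.5, (a,b)=0.5 -> mean 2/3
        assert pairwise_wdsc_mean([a, a, b]) == pytest.approx(2 / 3)
        assert pairwise_wdsc_mean([b, a, a]) == pytest.approx(2 / 3)

    def test_pairwise_needs_two(self):
        with pytest.raises(ValueError):
            pairwise_wdsc_mean([sparse_map(*GRID, {0: 1.0})])


class TestScalarMapping:
    def test_constant_volume(self):
        vol = np.full((5, 5, 5), 3.7)
        vals = map_scalar_along(straight(10, y=2, z=2, x0=0, x1=4), vol, np.eye(4))
        assert np.allclose(vals, 3.7)

    def test_linear_field_reproduced_exactly(self):
        ii = np.arange(6)
        vol = np.broadcast_to(ii[:, None, None], (6, 6, 6)).astype(float)
        pts = straight(15, y=2.5, z=1.5, x0=0.2, x1=4.8)
        vals = map_scalar_along(pts, vol, np.eye(4))
        assert np.allclose(vals, pts[:, 0], atol=1e-6)

    def test_voxel_center_exact(self):
        vol = np.random.default_rng(0).random((4, 4, 4))
        vals = map_scalar_along(np.array([[2.0, 1.0, 3.0], [0.0, 0.0, 0.0]]), vol, np.eye(4))
        assert vals[0] == pytest.approx(vol[2, 1, 3])

    def test_out_of_grid_is_nan(self):
        vol = np.ones((4, 4, 4))
        vals = map_scalar_along(np.array([[10.0, 0, 0], [1.0, 1, 1]]), vol, np.eye(4))
        assert np.isnan(vals[0]) and vals[1] == 1.0

    def test_profile_flip_aligned(self):
        ii = np.arange(8).astype(float)
        vol = np.broadcast_to(ii[:, None, None], (8, 8, 8)).copy()
        a = straight(10, y=3, z=3, x0=0.5, x1=6.5)
        prof_single = tract_profile(a[None], vol, np.eye(4))
        prof_pair = tract_profile(np.stack([a, a[::-1]]), vol, np.eye(4))
        assert np.allclose(prof_pair, prof_single, atol=1e-9)

    def test_constant_field_constant_profile(self):
        vol = np.full((8, 8, 8), 0.4)
        prof = tract_profile(straight(10, y=3, z=3, x0=1, x1=6)[None], vol, np.eye(4))
        assert np.allclose(prof, 0.4)


def icc_a1_oracle(X):
    """From-definitions two-way ANOVA variance decomposition, cell by cell."""
    n, k = X.shape
    grand = X.sum() / (n * k)
    ss_total = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = sum(k * (X[i, :].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (X[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr, msc, mse = ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_shared_profile_degenerate_case(self):
        base = np.linspace(0.2, 0.8, 10)
        X = np.tile(base, (5, 1))
        icc, (lo, hi), degen = icc_absolute(X)
        # zero residual and zero subject effect: perfect absolute agreement
        assert icc == pytest.approx(1.0, abs=1e-9)

    def test_matches_from_definitions_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(4, 6))
        icc, _, degen = icc_absolute(X)
        assert not degen
        assert icc == pytest.approx(icc_a1_oracle(X), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        X = rng.normal(0.5, 0.1, size=(8, 12)) + rng.normal(0, 0.05, size=(8, 1))
        icc, (lo, hi), _ = icc_absolute(X)
        n, k = X.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "score": X.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-8)
        # pingouin rounds the CI to 2 decimals
        assert lo == pytest.approx(row["CI95"][0], abs=6e-3)
        assert hi == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 8))
        a, _, _ = icc_absolute(X)
        b, _, _ = icc_absolute(X + 100.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_constant_matrix_flagged_degenerate(self):
        icc, ci, degen = icc_absolute(np.full((4, 5), 2.0))
        assert icc == 1.0 and degen

    def test_missing_columns_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 8))
        Xm = X.copy()
        Xm[2, 3] = np.nan
        icc_full, _, _ = icc_absolute(np.delete(X, 3, axis=1))
        icc_m, _, _ = icc_absolute(Xm)
        assert icc_m == pytest.approx(icc_full)

    def test_recovers_generating_intraclass_correlation(self):
        # profiles with subject-effect variance sb2 and residual se2 have
        # generating intraclass correlation rho = sb2/(sb2+se2); the ANOVA
        # estimator carries a small finite-sample (Jensen) downward bias at
        # n=15, so the mean of 200 replicate estimates is checked within 0.05
        # of rho, and tracking is asserted to be strictly monotone in rho
        rng = np.random.default_rng(3)
        means = []
        for rho in (0.2, 0.5, 0.8):
            sb = np.sqrt(rho)
            se = np.sqrt(1 - rho)
            est = [
                icc_absolute(
                    0.5
                    + rng.normal(0, sb, size=(15, 1))
                    + rng.normal(0, se, size=(15, 20))
                )[0]
                for _ in range(200)
            ]
            means.append(np.mean(est))
            assert abs(means[-1] - rho) < 0.05
        assert means[0] < means[1] < means[2]


class TestCV:
    def test_constant_counts(self):
        assert streamline_cv([10, 10, 10]) == 0.0

    def test_hand_case(self):
        assert streamline_cv([5, 10, 15]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        assert streamline_cv([35, 70, 105]) == pytest.approx(streamline_cv([5, 10, 15]))

    def test_zero_mean_is_nan(self):
        assert np.isnan(streamline_cv([0, 0, 0]))

    def test_poisson_counts_converge_to_100_over_sqrt_lambda(self):
        rng = np.random.default_rng(4)
        lam = 64.0
        cvs = [streamline_cv(rng.poisson(lam, size=30)) for _ in range(1000)]
        assert np.mean(cvs) == pytest.approx(100 / np.sqrt(lam), rel=0.1)


def spearman_oracle(x, y):
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestCorrelations:
    def _table(self, x, y):
        return pd.DataFrame({"a": x, "b": y, "mean_streamline_count": np.ones(len(x))})

    def test_monotone_pairs(self):
        x = np.arange(8, dtype=float)
        up = metric_correlations(self._table(x, x**3), metrics=["a", "b"])
        assert up["rho"].iloc[0] == pytest.approx(1.0)
        down = metric_correlations(self._table(x, -np.exp(x)), metrics=["a", "b"])
        assert down["rho"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2, 2, 3, 5, 5, 5, 9])
        y = np.array([2.0, 1, 4, 4, 4, 7, 6, 8])
        out = metric_correlations(self._table(x, y), metrics=["a", "b"])
        assert out["rho"].iloc[0] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_bh_stepup_hand_case(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.04, 0.5])
        q = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.0533333333, 0.5], atol=1e-9)

    def test_constant_column_reported_missing(self):
        x = np.arange(8, dtype=float)
        df = pd.DataFrame(
            {"a": x, "b": np.ones(8), "c": x**2, "mean_streamline_count": np.ones(8)}
        )
        out = metric_correlations(df, metrics=["a", "b", "c"])
        ab = out[(out.metric_i == "a") & (out.metric_j == "b")]
        assert np.isnan(ab["rho"].iloc[0])
        ac = out[(out.metric_i == "a") & (out.metric_j == "c")]
        assert ac["rho"].iloc[0] == pytest.approx(1.0)

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError):
            metric_correlations(self._table(np.arange(3.0), np.arange(3.0)), metrics=["a", "b"])


class TestParcelAssignment:
    def _label_vol(self):
        vol = np.zeros((10, 10, 10), dtype=int)
        vol[1, 5, 5] = 3  # parcel 3 near one end
        vol[8, 5, 5] = 7  # parcel 7 near the other
        return vol

    def test_endpoint_inside_labeled_voxel(self):
        vol = self._label_vol()
        s = np.stack([np.linspace(1, 8, 20), np.full(20, 5.0), np.full(20, 5.0)], axis=1)
        pa, pb = assign_endpoints_to_parcels(s[None], vol, np.eye(4))
        assert (pa, pb) == (3, 7)

    def test_nearest_within_radius_wins(self):
        vol = np.zeros((12, 6, 6), dtype=int)
        vol[3, 3, 3] = 2  # 3 mm from endpoint at x=0 (endpoint (0,3,3))
        vol[6, 3, 3] = 5  # 6 mm away
        s = np.stack([np.linspace(0, 0.5, 20), np.full(20, 3.0), np.full(20, 3.0)], axis=1)
        pa, _ = assign_endpoints_to_parcels(s[None], vol, np.eye(4), radius=4.0)
        assert pa == 2

    def test_beyond_radius_unassigned(self):
        vol = np.zeros((10, 10, 10), dtype=int)
        vol[9, 9, 9] = 1
        s = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pa, pb = assign_endpoints_to_parcels(s[None], vol, np.eye(4), radius=4.0)
        assert pa is None and pb is None

    def test_majority_vote_with_reversed_members(self):
        vol = self._label_vol()
        s = np.stack([np.linspace(1, 8, 20), np.full(20, 5.0), np.full(20, 5.0)], axis=1)
        members = np.stack([s, s[::-1], s])  # one reversed member
        pa, pb = assign_endpoints_to_parcels(members, vol, np.eye(4))
        assert (pa, pb) == (3, 7)
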