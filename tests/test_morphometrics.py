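"""Unit and property tests for the shell-shape stage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f_oneway

from pterotax import morphometrics as mm
from pterotax.errors import InputError


def make_circle(n=1000, radius=1.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return mm.Outline(
        points=np.column_stack([radius * np.cos(t), radius * np.sin(t)]),
        is_closed=True,
        anchor_indices=(0,),
    )


# ---------------------------------------------------------------------------
# resampling


class TestResampleOutline:
    def test_circle_four_points_equally_spaced(self):
        cfg = mm.resample_outline(make_circle(), 4)
        r = np.linalg.norm(cfg.coords, axis=1)
        assert np.allclose(r, 1.0, atol=1e-3)
        # successive points subtend equal angles of 2*pi/4
        ang = np.unwrap(np.arctan2(cfg.coords[:, 1], cfg.coords[:, 0]))
        assert np.allclose(np.diff(ang), np.pi / 2, atol=1e-3)

    def test_open_v_polyline_midpoint(self):
        v = mm.Outline(points=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]),
                       anchor_indices=(0, 2))
        cfg = mm.resample_outline(v, 3)
        assert np.allclose(cfg.coords[0], [0, 0])
        assert np.allclose(cfg.coords[1], [1, 0])  # apex at half arc length
        assert np.allclose(cfg.coords[2], [1, 1])

    def test_density_invariance(self):
        # same smooth curve digitized coarsely vs finely
        def curve(n):
            t = np.linspace(0, np.pi, n)
            return mm.Outline(
                points=np.column_stack([np.cos(t), np.sin(t) * 0.5]),
                anchor_indices=(0, n - 1),
            )

        a = mm.resample_outline(curve(200), 75).coords
        b = mm.resample_outline(curve(2000), 75).coords
        # curve length ~ pi * something; bound diffs by 0.5% of length ~ 2.4
        assert np.max(np.abs(a - b)) < 0.005 * 2.4

    def test_zero_length_outline_rejected(self):
        with pytest.raises(InputError):
            mm.Outline(points=np.array([[0, 0], [0, 0], [1, 1]]))


# ---------------------------------------------------------------------------
# centroid size


class TestCentroidSize:
    def test_unit_square(self):
        cfg = mm.LandmarkConfiguration(
            coords=np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
        )
        assert mm.centroid_size(cfg) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(min_value=-10, max_value=10).filter(lambda c: abs(c) > 1e-3))
    def test_homogeneity_under_scaling(self, c):
        pts = np.array([[0.0, 1.0], [2.0, -1.0], [-1.5, 0.3], [0.7, 0.7]])
        assert mm.centroid_size(pts * c) == pytest.approx(
            abs(c) * mm.centroid_size(pts), rel=1e-12
        )

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.normal(size=(76, 2))
        centroid = pts.mean(axis=0)
        brute = np.sqrt(sum((p - centroid) @ (p - centroid) for p in pts))
        assert mm.centroid_size(pts) == pytest.approx(brute, abs=1e-12)


# ---------------------------------------------------------------------------
# GPA


def random_config(rng, k=20):
    return rng.normal(size=(k, 2))


class TestGPA:
    def test_similarity_copies_align_exactly(self, rng):
        base = random_config(rng)
        ang = np.deg2rad(37.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        other = 3.0 * base @ rot.T + np.array([5.0, -2.0])
        pr = mm.gpa([mm.LandmarkConfiguration(coords=base),
                     mm.LandmarkConfiguration(coords=other)])
        d = np.sqrt(((pr.aligned[0] - pr.aligned[1]) ** 2).sum())
        assert d < 1e-10
        assert pr.centroid_sizes[1] / pr.centroid_sizes[0] == pytest.approx(3.0, rel=1e-12)

    def test_prealigned_is_fixed_point(self, rng):
        base = random_config(rng)
        base -= base.mean(axis=0)
        base /= np.sqrt((base**2).sum())
        pr = mm.gpa([mm.LandmarkConfiguration(coords=base.copy()) for _ in range(4)])
        for a in pr.aligned:
            assert np.allclose(a, base, atol=1e-10)

    def test_unit_size_and_centered_invariants(self, rng):
        configs = [mm.LandmarkConfiguration(coords=random_config(rng) * s)
                   for s in (1.0, 2.0, 5.0)]
        pr = mm.gpa(configs)
        for a in pr.aligned:
            assert np.allclose(a.mean(axis=0), 0.0, atol=1e-12)
            assert np.sqrt((a**2).sum()) == pytest.approx(1.0, abs=1e-12)
        assert np.sqrt((pr.mean_shape**2).sum()) == pytest.approx(1.0, abs=1e-12)

    def test_mean_recovers_base_under_noise(self, rng):
        base = random_config(rng, k=30)
        base -= base.mean(axis=0)
        cs = np.sqrt((base**2).sum())
        configs = [
            mm.LandmarkConfiguration(coords=base + rng.normal(0, 0.01 * cs, base.shape))
            for _ in range(50)
        ]
        pr = mm.gpa(configs)
        # align the true base to the consensus before comparing
        b = base / cs
        rot = np.linalg.svd(b.T @ pr.mean_shape)
        r = rot[0] @ np.diag([1, np.sign(np.linalg.det(rot[0] @ rot[2]))]) @ rot[2]
        assert np.max(np.abs(b @ r - pr.mean_shape)) < 0.005

    def test_similarity_invariance_of_aligned_distances(self, rng):
        configs = [random_config(rng) for _ in range(6)]
        pr1 = mm.gpa([mm.LandmarkConfiguration(coords=c) for c in configs])
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = [1.7 * c @ rot.T + rng.normal(size=2) for c in configs]
        pr2 = mm.gpa([mm.LandmarkConfiguration(coords=c) for c in moved])
        for i in range(6):
            for j in range(i + 1, 6):
                d1 = np.sqrt(((pr1.aligned[i] - pr1.aligned[j]) ** 2).sum())
                d2 = np.sqrt(((pr2.aligned[i] - pr2.aligned[j]) ** 2).sum())
                assert d1 == pytest.approx(d2, abs=1e-8)

    def test_mismatched_k_rejected(self, rng):
        with pytest.raises(InputError):
            mm.gpa([mm.LandmarkConfiguration(coords=random_config(rng, 10)),
                    mm.LandmarkConfiguration(coords=random_config(rng, 12))])


# ---------------------------------------------------------------------------
# relative warps


class TestRelativeWarps:
    def test_identical_shapes_zero_variance(self, rng):
        base = random_config(rng)
        pr = mm.gpa([mm.LandmarkConfiguration(coords=base.copy()) for _ in range(5)])
        rw = mm.relative_warps(pr)
        assert np.allclose(rw.variance_fraction, 0.0)
        assert np.allclose(rw.scores, 0.0, atol=1e-12)

    def test_variance_fractions_and_reconstruction(self, rng):
        configs = [mm.LandmarkConfiguration(coords=random_config(rng))
                   for _ in range(12)]
        pr = mm.gpa(configs)
        rw = mm.relative_warps(pr)
        assert rw.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(rw.variance_fraction >= 0)
        assert np.allclose(rw.scores.mean(axis=0), 0.0, atol=1e-10)
        # orthonormal axes
        gram = rw.axes @ rw.axes.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-10)
        # full reconstruction of the aligned coordinates
        recon = rw.scores @ rw.axes + rw.mean_flat
        flat = pr.aligned.reshape(len(configs), -1)
        assert np.max(np.abs(recon - flat)) < 1e-9

    def test_axis_count_bound(self, rng):
        configs = [mm.LandmarkConfiguration(coords=random_config(rng, k=8))
                   for _ in range(5)]
        rw = mm.relative_warps(mm.gpa(configs))
        assert rw.scores.shape[1] <= min(4, 16)


# ---------------------------------------------------------------------------
# ICC


def icc_anova_oracle(x):
    """Brute-force two-way ANOVA mean squares for the n x 2 table."""
    n, k = x.shape
    grand = x.mean()
    ms_r = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    ms_c = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    ss_e = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_e = ss_e / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


class TestICC:
    def test_self_agreement_is_one(self, rng):
        x = rng.normal(size=20)
        assert mm.icc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 15))
        assert mm.icc(a, b) == pytest.approx(mm.icc(b, a), abs=1e-12)

    def test_matches_anova_oracle_small_table(self):
        x = np.array([[9.0, 10.0], [12.0, 11.0], [8.0, 7.5], [14.0, 13.0]])
        assert mm.icc(x[:, 0], x[:, 1]) == pytest.approx(icc_anova_oracle(x), abs=1e-12)

    def test_independent_series_average_near_zero(self, rng):
        vals = [mm.icc(rng.normal(size=44), rng.normal(size=44)) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.05

    def test_bounded(self, rng):
        for _ in range(50):
            v = mm.icc(rng.normal(size=10), rng.normal(size=10))
            assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9


class TestSelectRepeatable:
    def test_strict_threshold_semantics(self):
        report = mm.RepeatabilityReport(
            feature_names=["f1", "f2", "f3"],
            icc_values=np.array([0.95, 0.79, 0.81]),
        )
        feats = pd.DataFrame({"f1": [1.0, 2], "f2": [3.0, 4], "f3": [5.0, 6]})
        out = mm.select_repeatable(report, feats)
        assert list(out.columns) == ["f1", "f3"]

    def test_boundary_equal_values_raise(self):
        report = mm.RepeatabilityReport(
            feature_names=["a", "b"], icc_values=np.array([0.80, 0.80])
        )
        feats = pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]})
        with pytest.raises(InputError):
            mm.select_repeatable(report, feats)


# ---------------------------------------------------------------------------
# LDA and jackknife


class TestLDA:
    def test_class_mean_assigned_to_its_class(self, rng):
        mu_a, mu_b = np.array([0.0, 0.0]), np.array([4.0, 4.0])
        X = np.vstack([rng.normal(mu_a, 1, (30, 2)), rng.normal(mu_b, 1, (30, 2))])
        y = ["a"] * 30 + ["b"] * 30
        train = pd.DataFrame(X, columns=["x", "y"])
        query = pd.DataFrame([mu_a, mu_b], columns=["x", "y"])
        assigned, _ = mm.lda_fit_assign(train, y, query)
        assert list(assigned) == ["a", "b"]

    def test_well_separated_clusters_fully_assigned(self, rng):
        # class means 6 pooled-sd apart
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(6, 1, (100, 3))])
        y = ["a"] * 100 + ["b"] * 100
        q = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(6, 1, (100, 3))])
        cols = ["f1", "f2", "f3"]
        assigned, _ = mm.lda_fit_assign(pd.DataFrame(X, columns=cols), y,
                                        pd.DataFrame(q, columns=cols))
        assert list(assigned) == y

    def test_jackknife_perfect_separation(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(10, 0.5, (20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        cm = mm.jackknife_confusion(pd.DataFrame(X, columns=["u", "v"]), y)
        assert cm.percent_correct == 100.0
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_jackknife_chance_level_for_shuffled_labels(self, rng):
        rates = []
        for _ in range(20):
            X = rng.normal(size=(60, 2))
            y = rng.permutation(["a"] * 30 + ["b"] * 30)
            cm = mm.jackknife_confusion(pd.DataFrame(X, columns=["u", "v"]), y)
            rates.append(cm.percent_correct)
        assert abs(np.mean(rates) - 50.0) < 6.0

    def test_row_sums_equal_class_sizes(self, rng):
        X = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(3, 1, (12, 2))])
        y = ["a"] * 8 + ["b"] * 12
        cm = mm.jackknife_confusion(pd.DataFrame(X, columns=["u", "v"]), y)
        assert list(cm.counts.sum(axis=1)) == [8, 12]


# ---------------------------------------------------------------------------
# PerMANOVA


class TestPermanova:
    def test_univariate_equals_classical_anova_f(self, rng):
        a, b, c = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12), rng.normal(1, 1, 8)
        x = np.concatenate([a, b, c])
        groups = ["a"] * 10 + ["b"] * 12 + ["c"] * 8
        res = mm.permanova(x[:, None], groups, n_perm=99, seed=0)
        f_classic = f_oneway(a, b, c).statistic
        assert res.F == pytest.approx(f_classic, abs=1e-10)

    def test_partition_of_sums_of_squares(self, rng):
        X = rng.normal(size=(30, 4))
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = mm.permanova(X, groups, n_perm=0)
        assert res.SS_total == pytest.approx(res.SS_among + res.SS_within,
                                             rel=1e-9)
        assert res.p is None

    def test_translation_and_rotation_invariance(self, rng):
        X = rng.normal(size=(24, 3))
        groups = ["a"] * 12 + ["b"] * 12
        f0 = mm.permanova(X, groups, n_perm=0).F
        f_shift = mm.permanova(X + 7.3, groups, n_perm=0).F
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        f_rot = mm.permanova(X @ q, groups, n_perm=0).F
        assert f_shift == pytest.approx(f0, rel=1e-10)
        assert f_rot == pytest.approx(f0, rel=1e-10)

    def test_matches_skbio_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        X = rng.normal(size=(18, 3))
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = mm.permanova(X, groups, n_perm=0)
        dm = skbio.DistanceMatrix(squareform(pdist(X)))
        sk = skbio.stats.distance.permanova(dm, grouping=groups, permutations=0)
        assert res.F == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_p_value_bounds_and_signal(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(5, 1, (15, 2))])
        groups = ["a"] * 15 + ["b"] * 15
        res = mm.permanova(X, groups, n_perm=999, seed=1)
        assert res.p == pytest.approx(1.0 / 1000.0)


class TestSequentialBonferroni:
    def test_hand_stepped_example(self):
        # sorted p: 0.01 vs 0.05/3 -> reject; 0.03 vs 0.05/2 -> fail, stop
        decisions = mm.sequential_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        assert list(decisions) == [True, False, False]

    def test_all_ones_never_rejected(self):
        assert not mm.sequential_bonferroni([1.0, 1.0, 1.0]).any()

    def test_single_test_plain_alpha(self):
        assert mm.sequential_bonferroni([0.049]).all()

    def test_empty_input(self):
        assert len(mm.sequential_bonferroni([])) == 0
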