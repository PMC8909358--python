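import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import sample_with_moments
from spheroflux.errors import ValidationError
from spheroflux.phenotyping import (
    bioenergetic_map,
    coefficient_of_variation,
    compare_groups,
    cv_from_moments,
    cv_summary,
    minmax_scale,
    run_hclust,
    run_pca,
    significance_stars,
)


class TestCoefficientOfVariation:
    # published per-cohort (mean, SD, CV%) summaries
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [
            (95_997.4, 48_223.0, 50.2),  # multi-spheroid area
            (421_135.9, 36_417.5, 8.6),  # single-spheroid area
            (45.76, 6.68, 14.6),         # single-spheroid basal OCR
            (26.20, 10.99, 41.9),        # multi-spheroid basal OCR
        ],
    )
    def test_reproduces_published_cvs(self, mean, sd, expected):
        rng = np.random.default_rng(0)
        sample = sample_with_moments(mean, sd, 40, rng)
        assert round(coefficient_of_variation(sample), 1) == expected
        assert round(cv_from_moments(mean, sd), 1) == expected

    def test_constant_vector_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_uses_sample_sd(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            100 * np.sqrt(2) / 2
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, 30)
        assert coefficient_of_variation(7.3 * x) == pytest.approx(
            coefficient_of_variation(x)
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([-1.0, 1.0])

    def test_needs_two_values(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([1.0])


class TestMinMaxScale:
    def test_basic_column(self):
        pm = minmax_scale(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(pm.data["a"], [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        df = pd.DataFrame({"a": [0.0, 0.25, 1.0]})
        pm = minmax_scale(df)
        np.testing.assert_allclose(pm.data["a"], df["a"])

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(5, 3, (20, 4)), columns=list("abcd"))
        pm = minmax_scale(df)
        np.testing.assert_allclose(pm.inverse().to_numpy(), df.to_numpy(), atol=1e-12)

    def test_constant_column_warns_and_zeroes(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "c": [7.0, 7.0]})
        with pytest.warns(UserWarning, match="constant"):
            pm = minmax_scale(df)
        np.testing.assert_array_equal(pm.data["c"], [0.0, 0.0])

    def test_column_ranges(self):
        rng = np.random.default_rng(3)
        pm = minmax_scale(pd.DataFrame(rng.normal(size=(15, 3))))
        assert np.allclose(pm.data.min(axis=0), 0.0)
        assert np.allclose(pm.data.max(axis=0), 1.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            minmax_scale(pd.DataFrame({"a": [1.0]}))


class TestPCA:
    def _pm(self, X, cols=None):
        df = pd.DataFrame(X, columns=cols or [f"p{i}" for i in range(X.shape[1])])
        return minmax_scale(df)

    def test_collinear_data_pc1_explains_all(self):
        t = np.linspace(0, 1, 30)
        pm = self._pm(np.column_stack([t, 2 * t]))
        res = run_pca(pm)
        assert res.explained_proportion[0] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        res = run_pca(self._pm(rng.normal(size=(40, 5))))
        assert res.explained_proportion.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_proportion) <= 1e-12)

    def test_isotropic_gaussian_splits_evenly(self):
        # both columns mapped through one common affine transform into [0, 1]
        # (independent per-column min-max would inject range-ratio noise an
        # order of magnitude above the PCA sampling error being tested)
        from spheroflux.phenotyping import PhenotypeMatrix
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10_000, 2))
        lo, hi = X.min(), X.max()
        df = pd.DataFrame((X - lo) / (hi - lo), columns=["a", "b"])
        pm = PhenotypeMatrix(data=df, column_min=df.min(), column_max=df.max())
        res = run_pca(pm)
        assert res.explained_proportion[0] == pytest.approx(0.5, abs=0.02)
        assert res.explained_proportion[1] == pytest.approx(0.5, abs=0.02)

    def test_isometry_with_all_components(self):
        rng = np.random.default_rng(6)
        pm = self._pm(rng.normal(size=(12, 4)))
        res = run_pca(pm, n_components=4)
        X = pm.data.to_numpy() - pm.data.to_numpy().mean(axis=0)
        S = res.scores.to_numpy()
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(S), pdist(X), atol=1e-9)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(7)
        pm = self._pm(rng.normal(size=(25, 3)))
        a, b = run_pca(pm), run_pca(pm)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for col in a.loadings:
            j = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[j, col] > 0

    def test_zero_variance_degenerate(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning):
            pm = minmax_scale(df)
        with pytest.raises(ValidationError):
            run_pca(pm)


def upgma_oracle(X):
    """Brute-force O(n^3) average-linkage merge heights and final partitions.

    Returns the cophenetic distance matrix implied by UPGMA merging with the
    inter-cluster distance defined as the mean pairwise member distance.
    """
    n = len(X)
    d = {(i, j): float(np.linalg.norm(X[i] - X[j])) for i, j in itertools.combinations(range(n), 2)}
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([d[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-15:
                best = (dist, a, b)
        dist, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = dist
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


class TestHierarchicalClustering:
    def _pm(self, X):
        df = pd.DataFrame(X, columns=[f"p{i}" for i in range(X.shape[1])])
        return minmax_scale(df)

    def test_two_singletons_merge_at_their_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        pm = self._pm(X)
        res = run_hclust(pm, k=1)
        scaled = pm.data.to_numpy()
        expected = float(np.linalg.norm(scaled[0] - scaled[1]))
        assert res.merge_tree[0, 2] == pytest.approx(expected)

    def test_average_linkage_definition_three_points(self):
        # {a} vs {b, c}: distance must be (d(a,b) + d(a,c)) / 2
        X = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 1.0]])
        coph = upgma_oracle(X)
        dab = np.linalg.norm(X[0] - X[1])
        dac = np.linalg.norm(X[0] - X[2])
        assert coph[0, 1] == pytest.approx((dab + dac) / 2)
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import pdist, squareform
        Z = linkage(X, method="average")
        np.testing.assert_allclose(squareform(cophenet(Z)), coph, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 9)
        X = rng.normal(size=(n, 3))
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform
        Z = linkage(X, method="average")
        np.testing.assert_allclose(squareform(cophenet(Z)), upgma_oracle(X), atol=1e-9)

    def test_two_profile_purity(self):
        rng = np.random.default_rng(8)
        centers = {0: np.zeros(4), 1: np.full(4, 4.0)}  # 4x within-group SD
        rows, labels = [], []
        for g in (0, 1):
            for size_shift in (-0.5, 0.0, 0.5):  # three size classes mixed in
                rows.append(centers[g] + size_shift + rng.normal(0, 1.0, (10, 4)))
                labels += [g] * 10
        X = np.vstack(rows)
        res = run_hclust(self._pm(X), k=2)
        labels = np.array(labels)
        purity = max(
            np.mean((res.labels == 1) == (labels == g)) for g in (0, 1)
        )
        assert purity >= 0.95

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValidationError):
            run_hclust(self._pm(np.eye(3)), k=4)

    def test_newick_serialization(self):
        pm = self._pm(np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]]))
        nwk = run_hclust(pm, k=2).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_gaussians(self):
        rng = np.random.default_rng(9)
        res = compare_groups(rng.normal(0, 1, 50), rng.normal(5, 1, 50))
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_welch_closed_form_oracle(self):
        from scipy import stats as sps
        a = np.array([2.1, 2.5, 2.9, 3.3, 2.0])
        b = np.array([4.0, 4.4, 3.6, 5.1])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / len(a) + vb / len(b))
        t_oracle = (a.mean() - b.mean()) / se
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df)
        res = compare_groups(a, b)
        assert res.t_statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_degenerate_equal_constants(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_star_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == "ns"


def _stress_records(stress_multiplier, seed=10, n=40):
    from spheroflux.flux_io import InjectionSchedule, assign_phases
    from spheroflux.mito_stress import extract_params, normalize_params
    from spheroflux.synthetic_cohort import AEROBIC_PROFILE, CohortConfig, simulate_cohort
    from dataclasses import replace

    profile = replace(AEROBIC_PROFILE, fccp_multiplier=stress_multiplier)
    schedule = InjectionSchedule.default_mito_stress()
    cohort = simulate_cohort(CohortConfig.single_default(seed=seed, n_wells=n), profile=profile)
    plate = assign_phases(cohort.plate, schedule)
    truth = cohort.truth.set_index("well")
    rows = []
    for w in plate.sample_wells:
        p = normalize_params(extract_params(plate.wells[w], schedule),
                             cells=truth.loc[w, "true_cells"])
        rows.append({
            "well": w, "group": "g", "size_class": "(07-10)k",
            "last_basal_ocr": p.last_basal_ocr, "last_basal_ecar": p.last_basal_ecar,
            "stressed_ocr": p.stressed_ocr, "stressed_ecar": p.stressed_ecar,
        })
    return pd.DataFrame(rows)


class TestBioenergeticMap:
    def test_single_record_point(self):
        df = pd.DataFrame([{"group": "g", "size_class": "s",
                            "last_basal_ocr": 2.0, "last_basal_ecar": 1.0,
                            "stressed_ocr": 3.0, "stressed_ecar": 1.5}])
        out = bioenergetic_map(df)
        assert len(out) == 1
        assert out.loc[0, "last_basal_ocr_mean"] == 2.0
        assert out.loc[0, "last_basal_ocr_sd"] == 0.0
        assert out.loc[0, "n"] == 1

    def test_null_stress_points_coincide(self):
        records = _stress_records(stress_multiplier=1.0)
        out = bioenergetic_map(records).iloc[0]
        assert out["stressed_ocr_mean"] == pytest.approx(
            out["last_basal_ocr_mean"], rel=0.1
        )

    def test_stress_raises_ocr(self):
        from scipy import stats as sps
        records = _stress_records(stress_multiplier=1.6)
        out = bioenergetic_map(records).iloc[0]
        assert out["stressed_ocr_mean"] > out["last_basal_ocr_mean"]
        t, p = sps.ttest_rel(records["stressed_ocr"], records["last_basal_ocr"],
                             alternative="greater")
        assert p < 0.01

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            bioenergetic_map(pd.DataFrame({"group": ["g"], "last_basal_ocr": [1.0]}))


class TestCVSummary:
    def test_groups_and_moments(self):
        df = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3,
            "basal_resp": [1.0, 2.0, 3.0, 10.0, 10.0, 10.0],
        })
        out = cv_summary(df, value_cols=["basal_resp"]).set_index("group")
        assert out.loc["a", "mean"] == pytest.approx(2.0)
        assert out.loc["a", "cv_pct"] == pytest.approx(50.0)
        assert out.loc["b", "cv_pct"] == pytest.approx(0.0)
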