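import itertools
import math

import numpy as np
import pytest
from scipy import stats

from aimkit.core_data import GenotypeMatrix, SampleMeta, Variant
from aimkit.structure_geo import (PCAResult, cluster2, corr_dist,
                                  corr_pc_coords, geo_distance_matrix,
                                  haversine_km, pair_mask, pc_distance, pca)
from aimkit.synthetic_population import (GeoModel, PopModel, generate_dataset)


def _matrix(calls, ploidy=None):
    calls = np.asarray(calls, dtype=np.int16)
    n_s, n_v = calls.shape
    return GenotypeMatrix(
        [SampleMeta(id=f"S{i}") for i in range(n_s)],
        [Variant(chrom=1, pos=100 * (j + 1), id=f"v{j}") for j in range(n_v)],
        calls, np.ones(n_s, dtype=int) if ploidy is None else ploidy)


class TestPCA:
    def test_differentiated_pops_separate_on_pc1(self, rng):
        p1 = np.full(60, 0.9)
        p2 = np.full(60, 0.1)
        calls = np.vstack([(rng.random((15, 60)) < p1),
                           (rng.random((15, 60)) < p2)]).astype(np.int16)
        res = pca(_matrix(calls), n_pc=4)
        pc1 = res.scores[:, 0]
        assert (pc1[:15] > 0).all() != (pc1[15:] > 0).all()
        assert np.sign(pc1[:15]).std() == 0 and np.sign(pc1[15:]).std() == 0
        assert res.pct_variance[0] == res.pct_variance.max()
        assert res.pct_variance.sum() <= 100 + 1e-9

    def test_scores_orthogonal(self, small_dataset):
        res = pca(small_dataset.genotypes, n_pc=5)
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_eigenvalues_match_dense_oracle(self, rng):
        calls = rng.integers(0, 2, size=(20, 50)).astype(np.int16)
        gm = _matrix(calls)
        res = pca(gm, n_pc=10)
        # independent dense oracle: same normalization, eigh of covariance
        x = calls.astype(float)
        mean = x.mean(axis=0)
        var = mean * (1 - mean)
        keep = var > 0
        xn = (x[:, keep] - mean[keep]) / np.sqrt(var[keep])
        cov = xn @ xn.T / (20 - 1)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, ev[:10], rtol=1e-8,
                                   atol=1e-10)

    def test_eigenvalues_non_increasing(self, small_dataset):
        res = pca(small_dataset.genotypes, n_pc=6)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestPCDistance:
    def _res(self, scores, eig):
        scores = np.asarray(scores, dtype=float)
        eig = np.asarray(eig, dtype=float)
        return PCAResult(scores=scores, eigenvalues=eig,
                         pct_variance=100 * eig / eig.sum(),
                         sample_ids=[f"S{i}" for i in range(len(scores))])

    def test_identical_scores_zero(self):
        res = self._res([[1.0, 2.0], [1.0, 2.0]], [2.0, 1.0])
        assert pc_distance(res)[0, 1] == 0.0

    def test_equal_eigenvalues_plain_euclidean(self):
        res = self._res([[0.0, 0.0], [3.0, 4.0]], [1.0, 1.0])
        assert pc_distance(res)[0, 1] == pytest.approx(5.0)

    def test_weighting_of_pc1_difference(self):
        # lambda1/lambda2 = 2, dPC1 = 1, dPC2 = 0 -> d = 2
        res = self._res([[0.0, 0.0], [1.0, 0.0]], [2.0, 1.0])
        assert pc_distance(res)[0, 1] == pytest.approx(2.0)
        # alternative placement: weight on the squared term -> sqrt(2)
        assert pc_distance(res, weight_on="squared")[0, 1] == pytest.approx(
            math.sqrt(2.0))

    def test_zero_second_eigenvalue_errors(self):
        res = self._res([[0.0, 0.0], [1.0, 0.0]], [2.0, 0.0])
        with pytest.raises(ValueError):
            pc_distance(res)


class TestHaversine:
    def test_same_point_zero(self):
        assert haversine_km(36.0, 3.0, 36.0, 3.0) == 0.0

    def test_pole_to_pole(self):
        assert haversine_km(90, 0, -90, 0) == pytest.approx(
            math.pi * 6371.0, rel=1e-9)

    def test_against_spherical_law_of_cosines(self):
        lat1, lon1, lat2, lon2 = 0.0, 0.0, 0.0, 1.0
        d = haversine_km(lat1, lon1, lat2, lon2)
        # independent formula
        oracle = 6371.0 * math.acos(
            math.sin(math.radians(lat1)) * math.sin(math.radians(lat2))
            + math.cos(math.radians(lat1)) * math.cos(math.radians(lat2))
            * math.cos(math.radians(lon2 - lon1)))
        assert d == pytest.approx(oracle, abs=1e-6)

    def test_invalid_coordinates_error(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            haversine_km(0, 181, 0, 0)

    def test_symmetry(self):
        assert haversine_km(35, 2, 40, 10) == haversine_km(40, 10, 35, 2)


class TestCorrPCCoords:
    def _samples(self, lats, lons, alts):
        return [SampleMeta(id=f"S{i}", latitude=la, longitude=lo, altitude=al)
                for i, (la, lo, al) in enumerate(zip(lats, lons, alts))]

    def test_pc_linear_in_longitude(self, rng):
        n = 40
        lons = rng.uniform(0, 10, n)
        scores = np.column_stack([lons, rng.normal(size=n)])
        res = PCAResult(scores=scores, eigenvalues=np.array([2.0, 1.0]),
                        pct_variance=np.array([60.0, 30.0]),
                        sample_ids=[f"S{i}" for i in range(n)])
        samples = self._samples(rng.uniform(30, 40, n), lons,
                                rng.uniform(0, 100, n))
        tab = corr_pc_coords(res, samples, n_pc=2)
        row = tab[(tab["pc"] == 1) & (tab["coordinate"] == "longitude")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert row["p"].iloc[0] < 1e-10
        assert row["sig"].iloc[0] == "***"

    def test_p_value_matches_t_transform(self, rng):
        n = 30
        scores = rng.normal(size=(n, 2))
        samples = self._samples(rng.uniform(30, 40, n), rng.uniform(0, 10, n),
                                rng.uniform(0, 100, n))
        tab = corr_pc_coords(PCAResult(
            scores=scores, eigenvalues=np.array([2.0, 1.0]),
            pct_variance=np.array([60.0, 30.0]),
            sample_ids=[f"S{i}" for i in range(n)]), samples, n_pc=1)
        for _, row in tab.iterrows():
            t = row["r"] * math.sqrt((n - 2) / (1 - row["r"] ** 2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_too_few_coordinates_error(self, rng):
        samples = self._samples([35.0], [3.0], [10.0])
        res = PCAResult(scores=np.zeros((1, 2)),
                        eigenvalues=np.array([1.0, 1.0]),
                        pct_variance=np.array([50.0, 50.0]),
                        sample_ids=["S0"])
        with pytest.raises(ValueError):
            corr_pc_coords(res, samples)


class TestCorrDist:
    def test_identical_matrices_r_one(self, rng):
        d = np.abs(rng.normal(size=(10, 10)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tab = corr_dist(d, d)
        assert tab.loc[0, "r"] == pytest.approx(1.0)

    def test_pair_bookkeeping_102_samples(self, rng):
        """102 samples give 5151 pairs; masks partition them exactly."""
        n = 102
        labels = np.array(["W"] * 40 + ["E"] * 62)
        d1 = np.abs(rng.normal(size=(n, n)))
        d1 = (d1 + d1.T) / 2
        d2 = np.abs(rng.normal(size=(n, n)))
        d2 = (d2 + d2.T) / 2
        tab = corr_dist(d1, d2, labels).set_index("group")
        assert tab.loc["all", "n"] == 5151
        assert tab.loc["within-W", "n"] == 40 * 39 // 2
        assert tab.loc["within-E", "n"] == 62 * 61 // 2
        assert tab.loc["between", "n"] == 40 * 62
        assert (tab.loc["within-W", "n"] + tab.loc["within-E", "n"]
                + tab.loc["between", "n"]) == 5151
        # brute-force r for the between group
        pairs = [(i, j) for i, j in itertools.combinations(range(n), 2)
                 if labels[i] != labels[j]]
        x = [d1[i, j] for i, j in pairs]
        y = [d2[i, j] for i, j in pairs]
        assert tab.loc["between", "r"] == pytest.approx(
            stats.pearsonr(x, y)[0], rel=1e-12)

    def test_isolation_by_distance_signs(self):
        """Under the default cline simulation, genetic distance correlates
        positively and kinship negatively with geographic distance."""
        model = PopModel(n_variants=1500, n_alg_train=60, n_m_train=0,
                         n_c_train=0, n_alg_test=0, n_m_test=0, n_c_test=0,
                         seed=31)
        ds = generate_dataset(model)
        gm = ds.genotypes
        res = pca(gm, n_pc=2)
        gen_d = pc_distance(res)
        geo_d = geo_distance_matrix([s.latitude for s in gm.samples],
                                    [s.longitude for s in gm.samples])
        tab = corr_dist(gen_d, geo_d)
        assert tab.loc[0, "r"] > 0.2
        # a similarity (negated distance, as a kinship stand-in) flips the sign
        tab2 = corr_dist(-gen_d, geo_d)
        assert tab2.loc[0, "r"] < -0.2
        # permuted coordinates destroy the correlation
        rng2 = np.random.default_rng(0)
        perm = rng2.permutation(gm.n_samples)
        tab3 = corr_dist(gen_d, geo_d[np.ix_(perm, perm)])
        assert abs(tab3.loc[0, "r"]) < 0.1

    def test_small_group_skipped_with_notice(self, rng):
        d = np.zeros((4, 4))
        labels = ["W", "W", "W", "W"]
        with pytest.warns(UserWarning, match="skipped"):
            tab = corr_dist(d + 1 - np.eye(4), d + 1 - np.eye(4), labels)
        assert "within-E" not in set(tab["group"])


class TestCluster2:
    def test_bimodal_pc1_exact_split(self):
        scores = np.array([[x, 0.0] for x in [-5, -5.2, -4.8, 5, 5.1, 4.9]])
        res = PCAResult(scores=scores, eigenvalues=np.array([2.0, 1.0]),
                        pct_variance=np.array([60.0, 30.0]),
                        sample_ids=[f"S{i}" for i in range(6)])
        samples = [SampleMeta(id=f"S{i}", longitude=lo, latitude=35.0)
                   for i, lo in enumerate([0, 0, 0, 8, 8, 8])]
        labels = cluster2(res, samples, seed=1)
        assert list(labels) == ["W"] * 3 + ["E"] * 3

    def test_label_longitude_agreement_on_cline(self):
        model = PopModel(n_variants=1500, n_alg_train=100, n_m_train=0,
                         n_c_train=0, n_alg_test=0, n_m_test=0, n_c_test=0,
                         cline_steepness=3.0, seed=37)
        ds = generate_dataset(model)
        gm = ds.genotypes
        res = pca(gm, n_pc=2)
        labels = cluster2(res, gm.samples, seed=2)
        lons = np.array([s.longitude for s in gm.samples])
        truth = np.where(lons > np.median(lons), "E", "W")
        assert (labels == truth).mean() > 0.9

    def test_restart_determinism(self, small_dataset):
        res = pca(small_dataset.genotypes, n_pc=2)
        l1 = cluster2(res, small_dataset.genotypes.samples, seed=3)
        l2 = cluster2(res, small_dataset.genotypes.samples, seed=3)
        assert (l1 == l2).all()

    def test_degenerate_pc1_errors(self):
        res = PCAResult(scores=np.zeros((5, 2)),
                        eigenvalues=np.array([1.0, 1.0]),
                        pct_variance=np.array([50.0, 50.0]),
                        sample_ids=[f"S{i}" for i in range(5)])
        with pytest.raises(ValueError):
            cluster2(res)
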