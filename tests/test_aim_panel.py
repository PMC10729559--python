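import numpy as np
import pytest

from aimkit.aim_panel import (CONFIGURATIONS, AIMPanel, PanelConfig,
                              build_panel, candidate_snps, classify,
                              importance_runs, random_panel_null,
                              rank_from_importances, select_aim_panels,
                              select_panel, validate_panel_pca)
from aimkit.core_data import MISSING, GenotypeMatrix, SampleMeta, Variant


def _matrix(calls, groups=None):
    calls = np.asarray(calls, dtype=np.int16)
    n_s, n_v = calls.shape
    samples = [SampleMeta(id=f"S{i}", group=(groups[i] if groups else "ALG"))
               for i in range(n_s)]
    variants = [Variant(chrom=1 + j // 500, pos=1000 * (j % 500 + 1),
                        id=f"v{j}") for j in range(n_v)]
    return GenotypeMatrix(samples, variants, calls, np.ones(n_s, dtype=int))


@pytest.fixture(scope="module")
def planted_dataset():
    """40 + 40 haploid samples, 200 noise SNPs + 2 fixed differences."""
    rng = np.random.default_rng(51)
    n_a, n_b, n_noise = 40, 40, 200
    noise = rng.integers(0, 2, size=(n_a + n_b, n_noise))
    fixed = np.vstack([np.ones((n_a, 2)), np.zeros((n_b, 2))])
    calls = np.column_stack([noise[:, :100], fixed, noise[:, 100:]])
    gm = _matrix(calls, groups=["ALG"] * n_a + ["M"] * n_b)
    labels = np.array(["ALG"] * n_a + ["nonALG"] * n_b)
    planted = [100, 101]  # column indices of the perfect separators
    return gm, labels, planted


class TestCandidates:
    def test_variant_with_missing_call_excluded(self, rng):
        calls = rng.integers(0, 2, size=(30, 60)).astype(np.int16)
        calls[3, 7] = MISSING
        gm = _matrix(calls)
        ids, idx = candidate_snps(gm, window_n=30, min_candidates=2)
        assert "v7" not in ids
        assert 7 not in idx

    def test_output_subset_obeys_ld_threshold(self, rng):
        calls = rng.integers(0, 2, size=(80, 100)).astype(np.int16)
        calls[:, 1] = calls[:, 0]  # r^2 = 1 pair
        gm = _matrix(calls)
        ids, idx = candidate_snps(gm, window_n=50, min_candidates=2)
        assert set(idx) <= set(range(100))
        assert ("v0" in ids) != ("v1" in ids)  # the duplicated pair
        # within-window oracle, replicating the window layout over the
        # MAF-passing candidates (all sites complete and on one chromosome)
        import math
        from aimkit.core_data import minor_allele_freq
        dos = gm.dosage()
        kept = set(idx)
        cand = np.flatnonzero(minor_allele_freq(gm) >= 0.01)
        step = math.ceil(50 * 0.9)
        for start in range(0, len(cand), step):
            win = [j for j in cand[start:start + 50] if j in kept]
            for a in range(len(win)):
                for b in range(a + 1, len(win)):
                    r = np.corrcoef(dos[:, win[a]], dos[:, win[b]])[0, 1]
                    assert r * r <= 0.13 + 1e-9
            if start + 50 >= len(cand):
                break

    def test_too_few_candidates_errors(self, rng):
        calls = rng.integers(0, 2, size=(10, 20)).astype(np.int16)
        with pytest.raises(ValueError, match="candidate"):
            candidate_snps(_matrix(calls), window_n=10, min_candidates=50)


class TestRanking:
    def test_perfect_separator_ranks_first_in_all_configurations(
            self, planted_dataset):
        gm, labels, planted = planted_dataset
        cand_idx = np.arange(gm.n_variants)
        cfg = PanelConfig(n_runs=10, n_trees=30, seed=1)
        stacks = {}
        for crit in ("gini", "entropy"):
            stacks[crit] = importance_runs(
                gm.dosage(), labels, crit, cfg, seed=5)
        for crit in ("gini", "entropy"):
            for method in ("freq_top", "mean_importance"):
                order = rank_from_importances(stacks[crit], method,
                                              cfg.per_run_top)
                assert set(order[:2]) == set(planted)

    def test_rank_deterministic_given_seed(self, planted_dataset):
        gm, labels, _ = planted_dataset
        cfg = PanelConfig(n_runs=4, n_trees=20, seed=9)
        i1 = importance_runs(gm.dosage(), labels, "gini", cfg, seed=9)
        i2 = importance_runs(gm.dosage(), labels, "gini", cfg, seed=9)
        np.testing.assert_array_equal(i1, i2)

    def test_freq_top_scores_equal_brute_force_recount(self, rng):
        imp = rng.random((20, 50))
        order = rank_from_importances(imp, "freq_top", per_run_top=10)
        counts = np.zeros(50, dtype=int)
        for r in range(20):
            top = set(np.argsort(-imp[r])[:10])
            for j in top:
                counts[j] += 1
        # scores along the returned order must be non-increasing and the
        # first element must achieve the maximum count
        assert counts[order[0]] == counts.max()
        assert all(counts[order[a]] >= counts[order[a + 1]]
                   for a in range(49))

    def test_single_class_errors(self, rng):
        feats = rng.random((10, 5))
        with pytest.raises(ValueError, match="two classes"):
            importance_runs(feats, ["ALG"] * 10, "gini", PanelConfig(n_runs=1),
                            seed=0)


class TestBuildPanel:
    def test_disjoint_top48_gives_96(self):
        ranked_m = list(range(100))
        ranked_c = list(range(100, 200))
        ids = [f"v{i}" for i in range(200)]
        panel = build_panel(ranked_m, ranked_c, ids, "GI1")
        assert len(panel.variant_ids) == 96
        assert sum(1 for s in panel.source_setting.values() if s == "M") == 48

    def test_shared_snps_filled_from_rank_49_onward(self):
        # 5 SNPs shared between the two top-48 lists
        ranked_m = list(range(100))
        ranked_c = list(range(5)) + list(range(200, 295))
        ids = [f"v{i}" for i in range(300)]
        panel = build_panel(ranked_m, ranked_c, ids, "GI1")
        assert len(panel.variant_ids) == 96
        fill = [v for v in panel.variant_ids
                if panel.ranks[v][1] > 48]
        assert len(fill) == 5
        # fill-ins alternate down both rankings past rank 48
        fill_m = [v for v in fill if panel.ranks[v][0] == "M"]
        fill_c = [v for v in fill if panel.ranks[v][0] == "C"]
        assert abs(len(fill_m) - len(fill_c)) <= 1

    def test_panel_matches_oracle_recomputation(self):
        rng = np.random.default_rng(3)
        ranked_m = list(rng.permutation(150))
        ranked_c = list(rng.permutation(150))
        ids = [f"v{i}" for i in range(150)]
        panel = build_panel(ranked_m, ranked_c, ids, "EN2")
        expected = set(ranked_m[:48]) | set(ranked_c[:48])
        got = {int(v[1:]) for v in panel.variant_ids}
        assert expected <= got
        assert len(got) == 96

    def test_insufficient_candidates_error(self):
        with pytest.raises(ValueError):
            build_panel(list(range(50)), list(range(50)),
                        [f"v{i}" for i in range(50)], "GI1")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            AIMPanel(configuration="GI1", variant_ids=["a", "a"])


class TestValidationSelection:
    def test_perfect_separators_between_far_exceeds_within(
            self, planted_dataset):
        gm, labels, planted = planted_dataset
        panel = AIMPanel(configuration="GI1",
                         variant_ids=[f"v{j}" for j in planted])
        v = validate_panel_pca(panel, gm, labels == "ALG")
        assert v["between_mean"] > 5 * v["within_mean"]

    def test_means_equal_brute_force_pairs(self, planted_dataset):
        gm, labels, planted = planted_dataset
        panel = AIMPanel(configuration="GI1",
                         variant_ids=[f"v{j}" for j in planted] + ["v0", "v1"])
        v = validate_panel_pca(panel, gm, labels == "ALG")
        from aimkit.structure_geo import pca
        idx = gm.variant_index(panel.variant_ids)
        sc = pca(gm.subset(variant_idx=idx), n_pc=2).scores
        alg = np.flatnonzero(labels == "ALG")
        non = np.flatnonzero(labels != "ALG")
        within = [np.linalg.norm(sc[a] - sc[b]) for i, a in enumerate(alg)
                  for b in alg[i + 1:]]
        between = [np.linalg.norm(sc[a] - sc[b]) for a in alg for b in non]
        assert v["within_mean"] == pytest.approx(np.mean(within), rel=1e-9)
        assert v["between_mean"] == pytest.approx(np.mean(between), rel=1e-9)

    def test_select_panel_ratio_and_tiebreak(self, planted_dataset):
        gm, labels, planted = planted_dataset
        good = AIMPanel(configuration="GI1",
                        variant_ids=[f"v{j}" for j in planted])
        noisy = AIMPanel(configuration="EN1",
                         variant_ids=[f"v{j}" for j in range(4)])
        best, table = select_panel({"GI1": good, "EN1": noisy}, gm,
                                   labels == "ALG")
        assert best.configuration == "GI1"
        t = table.set_index("configuration")
        assert t.loc["GI1", "ratio"] == pytest.approx(
            t.loc["GI1", "between_mean"] / t.loc["GI1", "within_mean"])
        # identical panels tie -> configuration order wins
        best2, _ = select_panel({"GI2": good, "GI1": good}, gm,
                                labels == "ALG")
        assert best2.configuration == "GI1"


class TestClassify:
    def test_training_set_self_classification(self, planted_dataset):
        gm, labels, planted = planted_dataset
        res = classify(gm, gm, [f"v{j}" for j in planted], labels, labels,
                       n_runs=3, seed=0, n_trees=20)
        assert res["accuracy"] == 1.0
        assert ((res["p_alg"] >= 0) & (res["p_alg"] <= 1)).all()

    def test_accuracy_equals_brute_force_comparison(self, planted_dataset):
        gm, labels, _ = planted_dataset
        ids = [f"v{j}" for j in range(6)]  # noise-only panel
        res = classify(gm, gm, ids, labels, labels, n_runs=1, seed=4,
                       n_trees=15)
        pred = np.where(res["p_alg"] >= 0.5, "ALG", "nonALG")
        # with a single run, run accuracy equals mean-probability accuracy
        assert res["accuracy"] == pytest.approx(np.mean(pred == labels))

    def test_unknown_panel_snp_errors(self, planted_dataset):
        gm, labels, _ = planted_dataset
        with pytest.raises(KeyError):
            classify(gm, gm, ["nope"], labels, labels, n_runs=1)


class TestNull:
    def test_null_has_requested_size_and_panel_wins(self, planted_dataset):
        gm, labels, planted = planted_dataset
        cand = [f"v{j}" for j in range(80) if j not in (0, 1)]
        null = random_panel_null(gm, gm, cand, labels, labels, n_panels=8,
                                 panel_size=6, n_runs=2, seed=6, n_trees=15)
        assert len(null.accuracy) == 8
        res = classify(gm, gm, [f"v{j}" for j in planted], labels, labels,
                       n_runs=2, seed=7, n_trees=15)
        pct = null.percentile_of(res["accuracy"], res["min_p_alg"],
                                 res["max_p_alg"])
        assert pct["accuracy"] == 100.0


class TestFullSelection:
    def test_four_configurations_and_planted_marker_recovery(
            self, planted_dataset):
        gm, labels, planted = planted_dataset
        groups = np.array([s.group for s in gm.samples])
        cfg = PanelConfig(n_runs=6, n_trees=30, top_k_per_setting=10,
                          panel_size=20, seed=2)
        panels = select_aim_panels(gm, labels, np.arange(gm.n_variants),
                                   gm.variant_ids, cfg,
                                   m_mask=np.isin(groups, ["ALG", "M"]),
                                   c_mask=np.isin(groups, ["ALG", "M"]))
        for conf in CONFIGURATIONS:
            assert len(panels[conf].variant_ids) == 20
            assert {f"v{j}" for j in planted} <= set(panels[conf].variant_ids)
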