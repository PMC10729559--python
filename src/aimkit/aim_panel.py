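"""Random-forest selection of a 96-SNP ancestry-informative-marker panel.

Candidate SNPs (no missing genotypes, aggressively LD-pruned at r^2 = 0.13)
are ranked by repeated random-forest fits discriminating Algerian (ALG) from
non-Algerian samples, separately against the M and the C lineage.  Four
configurations are assessed: split criterion (Gini impurity "GI" vs entropy
"EN") crossed with ranking method (1: frequency of appearance in each run's
top-96 importance list over 100 runs; 2: mean importance over 100 runs).
Each configuration yields a panel of 96 SNPs (top 48 per lineage setting);
panels are compared by PCA on held-out test samples (between-class vs
within-ALG mean pair distance on the top two PCs) and the winner is bench-
marked against panels of randomly chosen SNPs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core_data import MISSING, GenotypeMatrix, ld_prune
from .structure_geo import pca

CONFIGURATIONS = ("GI1", "GI2", "EN1", "EN2")
_CRITERION = {"GI": "gini", "EN": "entropy"}
_METHOD = {"1": "freq_top", "2": "mean_importance"}


@dataclass
class PanelConfig:
    n_runs: int = 100
    per_run_top: int = 96
    top_k_per_setting: int = 48
    n_trees: int = 100            # scikit-learn's RandomForestClassifier default
    seed: int = 0
    panel_size: int = 96

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if 2 * self.top_k_per_setting < self.panel_size:
            raise ValueError("2 * top_k_per_setting must cover the panel size")


@dataclass
class AIMPanel:
    configuration: str
    variant_ids: list                       # exactly panel_size unique ids
    source_setting: dict = field(default_factory=dict)   # id -> "M" / "C"
    ranks: dict = field(default_factory=dict)            # id -> (setting, rank)

    def __post_init__(self):
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("panel contains duplicate variants")


@dataclass
class NullDistribution:
    accuracy: np.ndarray          # per random panel, mean accuracy
    min_p_alg: np.ndarray         # min P(ALG) over ALG test samples
    max_p_alg: np.ndarray         # max P(ALG) over non-ALG test samples

    def percentile_of(self, acc, min_p, max_p):
        """Empirical percentile of a focal panel on each summary (higher =
        better for accuracy and min_p, lower = better for max_p)."""
        return {
            "accuracy": float(np.mean(self.accuracy <= acc) * 100),
            "min_p_alg": float(np.mean(self.min_p_alg <= min_p) * 100),
            "max_p_alg": float(np.mean(self.max_p_alg >= max_p) * 100),
        }


# ---------------------------------------------------------------------------
# candidates and ranking
# ---------------------------------------------------------------------------

def candidate_snps(gm: GenotypeMatrix, r2_max: float = 0.13,
                   window_n: int = 1749, min_candidates: int | None = None,
                   panel_size: int = 96):
    """AIM candidates: zero-missingness sites, then strengthened LD pruning.

    Returns ``(ids, indices)`` into ``gm``.
    """
    complete = np.flatnonzero((gm.calls != MISSING).all(axis=0))
    sub = gm.subset(variant_idx=complete)
    _, kept = ld_prune(sub, window_n=window_n, r2_max=r2_max)
    idx = complete[kept]
    need = min_candidates if min_candidates is not None else 2 * panel_size
    if len(idx) < need:
        raise ValueError(f"only {len(idx)} candidate SNPs (< {need})")
    return [gm.variants[j].id for j in idx], idx


def _features(gm: GenotypeMatrix, variant_idx=None) -> np.ndarray:
    """Classifier features: dosage fractions (missing not allowed here)."""
    sub = gm if variant_idx is None else gm.subset(variant_idx=variant_idx)
    d = sub.dosage()
    if np.isnan(d).any():
        raise ValueError("classifier features contain missing genotypes")
    return d


def importance_runs(features: np.ndarray, labels, criterion: str,
                    cfg: PanelConfig, seed: int) -> np.ndarray:
    """Stack of per-run impurity importances, shape (n_runs, n_features)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need two classes to rank SNPs")
    rng = np.random.default_rng(seed)
    out = np.empty((cfg.n_runs, features.shape[1]))
    for r in range(cfg.n_runs):
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees, criterion=criterion,
            random_state=int(rng.integers(2 ** 31)))
        clf.fit(features, labels)
        out[r] = clf.feature_importances_
    return out


def rank_from_importances(imp: np.ndarray, method: str,
                          per_run_top: int = 96) -> np.ndarray:
    """Rank features from an (n_runs, n_features) importance stack.

    ``freq_top``: score = number of runs where the feature is in that run's
    top ``per_run_top`` importances; ties broken by mean importance, then by
    feature index.  ``mean_importance``: mean importance, ties by index.
    Returns feature indices, best first.
    """
    n_runs, n_feat = imp.shape
    mean_imp = imp.mean(axis=0)
    if method == "mean_importance":
        order = np.lexsort((np.arange(n_feat), -mean_imp))
        return order
    if method != "freq_top":
        raise ValueError(f"unknown ranking method {method!r}")
    k = min(per_run_top, n_feat)
    counts = np.zeros(n_feat, dtype=np.int64)
    for r in range(n_runs):
        top = np.argpartition(-imp[r], k - 1)[:k]
        counts[top] += 1
    return np.lexsort((np.arange(n_feat), -mean_imp, -counts))


def rank_snps(gm: GenotypeMatrix, labels, candidate_idx, configuration: str,
              cfg: PanelConfig | None = None, seed: int | None = None,
              importances: np.ndarray | None = None):
    """Ranked candidate indices (best first) for one configuration.

    ``labels`` is the binary ALG / non-ALG vector for the training samples in
    ``gm``.  A precomputed importance stack may be passed so that the two
    ranking methods of one split criterion reuse the same 100 forest fits.
    Returns ``(ranked_candidate_positions, importances)``.
    """
    cfg = cfg or PanelConfig()
    crit = _CRITERION[configuration[:2]]
    method = _METHOD[configuration[2]]
    feats = _features(gm, candidate_idx)
    if importances is None:
        importances = importance_runs(
            feats, labels, crit, cfg, cfg.seed if seed is None else seed)
    order = rank_from_importances(importances, method, cfg.per_run_top)
    return order, importances


def build_panel(ranked_m, ranked_c, candidate_ids, configuration: str = "",
                top_k: int = 48, panel_size: int = 96) -> AIMPanel:
    """Union of the top-``top_k`` SNPs of the two lineage settings.

    When the two top lists overlap, both rankings are advanced alternately
    (M first) past rank ``top_k`` until ``panel_size`` unique SNPs are
    collected.
    """
    ranked_m = list(ranked_m)
    ranked_c = list(ranked_c)
    chosen: dict[int, str] = {}
    ranks = {}
    for setting, ranked in (("M", ranked_m[:top_k]), ("C", ranked_c[:top_k])):
        for rank, idx in enumerate(ranked, start=1):
            if idx not in chosen:
                chosen[idx] = setting
                ranks[idx] = (setting, rank)
    pos = {"M": top_k, "C": top_k}
    order = itertools.cycle(("M", "C"))
    lists = {"M": ranked_m, "C": ranked_c}
    while len(chosen) < panel_size:
        setting = next(order)
        ranked = lists[setting]
        while pos[setting] < len(ranked) and ranked[pos[setting]] in chosen:
            pos[setting] += 1
        if pos[setting] >= len(ranked):
            if all(pos[s] >= len(lists[s]) for s in lists):
                raise ValueError("not enough candidates to fill the panel")
            continue
        idx = ranked[pos[setting]]
        chosen[idx] = setting
        ranks[idx] = (setting, pos[setting] + 1)
        pos[setting] += 1
    ids = [candidate_ids[i] for i in chosen]
    return AIMPanel(
        configuration=configuration, variant_ids=ids,
        source_setting={candidate_ids[i]: s for i, s in chosen.items()},
        ranks={candidate_ids[i]: r for i, r in ranks.items()},
    )


def select_aim_panels(train_gm: GenotypeMatrix, labels, candidate_idx,
                      candidate_ids, cfg: PanelConfig | None = None,
                      m_mask=None, c_mask=None) -> dict[str, AIMPanel]:
    """Run all four configurations and assemble their 96-SNP panels.

    ``m_mask`` / ``c_mask`` select the training samples of the ALG-vs-M and
    ALG-vs-C settings (ALG samples included in both).  The 100-run importance
    stacks are shared between the two ranking methods of each criterion.
    """
    cfg = cfg or PanelConfig()
    labels = np.asarray(labels)
    if m_mask is None or c_mask is None:
        raise ValueError("m_mask and c_mask are required")
    panels = {}
    stacks = {}
    for crit_tag, crit_seed in (("GI", cfg.seed), ("EN", cfg.seed + 1)):
        for setting, mask in (("M", np.asarray(m_mask)), ("C", np.asarray(c_mask))):
            sub = train_gm.subset(sample_idx=np.flatnonzero(mask))
            stacks[(crit_tag, setting)] = importance_runs(
                _features(sub, candidate_idx), labels[mask],
                _CRITERION[crit_tag], cfg,
                crit_seed + (0 if setting == "M" else 7919))
    for conf in CONFIGURATIONS:
        crit_tag, method = conf[:2], _METHOD[conf[2]]
        rm = rank_from_importances(stacks[(crit_tag, "M")], method, cfg.per_run_top)
        rc = rank_from_importances(stacks[(crit_tag, "C")], method, cfg.per_run_top)
        panels[conf] = build_panel(rm, rc, candidate_ids, conf,
                                   cfg.top_k_per_setting, cfg.panel_size)
    return panels


# ---------------------------------------------------------------------------
# validation and selection
# ---------------------------------------------------------------------------

def validate_panel_pca(panel: AIMPanel, test_gm: GenotypeMatrix, alg_mask):
    """Mean pair distances on the top-2 PCs of the panel-restricted test set.

    Returns a dict with the within-ALG and ALG-vs-rest mean distances, their
    standard errors and the between/within ratio.
    """
    alg_mask = np.asarray(alg_mask, dtype=bool)
    if alg_mask.all() or not alg_mask.any():
        raise ValueError("test set must contain ALG and non-ALG samples")
    idx = test_gm.variant_index(panel.variant_ids)
    res = pca(test_gm.subset(variant_idx=idx), n_pc=2)
    sc = res.scores[:, :2]
    diff = sc[:, None, :] - sc[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    n = len(alg_mask)
    within, between = [], []
    for i, j in itertools.combinations(range(n), 2):
        if alg_mask[i] and alg_mask[j]:
            within.append(d[i, j])
        elif alg_mask[i] != alg_mask[j]:
            between.append(d[i, j])
    within = np.asarray(within)
    between = np.asarray(between)
    return {
        "within_mean": float(within.mean()),
        "within_se": float(within.std(ddof=1) / np.sqrt(len(within))),
        "between_mean": float(between.mean()),
        "between_se": float(between.std(ddof=1) / np.sqrt(len(between))),
        "ratio": float(between.mean() / within.mean()),
    }


def select_panel(panels: dict[str, AIMPanel], test_gm: GenotypeMatrix,
                 alg_mask):
    """Pick the panel maximizing the between/within PC-distance ratio.

    Ties are broken by configuration order GI1, GI2, EN1, EN2.  Returns
    ``(best_panel, comparison_table)``; the table makes the choice auditable.
    """
    rows = []
    for conf in CONFIGURATIONS:
        if conf not in panels:
            continue
        v = validate_panel_pca(panels[conf], test_gm, alg_mask)
        rows.append({"configuration": conf, **v})
    table = pd.DataFrame(rows)
    best_conf = table.loc[table["ratio"].idxmax(), "configuration"]
    return panels[best_conf], table


# ---------------------------------------------------------------------------
# classification and the random-panel null
# ---------------------------------------------------------------------------

def classify(train_gm: GenotypeMatrix, test_gm: GenotypeMatrix,
             variant_ids, train_labels, test_labels, n_runs: int = 50,
             seed: int = 0, n_trees: int = 100):
    """Repeated RF classification on the given SNP set.

    Labels are binary ALG / non-ALG strings.  Returns a dict with per-sample
    mean P(ALG) over ``n_runs`` fits, the mean accuracy, and the min P(ALG)
    among ALG test samples / max P(ALG) among non-ALG test samples.
    """
    ti = train_gm.variant_index(variant_ids)
    si = test_gm.variant_index(variant_ids)
    xtr = _features(train_gm, ti)
    xte = _features(test_gm, si)
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    rng = np.random.default_rng(seed)
    p_alg = np.zeros(len(yte))
    acc = np.zeros(n_runs)
    for r in range(n_runs):
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)))
        clf.fit(xtr, ytr)
        proba = clf.predict_proba(xte)
        col = list(clf.classes_).index("ALG")
        p = proba[:, col]
        p_alg += p
        pred = np.where(p >= 0.5, "ALG", "nonALG")
        acc[r] = float(np.mean(pred == yte))
    p_alg /= n_runs
    is_alg = yte == "ALG"
    return {
        "p_alg": p_alg,
        "accuracy": float(acc.mean()),
        "accuracy_runs": acc,
        "min_p_alg": float(p_alg[is_alg].min()) if is_alg.any() else np.nan,
        "max_p_alg": float(p_alg[~is_alg].max()) if (~is_alg).any() else np.nan,
    }


def random_panel_null(train_gm, test_gm, candidate_ids, train_labels,
                      test_labels, n_panels: int = 1000, panel_size: int = 96,
                      n_runs: int = 50, seed: int = 0,
                      n_trees: int = 100) -> NullDistribution:
    """Empirical null: panels of randomly chosen candidate SNPs.

    Each panel is drawn without replacement from the candidate set and
    scored with :func:`classify`; the three summaries per panel form the
    null distributions of Fig-S7 type comparisons.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(candidate_ids)
    accs, minps, maxps = [], [], []
    for b in range(n_panels):
        panel = rng.choice(ids, size=panel_size, replace=False)
        res = classify(train_gm, test_gm, list(panel), train_labels,
                       test_labels, n_runs=n_runs,
                       seed=int(rng.integers(2 ** 31)), n_trees=n_trees)
        accs.append(res["accuracy"])
        minps.append(res["min_p_alg"])
        maxps.append(res["max_p_alg"])
    return NullDistribution(np.asarray(accs), np.asarray(minps),
                            np.asarray(maxps))


def write_ranking_table(panels: dict[str, AIMPanel], path) -> None:
    """Per-SNP ranks across configurations (unselected SNPs get rank 97)."""
    all_ids = sorted({v for p in panels.values() for v in p.variant_ids})
    rows = []
    for vid in all_ids:
        row = {"snp": vid}
        for conf, p in panels.items():
            row[conf] = p.ranks[vid][1] if vid in p.ranks else 97
        row["total_rank"] = sum(row[c] for c in panels)
        rows.append(row)
    pd.DataFrame(rows).sort_values("total_rank").to_csv(path, sep="\t",
                                                        index=False)
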