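"""Pedigree-based simulation of F1 and backcross hybrids and the
classification experiments stress-testing the AIM panel on them.

Haploid drones are used directly as gametes: an F1 hybrid is one European
plus one Algerian haplotype; each subsequent backcross generation BC(n+1)
combines a meiosis gamete of a BC(n) (or F1) individual with a fresh random
Algerian haplotype, so expected European ancestry halves each generation
(F1: 1/2, BC1: 1/4, BC2: 1/8, BC3: 1/16).  Meiosis draws Poisson crossover
counts per chromosome (rate rho per bp, no interference) with uniform
breakpoints.  Parent pairs are sampled without replacement among all unique
combinations, per cross type, per lineage and per train/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import GenotypeMatrix, SampleMeta
from .synthetic_population import (DEFAULT_CHROM_LENGTHS, DEFAULT_REC_RATE,
                                   meiosis_gamete)
from . import aim_panel as _aim

CROSS_TYPES = ("F1", "BC1", "BC2", "BC3")
LINEAGES = ("M", "C")
SPLITS = ("train", "test")


@dataclass
class RecombinationMap:
    chrom_lengths: tuple = DEFAULT_CHROM_LENGTHS
    rec_rate: float = DEFAULT_REC_RATE

    def __post_init__(self):
        if self.rec_rate <= 0:
            raise ValueError("rec_rate must be positive")


@dataclass
class CrossPlan:
    matings_per_cross: int = 40
    cross_types: tuple = CROSS_TYPES
    lineages: tuple = LINEAGES
    splits: tuple = SPLITS
    seed: int = 0

    @property
    def n_hybrids(self) -> int:
        return (self.matings_per_cross * len(self.cross_types)
                * len(self.lineages) * len(self.splits))


@dataclass
class Hybrid:
    id: str
    cross_type: str
    lineage: str
    split: str
    hap0: np.ndarray       # genotype haplotype (allele calls)
    hap1: np.ndarray
    anc0: np.ndarray       # per-site ancestry: 1 = European, 0 = Algerian
    anc1: np.ndarray
    parents: tuple = ("", "")

    @property
    def diploid_calls(self) -> np.ndarray:
        return (self.hap0 + self.hap1).astype(np.int16)

    @property
    def european_ancestry(self) -> float:
        return float((self.anc0.mean() + self.anc1.mean()) / 2)


@dataclass
class HybridCohort:
    hybrids: list
    variants: list

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "id": h.id, "cross_type": h.cross_type, "lineage": h.lineage,
            "split": h.split, "parent1": h.parents[0], "parent2": h.parents[1],
            "european_ancestry": h.european_ancestry,
        } for h in self.hybrids])

    def genotypes(self, subset=None) -> GenotypeMatrix:
        """Diploid GenotypeMatrix of (a subset of) the cohort."""
        hy = self.hybrids if subset is None else [self.hybrids[i] for i in subset]
        calls = np.stack([h.diploid_calls for h in hy])
        metas = [SampleMeta(id=h.id, group=f"HYB_{h.cross_type}{h.lineage}")
                 for h in hy]
        return GenotypeMatrix(metas, self.variants, calls,
                              np.full(len(hy), 2, dtype=np.int16))

    def split_idx(self, split: str) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hybrids)
                         if h.split == split], dtype=int)


def _gamete_of(hybrid: Hybrid, variants, recmap: RecombinationMap, rng):
    """One meiosis gamete of a diploid hybrid, with its ancestry labels."""
    g, source = meiosis_gamete(hybrid.hap0, hybrid.hap1, variants, rng,
                               rec_rate=recmap.rec_rate,
                               chrom_lengths=recmap.chrom_lengths)
    anc = np.where(source == 0, hybrid.anc0, hybrid.anc1)
    return g, anc


def _unique_pairs(n_a: int, n_b: int, k: int, rng) -> list:
    """k parent pairs sampled without replacement from the n_a x n_b grid."""
    total = n_a * n_b
    if total < k:
        raise ValueError(f"only {total} unique parent combinations, need {k}")
    flat = rng.choice(total, size=k, replace=False)
    return [(int(f // n_b), int(f % n_b)) for f in flat]


def make_cohort(alg_pools: dict, eur_pools: dict, variants,
                plan: CrossPlan | None = None,
                recmap: RecombinationMap | None = None) -> HybridCohort:
    """Simulate the full hybrid cohort.

    ``alg_pools[split]`` is an (n, n_variants) array of Algerian haploid
    genotypes for that split; ``eur_pools[(lineage, split)]`` likewise for
    the European lineages.  Hybrids of a split descend only from samples of
    that split, so train hybrids never leak test genotypes.
    """
    plan = plan or CrossPlan()
    recmap = recmap or RecombinationMap()
    rng = np.random.default_rng(plan.seed)
    hybrids = []
    for split in plan.splits:
        alg = np.asarray(alg_pools[split])
        for lineage in plan.lineages:
            eur = np.asarray(eur_pools[(lineage, split)])
            prev_gen: list[Hybrid] = []
            for cross in plan.cross_types:
                cur = []
                if cross == "F1":
                    pairs = _unique_pairs(len(eur), len(alg),
                                          plan.matings_per_cross, rng)
                    for n, (ie, ia) in enumerate(pairs):
                        h = Hybrid(
                            id=f"{cross}{lineage}_{split}_{n:03d}",
                            cross_type=cross, lineage=lineage, split=split,
                            hap0=eur[ie].astype(np.int16),
                            hap1=alg[ia].astype(np.int16),
                            anc0=np.ones(eur.shape[1], dtype=np.int8),
                            anc1=np.zeros(alg.shape[1], dtype=np.int8),
                            parents=(f"{lineage}_{split}_{ie}",
                                     f"ALG_{split}_{ia}"),
                        )
                        cur.append(h)
                else:
                    pairs = _unique_pairs(len(prev_gen), len(alg),
                                          plan.matings_per_cross, rng)
                    for n, (ih, ia) in enumerate(pairs):
                        g, anc = _gamete_of(prev_gen[ih], variants, recmap, rng)
                        h = Hybrid(
                            id=f"{cross}{lineage}_{split}_{n:03d}",
                            cross_type=cross, lineage=lineage, split=split,
                            hap0=g, hap1=alg[ia].astype(np.int16),
                            anc0=anc, anc1=np.zeros(alg.shape[1], dtype=np.int8),
                            parents=(prev_gen[ih].id, f"ALG_{split}_{ia}"),
                        )
                        cur.append(h)
                hybrids.extend(cur)
                prev_gen = cur
    return HybridCohort(hybrids=hybrids, variants=list(variants))


# ---------------------------------------------------------------------------
# classification experiments
# ---------------------------------------------------------------------------

def _concat_matrices(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    if [v.key() for v in a.variants] != [v.key() for v in b.variants]:
        raise ValueError("matrices must share the variant set")
    return GenotypeMatrix(a.samples + b.samples, a.variants,
                          np.vstack([a.calls, b.calls]),
                          np.concatenate([a.ploidy, b.ploidy]),
                          het_counts=a.het_counts)

def hybrid_experiment(train_gm: GenotypeMatrix, test_gm: GenotypeMatrix,
                      train_labels, test_labels, cohort: HybridCohort,
                      panel_ids, all_candidate_ids=None, n_runs: int = 50,
                      seed: int = 0, n_trees: int = 100) -> dict:
    """The three hybrid classification experiments.

    A: classifiers trained on the original training samples only (panel
       SNPs); per-cross-type distributions of P(ALG) for test-split hybrids.
    B: training augmented with the train-split hybrids labelled non-ALG;
       accuracy and per-class misassignment rates on originals + hybrids.
    C: experiment B repeated with all candidate SNPs instead of the panel
       (skipped when ``all_candidate_ids`` is None).

    Test sets never contain train-split hybrids (and vice versa).
    """
    train_ids = set(train_gm.sample_ids)
    tr_idx = cohort.split_idx("train")
    te_idx = cohort.split_idx("test")
    hyb_train = cohort.genotypes(tr_idx)
    hyb_test = cohort.genotypes(te_idx)
    if train_ids & set(hyb_test.sample_ids) or set(hyb_train.sample_ids) & set(
            test_gm.sample_ids) or set(hyb_train.sample_ids) & set(
            hyb_test.sample_ids):
        raise ValueError("hybrid appears in both training and test data")

    test_aug = _concat_matrices(test_gm, hyb_test)
    ylab_test = list(test_labels) + ["nonALG"] * hyb_test.n_samples
    test_classes = (
        [("ALG" if l == "ALG" else "REF") for l in test_labels]
        + [h.cross_type + h.lineage for h in
           (cohort.hybrids[i] for i in te_idx)]
    )

    def per_class(p_alg):
        df = pd.DataFrame({"cls": test_classes, "p_alg": p_alg,
                           "truth": ylab_test})
        df["misassigned"] = ((df["truth"] == "nonALG") & (df["p_alg"] >= 0.5)) | \
                            ((df["truth"] == "ALG") & (df["p_alg"] < 0.5))
        agg = df.groupby("cls").agg(n=("p_alg", "size"),
                                    mean_p_alg=("p_alg", "mean"),
                                    median_p_alg=("p_alg", "median"),
                                    misassignment=("misassigned", "mean"))
        return agg.reset_index()

    report = {}
    res_a = _aim.classify(train_gm, test_aug, panel_ids, train_labels,
                          ylab_test, n_runs=n_runs, seed=seed,
                          n_trees=n_trees)
    report["A"] = {"summary": res_a, "per_class": per_class(res_a["p_alg"])}

    train_aug = _concat_matrices(train_gm, hyb_train)
    ylab_train = list(train_labels) + ["nonALG"] * hyb_train.n_samples
    res_b = _aim.classify(train_aug, test_aug, panel_ids, ylab_train,
                          ylab_test, n_runs=n_runs, seed=seed + 1,
                          n_trees=n_trees)
    report["B"] = {"summary": res_b, "per_class": per_class(res_b["p_alg"])}

    if all_candidate_ids is not None:
        res_c = _aim.classify(train_aug, test_aug, all_candidate_ids,
                              ylab_train, ylab_test, n_runs=n_runs,
                              seed=seed + 2, n_trees=n_trees)
        report["C"] = {"summary": res_c, "per_class": per_class(res_c["p_alg"])}
    report["n_train_merged"] = train_aug.n_samples
    report["n_test_merged"] = test_aug.n_samples
    return report
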