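"""End-to-end pipeline on synthetic data: simulate -> QC -> LD prune ->
kinship / family filter -> structure & geography -> AIM selection ->
random-panel null -> hybrid experiments.

A single master seed fans out to per-stage seeds through a fixed counter
scheme (``stage_seed = (master_seed * 1009 + stage_offset) % 2**31``), so
any stage can be reproduced in isolation.  Every stage writes its outputs
under the run directory and registers them in a manifest with SHA-256
checksums; re-running with the same configuration and seed reproduces the
manifest byte-identically, and stages whose outputs are already present and
checksummed are skipped when ``resume`` is enabled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import aim_panel as aim
from . import core_data as cd
from . import hybrid_sim as hs
from . import ibd_kinship as ibd
from . import structure_geo as sg
from . import synthetic_population as synth

log = logging.getLogger("aimkit")

STAGE_OFFSETS = {
    "simulate": 1, "kinship": 2, "structure": 3, "aim": 4,
    "null": 5, "hybrids": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed * 1009 + STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """Full pipeline configuration (demo-scale defaults)."""

    seed: int = 0
    out_dir: str = "aimkit_run"
    # population (small demo sizes; the study layout is 82/50/118 + 20/13/30)
    n_variants: int = 2000
    n_alg_train: int = 24
    n_m_train: int = 16
    n_c_train: int = 24
    n_alg_test: int = 8
    n_m_test: int = 6
    n_c_test: int = 8
    fst_lineage: float = 0.12
    fst_intra_alg: float = 0.02
    missing_rate: float = 0.01
    het_artifact_rate: float = 0.002
    family_sizes: tuple = (3,)
    # QC / pruning
    max_het_frac: float = 0.01
    max_missing: float = 0.05
    min_call_rate: float = 0.90
    prune_window: int = 200
    prune_overlap: float = 0.10
    prune_r2: float = 0.30
    prune_maf: float = 0.01
    # kinship
    kin_subsample_frac: float = 0.25
    family_threshold: float = 0.30
    close_kin_cutoff: float = 0.10
    # AIM selection
    aim_r2: float = 0.13
    aim_n_runs: int = 10
    aim_n_trees: int = 50
    classify_runs: int = 10
    # null
    null_panels: int = 50
    null_runs: int = 5
    # hybrids
    matings_per_cross: int = 10
    hybrid_runs: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "family_sizes" in raw:
            raw["family_sizes"] = tuple(raw["family_sizes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["family_sizes"] = list(d["family_sizes"])
        return d


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Executes the stages and maintains the manifest."""

    def __init__(self, config: RunConfig, resume: bool = False):
        self.cfg = config
        self.out = pathlib.Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.manifest = {"config": config.to_dict(), "seed": config.seed,
                         "stages": {}}
        self._state: dict = {}
        self._prev = {}
        mpath = self.out / "manifest.json"
        if resume and mpath.exists():
            with open(mpath) as fh:
                prev = json.load(fh)
            if prev.get("config") == self.manifest["config"]:
                self._prev = prev.get("stages", {})

    # -- bookkeeping ------------------------------------------------------
    def _register(self, stage: str, paths: dict):
        self.manifest["stages"][stage] = {
            "seed": stage_seed(self.cfg.seed, stage) if stage in STAGE_OFFSETS
            else None,
            "outputs": {k: {"path": str(p.relative_to(self.out)),
                            "sha256": _sha256(p)}
                        for k, p in paths.items()},
        }

    def _cached(self, stage: str) -> bool:
        entry = self._prev.get(stage)
        if not entry:
            return False
        for rec in entry["outputs"].values():
            p = self.out / rec["path"]
            if not p.exists() or _sha256(p) != rec["sha256"]:
                return False
        self.manifest["stages"][stage] = entry
        log.info("stage %s: cached outputs valid, skipped", stage)
        return True

    # -- stages -----------------------------------------------------------
    def run(self) -> dict:
        stages = [self.simulate, self.qc_prune, self.kinship, self.structure,
                  self.select_aim, self.null, self.hybrids]
        for fn in stages:
            name = fn.__name__
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception:
                self._write_manifest(partial=name)
                log.error("stage %s failed; partial manifest written", name)
                raise
            log.info("stage %s: done", name)
        self._write_manifest()
        self._report()
        return self.manifest

    def _write_manifest(self, partial=None):
        if partial:
            self.manifest["failed_stage"] = partial
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    def simulate(self):
        cfg = self.cfg
        model = synth.PopModel(
            n_variants=cfg.n_variants, fst_lineage=cfg.fst_lineage,
            fst_intra_alg=cfg.fst_intra_alg,
            n_alg_train=cfg.n_alg_train, n_m_train=cfg.n_m_train,
            n_c_train=cfg.n_c_train, n_alg_test=cfg.n_alg_test,
            n_m_test=cfg.n_m_test, n_c_test=cfg.n_c_test,
            missing_rate=cfg.missing_rate,
            het_artifact_rate=cfg.het_artifact_rate,
            family_sizes=cfg.family_sizes,
            seed=stage_seed(cfg.seed, "simulate"))
        ds = synth.generate_dataset(model)
        self._state["ds"] = ds
        paths = synth.write_dataset(ds, self.out / "sim")
        self._register("simulate", paths)

    def qc_prune(self):
        cfg = self.cfg
        ds = self._state["ds"]
        gm, report = cd.site_qc(ds.genotypes, cd.QCThresholds(
            max_het_frac=cfg.max_het_frac, max_missing=cfg.max_missing))
        gm = cd.sample_qc(gm, cfg.min_call_rate)
        _, kept = cd.ld_prune(gm, window_n=cfg.prune_window,
                              overlap_frac=cfg.prune_overlap,
                              r2_max=cfg.prune_r2, maf_min=cfg.prune_maf)
        pruned = gm.subset(variant_idx=kept)
        self._state["qc"] = gm
        self._state["pruned"] = pruned
        p1 = self.out / "qc_report.json"
        with open(p1, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        p2 = self.out / "pruned.vcf"
        cd.write_genotypes(pruned, p2, meta_path=self.out / "pruned_meta.tsv")
        self._register("qc_prune", {"report": p1, "vcf": p2,
                                    "meta": self.out / "pruned_meta.tsv"})

    def _apply_family_filter(self, retained, families):
        pruned = self._state["pruned"]
        keep_ids = set(retained)
        keep = [i for i, s in enumerate(pruned.samples)
                if s.group != "ALG" or s.id in keep_ids]
        self._state["pruned"] = pruned.subset(sample_idx=keep)
        self._state["families"] = families

    def kinship(self):
        cfg = self.cfg
        if self.resume and self._cached("kinship"):
            with open(self.out / "families.json") as fh:
                fam = json.load(fh)
            self._apply_family_filter(fam["retained"], fam["families"])
            return
        pruned = self._state["pruned"]
        alg_idx = [i for i, s in enumerate(pruned.samples) if s.group == "ALG"]
        alg = pruned.subset(sample_idx=alg_idx)
        K = ibd.kinship_matrix(alg, ibd.HMMConfig(
            subsample_frac=cfg.kin_subsample_frac,
            seed=stage_seed(cfg.seed, "kinship")))
        call_rates = {s.id: s.call_rate for s in alg.samples}
        families, retained = ibd.family_components(
            K, cfg.family_threshold, call_rates)
        meta = {s.id: s for s in alg.samples}
        ck = ibd.close_kin(K, cfg.close_kin_cutoff, meta)
        self._apply_family_filter(retained, families)
        p1 = self.out / "kinship.tsv"
        ibd.write_pair_table(K.pairs, p1)
        p2 = self.out / "ibd_segments.tsv"
        ibd.write_segment_table(K.pairs, p2)
        p3 = self.out / "families.json"
        with open(p3, "w") as fh:
            json.dump({"families": families, "retained": retained},
                      fh, indent=2, sort_keys=True)
        p4 = self.out / "close_kin.tsv"
        ck.to_csv(p4, sep="\t", index=False, float_format="%.6g")
        self._register("kinship", {"pairs": p1, "segments": p2,
                                   "families": p3, "close_kin": p4})

    def structure(self):
        pruned = self._state["pruned"]
        alg_idx = [i for i, s in enumerate(pruned.samples) if s.group == "ALG"]
        alg = pruned.subset(sample_idx=alg_idx)
        res = sg.pca(alg, n_pc=7)
        labels = sg.cluster2(res, alg.samples,
                             seed=stage_seed(self.cfg.seed, "structure"))
        t1 = sg.corr_pc_coords(res, alg.samples, n_pc=7)
        gen_d = sg.pc_distance(res)
        lats = [s.latitude for s in alg.samples]
        lons = [s.longitude for s in alg.samples]
        geo_d = sg.geo_distance_matrix(lats, lons)
        t2 = sg.corr_dist(gen_d, geo_d, labels)
        paths = {}
        paths["scores"] = self.out / "pca_scores.tsv"
        res.to_frame().assign(cluster=labels).to_csv(
            paths["scores"], sep="\t", float_format="%.6g")
        paths["eigenvalues"] = self.out / "pca_eigenvalues.tsv"
        pd.DataFrame({"eigenvalue": res.eigenvalues,
                      "pct_variance": res.pct_variance}).to_csv(
            paths["eigenvalues"], sep="\t", index=False, float_format="%.6g")
        paths["corr_pc_coords"] = self.out / "corr_pc_coords.tsv"
        t1.to_csv(paths["corr_pc_coords"], sep="\t", index=False,
                  float_format="%.6g")
        paths["corr_dist"] = self.out / "corr_dist.tsv"
        t2.to_csv(paths["corr_dist"], sep="\t", index=False,
                  float_format="%.6g")
        self._register("structure", paths)

    def _split(self):
        ds = self._state["ds"]
        gm = self._state["qc"]
        split = dict(zip(ds.truth["sample_id"], ds.truth["split"]))
        tr = [i for i, s in enumerate(gm.samples) if split[s.id] == "train"]
        te = [i for i, s in enumerate(gm.samples) if split[s.id] == "test"]
        return gm.subset(sample_idx=tr), gm.subset(sample_idx=te)

    def select_aim(self):
        cfg = self.cfg
        train, test = self._split()
        y_tr = np.array(["ALG" if s.group == "ALG" else "nonALG"
                         for s in train.samples])
        y_te = np.array(["ALG" if s.group == "ALG" else "nonALG"
                         for s in test.samples])
        if self.resume and self._cached("aim"):
            with open(self.out / "aim_best.json") as fh:
                best_info = json.load(fh)
            panel_df = pd.read_csv(self.out / "aim_panel.tsv", sep="\t")
            best = aim.AIMPanel(configuration=best_info["configuration"],
                                variant_ids=list(panel_df["snp"]))
            self._state.update(
                train=train, test=test, y_tr=y_tr, y_te=y_te,
                cand_ids=list(pd.read_csv(self.out / "aim_candidates.tsv",
                                          sep="\t")["snp"]),
                panels={}, best=best, best_perf=best_info["performance"])
            return
        # zero-missingness is assessed on the full dataset (both splits) so
        # panel SNPs are complete in the test samples too; ranking itself
        # only ever sees training samples
        cand_ids, cand_idx = aim.candidate_snps(
            self._state["qc"], r2_max=cfg.aim_r2, window_n=cfg.prune_window)
        pc = aim.PanelConfig(n_runs=cfg.aim_n_runs, n_trees=cfg.aim_n_trees,
                             seed=stage_seed(cfg.seed, "aim"))
        groups = np.array([s.group for s in train.samples])
        panels = aim.select_aim_panels(
            train, y_tr, cand_idx, cand_ids, pc,
            m_mask=np.isin(groups, ["ALG", "M"]),
            c_mask=np.isin(groups, ["ALG", "C"]))
        test_cand = test  # panels are scored on the same variant space
        best, table = aim.select_panel(panels, test_cand,
                                       np.array([s.group == "ALG"
                                                 for s in test.samples]))
        perf = aim.classify(train, test, best.variant_ids, y_tr, y_te,
                            n_runs=cfg.classify_runs,
                            seed=stage_seed(cfg.seed, "aim") + 1,
                            n_trees=cfg.aim_n_trees)
        self._state.update(train=train, test=test, y_tr=y_tr, y_te=y_te,
                           cand_ids=cand_ids, panels=panels, best=best,
                           best_perf=perf)
        paths = {}
        paths["ranking"] = self.out / "aim_ranking.tsv"
        aim.write_ranking_table(panels, paths["ranking"])
        paths["panel"] = self.out / "aim_panel.tsv"
        by_id = {v.id: v for v in train.variants}
        pd.DataFrame([{
            "snp": vid, "chrom": by_id[vid].chrom, "pos": by_id[vid].pos,
            "setting": best.source_setting[vid],
            "rank": best.ranks[vid][1],
        } for vid in best.variant_ids]).to_csv(paths["panel"], sep="\t",
                                               index=False)
        paths["comparison"] = self.out / "panel_comparison.tsv"
        table.to_csv(paths["comparison"], sep="\t", index=False,
                     float_format="%.6g")
        paths["probs"] = self.out / "panel_test_probs.tsv"
        pd.DataFrame({"sample": test.sample_ids, "truth": y_te,
                      "p_alg": perf["p_alg"]}).to_csv(
            paths["probs"], sep="\t", index=False, float_format="%.6g")
        paths["candidates"] = self.out / "aim_candidates.tsv"
        pd.DataFrame({"snp": cand_ids}).to_csv(paths["candidates"], sep="\t",
                                               index=False)
        paths["best"] = self.out / "aim_best.json"
        with open(paths["best"], "w") as fh:
            json.dump({"configuration": best.configuration,
                       "performance": {
                           "accuracy": perf["accuracy"],
                           "min_p_alg": perf["min_p_alg"],
                           "max_p_alg": perf["max_p_alg"]}},
                      fh, indent=2, sort_keys=True)
        self._register("aim", paths)

    def null(self):
        cfg = self.cfg
        st = self._state
        if self.resume and self._cached("null"):
            with open(self.out / "null_percentiles.json") as fh:
                self._state["null_pct"] = json.load(fh)
            return
        null = aim.random_panel_null(
            st["train"], st["test"], st["cand_ids"], st["y_tr"], st["y_te"],
            n_panels=cfg.null_panels, panel_size=min(96, len(st["cand_ids"]) // 2),
            n_runs=cfg.null_runs, seed=stage_seed(cfg.seed, "null"),
            n_trees=cfg.aim_n_trees)
        pct = null.percentile_of(st["best_perf"]["accuracy"],
                                 st["best_perf"]["min_p_alg"],
                                 st["best_perf"]["max_p_alg"])
        self._state["null_pct"] = pct
        p1 = self.out / "null_distribution.tsv"
        pd.DataFrame({"accuracy": null.accuracy, "min_p_alg": null.min_p_alg,
                      "max_p_alg": null.max_p_alg}).to_csv(
            p1, sep="\t", index=False, float_format="%.6g")
        p2 = self.out / "null_percentiles.json"
        with open(p2, "w") as fh:
            json.dump(pct, fh, indent=2, sort_keys=True)
        self._register("null", {"distribution": p1, "percentiles": p2})

    def hybrids(self):
        cfg = self.cfg
        st = self._state
        if self.resume and self._cached("hybrids"):
            n_hyb = hs.CrossPlan(matings_per_cross=cfg.matings_per_cross).n_hybrids
            st["hybrid_report"] = {
                "n_train_merged": st["train"].n_samples + n_hyb // 2,
                "n_test_merged": st["test"].n_samples + n_hyb // 2,
            }
            return
        train, test = st["train"], st["test"]
        seed = stage_seed(cfg.seed, "hybrids")
        pools_alg, pools_eur = {}, {}
        for split, gm in (("train", train), ("test", test)):
            groups = np.array([s.group for s in gm.samples])
            pools_alg[split] = gm.calls[groups == "ALG"]
            for lin in ("M", "C"):
                pools_eur[(lin, split)] = gm.calls[groups == lin]
        plan = hs.CrossPlan(matings_per_cross=cfg.matings_per_cross, seed=seed)
        cohort = hs.make_cohort(pools_alg, pools_eur, train.variants, plan)
        report = hs.hybrid_experiment(
            train, test, st["y_tr"], st["y_te"], cohort,
            st["best"].variant_ids, all_candidate_ids=st["cand_ids"],
            n_runs=cfg.hybrid_runs, seed=seed + 1, n_trees=cfg.aim_n_trees)
        paths = {}
        paths["pedigree"] = self.out / "hybrid_pedigree.tsv"
        cohort.table().to_csv(paths["pedigree"], sep="\t", index=False,
                              float_format="%.6g")
        paths["report"] = self.out / "hybrid_report.tsv"
        frames = []
        for exp in ("A", "B", "C"):
            if exp in report:
                frames.append(report[exp]["per_class"].assign(experiment=exp))
        pd.concat(frames).to_csv(paths["report"], sep="\t", index=False,
                                 float_format="%.6g")
        self._state["hybrid_report"] = report
        self._register("hybrids", paths)

    def _report(self):
        st = self._state
        lines = [
            "aimkit pipeline report",
            "======================",
            f"seed: {self.cfg.seed}",
            f"samples simulated: {st['ds'].genotypes.n_samples}",
            f"variants simulated: {st['ds'].genotypes.n_variants}",
            f"variants after QC: {st['qc'].n_variants}",
            f"families found: {len(st.get('families', []))}",
            f"AIM candidates: {len(st['cand_ids'])}",
            f"selected panel: {st['best'].configuration} "
            f"({len(st['best'].variant_ids)} SNPs)",
            f"panel test accuracy: {st['best_perf']['accuracy']:.3f}",
            f"null percentiles: {st['null_pct']}",
            f"merged hybrid training size: {st['hybrid_report']['n_train_merged']}",
        ]
        with open(self.out / "report.txt", "w") as fh:
            fh.write("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    return PipelineRun(config, resume=resume).run()
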