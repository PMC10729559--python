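"""Genotype containers, minimal VCF / metadata I/O, QC filters and LD pruning.

The central container is :class:`GenotypeMatrix`: a samples x variants matrix
of alternate-allele counts with per-sample ploidy (1 for drones, 2 for
simulated hybrids) and per-variant chromosome/position metadata.  Heterozygous
calls observed in haploid samples are genotyping artifacts; they are recorded
in a per-variant side table (``het_counts``) and stored as missing, so they
act as a site-level QC signal rather than as genotypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1

META_COLUMNS = ["id", "group", "subspecies", "latitude", "longitude", "altitude"]

#: INFO keys carried through when present (upstream variant-caller annotations).
ANNOT_INFO_KEYS = ("SOR", "FS", "MQ", "QD")


@dataclass(frozen=True)
class Variant:
    """A bi-allelic (or allele-count-capped multi-allelic) SNP."""

    chrom: int
    pos: int
    ref: str = "A"
    alt: str = "T"
    id: str = ""
    n_alleles: int = 2

    def key(self):
        return (self.chrom, self.pos)


@dataclass
class SampleMeta:
    id: str
    group: str = ""
    subspecies: str = ""
    latitude: float = math.nan
    longitude: float = math.nan
    altitude: float = math.nan
    call_rate: float = math.nan


@dataclass
class QCThresholds:
    """Site-level QC thresholds.

    ``max_alleles`` is exclusive: sites with >= this many observed alleles are
    removed.  The annotation thresholds mirror common variant-caller filters
    and are applied only when the corresponding annotation is present.
    """

    max_het_frac: float = 0.01
    max_missing: float = 0.05
    max_alleles: int = 4
    maf_min: float = 0.01
    max_sor: float | None = None
    max_fs: float | None = None
    min_mq: float | None = None
    min_qual: float | None = None
    max_qd: float | None = None


class GenotypeMatrix:
    """Samples x variants alternate-allele-count matrix with metadata.

    Parameters
    ----------
    calls : (n_samples, n_variants) int array
        Alternate-allele counts, ``MISSING`` (-1) for no-calls.
    ploidy : (n_samples,) int array
        1 for haploid drones, 2 for diploid (simulated hybrid) samples.
    het_counts : (n_variants,) int array, optional
        Number of heterozygous calls observed in haploid samples per site.
    """

    def __init__(self, samples, variants, calls, ploidy, het_counts=None,
                 qual=None, info=None):
        self.samples = list(samples)
        self.variants = list(variants)
        self.calls = np.asarray(calls, dtype=np.int16)
        self.ploidy = np.asarray(ploidy, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        if self.ploidy.shape != (len(self.samples),):
            raise ValueError("ploidy must be one entry per sample")
        valid = self.calls != MISSING
        if np.any(self.calls[valid] > self.ploidy[:, None].repeat(
                len(self.variants), axis=1)[valid]):
            raise ValueError("allele count exceeds sample ploidy")
        if het_counts is None:
            het_counts = np.zeros(len(self.variants), dtype=np.int64)
        self.het_counts = np.asarray(het_counts, dtype=np.int64)
        self.qual = None if qual is None else np.asarray(qual, dtype=float)
        #: optional {key: (n_variants,) float array} of caller annotations
        self.info = {} if info is None else dict(info)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def dosage(self) -> np.ndarray:
        """Dosage fractions calls/ploidy in [0, 1], NaN where missing.

        This is the feature encoding shared by PCA and the classifiers, so
        haploid (0/1) and diploid (0/0.5/1) samples live on a common scale.
        """
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d / self.ploidy[:, None]

    def call_rates(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.full(self.n_samples, np.nan)
        return (self.calls != MISSING).mean(axis=1)

    def update_call_rates(self) -> None:
        for s, cr in zip(self.samples, self.call_rates()):
            s.call_rate = float(cr)

    # -- subsetting -------------------------------------------------------
    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        info = {k: v[vi] for k, v in self.info.items()}
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            [self.variants[j] for j in vi],
            self.calls[np.ix_(si, vi)],
            self.ploidy[si],
            het_counts=self.het_counts[vi],
            qual=None if self.qual is None else self.qual[vi],
            info=info,
        )

    def variant_index(self, ids) -> np.ndarray:
        lookup = {v: j for j, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"variant {e.args[0]!r} not present in matrix") from None

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and [v.key() for v in self.variants] == [v.key() for v in other.variants]
            and np.array_equal(self.ploidy, other.ploidy)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.het_counts, other.het_counts)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(SampleMeta(
            id=str(row.id), group=str(row.group), subspecies=str(row.subspecies),
            latitude=float(row.latitude), longitude=float(row.longitude),
            altitude=float(row.altitude),
            call_rate=float(getattr(row, "call_rate", math.nan)),
        ))
    return out


def write_sample_meta(samples, path) -> None:
    df = pd.DataFrame([{
        "id": s.id, "group": s.group, "subspecies": s.subspecies,
        "latitude": s.latitude, "longitude": s.longitude,
        "altitude": s.altitude, "call_rate": s.call_rate,
    } for s in samples])
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, meta_path=None, ploidy=None) -> GenotypeMatrix:
    """Read a minimal VCF (v4.2 subset, GT required) into a GenotypeMatrix.

    Per-sample ploidy is the modal GT arity across records unless given
    explicitly via ``ploidy`` ({sample_id: int}).  A diploid-style
    heterozygous call in a haploid sample increments the site's het count and
    is stored as MISSING; a homozygous diploid-style call in a haploid sample
    is accepted as the single allele.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta_by_id = {}
    if meta_path is not None:
        meta_by_id = {m.id: m for m in read_sample_meta(meta_path)}
        absent = [s for s in sample_ids if s not in meta_by_id]
        if absent:
            raise ValueError(f"samples in VCF absent from metadata: {absent}")

    variants, cols, quals = [], [], []
    het_counts = []
    info_cols = {k: [] for k in ANNOT_INFO_KEYS}
    arity = np.zeros((len(sample_ids), 3), dtype=np.int64)  # votes per ploidy
    for rec in vcf:
        gts = rec.genotypes
        if gts is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        alleles_gt = np.full(len(sample_ids), MISSING, dtype=np.int16)
        arities = np.zeros(len(sample_ids), dtype=np.int16)
        for i, g in enumerate(gts):
            a = [x for x in g[:-1]]  # last element is the phased flag
            if len(a) not in (1, 2):
                raise ValueError(
                    f"malformed GT for sample {sample_ids[i]} at "
                    f"{rec.CHROM}:{rec.POS}")
            arities[i] = len(a)
            if all(x < 0 for x in a):
                continue
            if any(x < 0 for x in a):  # half-missing diploid call
                continue
            # allele-count capping for multiallelics: any non-ref counts as alt
            alleles_gt[i] = sum(1 for x in a if x > 0)
            if len(a) == 2:
                arity[i, 2] += 1
            else:
                arity[i, 1] += 1
        try:
            chrom = int(str(rec.CHROM).removeprefix("chr"))
        except ValueError:
            raise ValueError(f"non-integer chromosome name {rec.CHROM!r}")
        alt = rec.ALT or ["."]
        variants.append(Variant(
            chrom=chrom, pos=rec.POS, ref=rec.REF, alt=",".join(alt),
            id=rec.ID or f"{chrom}:{rec.POS}", n_alleles=1 + len(alt)))
        hc = rec.INFO.get("HC")
        het_counts.append(int(hc) if hc is not None else 0)
        quals.append(rec.QUAL if rec.QUAL is not None else np.nan)
        for k in ANNOT_INFO_KEYS:
            v = rec.INFO.get(k)
            info_cols[k].append(float(v) if v is not None else np.nan)
        cols.append((alleles_gt, arities))

    if ploidy is not None:
        pl = np.array([int(ploidy[s]) for s in sample_ids], dtype=np.int16)
    else:
        # modal observed arity; default haploid if no calls at all
        pl = np.where(arity[:, 2] > arity[:, 1], 2, 1).astype(np.int16)

    n_var = len(variants)
    calls = np.full((len(sample_ids), n_var), MISSING, dtype=np.int16)
    het = np.asarray(het_counts, dtype=np.int64)
    for j, (alleles_gt, arities) in enumerate(cols):
        col = alleles_gt.copy()
        # het artifact: diploid-style 'a/b' (a != b -> count 1) in a haploid
        haploid = pl == 1
        artifact = haploid & (arities == 2) & (col == 1)
        het[j] += int(artifact.sum())
        col[artifact] = MISSING
        # 'a/a' in a haploid collapses to the single allele count
        col[haploid & (col == 2)] = 1
        calls[:, j] = col

    order = np.lexsort(([v.pos for v in variants], [v.chrom for v in variants]))
    samples = [meta_by_id.get(s, SampleMeta(id=s)) for s in sample_ids]
    info = {k: np.asarray(v)[order] for k, v in info_cols.items()
            if np.isfinite(v).any()}
    gm = GenotypeMatrix(
        samples, [variants[j] for j in order], calls[:, order], pl,
        het_counts=het[order],
        qual=np.asarray(quals)[order] if np.isfinite(quals).any() else None,
        info=info)
    gm.update_call_rates()
    return gm


def write_genotypes(gm: GenotypeMatrix, path, meta_path=None) -> None:
    """Write a GenotypeMatrix as a plain-text VCF (plus optional metadata TSV).

    Haploid samples get single-allele GTs; the round trip
    ``read_genotypes(write_genotypes(gm))`` is lossless (het counts are
    carried in the HC INFO field).
    """
    chrom_max = {}
    for v in gm.variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=HC,Number=1,Type=Integer,'
                 'Description="Heterozygous calls observed in haploid samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(chrom_max):
            fh.write(f"##contig=<ID={c},length={chrom_max[c] + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, v in enumerate(gm.variants):
            qual = "." if gm.qual is None or not np.isfinite(gm.qual[j]) \
                else f"{gm.qual[j]:g}"
            info_parts = []
            if gm.het_counts[j] > 0:
                info_parts.append(f"HC={gm.het_counts[j]}")
            for k, arr in gm.info.items():
                if np.isfinite(arr[j]):
                    info_parts.append(f"{k}={arr[j]:g}")
            info_str = ";".join(info_parts) or "."
            gts = []
            for i in range(gm.n_samples):
                c = gm.calls[i, j]
                if gm.ploidy[i] == 1:
                    gts.append("." if c == MISSING else str(int(c)))
                else:
                    if c == MISSING:
                        gts.append("./.")
                    else:
                        gts.append(["0/0", "0/1", "1/1"][int(c)])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t"
                     f"{qual}\t.\t{info_str}\tGT\t" + "\t".join(gts) + "\n")
    if meta_path is not None:
        write_sample_meta(gm.samples, meta_path)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def site_qc(gm: GenotypeMatrix, thr: QCThresholds | None = None):
    """Drop sites failing the het-fraction / missingness / allele-number
    filters (and any caller-annotation thresholds whose annotation exists).

    Returns ``(filtered_matrix, report)`` where the report maps filter name
    to the number of sites it flags (a site may be flagged by several).
    """
    thr = thr or QCThresholds()
    n = gm.n_samples
    het_frac = gm.het_counts / n
    miss_frac = (gm.calls == MISSING).mean(axis=0)
    n_alleles = np.array([v.n_alleles for v in gm.variants])

    fails = {
        "het_frac": het_frac > thr.max_het_frac,
        "missing": miss_frac > thr.max_missing,
        "n_alleles": n_alleles >= thr.max_alleles,
    }
    annot_specs = [
        ("SOR", gm.info.get("SOR"), thr.max_sor, "gt"),
        ("FS", gm.info.get("FS"), thr.max_fs, "gt"),
        ("MQ", gm.info.get("MQ"), thr.min_mq, "lt"),
        ("QD", gm.info.get("QD"), thr.max_qd, "gt"),
        ("QUAL", gm.qual, thr.min_qual, "lt"),
    ]
    for name, values, cutoff, sense in annot_specs:
        if cutoff is None:
            continue
        if values is None:
            warnings.warn(f"{name} threshold requested but annotation absent; skipped")
            continue
        with np.errstate(invalid="ignore"):
            bad = values > cutoff if sense == "gt" else values < cutoff
        fails[name] = np.nan_to_num(bad.astype(float)).astype(bool)

    drop = np.zeros(gm.n_variants, dtype=bool)
    report = {}
    for name, mask in fails.items():
        report[name] = int(mask.sum())
        drop |= mask
    report["removed_total"] = int(drop.sum())
    report["retained"] = int((~drop).sum())
    if report["retained"] == 0:
        warnings.warn("site_qc removed every variant")
    out = gm.subset(variant_idx=np.flatnonzero(~drop))
    out.update_call_rates()
    return out, report


def sample_qc(gm: GenotypeMatrix, min_call_rate: float = 0.90) -> GenotypeMatrix:
    """Drop samples whose call rate falls below ``min_call_rate``."""
    keep = np.flatnonzero(gm.call_rates() >= min_call_rate)
    out = gm.subset(sample_idx=keep)
    out.update_call_rates()
    return out


def allele_freq(gm: GenotypeMatrix, sample_subset=None):
    """Per-variant alternate-allele frequency over non-missing calls.

    Frequency = sum(calls) / sum(ploidy) across samples with a call, so
    haploid and diploid samples are weighted by the number of alleles they
    contribute.  Returns ``(freq, undefined)`` where ``undefined`` flags
    variants with no called sample in the subset (freq NaN there).
    """
    if sample_subset is None:
        sub = gm
    else:
        sub = gm.subset(sample_idx=np.asarray(sample_subset))
        if sub.n_samples == 0:
            raise ValueError("empty sample subset")
    called = sub.calls != MISSING
    alt = np.where(called, sub.calls, 0).sum(axis=0).astype(float)
    tot = (called * sub.ploidy[:, None]).sum(axis=0).astype(float)
    undefined = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(undefined, np.nan, alt / np.maximum(tot, 1))
    return freq, undefined


def minor_allele_freq(gm: GenotypeMatrix, sample_subset=None) -> np.ndarray:
    freq, _ = allele_freq(gm, sample_subset)
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _window_r2(dos: np.ndarray) -> np.ndarray:
    """Squared pairwise Pearson correlation of columns, pairwise-complete."""
    if not np.isnan(dos).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(dos, rowvar=False)
    else:
        r = pd.DataFrame(dos).corr(min_periods=2).to_numpy()
    return np.square(r)


def ld_prune(gm: GenotypeMatrix, window_n: int = 1749, overlap_frac: float = 0.10,
             r2_max: float = 0.30, maf_min: float = 0.01, sample_subset=None):
    """PLINK-style windowed LD pruning on dosage fractions.

    Variants with minor-allele frequency below ``maf_min`` are removed first.
    Windows of ``window_n`` SNPs then slide per chromosome, advancing by
    ``ceil(window_n * (1 - overlap_frac))``; within a window, for every pair
    with r^2 > ``r2_max`` the lower-MAF member is dropped (tie: the
    later-position member).  Returns ``(retained_ids, retained_indices)``.
    """
    if window_n < 2:
        raise ValueError("window_n must be >= 2")
    maf = minor_allele_freq(gm, sample_subset)
    with np.errstate(invalid="ignore"):
        cand = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    keep = np.ones(gm.n_variants, dtype=bool)
    keep[:] = False
    keep[cand] = True

    dos_all = gm.dosage()
    if sample_subset is not None:
        dos_all = dos_all[np.asarray(sample_subset)]
    chroms = np.array([v.chrom for v in gm.variants])
    step = math.ceil(window_n * (1.0 - overlap_frac))
    for c in np.unique(chroms[cand]):
        idx = cand[chroms[cand] == c]  # chromosome-local candidates, sorted
        for start in range(0, len(idx), step):
            win = idx[start:start + window_n]
            if len(win) < 2:
                continue
            alive = keep[win].copy()
            r2 = _window_r2(dos_all[:, win])
            nw = len(win)
            for a in range(nw):
                if not alive[a]:
                    continue
                for b in range(a + 1, nw):
                    if not alive[b]:
                        continue
                    v = r2[a, b]
                    if np.isfinite(v) and v > r2_max:
                        if maf[win[a]] < maf[win[b]]:
                            alive[a] = False
                            break
                        alive[b] = False
            keep[win] = alive
            if start + window_n >= len(idx):
                break
    retained = np.flatnonzero(keep)
    return [gm.variants[j].id for j in retained], retained
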