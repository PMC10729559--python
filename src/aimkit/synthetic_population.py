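"""Synthetic genotype datasets with the structure the analyses assume.

Three differentiated source populations stand in for the Algerian population
(ALG) and the European M and C lineages, generated under the Balding-Nichols
drift model: for ancestral frequency p and drift parameter F, a population
frequency is drawn Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and
variance F.p(1-p) -- i.e. F plays the role of Fst to the ancestor.  Within
ALG, two sub-populations (ALG_W, ALG_E) drift mildly from ALG and each ALG
sample is an ancestry mixture whose eastern weight follows a logistic cline
in longitude, emulating the observed West-East structure.  Queen pedigrees
(a diploid queen whose drones are single meiosis gametes) and tract-copying
related pairs provide ground-truth IBD at 50 / 25 / 12.5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MISSING, GenotypeMatrix, SampleMeta, Variant

#: genome layout: 16 chromosomes, uniform 14 Mb each by default (~224 Mb)
DEFAULT_CHROM_LENGTHS = tuple([14_000_000] * 16)

#: per-bp per-generation recombination rate shared with the IBD HMM
DEFAULT_REC_RATE = 9.04e-7


@dataclass
class PopModel:
    """Configuration of the synthetic population generator.

    Sample sizes default to the study layout: 82 ALG + 50 M + 118 C training
    samples and 20 + 13 + 30 test samples (102 ALG, 63 M, 148 C in total).
    """

    n_variants: int = 5000
    chrom_lengths: tuple = DEFAULT_CHROM_LENGTHS
    freq_low: float = 0.05
    freq_high: float = 0.95
    fst_lineage: float = 0.12
    fst_intra_alg: float = 0.02
    cline_steepness: float = 2.0
    n_alg_train: int = 82
    n_m_train: int = 50
    n_c_train: int = 118
    n_alg_test: int = 20
    n_m_test: int = 13
    n_c_test: int = 30
    missing_rate: float = 0.0
    het_artifact_rate: float = 0.0
    #: sibling-drone family sizes appended as extra ALG training samples
    #: (each family is the gametes of one simulated queen)
    family_sizes: tuple = ()
    rec_rate: float = DEFAULT_REC_RATE
    seed: int = 0

    def __post_init__(self):
        for f in (self.fst_lineage, self.fst_intra_alg):
            if not 0.0 <= f < 1.0:
                raise ValueError("Fst parameters must lie in [0, 1)")
        for n in (self.n_alg_train, self.n_m_train, self.n_c_train,
                  self.n_alg_test, self.n_m_test, self.n_c_test):
            if n < 0:
                raise ValueError("sample sizes must be non-negative")
        if not (0 <= self.missing_rate < 1 and 0 <= self.het_artifact_rate < 1):
            raise ValueError("rates must lie in [0, 1)")


@dataclass
class GeoModel:
    """Sampling-site geography for the ALG samples.

    Longitudes span the configured range; the eastern-ancestry weight of a
    sample follows a logistic in longitude centred at the midpoint.  Altitude
    is anti-correlated with latitude (southern, inland sites are higher).
    """

    lon_range: tuple = (-2.0, 8.0)
    lat_range: tuple = (32.0, 37.0)
    alt_mean: float = 600.0
    alt_sd: float = 350.0
    alt_lat_corr: float = -0.6

    def __post_init__(self):
        if not -1.0 < self.alt_lat_corr < 1.0:
            raise ValueError("altitude-latitude correlation must lie in (-1, 1)")


@dataclass
class QueenPedigree:
    """A diploid queen: two founder haplotypes whose gametes are drones."""

    queen_id: str
    hap0: np.ndarray
    hap1: np.ndarray
    drone_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome / variant layout
# ---------------------------------------------------------------------------

def variant_layout(n_variants: int, chrom_lengths, rng) -> list[Variant]:
    """Uniformly scatter ``n_variants`` SNPs over the genome (sorted)."""
    lengths = np.asarray(chrom_lengths, dtype=float)
    counts = rng.multinomial(n_variants, lengths / lengths.sum())
    variants = []
    for c, (n, L) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.choice(int(L) - 1, size=n, replace=False)) + 1
        for p in pos:
            variants.append(Variant(chrom=c, pos=int(p), id=f"snp_{c}_{int(p)}"))
    return variants


def _positions(variants):
    chrom = np.array([v.chrom for v in variants])
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    return chrom, pos


# ---------------------------------------------------------------------------
# allele frequencies (Balding-Nichols)
# ---------------------------------------------------------------------------

def balding_nichols(p: np.ndarray, fst: float, rng) -> np.ndarray:
    """Draw drifted population frequencies for ancestral ``p`` at the given Fst."""
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def draw_freqs(model: PopModel, rng=None) -> dict[str, np.ndarray]:
    """Ancestral + per-population frequencies for the lineage hierarchy.

    Returns a dict with keys ``ancestral, ALG, M, C, ALG_W, ALG_E``; the two
    ALG sub-populations drift from ALG with ``fst_intra_alg``.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    p = rng.uniform(model.freq_low, model.freq_high, size=model.n_variants)
    freqs = {"ancestral": p}
    for pop in ("ALG", "M", "C"):
        freqs[pop] = balding_nichols(p, model.fst_lineage, rng)
    for pop in ("ALG_W", "ALG_E"):
        freqs[pop] = balding_nichols(freqs["ALG"], model.fst_intra_alg, rng)
    return freqs


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson's Fst estimator between two haploid genotype matrices.

    Ratio-of-averages form: mean(p1-p2)^2 minus within-population sampling
    corrections, over mean total heterozygosity.
    """
    n1, n2 = g1.shape[0], g2.shape[0]
    p1 = g1.mean(axis=0)
    p2 = g2.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# haploid genotypes
# ---------------------------------------------------------------------------

def simulate_drone(freqs: np.ndarray, rng) -> np.ndarray:
    """An unrelated haploid genome: independent Bernoulli(p) per site."""
    return (rng.random(freqs.shape[0]) < freqs).astype(np.int16)


def meiosis_gamete(hap0, hap1, variants, rng, rec_rate=DEFAULT_REC_RATE,
                   chrom_lengths=DEFAULT_CHROM_LENGTHS):
    """One recombinant gamete of a diploid: Poisson crossovers, no interference.

    Returns ``(gamete, source)`` where ``source`` is the per-site parental
    haplotype index (0/1).
    """
    chrom, pos = _positions(variants)
    source = np.empty(len(variants), dtype=np.int8)
    for c, L in enumerate(chrom_lengths, start=1):
        mask = chrom == c
        if not mask.any():
            continue
        n_x = rng.poisson(rec_rate * L)
        breaks = np.sort(rng.uniform(0, L, size=n_x))
        start = rng.integers(2)
        # haplotype index flips at each crossover breakpoint
        source[mask] = (start + np.searchsorted(breaks, pos[mask])) % 2
    gamete = np.where(source == 0, hap0, hap1).astype(np.int16)
    return gamete, source


def make_queen(freqs, variants, rng, queen_id="Q0") -> QueenPedigree:
    return QueenPedigree(
        queen_id=queen_id,
        hap0=simulate_drone(freqs, rng),
        hap1=simulate_drone(freqs, rng),
    )


def drone_from_queen(queen: QueenPedigree, variants, rng,
                     rec_rate=DEFAULT_REC_RATE,
                     chrom_lengths=DEFAULT_CHROM_LENGTHS):
    """A drone is a single meiosis gamete of its queen."""
    return meiosis_gamete(queen.hap0, queen.hap1, variants, rng,
                          rec_rate=rec_rate, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# related pairs with known IBD
# ---------------------------------------------------------------------------

def make_related_pair(degree: int, freqs, variants, rng, mode="tract",
                      tract_mean_bp: float = 2_000_000,
                      rec_rate=DEFAULT_REC_RATE,
                      chrom_lengths=DEFAULT_CHROM_LENGTHS):
    """Two haploid genomes sharing a known IBD fraction 2**-degree.

    ``tract`` mode copies exponential-length tracts (mean ``tract_mean_bp``)
    from one independent genome onto another until exactly the target
    fraction of the genome (in bp) is covered, trimming the final tract; the
    returned site mask is exact.  ``pedigree`` mode (degree 1 only) returns
    two meiosis gametes of one queen, whose realised sharing fluctuates
    around 50%.

    Returns ``(g1, g2, ibd_site_mask, ibd_bp_fraction)``.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    chrom, pos = _positions(variants)
    lengths = np.asarray(chrom_lengths, dtype=float)
    genome_len = lengths.sum()

    if mode == "pedigree":
        if degree != 1:
            raise ValueError("pedigree mode supports degree 1 (sibling drones)")
        queen = make_queen(freqs, variants, rng)
        g1, s1 = drone_from_queen(queen, variants, rng, rec_rate, chrom_lengths)
        g2, s2 = drone_from_queen(queen, variants, rng, rec_rate, chrom_lengths)
        mask = s1 == s2
        return g1, g2, mask, float(mask.mean())
    if mode != "tract":
        raise ValueError(f"unknown mode {mode!r}")

    target = genome_len * 2.0 ** (-degree)
    g1 = simulate_drone(freqs, rng)
    g2 = simulate_drone(freqs, rng)
    # per-chromosome covered intervals [start, end)
    covered = {c: [] for c in range(1, len(lengths) + 1)}
    total = 0.0
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    while total < target:
        length = rng.exponential(tract_mean_bp)
        length = min(length, target - total) if total + length > target else length
        gpos = rng.uniform(0, genome_len)
        c = int(np.searchsorted(cum, gpos, side="right"))
        start = gpos - cum[c - 1]
        end = min(start + length, lengths[c - 1])
        # reject overlaps so coverage bookkeeping stays exact
        if any(s < end and start < e for s, e in covered[c]):
            continue
        covered[c].append((start, end))
        total += end - start
    mask = np.zeros(len(variants), dtype=bool)
    for c, ivals in covered.items():
        cmask = chrom == c
        for s, e in ivals:
            mask |= cmask & (pos >= s) & (pos < e)
    g2 = g2.copy()
    g2[mask] = g1[mask]
    return g1, g2, mask, total / genome_len


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def assign_geography(n_samples: int, geo: GeoModel, rng,
                     cline_steepness: float = 2.0):
    """Coordinates plus eastern-ancestry weight for ALG samples.

    Returns a DataFrame with columns ``latitude, longitude, altitude,
    east_weight``.  The eastern weight is logistic in longitude:
    w = 1 / (1 + exp(-s * (lon - mid))).
    """
    lon = rng.uniform(*geo.lon_range, size=n_samples)
    lat = rng.uniform(*geo.lat_range, size=n_samples)
    mid = 0.5 * (geo.lon_range[0] + geo.lon_range[1])
    with np.errstate(over="ignore"):
        w = 1.0 / (1.0 + np.exp(-cline_steepness * (lon - mid)))
    # altitude = correlated Gaussian in standardized latitude
    r = geo.alt_lat_corr
    z_lat = (lat - np.mean(geo.lat_range)) / (np.ptp(geo.lat_range) / math.sqrt(12))
    z = r * z_lat + math.sqrt(1 - r * r) * rng.standard_normal(n_samples)
    alt = np.maximum(0.0, geo.alt_mean + geo.alt_sd * z)
    return pd.DataFrame({
        "latitude": lat, "longitude": lon, "altitude": alt, "east_weight": w,
    })


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A generated cohort plus the truth tables needed to score analyses."""

    genotypes: GenotypeMatrix
    freqs: dict
    truth: pd.DataFrame          # sample_id, group, split, east_weight
    geo: pd.DataFrame

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero((self.truth["split"] == "train").to_numpy())

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero((self.truth["split"] == "test").to_numpy())


def generate_dataset(model: PopModel, geo: GeoModel | None = None) -> SyntheticDataset:
    """Simulate the full cohort: ALG (clinal), M and C haploid samples.

    ALG samples are Bernoulli draws from per-sample mixture frequencies
    w*p_E + (1-w)*p_W; M and C samples draw from their lineage frequencies.
    Missingness and haploid het artifacts are injected at the configured
    rates (an artifact site records a het count and a missing call, matching
    how real drone data present genotyping errors).
    """
    geo = geo or GeoModel()
    rng = np.random.default_rng(model.seed)
    variants = variant_layout(model.n_variants, model.chrom_lengths, rng)
    freqs = draw_freqs(model, rng)

    groups = (
        [("ALG", "train")] * model.n_alg_train + [("M", "train")] * model.n_m_train
        + [("C", "train")] * model.n_c_train + [("ALG", "test")] * model.n_alg_test
        + [("M", "test")] * model.n_m_test + [("C", "test")] * model.n_c_test
    )
    n_alg = model.n_alg_train + model.n_alg_test
    geo_df = assign_geography(n_alg, geo, rng, model.cline_steepness)

    rows, metas = [], []
    calls = np.empty((len(groups), model.n_variants), dtype=np.int16)
    alg_i = 0
    for i, (grp, split) in enumerate(groups):
        if grp == "ALG":
            w = geo_df["east_weight"].iloc[alg_i]
            p = w * freqs["ALG_E"] + (1 - w) * freqs["ALG_W"]
            lat, lon, alt = (geo_df[c].iloc[alg_i]
                             for c in ("latitude", "longitude", "altitude"))
            alg_i += 1
        else:
            p = freqs[grp]
            w = math.nan
            # reference lineages sit outside the ALG sampling area
            lat = 46.0 + rng.normal(0, 1.5)
            lon = (2.0 if grp == "M" else 14.0) + rng.normal(0, 1.5)
            alt = max(0.0, rng.normal(400, 150))
        sid = f"{grp}_{split}_{i:03d}"
        calls[i] = simulate_drone(p, rng)
        metas.append(SampleMeta(id=sid, group=grp,
                                subspecies="intermissa" if grp == "ALG" else grp,
                                latitude=float(lat), longitude=float(lon),
                                altitude=float(alt)))
        rows.append({"sample_id": sid, "group": grp, "split": split,
                     "east_weight": w, "family": ""})

    # sibling-drone families: gametes of one queen, appended as ALG train
    fam_calls = []
    for k, size in enumerate(model.family_sizes):
        w = rng.random()
        p = w * freqs["ALG_E"] + (1 - w) * freqs["ALG_W"]
        queen = make_queen(p, variants, rng, queen_id=f"Q{k}")
        lat = rng.uniform(*geo.lat_range)
        lon = rng.uniform(*geo.lon_range)
        for d in range(size):
            g, _ = drone_from_queen(queen, variants, rng,
                                    rec_rate=model.rec_rate,
                                    chrom_lengths=model.chrom_lengths)
            sid = f"FAM{k}_{d:02d}"
            fam_calls.append(g)
            metas.append(SampleMeta(id=sid, group="ALG",
                                    subspecies="intermissa",
                                    latitude=float(lat), longitude=float(lon),
                                    altitude=500.0))
            rows.append({"sample_id": sid, "group": "ALG", "split": "train",
                         "east_weight": w, "family": f"Q{k}"})
    if fam_calls:
        calls = np.vstack([calls, np.stack(fam_calls)])

    het_counts = np.zeros(model.n_variants, dtype=np.int64)
    if model.het_artifact_rate > 0:
        art = rng.random(calls.shape) < model.het_artifact_rate
        het_counts = art.sum(axis=0).astype(np.int64)
        calls[art] = MISSING
    if model.missing_rate > 0:
        calls[rng.random(calls.shape) < model.missing_rate] = MISSING

    gm = GenotypeMatrix(metas, variants, calls,
                        np.ones(calls.shape[0], dtype=np.int16),
                        het_counts=het_counts)
    gm.update_call_rates()
    truth = pd.DataFrame(rows)
    return SyntheticDataset(genotypes=gm, freqs=freqs, truth=truth, geo=geo_df)


def write_dataset(ds: SyntheticDataset, out_dir) -> dict:
    """Write VCF + metadata TSV + truth tables; returns the path map."""
    import pathlib

    from .core_data import write_genotypes

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "meta": out / "samples.tsv",
        "truth": out / "truth_samples.tsv",
        "freqs": out / "truth_freqs.tsv",
    }
    write_genotypes(ds.genotypes, paths["vcf"], meta_path=paths["meta"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame({
        "variant": ds.genotypes.variant_ids,
        **{k: v for k, v in ds.freqs.items()},
    }).to_csv(paths["freqs"], sep="\t", index=False, float_format="%.6g")
    return paths
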