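"""Pairwise IBD estimation for haploid genomes via a two-state HMM.

The model follows the haploid IBD-segment HMM widely used for malaria
parasites, re-parameterised for the honey bee (16 chromosomes, recombination
rate 9.04e-7 per bp per generation).  For a pair of haploid genotypes the
hidden state at each site is IBD (the two samples descend from a common
ancestral copy) or DBD (distinct by descent).  Writing f for the stationary
IBD fraction and k for the number of generations separating the pair, the
transition probability over an inter-site gap of d bp is

    a_ij(d) = delta_ij * exp(-k*rho*d) + (1 - exp(-k*rho*d)) * pi_j,

with pi = (f, 1-f).  Emissions allow a genotype error rate eps: with
population alt frequency p and e(a|t) = 1-eps if a == t else eps,

    DBD emits m(a1) * m(a2),        m(a) = sum_t p_t e(a|t)
    IBD emits sum_t p_t e(a1|t) e(a2|t).

f and k are estimated by Baum-Welch EM (f <- mean posterior IBD occupancy;
k <- expected state-switch count / (rho * total inter-site gap)), and the
reported kinship statistic f_viterbi is the fraction of informative sites
assigned to the IBD state on the Viterbi path.  Chromosomes are independent:
the chain restarts from pi at every chromosome start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import MISSING, GenotypeMatrix, allele_freq


@dataclass
class HMMConfig:
    nchrom: int = 16
    rec_rate: float = 9.04e-7
    genotype_error: float = 0.001
    max_em_iters: int = 5
    em_tol: float = 1e-3
    k_init: float = 1.0
    f_init: float = 0.5
    subsample_frac: float = 0.05
    min_informative_sites: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.rec_rate <= 0:
            raise ValueError("rec_rate must be positive")
        if not 0.0 <= self.genotype_error < 0.5:
            raise ValueError("genotype_error must lie in [0, 0.5)")
        if not 0.0 <= self.f_init <= 1.0:
            raise ValueError("f_init must lie in [0, 1]")


@dataclass
class PairIBD:
    """Fitted results for one haploid pair."""

    id1: str
    id2: str
    f_viterbi: float
    f_posterior: float
    f_hat: float
    k_hat: float
    segments: list          # (chrom, start_pos, end_pos)
    loglik: float
    n_sites_used: int
    n_em_iters: int
    low_confidence: bool = False

    def summary(self) -> str:
        lines = [
            "Haploid pair IBD (two-state HMM)",
            "=" * 40,
            f"samples            {self.id1} / {self.id2}",
            f"sites used         {self.n_sites_used}",
            f"f (Viterbi)        {self.f_viterbi:.4f}",
            f"f (posterior mean) {self.f_posterior:.4f}",
            f"f (stationary)     {self.f_hat:.4f}",
            f"k (generations)    {self.k_hat:.3f}",
            f"log-likelihood     {self.loglik:.3f}",
            f"IBD segments       {len(self.segments)}",
            f"EM iterations      {self.n_em_iters}",
        ]
        if self.low_confidence:
            lines.append("WARNING: < minimum informative sites; low confidence")
        return "\n".join(lines)


class HaploidPairIBD:
    """Two-state IBD/DBD hidden Markov model for one pair of haploid genomes.

    Parameters
    ----------
    g1, g2 : (n_variants,) int arrays
        Haploid alt-allele calls (0/1, MISSING for no-calls).
    freqs : (n_variants,) float array
        Population alt-allele frequencies of the analysis panel.
    variants : sequence of Variant
        Chromosome/position metadata, sorted by (chrom, pos).
    """

    def __init__(self, g1, g2, freqs, variants, config: HMMConfig | None = None,
                 id1="sample1", id2="sample2"):
        self.config = config or HMMConfig()
        g1 = np.asarray(g1)
        g2 = np.asarray(g2)
        freqs = np.asarray(freqs, dtype=float)
        chrom = np.array([v.chrom for v in variants])
        pos = np.array([v.pos for v in variants], dtype=np.int64)
        used = (g1 != MISSING) & (g2 != MISSING) & np.isfinite(freqs)
        informative = used & (freqs > 0.0) & (freqs < 1.0)
        if not informative.any():
            raise ValueError("no polymorphic informative sites for this pair")
        self.id1, self.id2 = id1, id2
        self._chrom = chrom[used]
        self._pos = pos[used]
        self._g1 = g1[used]
        self._g2 = g2[used]
        self._freqs = freqs[used]
        self.n_sites_used = int(used.sum())
        self._build_emissions()

    def _build_emissions(self):
        eps = self.config.genotype_error
        p = self._freqs
        e_a1_alt = np.where(self._g1 == 1, 1 - eps, eps)
        e_a1_ref = np.where(self._g1 == 0, 1 - eps, eps)
        e_a2_alt = np.where(self._g2 == 1, 1 - eps, eps)
        e_a2_ref = np.where(self._g2 == 0, 1 - eps, eps)
        m1 = p * e_a1_alt + (1 - p) * e_a1_ref
        m2 = p * e_a2_alt + (1 - p) * e_a2_ref
        e_ibd = p * e_a1_alt * e_a2_alt + (1 - p) * e_a1_ref * e_a2_ref
        e_dbd = m1 * m2
        # per-chromosome blocks: (emissions, gaps) as python lists for speed
        self._blocks = []
        for c in np.unique(self._chrom):
            m = self._chrom == c
            bpos = self._pos[m]
            self._blocks.append({
                "chrom": int(c),
                "pos": bpos,
                "e0": e_ibd[m].tolist(),
                "e1": e_dbd[m].tolist(),
                "gaps": np.diff(bpos).astype(float),
            })
        self._total_gap = float(sum(b["gaps"].sum() for b in self._blocks))

    # -- core recursions (scalar python loops: 2 states, fastest in CPython) --
    @staticmethod
    def _fwd_bwd(e0, e1, stay, f):
        """Scaled forward-backward for one chromosome.

        Returns (loglik, gamma_ibd list, expected_switches).
        """
        n = len(e0)
        pi0, pi1 = f, 1.0 - f
        alpha0 = [0.0] * n
        alpha1 = [0.0] * n
        scale = [0.0] * n
        a0 = pi0 * e0[0]
        a1 = pi1 * e1[0]
        c = a0 + a1
        alpha0[0], alpha1[0], scale[0] = a0 / c, a1 / c, c
        for t in range(1, n):
            s = stay[t - 1]
            # alpha is normalized, so sum(alpha) == 1 in the pi term
            a0 = (s * alpha0[t - 1] + (1.0 - s) * pi0) * e0[t]
            a1 = (s * alpha1[t - 1] + (1.0 - s) * pi1) * e1[t]
            c = a0 + a1
            alpha0[t], alpha1[t], scale[t] = a0 / c, a1 / c, c
        loglik = sum(math.log(c) for c in scale)

        b0 = b1 = 1.0
        gamma0 = [0.0] * n
        g = alpha0[n - 1] * b0 / (alpha0[n - 1] * b0 + alpha1[n - 1] * b1)
        gamma0[n - 1] = g
        switches = 0.0
        for t in range(n - 2, -1, -1):
            s = stay[t]
            cn = scale[t + 1]
            eb0 = e0[t + 1] * b0
            eb1 = e1[t + 1] * b1
            mix = pi0 * eb0 + pi1 * eb1
            nb0 = (s * eb0 + (1.0 - s) * mix) / cn
            nb1 = (s * eb1 + (1.0 - s) * mix) / cn
            # pairwise marginals xi(i, j) for the transition t -> t+1
            x00 = alpha0[t] * (s + (1.0 - s) * pi0) * eb0 / cn
            x01 = alpha0[t] * (1.0 - s) * pi1 * eb1 / cn
            x10 = alpha1[t] * (1.0 - s) * pi0 * eb0 / cn
            x11 = alpha1[t] * (s + (1.0 - s) * pi1) * eb1 / cn
            tot = x00 + x01 + x10 + x11
            switches += (x01 + x10) / tot
            b0, b1 = nb0, nb1
            num0 = alpha0[t] * b0
            num1 = alpha1[t] * b1
            gamma0[t] = num0 / (num0 + num1)
        return loglik, gamma0, switches

    @staticmethod
    def _viterbi(e0, e1, stay, f):
        """Most probable state path (log space) for one chromosome."""
        n = len(e0)
        lpi0 = math.log(f) if f > 0 else -math.inf
        lpi1 = math.log(1.0 - f) if f < 1 else -math.inf
        le0 = [math.log(x) for x in e0]
        le1 = [math.log(x) for x in e1]
        v0 = lpi0 + le0[0]
        v1 = lpi1 + le1[0]
        back = [[0, 0] for _ in range(n)]
        for t in range(1, n):
            s = stay[t - 1]
            l00 = math.log(s + (1.0 - s) * f)
            l01 = math.log((1.0 - s) * (1.0 - f)) if s < 1.0 else -math.inf
            l10 = math.log((1.0 - s) * f) if s < 1.0 else -math.inf
            l11 = math.log(s + (1.0 - s) * (1.0 - f))
            c00, c10 = v0 + l00, v1 + l10
            c01, c11 = v0 + l01, v1 + l11
            if c00 >= c10:
                nv0, back[t][0] = c00, 0
            else:
                nv0, back[t][0] = c10, 1
            if c11 >= c01:
                nv1, back[t][1] = c11, 1
            else:
                nv1, back[t][1] = c01, 0
            v0, v1 = nv0 + le0[t], nv1 + le1[t]
        path = [0] * n
        path[n - 1] = 0 if v0 >= v1 else 1
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t][path[t]]
        return path

    def _stay_arrays(self, k):
        krho = k * self.config.rec_rate
        return [np.exp(-krho * b["gaps"]).tolist() for b in self._blocks]

    def loglikelihood(self, f=None, k=None) -> float:
        """Forward log-likelihood at the given (or initial) parameters."""
        f = self.config.f_init if f is None else f
        k = self.config.k_init if k is None else k
        ll = 0.0
        for b, stay in zip(self._blocks, self._stay_arrays(k)):
            ll += self._fwd_bwd(b["e0"], b["e1"], stay, f)[0]
        return ll

    def fit(self) -> PairIBD:
        cfg = self.config
        f, k = cfg.f_init, cfg.k_init
        loglik = math.nan
        n_iter = 0
        for n_iter in range(1, cfg.max_em_iters + 1):
            stays = self._stay_arrays(k)
            loglik = 0.0
            gsum = 0.0
            switches = 0.0
            for b, stay in zip(self._blocks, stays):
                ll, gamma0, sw = self._fwd_bwd(b["e0"], b["e1"], stay, f)
                loglik += ll
                gsum += sum(gamma0)
                switches += sw
            f_new = min(1.0 - 1e-9, max(1e-9, gsum / self.n_sites_used))
            if self._total_gap > 0:
                k_new = switches / (cfg.rec_rate * self._total_gap)
                k_new = min(1e4, max(1e-4, k_new))
            else:
                k_new = k
            converged = abs(f_new - f) < cfg.em_tol and abs(k_new - k) < cfg.em_tol
            f, k = f_new, k_new
            if converged:
                break

        # posterior occupancy and Viterbi path at the fitted parameters
        stays = self._stay_arrays(k)
        loglik = 0.0
        gsum = 0.0
        n_ibd = 0
        segments = []
        for b, stay in zip(self._blocks, stays):
            ll, gamma0, _ = self._fwd_bwd(b["e0"], b["e1"], stay, f)
            loglik += ll
            gsum += sum(gamma0)
            path = self._viterbi(b["e0"], b["e1"], stay, f)
            n_ibd += path.count(0)
            start = None
            for t, st in enumerate(path):
                if st == 0 and start is None:
                    start = t
                elif st != 0 and start is not None:
                    segments.append((b["chrom"], int(b["pos"][start]),
                                     int(b["pos"][t - 1])))
                    start = None
            if start is not None:
                segments.append((b["chrom"], int(b["pos"][start]),
                                 int(b["pos"][-1])))
        return PairIBD(
            id1=self.id1, id2=self.id2,
            f_viterbi=n_ibd / self.n_sites_used,
            f_posterior=gsum / self.n_sites_used,
            f_hat=f, k_hat=k,
            segments=segments, loglik=loglik,
            n_sites_used=self.n_sites_used, n_em_iters=n_iter,
            low_confidence=self.n_sites_used < cfg.min_informative_sites,
        )


def pair_ibd(g1, g2, freqs, variants, config: HMMConfig | None = None,
             id1="sample1", id2="sample2") -> PairIBD:
    """Fit the pairwise IBD HMM; functional wrapper around HaploidPairIBD."""
    return HaploidPairIBD(g1, g2, freqs, variants, config, id1, id2).fit()


@dataclass
class KinshipMatrix:
    ids: list
    values: np.ndarray            # symmetric, diagonal 1
    pairs: list = field(default_factory=list)   # PairIBD per (i, j), i < j

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def kinship_matrix(gm: GenotypeMatrix, config: HMMConfig | None = None,
                   progress: bool = False) -> KinshipMatrix:
    """All-pairs f_viterbi on a seeded random subsample of polymorphic sites."""
    cfg = config or HMMConfig()
    if np.any(gm.ploidy != 1):
        raise ValueError("kinship_matrix requires haploid samples")
    freqs, _ = allele_freq(gm)
    poly = np.flatnonzero(np.nan_to_num(freqs) * (1 - np.nan_to_num(freqs)) > 0)
    rng = np.random.default_rng(cfg.seed)
    n_sub = max(2, int(round(cfg.subsample_frac * len(poly))))
    sub = np.sort(rng.choice(poly, size=min(n_sub, len(poly)), replace=False))
    variants = [gm.variants[j] for j in sub]
    calls = gm.calls[:, sub]
    f_sub = freqs[sub]

    n = gm.n_samples
    K = np.eye(n)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            res = pair_ibd(calls[i], calls[j], f_sub, variants, cfg,
                           id1=gm.samples[i].id, id2=gm.samples[j].id)
            K[i, j] = K[j, i] = res.f_viterbi
            pairs.append(res)
    return KinshipMatrix(ids=gm.sample_ids, values=K, pairs=pairs)


def family_components(K: KinshipMatrix, threshold: float = 0.30,
                      call_rates: dict | None = None):
    """Connected components of the kinship graph above ``threshold``.

    Components of size >= 2 are putative full-sib families; within each, the
    sample with the best call rate is retained (ties: lexicographically first
    id).  Returns ``(families, retained_ids)`` with families as sorted id
    lists and singletons always retained.
    """
    call_rates = call_rates or {}
    g = nx.Graph()
    g.add_nodes_from(K.ids)
    n = len(K.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if K.values[i, j] > threshold:
                g.add_edge(K.ids[i], K.ids[j])
    families, retained = [], []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            retained.append(members[0])
            continue
        families.append(members)
        best = min(members, key=lambda s: (-call_rates.get(s, 0.0), s))
        retained.append(best)
    return families, sorted(retained)


def close_kin(K: KinshipMatrix, cutoff: float = 0.10, meta=None,
              labels: dict | None = None) -> pd.DataFrame:
    """All pairs with kinship above ``cutoff``, with great-circle distances.

    ``meta`` maps sample id -> SampleMeta (for coordinates); ``labels`` maps
    sample id -> cluster label.  Distance is NaN when either coordinate is
    missing; the pair is still listed.
    """
    from .structure_geo import haversine_km

    meta = meta or {}
    labels = labels or {}
    rows = []
    n = len(K.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if K.values[i, j] <= cutoff:
                continue
            s1, s2 = K.ids[i], K.ids[j]
            dist = math.nan
            m1, m2 = meta.get(s1), meta.get(s2)
            if m1 is not None and m2 is not None and all(
                    math.isfinite(x) for x in
                    (m1.latitude, m1.longitude, m2.latitude, m2.longitude)):
                dist = haversine_km(m1.latitude, m1.longitude,
                                    m2.latitude, m2.longitude)
            rows.append({
                "sample1": s1, "sample2": s2,
                "kinship": K.values[i, j],
                "distance_km": dist,
                "cluster1": labels.get(s1, ""),
                "cluster2": labels.get(s2, ""),
            })
    return pd.DataFrame(rows, columns=["sample1", "sample2", "kinship",
                                       "distance_km", "cluster1", "cluster2"])


def write_pair_table(pairs, path) -> None:
    """Stable TSV: sample1, sample2, n_sites, k_hat, f_viterbi, f_posterior."""
    pd.DataFrame([{
        "sample1": p.id1, "sample2": p.id2, "n_sites": p.n_sites_used,
        "k_hat": p.k_hat, "f_viterbi": p.f_viterbi, "f_posterior": p.f_posterior,
    } for p in pairs]).to_csv(path, sep="\t", index=False)


def write_segment_table(pairs, path) -> None:
    rows = []
    for p in pairs:
        for chrom, start, end in p.segments:
            rows.append({"sample1": p.id1, "sample2": p.id2,
                         "chrom": chrom, "start": start, "end": end})
    pd.DataFrame(rows, columns=["sample1", "sample2", "chrom", "start", "end"]
                 ).to_csv(path, sep="\t", index=False)
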