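"""Population structure and geography: PCA, genetic/geographic distances,
correlation tables, and a PC1-based two-cluster assignment.

PCA uses the standard population-genetics normalization: dosage fractions
are centred by their column mean and scaled by sqrt(p(1-p)) with p the
observed alt frequency, missing values mean-imputed, followed by an SVD.
Genetic distance between samples is the Euclidean distance on the top two
PCs with the PC1 coordinate difference weighted by the eigenvalue ratio
lambda1/lambda2; geographic distance is the great-circle (haversine)
distance on a sphere of radius 6371 km.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core_data import GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


@dataclass
class PCAResult:
    scores: np.ndarray        # samples x n_pc
    eigenvalues: np.ndarray   # non-increasing
    pct_variance: np.ndarray  # percent of total variance per PC
    sample_ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca(gm: GenotypeMatrix, n_pc: int = 10) -> PCAResult:
    """Frequency-normalized PCA of the genotype matrix."""
    if gm.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    n_pc = min(n_pc, gm.n_samples - 1, gm.n_variants)
    dos = gm.dosage()
    mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), mean, dos)  # mean-impute missing
    var = mean * (1.0 - mean)
    keep = var > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variants")
    x = (dos[:, keep] - mean[keep]) / np.sqrt(var[keep])
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s ** 2 / (gm.n_samples - 1)
    total = eig.sum()
    scores = u[:, :n_pc] * s[:n_pc]
    return PCAResult(
        scores=scores,
        eigenvalues=eig[:n_pc],
        pct_variance=100.0 * eig[:n_pc] / total,
        sample_ids=gm.sample_ids,
    )


def pc_distance(res: PCAResult, weight_on="coordinate") -> np.ndarray:
    """Pairwise eigenvalue-weighted Euclidean distance on the top two PCs.

    d_ij = sqrt((w * dPC1)^2 + dPC2^2) with w = lambda1/lambda2.  With
    ``weight_on="squared"`` the weight multiplies the squared difference
    instead: d_ij = sqrt(w * dPC1^2 + dPC2^2).
    """
    if res.scores.shape[1] < 2:
        raise ValueError("pc_distance needs at least two PCs")
    l1, l2 = res.eigenvalues[0], res.eigenvalues[1]
    if l2 == 0:
        raise ValueError("second eigenvalue is zero")
    w = l1 / l2
    d1 = res.scores[:, 0][:, None] - res.scores[:, 0][None, :]
    d2 = res.scores[:, 1][:, None] - res.scores[:, 1][None, :]
    if weight_on == "coordinate":
        return np.sqrt((w * d1) ** 2 + d2 ** 2)
    if weight_on == "squared":
        return np.sqrt(w * d1 ** 2 + d2 ** 2)
    raise ValueError("weight_on must be 'coordinate' or 'squared'")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km) on a sphere of radius 6371 km."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"invalid coordinate ({lat}, {lon})")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geo_distance_matrix(lats, lons) -> np.ndarray:
    n = len(lats)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = haversine_km(lats[i], lons[i], lats[j], lons[j])
    return d


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def corr_pc_coords(res: PCAResult, samples, n_pc: int = 7) -> pd.DataFrame:
    """Pearson correlations of the top PCs vs latitude/longitude/altitude.

    One row per (PC, coordinate); two-sided p-values from the t transform
    with n-2 degrees of freedom, significance stars at 5/1/0.1%.
    """
    coords = {
        "latitude": np.array([s.latitude for s in samples]),
        "longitude": np.array([s.longitude for s in samples]),
        "altitude": np.array([s.altitude for s in samples]),
    }
    ok = np.isfinite(coords["latitude"]) & np.isfinite(coords["longitude"])
    if ok.sum() < 3:
        raise ValueError("need >= 3 samples with coordinates")
    n_pc = min(n_pc, res.scores.shape[1])
    rows = []
    for i in range(n_pc):
        for name, vals in coords.items():
            m = ok & np.isfinite(vals)
            r, p = stats.pearsonr(res.scores[m, i], vals[m])
            rows.append({"pc": i + 1, "coordinate": name, "n": int(m.sum()),
                         "r": r, "r2": r * r, "p": p, "sig": _stars(p)})
    return pd.DataFrame(rows)


def pair_mask(labels, kind: str) -> np.ndarray:
    """Boolean mask over the condensed upper-triangle pair ordering.

    ``kind``: 'all', 'within-W', 'within-E' or 'between' for W/E labels.
    """
    labels = np.asarray(labels)
    n = len(labels)
    out = []
    for i, j in itertools.combinations(range(n), 2):
        if kind == "all":
            out.append(True)
        elif kind == "within-W":
            out.append(labels[i] == "W" and labels[j] == "W")
        elif kind == "within-E":
            out.append(labels[i] == "E" and labels[j] == "E")
        elif kind == "between":
            out.append(labels[i] != labels[j])
        else:
            raise ValueError(f"unknown pair group {kind!r}")
    return np.array(out, dtype=bool)


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def corr_dist(gen_d: np.ndarray, geo_d: np.ndarray, labels=None,
              groups=("all", "within-W", "within-E", "between")) -> pd.DataFrame:
    """Pearson correlation of genetic vs geographic pairwise distances.

    ``gen_d`` may equally be a kinship matrix (correlations then come out
    negative under isolation by distance).  Pair groups are defined by the
    W/E cluster labels; 'all' uses every pair (n*(n-1)/2).
    """
    gv = _condensed(np.asarray(gen_d))
    dv = _condensed(np.asarray(geo_d))
    rows = []
    for kind in groups:
        if kind != "all" and labels is None:
            continue
        m = pair_mask(labels if labels is not None else [""] * gen_d.shape[0],
                      "all" if kind == "all" else kind)
        if m.sum() < 3:
            warnings.warn(f"pair group {kind!r} has < 3 pairs; skipped")
            continue
        r, p = stats.pearsonr(gv[m], dv[m])
        rows.append({"group": kind, "n": int(m.sum()),
                     "r": r, "r2": r * r, "p": p, "sig": _stars(p)})
    return pd.DataFrame(rows)


def cluster2(res: PCAResult, samples=None, seed: int = 0,
             n_restarts: int = 50) -> np.ndarray:
    """Two-cluster W/E assignment from PC1 (k-means, best of 50 restarts).

    The cluster whose samples have the lower mean longitude is labelled W;
    without coordinates, the lower-mean-PC1 cluster is W.
    """
    x = res.scores[:, [0]]
    if np.ptp(x) == 0:
        raise ValueError("PC1 is degenerate (zero spread)")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(x)
    lab = km.labels_
    if samples is not None:
        lons = np.array([s.longitude for s in samples])
        mean0 = np.nanmean(lons[lab == 0])
        mean1 = np.nanmean(lons[lab == 1])
        west_cluster = 0 if mean0 <= mean1 else 1
    else:
        west_cluster = 0 if x[lab == 0].mean() <= x[lab == 1].mean() else 1
    return np.where(lab == west_cluster, "W", "E")
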