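"""Linkage disequilibrium and population structure.

LD is measured as the squared Pearson correlation of alternate-allele
dosages (genotype r², usable on unphased data).  The decay curve averages r²
in seven inter-variant distance classes (0–0.2, 0.2–1, 1–2, 2–10, 10–30,
30–60, 60–120 kb) and the crossing distance of a level is read off by linear
interpolation between consecutive bin mean distances.  Pruning slides
non-overlapping 50-marker windows and removes the later-positioned marker of
every pair with r² above 0.95.  PCA centers dosages per site and scales by
√(p(1−p)) before an SVD of the sample matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

#: The seven distance classes, in kb.
DEFAULT_BINS_KB = (0.0, 0.2, 1.0, 2.0, 10.0, 30.0, 60.0, 120.0)

PRUNE_WINDOW = 50
PRUNE_R2 = 0.95

NOT_REACHED = float("nan")  # sentinel returned when a level is never crossed


@dataclass
class LdDecayCurve:
    bin_edges_kb: tuple[float, ...]
    mean_r2: np.ndarray  # per bin, NaN for empty bins
    mean_dist_kb: np.ndarray  # mean pair distance per bin
    pair_count: np.ndarray
    maf_filter: float | None


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_components)
    variance_fraction: np.ndarray
    n_markers: int


def _biallelic_snp_like(matrix: GenotypeMatrix) -> np.ndarray:
    # biallelic variants (SNPs and indels alike enter LD per the estimator)
    return np.ones(matrix.n_sites, dtype=bool)


def _site_maf(matrix: GenotypeMatrix) -> np.ndarray:
    d = matrix.dosage
    called = (d >= 0).sum(axis=0) * 2.0
    alt = d.sum(axis=0, where=d >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1.0), np.nan)
    return np.minimum(p, 1 - p)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Dosage r² over samples with both genotypes called; NaN if degenerate."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def pairwise_r2(
    matrix: GenotypeMatrix,
    segment: tuple[str, int, int] | None = None,
    max_dist_bp: int | None = 120_000,
    min_maf: float | None = None,
) -> pd.DataFrame:
    """All-pairs dosage r² within a (chrom, start, end) segment.

    Sites monomorphic among the called samples are skipped; an optional MAF
    filter removes sites with MAF < ``min_maf`` before pairing.  Pairs
    farther apart than ``max_dist_bp`` are omitted (None = keep all).
    Returns a DataFrame with columns pos1, pos2, dist_bp, r2.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    keep = _biallelic_snp_like(matrix)
    if segment is not None:
        chrom, start, end = segment
        keep &= (chroms == chrom) & (pos >= start) & (pos <= end)
    if min_maf is not None:
        maf = _site_maf(matrix)
        keep &= ~np.isnan(maf) & (maf >= min_maf)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        import warnings

        warnings.warn("segment has < 2 usable sites; empty LD result")
        return pd.DataFrame(columns=["pos1", "pos2", "dist_bp", "r2"])
    d = matrix.dosage[:, idx]
    p = pos[idx]
    order = np.argsort(p, kind="stable")
    d, p = d[:, order], p[order]
    m = d.shape[1]

    no_missing = (d >= 0).all()
    corr = None
    if no_missing and m <= 4000:
        dd = d.astype(float)
        sd = dd.std(axis=0)
        ok = sd > 0
        corr = np.full((m, m), np.nan)
        if ok.sum() >= 2:
            c = np.corrcoef(dd[:, ok], rowvar=False)
            corr[np.ix_(ok, ok)] = c
    rows = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            dist = int(p[j] - p[i])
            if max_dist_bp is not None and dist > max_dist_bp:
                break
            r2 = corr[i, j] ** 2 if corr is not None else _pair_r2(d[:, i], d[:, j])
            if np.isnan(r2):
                continue
            rows.append((int(p[i]), int(p[j]), dist, float(r2)))
    return pd.DataFrame(rows, columns=["pos1", "pos2", "dist_bp", "r2"])


def ld_decay(
    pairs: pd.DataFrame,
    bins_kb: tuple[float, ...] = DEFAULT_BINS_KB,
    maf_filter: float | None = None,
) -> LdDecayCurve:
    """Bin pair r² by inter-variant distance and average per class."""
    nb = len(bins_kb) - 1
    mean_r2 = np.full(nb, np.nan)
    mean_dist = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    if len(pairs):
        dist_kb = pairs["dist_bp"].to_numpy() / 1000.0
        r2 = pairs["r2"].to_numpy()
        which = np.digitize(dist_kb, bins_kb) - 1
        for b in range(nb):
            sel = which == b
            counts[b] = int(sel.sum())
            if counts[b]:
                mean_r2[b] = float(r2[sel].mean())
                mean_dist[b] = float(dist_kb[sel].mean())
    return LdDecayCurve(tuple(bins_kb), mean_r2, mean_dist, counts, maf_filter)


def decay_distance(curve: LdDecayCurve, level: float) -> float:
    """Distance (kb) at which the binned mean r² first drops below ``level``,
    linearly interpolated between consecutive bin mean distances.

    Returns the first bin's mean distance when the curve starts below the
    level already, and the NaN sentinel when the level is never crossed.
    """
    valid = ~np.isnan(curve.mean_r2)
    r2 = curve.mean_r2[valid]
    dist = curve.mean_dist_kb[valid]
    if r2.size == 0:
        return NOT_REACHED
    if r2[0] < level:
        return float(dist[0])
    for i in range(1, r2.size):
        if r2[i] < level:
            t = (r2[i - 1] - level) / (r2[i - 1] - r2[i])
            return float(dist[i - 1] + t * (dist[i] - dist[i - 1]))
    return NOT_REACHED


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = PRUNE_WINDOW,
    r2_threshold: float = PRUNE_R2,
) -> np.ndarray:
    """Indices of retained markers after windowed pruning.

    Non-overlapping ``window``-marker blocks per chromosome, in position
    order; within a block, each pair with r² > threshold drops the
    later-positioned marker.  Deterministic for a given input order.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    retained: list[int] = []
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        cidx = cidx[np.argsort(pos[cidx], kind="stable")]
        for start in range(0, cidx.size, window):
            block = cidx[start : start + window]
            d = matrix.dosage[:, block]
            alive = np.ones(block.size, dtype=bool)
            for i in range(block.size - 1):
                if not alive[i]:
                    continue
                for j in range(i + 1, block.size):
                    if not alive[j]:
                        continue
                    r2 = _pair_r2(d[:, i], d[:, j])
                    if not np.isnan(r2) and r2 > r2_threshold:
                        alive[j] = False
            retained.extend(block[alive].tolist())
    return np.array(sorted(retained), dtype=int)


def pca(
    matrix: GenotypeMatrix,
    marker_idx: np.ndarray | None = None,
    n_components: int = 10,
) -> PcaResult:
    """PCA of the dosage matrix with per-site centering and √(p(1−p)) scaling.

    Missing dosages are imputed with the site mean; sites fixed in the sample
    are dropped.  Components are ordered by decreasing explained variance.
    """
    d = matrix.dosage.astype(float)
    if marker_idx is not None:
        d = d[:, marker_idx]
    d[d < 0] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    ok = (p > 0) & (p < 1)
    d, p, mean = d[:, ok], p[ok], mean[ok]
    x = (d - mean[None, :]) / np.sqrt(p * (1 - p))[None, :]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    var = s**2
    return PcaResult(
        scores=u[:, :k] * s[None, :k],
        variance_fraction=var[:k] / var.sum(),
        n_markers=int(d.shape[1]),
    )
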