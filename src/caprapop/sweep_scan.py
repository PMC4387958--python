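"""Cross-population composite-likelihood (XP-CLR) selective-sweep scan.

The scan evaluates, at grid points spaced 2500 bp apart, a composite
likelihood ratio contrasting two models of the test population's allele
frequency ``p1`` around the reference population's frequency ``p2``:

* neutral drift — ``p1`` follows a truncated normal on [0, 1] centered on
  ``p2`` with variance ``ω·p2(1−p2)`` plus binomial sampling noise;
* hitchhiking — each lineage escapes a sweep of strength ``s`` at map
  distance ``d`` with probability ``c(d, s) = 1 − exp(−d/s)`` (d in
  Morgans); unescaped lineages carry the beneficial haplotype's allele, so
  the frequency distribution becomes a two-component mixture pushed toward
  0 or 1 with its drift variance shrunk by ``c²``.

Each grid point uses at most 250 variants inside a 0.5 cM window, with
variants that are highly correlated in the reference group (r² > 0.95,
single-linkage clusters) down-weighted by cluster size.  Chromosomes are
scanned in overlapping segments of at most 27 cM (2 cM overlap) and the
scores in the extreme 1 cM of each overlapped edge are discarded before
assembly, so kept spans tile the chromosome exactly.  Physical positions
convert to map positions at 1 cM per Mb.  The top 0.1% of grid scores
defines candidate regions, which are intersected with gene intervals
extended by 1500 bp flanks on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_formats import GeneInterval, GenotypeMatrix


@dataclass
class XpclrConfig:
    grid_spacing_bp: int = 2500
    window_radius_cm: float = 0.25  # 0.5 cM total window
    max_snps_per_window: int = 250
    downweight_r2: float = 0.95
    segment_max_cm: float = 27.0
    segment_overlap_cm: float = 2.0
    trim_cm: float = 1.0
    map_rate_cm_per_mb: float = 1.0
    omega: float | None = None  # drift scale; estimated genome-wide when None
    s_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4.0, -0.5, 36)  # 10 points/decade
    )
    top_fraction: float = 0.001
    gene_flank_bp: int = 1500

    def __post_init__(self) -> None:
        if self.grid_spacing_bp <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.segment_overlap_cm >= self.segment_max_cm:
            raise ValueError("segment overlap must be smaller than the cap")


@dataclass
class Segment:
    index: int
    start_cm: float
    end_cm: float
    keep_start_cm: float
    keep_end_cm: float


@dataclass
class SweepRegion:
    region_id: int
    chrom: str
    start_bp: int
    end_bp: int
    peak_score: float
    peak_bp: int
    n_grid_points: int


@dataclass
class GeneHit:
    gene_id: str
    region_id: int
    overlap_bp: int


class DegenerateScoresError(ValueError):
    """All grid scores tie; a top-quantile threshold is meaningless."""


def physical_to_map(bp: float | np.ndarray, rate_cm_per_mb: float = 1.0):
    """Map position in cM from physical position, default 1 cM ≈ 1 Mb."""
    return np.asarray(bp, dtype=float) * rate_cm_per_mb / 1e6 if np.ndim(bp) \
        else float(bp) * rate_cm_per_mb / 1e6


def make_segments(length_cm: float, config: XpclrConfig | None = None
                  ) -> list[Segment]:
    """Overlapping ≤27 cM segments stepping by 25 cM, with kept spans.

    Interior kept-span boundaries sit at the midpoint of each overlap —
    1 cM trimmed from each side when the overlap is the standard 2 cM —
    while chromosome start and end are never trimmed, so kept spans tile
    [0, length] exactly.  A chromosome shorter than one segment yields a
    single untrimmed segment.
    """
    cfg = config or XpclrConfig()
    step = cfg.segment_max_cm - cfg.segment_overlap_cm
    starts = []
    s = 0.0
    while s < length_cm or not starts:
        starts.append(s)
        s += step
    segs = [
        Segment(i, st, min(st + cfg.segment_max_cm, length_cm), st, st)
        for i, st in enumerate(starts)
    ]
    for i, seg in enumerate(segs):
        seg.keep_start_cm = 0.0 if i == 0 else (segs[i - 1].end_cm + seg.start_cm) / 2.0
        seg.keep_end_cm = (
            length_cm
            if i == len(segs) - 1
            else (seg.end_cm + segs[i + 1].start_cm) / 2.0
        )
    return segs


def _correlation_clusters(ref_dosage: np.ndarray, r2_threshold: float
                          ) -> np.ndarray:
    """Single-linkage cluster sizes from reference-group dosage r².

    ``ref_dosage`` is (samples, snps); returns ``k_i`` per SNP, the size of
    its cluster among pairs with r² > threshold.
    """
    m = ref_dosage.shape[1]
    if m == 0:
        return np.zeros(0)
    d = ref_dosage.astype(float)
    sd = d.std(axis=0)
    ok = sd > 0
    parent = np.arange(m)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if ok.sum() >= 2:
        c = np.corrcoef(d[:, ok], rowvar=False) ** 2
        oki = np.flatnonzero(ok)
        ii, jj = np.nonzero(np.triu(c > r2_threshold, k=1))
        for a, b in zip(oki[ii], oki[jj]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(m)])
    _, inv, counts = np.unique(roots, return_inverse=True, return_counts=True)
    return counts[inv].astype(float)


def select_window_snps(
    site_cm: np.ndarray,
    grid_cm: float,
    ref_dosage: np.ndarray,
    config: XpclrConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """SNP indices within ±window_radius of the grid point, thinned evenly to
    the cap, with weights 1/k from reference-group correlation clusters."""
    inside = np.flatnonzero(np.abs(site_cm - grid_cm) <= config.window_radius_cm)
    if inside.size > config.max_snps_per_window:
        take = np.unique(
            np.round(
                np.linspace(0, inside.size - 1, config.max_snps_per_window)
            ).astype(int)
        )
        inside = inside[take]
    k = _correlation_clusters(ref_dosage[:, inside], config.downweight_r2)
    weights = 1.0 / k if k.size else k
    return inside, weights


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_truncnorm(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log density of a normal truncated/renormalized to [0, 1]."""
    sd = np.sqrt(var)
    z = ndtr((1.0 - mu) / sd) - ndtr((0.0 - mu) / sd)
    z = np.maximum(z, 1e-300)
    u = (x - mu) / sd
    return -0.5 * u * u - np.log(sd) - _LOG_SQRT_2PI - np.log(z)


def estimate_omega(
    p1: np.ndarray, p2: np.ndarray, n1_chr: int, n2_chr: int, thin: int = 10
) -> float:
    """Method-of-moments drift scale from genome-wide frequency divergence.

    Averages ``(p1−p2)²/(p2(1−p2))`` on a thinned SNP set after subtracting
    the binomial sampling variances of both sample frequencies.
    """
    p1t, p2t = p1[::thin], p2[::thin]
    ok = (p2t > 0.02) & (p2t < 0.98)
    p1t, p2t = p1t[ok], p2t[ok]
    if p1t.size < 10:
        raise ValueError("too few SNPs to estimate omega")
    v = p2t * (1 - p2t)
    num = (p1t - p2t) ** 2 - p1t * (1 - p1t) / n1_chr - p2t * (1 - p2t) / n2_chr
    return float(np.clip(np.mean(num / v), 1e-4, 10.0))


def xpclr_score(
    p1: np.ndarray,
    p2: np.ndarray,
    dist_cm: np.ndarray,
    weights: np.ndarray,
    omega: float,
    n1_chr: int,
    config: XpclrConfig | None = None,
) -> tuple[float, float]:
    """Composite log-likelihood-ratio score at one grid point.

    Returns ``(score, s_hat)``: twice the maximum over the selection-strength
    grid of the weighted sum of per-SNP log ratios, floored at zero, and the
    maximizing ``s``.
    """
    cfg = config or XpclrConfig()
    if p1.size == 0:
        return float("nan"), float("nan")
    p2c = np.clip(p2, 0.0, 1.0)
    v_drift = omega * p2c * (1 - p2c)
    v_samp = np.maximum(p2c * (1 - p2c), 0.01) / n1_chr
    ln_neutral = _log_truncnorm(p1, p2c, v_drift + v_samp)

    d_m = np.asarray(dist_cm, dtype=float)[None, :] / 100.0  # Morgans
    s = np.asarray(cfg.s_grid, dtype=float)[:, None]
    c = np.clip(1.0 - np.exp(-d_m / s), 1e-12, 1.0)  # escape probability
    var_s = c**2 * v_drift[None, :] + v_samp[None, :]
    mu_hi = 1.0 - c * (1.0 - p2c[None, :])  # beneficial hap carries the alt
    mu_lo = c * p2c[None, :]
    f_hi = _log_truncnorm(p1[None, :], mu_hi, var_s)
    f_lo = _log_truncnorm(p1[None, :], mu_lo, var_s)
    mx = np.maximum(f_hi, f_lo)
    ln_sweep = mx + np.log(
        p2c[None, :] * np.exp(f_hi - mx)
        + (1 - p2c[None, :]) * np.exp(f_lo - mx)
    )
    totals = (weights[None, :] * (ln_sweep - ln_neutral[None, :])).sum(axis=1)
    k = int(np.argmax(totals))
    return max(0.0, 2.0 * float(totals[k])), float(cfg.s_grid[k])


def _pop_freqs(matrix: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    sub = matrix.dosage[idx]
    called = (sub >= 0).sum(axis=0) * 2.0
    alt = sub.sum(axis=0, where=sub >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, alt / np.maximum(called, 1.0), np.nan)


def scan_chromosome(
    matrix: GenotypeMatrix,
    pop_map: dict[str, str],
    test_pop: str,
    chrom: str,
    chrom_length_bp: int | None = None,
    config: XpclrConfig | None = None,
) -> pd.DataFrame:
    """XP-CLR scores along one chromosome, segment by segment, assembled.

    The reference group pools all samples outside the test population.
    Returns the assembled ScanTrack as a DataFrame (chrom, bp, cm, score,
    s_hat, n_snps, segment).
    """
    cfg = config or XpclrConfig()
    test_idx = np.array(
        [i for i, s in enumerate(matrix.samples) if pop_map[s] == test_pop]
    )
    ref_idx = np.array(
        [i for i, s in enumerate(matrix.samples) if pop_map[s] != test_pop]
    )
    if test_idx.size == 0 or ref_idx.size == 0:
        raise ValueError("both test and reference groups must be non-empty")
    on_chrom = np.flatnonzero(matrix.sites["chrom"].to_numpy() == chrom)
    if on_chrom.size == 0:
        raise ValueError(f"no sites on chromosome {chrom}")
    sub = matrix.subset_sites(on_chrom)
    pos = sub.sites["pos"].to_numpy()
    if chrom_length_bp is None:
        chrom_length_bp = int(pos.max()) + cfg.grid_spacing_bp
    site_cm = pos * cfg.map_rate_cm_per_mb / 1e6
    length_cm = chrom_length_bp * cfg.map_rate_cm_per_mb / 1e6

    p1 = _pop_freqs(sub, test_idx)
    p2 = _pop_freqs(sub, ref_idx)
    usable = ~np.isnan(p1) & ~np.isnan(p2)
    n1_chr = 2 * test_idx.size
    n2_chr = 2 * ref_idx.size
    omega = cfg.omega
    if omega is None:
        omega = estimate_omega(p1[usable], p2[usable], n1_chr, n2_chr)
    ref_dosage = sub.dosage[ref_idx]

    grid_bp = np.arange(
        cfg.grid_spacing_bp, chrom_length_bp + 1, cfg.grid_spacing_bp
    )
    grid_cm = grid_bp * cfg.map_rate_cm_per_mb / 1e6
    rows = []
    for seg in make_segments(length_cm, cfg):
        in_seg_sites = np.flatnonzero(
            usable & (site_cm >= seg.start_cm) & (site_cm <= seg.end_cm)
        )
        last = seg.keep_end_cm == length_cm
        gmask = (grid_cm >= seg.keep_start_cm) & (
            (grid_cm <= seg.keep_end_cm) if last else (grid_cm < seg.keep_end_cm)
        )
        seg_cm = site_cm[in_seg_sites]
        seg_p1 = p1[in_seg_sites]
        seg_p2 = p2[in_seg_sites]
        seg_ref = ref_dosage[:, in_seg_sites]
        for g_bp, g_cm in zip(grid_bp[gmask], grid_cm[gmask]):
            snps, w = select_window_snps(seg_cm, g_cm, seg_ref, cfg)
            if snps.size == 0:
                rows.append((chrom, int(g_bp), float(g_cm), float("nan"),
                             float("nan"), 0, seg.index))
                continue
            score, s_hat = xpclr_score(
                seg_p1[snps],
                seg_p2[snps],
                np.abs(seg_cm[snps] - g_cm),
                w,
                omega,
                n1_chr,
                cfg,
            )
            rows.append((chrom, int(g_bp), float(g_cm), score, s_hat,
                         int(snps.size), seg.index))
    return pd.DataFrame(
        rows, columns=["chrom", "bp", "cm", "score", "s_hat", "n_snps", "segment"]
    )


def assemble_scan(segment_tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-chromosome tracks into one genome-wide ScanTrack."""
    track = pd.concat(segment_tracks, ignore_index=True)
    dup = track.duplicated(subset=["chrom", "bp"])
    if dup.any():
        raise ValueError("grid point covered by more than one kept span")
    return track.sort_values(["chrom", "bp"]).reset_index(drop=True)


def call_regions(
    track: pd.DataFrame,
    top_fraction: float = 0.001,
    gap_tolerance: int = 1,
) -> tuple[list[SweepRegion], float]:
    """Top-quantile threshold and maximal above-threshold runs.

    The threshold is the (1 − fraction) quantile of all defined grid scores
    genome-wide; ties at the threshold are included, and a run survives a gap
    of ``gap_tolerance`` grid steps.
    """
    scores = track["score"].to_numpy()
    defined = scores[~np.isnan(scores)]
    if defined.size == 0:
        raise ValueError("no defined grid scores")
    if np.allclose(defined, defined[0]):
        raise DegenerateScoresError("all grid scores are tied")
    threshold = float(np.quantile(defined, 1.0 - top_fraction))
    regions: list[SweepRegion] = []
    rid = 0
    for chrom, ctrack in track.groupby("chrom", sort=False):
        ctrack = ctrack.sort_values("bp")
        bp = ctrack["bp"].to_numpy()
        sc = ctrack["score"].to_numpy()
        above = np.flatnonzero(~np.isnan(sc) & (sc >= threshold))
        if above.size == 0:
            continue
        run_start = above[0]
        prev = above[0]
        for i in list(above[1:]) + [None]:
            if i is not None and i - prev <= gap_tolerance + 1:
                prev = i
                continue
            seg_sc = sc[run_start : prev + 1]
            peak = run_start + int(np.nanargmax(seg_sc))
            regions.append(
                SweepRegion(
                    rid,
                    str(chrom),
                    int(bp[run_start]),
                    int(bp[prev]),
                    float(sc[peak]),
                    int(bp[peak]),
                    int(prev - run_start + 1),
                )
            )
            rid += 1
            if i is not None:
                run_start = prev = i
    return regions, threshold


def map_genes(
    regions: list[SweepRegion],
    genes: list[GeneInterval],
    flank_bp: int = 1500,
) -> list[GeneHit]:
    """Genes whose 1500 bp-flanked interval intersects a candidate region."""
    hits: list[GeneHit] = []
    for g in genes:
        lo, hi = g.start - flank_bp, g.end + flank_bp
        for r in regions:
            if r.chrom != g.chrom:
                continue
            overlap = min(hi, r.end_bp) - max(lo, r.start_bp) + 1
            if overlap > 0:
                hits.append(GeneHit(g.gene_id, r.region_id, int(overlap)))
    return hits


def equalize_samples(
    pop_map: dict[str, str], target_size: int, seed: int
) -> dict[str, str]:
    """Random without-replacement subsample of each oversized population."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for pop in sorted(set(pop_map.values())):
        members = sorted(s for s, p in pop_map.items() if p == pop)
        if len(members) > target_size:
            members = [
                members[i]
                for i in sorted(
                    rng.choice(len(members), size=target_size, replace=False)
                )
            ]
        for s in members:
            out[s] = pop
    return out
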