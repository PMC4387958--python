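"""Diversity and differentiation statistics on a genotype matrix.

All estimators operate on alternate-allele dosages (0/1/2, −1 missing).
Nucleotide diversity π is averaged over the qualifying biallelic, fully
genotyped variant sites themselves (a per-variant mean, not per-bp).  The
per-individual inbreeding coefficient uses the method-of-moments
homozygosity-excess form with whole-sample allele frequencies and the
``n/(n−1)`` small-sample correction.  FST is the Weir & Cockerham (1984)
variance-components estimator θ̂ = a/(a+b+c), computed per polymorphic site
and weighted genome-wide as the ratio of component sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

RARE_MAF = 0.05  # strictly below this is "rare"


class UndefinedStatError(ValueError):
    """Statistic undefined for this input (e.g. no qualifying sites)."""


@dataclass
class FstResult:
    site_index: np.ndarray  # indices of sites entering the sums
    a: np.ndarray  # among-population variance component, per site
    b: np.ndarray  # among-individuals-within-population component
    c: np.ndarray  # within-individual component
    theta_site: np.ndarray  # per-site a/(a+b+c), NaN where denominator is 0
    theta_weighted: float  # Σa / Σ(a+b+c)
    n_skipped: int  # sites dropped for having a population with <2 calls


def _complete_biallelic_mask(matrix: GenotypeMatrix, snp_only: bool = False
                             ) -> np.ndarray:
    """Sites with no missing genotype and segregating (dosage not constant)."""
    d = matrix.dosage
    called = (d >= 0).all(axis=0)
    # an all-heterozygote column (max == min == 1) still segregates
    poly = ((d.max(axis=0) != d.min(axis=0)) | (d == 1).any(axis=0)) & called
    if snp_only:
        poly &= matrix.sites["is_snp"].to_numpy()
    return poly


def site_pi(alt_count: int, n_chromosomes: int) -> float:
    """Per-site nucleotide diversity 2j(n−j)/(n(n−1)) for allele count j of n."""
    j, n = alt_count, n_chromosomes
    if not 0 <= j <= n:
        raise ValueError(f"allele count {j} outside [0, {n}]")
    if n < 2:
        raise UndefinedStatError("pi needs >= 2 chromosomes")
    return 2.0 * j * (n - j) / (n * (n - 1))


def mean_pi(matrix: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> float:
    """Mean π over biallelic variant sites with no missing genotype in the
    subset; averaged over qualifying variant sites only."""
    sub = matrix if sample_idx is None else matrix.subset_samples(sample_idx)
    d = sub.dosage
    called = (d >= 0).all(axis=0)
    j = d.sum(axis=0, where=d >= 0)
    n = 2 * sub.n_samples
    qual = called & (j > 0) & (j < n)
    if not qual.any():
        raise UndefinedStatError("no polymorphic fully-genotyped site")
    jq = j[qual].astype(float)
    return float(np.mean(2.0 * jq * (n - jq) / (n * (n - 1))))


def het_observed(matrix: GenotypeMatrix, individual: int) -> float:
    """Observed heterozygosity: fraction of het genotypes among biallelic
    SNPs with no missing call in any sample."""
    qual = _complete_biallelic_mask(matrix, snp_only=True)
    if not qual.any():
        raise UndefinedStatError("no qualifying site for Ho")
    d = matrix.dosage[individual, qual]
    return float(np.mean(d == 1))


def inbreeding_f(matrix: GenotypeMatrix, individual: int) -> float:
    """Homozygosity-excess F with frequencies from the whole sample.

    ``F = (O_hom − E_hom) / (S − E_hom)`` where ``E_hom`` sums the per-site
    expected homozygosity ``1 − 2p(1−p)·n/(n−1)`` over qualifying sites.
    """
    qual = _complete_biallelic_mask(matrix, snp_only=True)
    if not qual.any():
        raise UndefinedStatError("no qualifying site for F")
    d = matrix.dosage[:, qual]
    n_chr = 2 * matrix.n_samples
    p = d.sum(axis=0) / n_chr
    e_hom = np.sum(1.0 - 2.0 * p * (1 - p) * n_chr / (n_chr - 1))
    o_hom = float(np.sum(d[individual] != 1))
    s = d.shape[1]
    if np.isclose(s, e_hom):
        raise UndefinedStatError("S == E_hom: F undefined")
    return float((o_hom - e_hom) / (s - e_hom))


def ibs_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS similarity: mean shared-allele proportion per site
    (1 identical genotype, 0.5 one allele shared, 0 none); missing sites
    excluded pairwise.  The distance is ``1 − similarity``."""
    d = matrix.dosage.astype(float)
    d[matrix.dosage < 0] = np.nan
    n = matrix.n_samples
    sim = np.ones((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            diff = np.abs(d[i] - d[k])
            ok = ~np.isnan(diff)
            if not ok.any():
                sim[i, k] = sim[k, i] = np.nan
                continue
            s = float(np.mean(1.0 - diff[ok] / 2.0))
            sim[i, k] = sim[k, i] = s
    return sim


def tstv(sites: pd.DataFrame) -> tuple[int, int, float]:
    """Transition/transversion counts and ratio over SNP alt alleles.

    A↔G and C↔T are transitions; all other substitutions transversions.
    A zero transversion count yields an infinite-ratio sentinel.
    """
    ts = tv = 0
    for ref, alt in zip(sites["ref"], sites["alt"]):
        for allele in str(alt).split(","):
            if len(ref) != 1 or len(allele) != 1 or allele == ref:
                continue
            if (ref, allele) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    ratio = float("inf") if tv == 0 else ts / tv
    return ts, tv, ratio


def tstv_from_counts(n_ts: int, n_tv: int) -> float:
    return float("inf") if n_tv == 0 else n_ts / n_tv


def maf_spectrum(
    matrix: GenotypeMatrix, bins: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """MAF histogram over all samples plus the rare fraction (MAF < 0.05).

    Returns (bin_edges, counts, rare_fraction); a site at exactly 0.05 is
    not rare.  Monomorphic sites are excluded.
    """
    d = matrix.dosage
    called = (d >= 0).sum(axis=0) * 2
    alt = d.sum(axis=0, where=d >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    maf = maf[(maf > 0) & ~np.isnan(maf)]
    if maf.size == 0:
        raise UndefinedStatError("no polymorphic site for the MAF spectrum")
    if bins is None:
        bins = np.arange(0.0, 0.55, 0.05)
    counts, edges = np.histogram(maf, bins=bins)
    rare = float(np.mean(maf < RARE_MAF))
    return edges, counts, rare


def rare_fraction_from_counts(n_rare: int, n_total: int) -> float:
    if n_total == 0:
        raise UndefinedStatError("no variants")
    return n_rare / n_total


def polymorphism_partition(
    matrix: GenotypeMatrix, pop_map: dict[str, str]
) -> dict[frozenset, int]:
    """Count sites by the subset of populations in which they segregate.

    A site is polymorphic within a population when ≥2 alleles segregate among
    that population's called genotypes; sites polymorphic nowhere are excluded.
    """
    pops = sorted(set(pop_map.values()))
    idx = {p: np.array([i for i, s in enumerate(matrix.samples)
                        if pop_map[s] == p]) for p in pops}
    d = matrix.dosage
    seg = {}
    for p in pops:
        sub = d[idx[p]]
        called = sub >= 0
        any_called = called.any(axis=0)
        mx = np.max(np.where(called, sub, -1), axis=0)
        mn = np.min(np.where(called, sub, 3), axis=0)
        # a het call alone (dosage 1) already carries two alleles
        seg[p] = any_called & ((mx != mn) | ((sub == 1).any(axis=0)))
    counts: dict[frozenset, int] = {}
    for j in range(matrix.n_sites):
        subset = frozenset(p for p in pops if seg[p][j])
        if subset:
            counts[subset] = counts.get(subset, 0) + 1
    return counts


def wc_fst(
    matrix: GenotypeMatrix,
    pop_map: dict[str, str],
    pops: list[str] | None = None,
) -> FstResult:
    """Weir & Cockerham (1984) variance components a, b, c per site and the
    genome-wide ratio-of-sums θ̂_w = Σa / Σ(a+b+c).

    Sites where any population has fewer than two called genotypes are
    skipped and counted; overall-monomorphic sites are excluded from sums.
    """
    if pops is None:
        pops = sorted(set(pop_map.values()))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    idx = [np.array([i for i, s in enumerate(matrix.samples)
                     if pop_map[s] == p]) for p in pops]
    r = len(pops)
    d = matrix.dosage
    m = matrix.n_sites

    n_i = np.zeros((r, m))  # called diploids per pop per site
    p_i = np.zeros((r, m))  # alt frequency per pop
    h_i = np.zeros((r, m))  # observed het frequency per pop
    for k, ix in enumerate(idx):
        sub = d[ix]
        called = sub >= 0
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(
                n_i[k] > 0, sub.sum(axis=0, where=called) / (2 * n_i[k]), 0.0
            )
            h_i[k] = np.where(
                n_i[k] > 0, (sub == 1).sum(axis=0) / np.maximum(n_i[k], 1), 0.0
            )

    usable = (n_i >= 2).all(axis=0)
    tot_n = n_i.sum(axis=0)
    pbar_all = (n_i * p_i).sum(axis=0) / np.maximum(tot_n, 1e-12)
    poly = (pbar_all > 0) & (pbar_all < 1)
    keep = usable & poly
    n_skipped = int(usable.size - usable.sum())

    ni = n_i[:, keep]
    pi_ = p_i[:, keep]
    hi = h_i[:, keep]
    nbar = ni.mean(axis=0)
    nc = (ni.sum(axis=0) - (ni**2).sum(axis=0) / ni.sum(axis=0)) / (r - 1)
    pbar = (ni * pi_).sum(axis=0) / (r * nbar)
    s2 = (ni * (pi_ - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ni * hi).sum(axis=0) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_site = np.where(denom != 0, a / denom, np.nan)
    ok = denom > 0
    theta_w = float(a[ok].sum() / denom[ok].sum()) if ok.any() else float("nan")
    return FstResult(
        site_index=np.flatnonzero(keep),
        a=a,
        b=b,
        c=c,
        theta_site=theta_site,
        theta_weighted=theta_w,
        n_skipped=n_skipped,
    )


def pairwise_fst(
    matrix: GenotypeMatrix, pop_map: dict[str, str]
) -> dict[tuple[str, str], float]:
    pops = sorted(set(pop_map.values()))
    out = {}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            res = wc_fst(matrix, pop_map, [pops[i], pops[j]])
            out[(pops[i], pops[j])] = res.theta_weighted
    return out


def diversity_report(
    matrix: GenotypeMatrix, pop_map: dict[str, str]
) -> dict:
    """Bundle the per-population and per-individual diversity summaries."""
    pops = sorted(set(pop_map.values()))
    report: dict = {"pi": {}, "ho": {}, "f": {}}
    report["pi"]["overall"] = mean_pi(matrix)
    for p in pops:
        ix = np.array([i for i, s in enumerate(matrix.samples)
                       if pop_map[s] == p])
        report["pi"][p] = mean_pi(matrix, ix)
    for i, s in enumerate(matrix.samples):
        report["ho"][s] = het_observed(matrix, i)
        report["f"][s] = inbreeding_f(matrix, i)
    ts, tv, ratio = tstv(matrix.sites)
    report["tstv"] = {"ts": ts, "tv": tv, "ratio": ratio}
    edges, counts, rare = maf_spectrum(matrix)
    report["maf"] = {"edges": edges.tolist(), "counts": counts.tolist(),
                     "rare_fraction": rare}
    report["partition"] = {
        "+".join(sorted(k)): v
        for k, v in polymorphism_partition(matrix, pop_map).items()
    }
    report["fst_weighted"] = wc_fst(matrix, pop_map).theta_weighted
    report["fst_pairwise"] = {
        f"{a}-{b}": v for (a, b), v in pairwise_fst(matrix, pop_map).items()
    }
    return report
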