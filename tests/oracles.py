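"""Independent brute-force oracles and small fixture builders.

Everything here is deliberately written with explicit scalar loops, straight
from the textbook definitions, independent of the vectorized implementations
it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from caprapop.io_formats import Genotype, GenotypeMatrix, VariantRecord


def make_matrix(
    dosage_rows: list[list[int]],
    positions: list[int] | None = None,
    chrom: str = "chr1",
    refs: list[str] | None = None,
    alts: list[str] | None = None,
    samples: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a per-sample list of dosage rows."""
    d = np.asarray(dosage_rows, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if refs is None:
        refs = ["A"] * m
    if alts is None:
        alts = ["G"] * m
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "is_snp": [len(r) == 1 and len(a) == 1 for r, a in zip(refs, alts)],
        }
    )
    return GenotypeMatrix(d, samples, sites)


def make_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alts=("G",),
    qual=50.0,
    genotypes=None,
    annotations=None,
    caller_id=None,
) -> VariantRecord:
    if genotypes is None:
        genotypes = [Genotype(0, 1, 60.0, 0.99)]
    return VariantRecord(
        chrom, pos, ref, tuple(alts), qual, dict(annotations or {}),
        list(genotypes), caller_id,
    )


def wc_site_components(genos_by_pop: list[list[int]]):
    """Weir & Cockerham (1984) a, b, c for one site, scalar arithmetic.

    ``genos_by_pop``: per population, the list of called dosages (0/1/2).
    """
    r = len(genos_by_pop)
    n_i = [len(g) for g in genos_by_pop]
    p_i = [sum(g) / (2 * len(g)) for g in genos_by_pop]
    h_i = [sum(1 for x in g if x == 1) / len(g) for g in genos_by_pop]
    n_tot = sum(n_i)
    nbar = n_tot / r
    nc = (n_tot - sum(n * n for n in n_i) / n_tot) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def inbreeding_f_site_sum(dosages: np.ndarray, individual: int) -> float:
    """Per-site-summation homozygosity-excess F, scalar arithmetic."""
    n, m = dosages.shape
    n_chr = 2 * n
    o_hom = 0.0
    e_hom = 0.0
    s = 0
    for j in range(m):
        col = [int(dosages[i, j]) for i in range(n)]
        p = sum(col) / n_chr
        e_hom += 1.0 - 2.0 * p * (1 - p) * n_chr / (n_chr - 1)
        o_hom += 1.0 if col[individual] != 1 else 0.0
        s += 1
    return (o_hom - e_hom) / (s - e_hom)


def stage1_enumeration(caller_records: dict[str, list[VariantRecord]]):
    """Direct enumeration of the consensus pass rules.

    Returns (passing site keys, surviving alleles per passing site).
    """
    by_site: dict[tuple, list[VariantRecord]] = {}
    for recs in caller_records.values():
        for r in recs:
            by_site.setdefault((r.chrom, r.pos), []).append(r)
    passing = set()
    alleles: dict[tuple, set] = {}
    for key, recs in by_site.items():
        n_support = sum(1 for r in recs if r.site_qual > 30.0)
        if n_support < 2:
            continue
        passing.add(key)
        surv = set()
        for r in recs:
            for k, alt in enumerate(r.alts, start=1):
                carried = any(g.a1 == k or g.a2 == k for g in r.genotypes)
                if carried:
                    surv.add(alt)
        alleles[key] = surv
    return passing, alleles


def pairwise_prune_oracle(dosage: np.ndarray, positions: np.ndarray,
                          threshold: float = 0.95) -> list[int]:
    """Exhaustive pairwise pruning of one window, scalar loops."""
    m = dosage.shape[1]
    order = sorted(range(m), key=lambda j: positions[j])
    alive = {j: True for j in order}
    for ii in range(m - 1):
        i = order[ii]
        if not alive[i]:
            continue
        for jj in range(ii + 1, m):
            j = order[jj]
            if not alive[j]:
                continue
            x, y = dosage[:, i].astype(float), dosage[:, j].astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r2 = float(np.corrcoef(x, y)[0, 1]) ** 2
            if r2 > threshold:
                alive[j] = False
    return sorted(j for j, ok in alive.items() if ok)
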