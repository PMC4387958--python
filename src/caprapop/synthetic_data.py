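"""Synthetic inputs with known truth for every pipeline stage.

The genotype generator combines a Balding–Nichols model of population
differentiation with a founder-mosaic haplotype model:

* each site draws an ancestral frequency ``p`` from a symmetric Beta law whose
  shape parameter skews the site-frequency spectrum toward rare variants;
* each population draws its own frequency ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``
  so the realized Weir–Cockerham FST is controlled by ``f_div``;
* ``K`` founder haplotypes per population are sampled from ``p_k`` and
  individual haplotypes are founder mosaics with per-bp switch probability
  equal to the recombination rate, so r² decays with physical distance.

Sweeps are injected post hoc by dragging carrier haplotypes in one population
toward a single template haplotype with escape probability rising with
distance — a deliberately simple hitchhiking emulation for testing scan
localization, not a model of sweep dynamics.

Multi-caller call sets are emulated by re-emitting the true sites through
per-caller error channels (false negatives, private and shared artifact
sites, noisy qualities, class-separated annotation laws) so the consensus and
recalibration filters have real work to do.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    ANNOTATION_KEYS,
    GenotypeMatrix,
    Genotype,
    VariantRecord,
    write_vcf,
)

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SweepSpec:
    chrom: str
    position: int  # bp
    target_pop: str
    sigma_bp: float = 100_000.0  # hitchhiking length scale
    final_freq: float = 1.0


@dataclass
class CallerProfile:
    """Error channel of one emulated variant caller.

    True-site annotations are Gaussian per INFO key.  Artifact sites draw
    from the same Gaussians but with a random error mode: each annotation is
    independently displaced by ``artifact_shift_sd`` standard deviations
    (random sign) with probability ``artifact_mode_prob``, emulating
    heterogeneous caller failure modes rather than one stereotyped artifact
    class, while keeping the per-annotation class separation near 2 SD.
    """

    name: str
    fn_rate: float = 0.02
    fp_rate: float = 0.04  # private artifacts, fraction of true-site count
    qual_true: tuple[float, float] = (220.0, 80.0)  # (mean, sd), phred
    qual_artifact: tuple[float, float] = (45.0, 18.0)
    gq_true: tuple[float, float] = (70.0, 18.0)
    gq_artifact: tuple[float, float] = (28.0, 10.0)
    gp_true: tuple[float, float] = (0.99, 0.02)
    gp_artifact: tuple[float, float] = (0.75, 0.12)
    artifact_mode_prob: float = 0.7
    artifact_shift_sd: float = 2.0
    # per-annotation (true mean, sd)
    annotation_laws: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "QD": (20.0, 8.0),
            "HaplotypeScore": (3.0, 5.0),
            "MQRankSum": (0.0, 2.0),
            "ReadPosRankSum": (0.0, 2.0),
            "FS": (5.0, 10.0),
            "DP": (300.0, 90.0),
            "InbreedingCoefficient": (0.0, 0.2),
        }
    )


def default_caller_profiles() -> list[CallerProfile]:
    """Three caller channels with mildly different error rates."""
    return [
        CallerProfile("mpileup", fn_rate=0.03, fp_rate=0.05),
        CallerProfile("ug", fn_rate=0.02, fp_rate=0.04),
        CallerProfile("fb", fn_rate=0.04, fp_rate=0.06),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate the sampling design under test: three weakly
    differentiated populations (22 + 14 + 8 diploids, genome-wide FST on the
    order of 10⁻³), a rare-variant-rich frequency spectrum, distance-decaying
    LD, and a transition-biased substitution mix.
    """

    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"Black": 22, "Draa": 14, "Northern": 8}
    )
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    n_sites: int = 20_000
    f_div: float = 0.0025  # Balding–Nichols divergence parameter
    #: founder haplotypes per population (mosaic/LD mode); ``None`` draws
    #: genotypes directly from the population frequencies — the pure
    #: Balding–Nichols model, LD-free.
    n_founders: int | None = 30
    recomb_rate: float = 1e-4  # founder-switch probability per bp
    sfs_shape: float = 0.1  # symmetric Beta shape; lower = more rare variants
    transition_prob: float = 0.71  # P(alt is a transition) for SNP sites
    indel_fraction: float = 0.05
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_div < 1.0:
            raise ValueError(
                "f_div must lie strictly in (0, 1); use a small positive "
                "floor such as 1e-4 instead of 0"
            )
        for r in (self.recomb_rate, self.indel_fraction, self.transition_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep chromosome {sw.chrom} not simulated")
            if not 1 <= sw.position <= self.chrom_lengths[sw.chrom]:
                raise ValueError("sweep position outside its chromosome")
            if sw.target_pop not in self.pop_sizes:
                raise ValueError(f"sweep target {sw.target_pop} not a population")


def population_map(config: SimConfig) -> dict[str, str]:
    return {
        f"{pop}_{i:02d}": pop
        for pop in config.pop_sizes
        for i in range(config.pop_sizes[pop])
    }


def _founder_paths(
    rng: np.random.Generator,
    n_haps: int,
    positions: np.ndarray,
    n_founders: int,
    recomb_rate: float,
) -> np.ndarray:
    """Founder index per (haplotype, site) under the mosaic model."""
    m = len(positions)
    switch = np.ones((n_haps, m), dtype=bool)
    if m > 1:
        gaps = np.diff(positions).astype(float)
        p_switch = 1.0 - np.exp(-recomb_rate * gaps)
        switch[:, 1:] = rng.random((n_haps, m - 1)) < p_switch
    # index of the most recent switch point, per site
    idx = np.where(switch, np.arange(m)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    draws = rng.integers(0, n_founders, size=(n_haps, m))
    return np.take_along_axis(draws, idx, axis=1)


def _draw_alleles(rng: np.random.Generator, m: int, is_indel: np.ndarray,
                  transition_prob: float) -> tuple[list[str], list[str]]:
    refs = rng.choice(_BASES, size=m)
    is_ts = rng.random(m) < transition_prob
    alts = []
    for j in range(m):
        ref = refs[j]
        if is_indel[j]:
            ins = "".join(rng.choice(_BASES, size=2))
            alts.append(ref + ins)
        elif is_ts[j]:
            alts.append(_TRANSITION[ref])
        else:
            choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
            alts.append(choices[rng.integers(0, 2)])
    return list(refs), alts


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Draw a genotype matrix under the Balding–Nichols founder-mosaic model.

    Returns the matrix (overall-monomorphic sites dropped, as in real call
    sets) and a truth record with the ancestral frequency ``p``, per-population
    frequencies ``p_k``, founder haplotypes and founder identities per site.
    """
    rng = np.random.default_rng(config.seed)
    pops = list(config.pop_sizes)
    total_len = sum(config.chrom_lengths.values())
    samples = list(population_map(config))

    all_dosage: list[np.ndarray] = []
    meta = {"chrom": [], "pos": [], "ref": [], "alt": [], "is_snp": []}
    truth: dict = {"p": [], "p_k": {k: [] for k in pops}, "founder_paths": {},
                   "founders": {}, "config": config}

    for chrom, length in config.chrom_lengths.items():
        m = max(2, round(config.n_sites * length / total_len))
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=min(m, length), replace=False)
        )
        m = len(positions)
        p = rng.beta(config.sfs_shape, config.sfs_shape, size=m)
        p = np.clip(p, 1e-4, 1 - 1e-4)
        F = config.f_div
        hap_blocks = []
        founders_by_pop = {}
        paths_by_pop = {}
        p_k_by_pop = {}
        # shared uniform field: founder pools are comonotone across
        # populations, so founder-sampling noise largely cancels out of the
        # among-population variance instead of inflating realized FST
        u_field = (
            rng.random((config.n_founders, m))
            if config.n_founders is not None
            else None
        )
        for pop in pops:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            p_k = rng.beta(a, b)
            n_haps = 2 * config.pop_sizes[pop]
            if config.n_founders is None:
                haps = (rng.random((n_haps, m)) < p_k[None, :]).astype(np.int8)
                founders, paths = None, None
            else:
                founders = (u_field < p_k[None, :]).astype(np.int8)
                paths = _founder_paths(
                    rng, n_haps, positions, config.n_founders, config.recomb_rate
                )
                haps = founders[paths, np.arange(m)[None, :]]
            hap_blocks.append(haps)
            founders_by_pop[pop] = founders
            paths_by_pop[pop] = paths
            p_k_by_pop[pop] = p_k
        haps = np.concatenate(hap_blocks, axis=0)
        dosage = (haps[0::2] + haps[1::2]).astype(np.int8)

        is_indel = rng.random(m) < config.indel_fraction
        refs, alts = _draw_alleles(rng, m, is_indel, config.transition_prob)
        all_dosage.append(dosage)
        meta["chrom"].extend([chrom] * m)
        meta["pos"].extend(positions.tolist())
        meta["ref"].extend(refs)
        meta["alt"].extend(alts)
        meta["is_snp"].extend((~is_indel).tolist())
        truth["p"].append(p)
        for pop in pops:
            truth["p_k"][pop].append(p_k_by_pop[pop])
        truth["founders"][chrom] = founders_by_pop
        truth["founder_paths"][chrom] = paths_by_pop

    dosage = np.concatenate(all_dosage, axis=1)
    truth["p"] = np.concatenate(truth["p"])
    for pop in pops:
        truth["p_k"][pop] = np.concatenate(truth["p_k"][pop])

    matrix = GenotypeMatrix(dosage, samples, pd.DataFrame(meta))
    # drop sites monomorphic over the whole sample, like a real call set
    poly = (dosage.max(axis=0) > 0) & (dosage.min(axis=0) < 2)
    keep = np.flatnonzero(poly)
    truth["kept_site_index"] = keep
    truth["p"] = truth["p"][keep]
    for pop in pops:
        truth["p_k"][pop] = truth["p_k"][pop][keep]
    return matrix.subset_sites(keep), truth


def inject_sweep(
    matrix: GenotypeMatrix,
    spec: SweepSpec,
    pop_map: dict[str, str],
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict]:
    """Drag target-population haplotypes toward one template around a sweep.

    Carrier haplotypes (a fraction ``final_freq`` of the target population's
    haplotypes) copy the template allele at each site with probability
    ``exp(-d / sigma_bp)``, ``d`` the distance to the sweep position; the
    escape probability is ``c(d) = 1 - exp(-d/sigma)``.  The template carries
    the alternate allele at the sweep site, so at ``d = 0`` the beneficial
    allele reaches exactly ``final_freq``.  Other populations and other
    chromosomes are untouched.
    """
    rng = np.random.default_rng(seed)
    target_idx = np.array(
        [i for i, s in enumerate(matrix.samples) if pop_map[s] == spec.target_pop]
    )
    if target_idx.size == 0:
        raise ValueError(f"no samples in target population {spec.target_pop}")
    site_idx = np.flatnonzero(matrix.sites["chrom"].to_numpy() == spec.chrom)
    pos = matrix.sites["pos"].to_numpy()[site_idx]
    sweep_j = site_idx[np.argmin(np.abs(pos - spec.position))]

    dosage = matrix.dosage.copy()
    sub = dosage[np.ix_(target_idx, site_idx)]
    n_t = len(target_idx)
    # split dosages into pseudo-haplotypes (phase is irrelevant to the harness)
    haps = np.zeros((2 * n_t, len(site_idx)), dtype=np.int8)
    haps[0::2] = (sub >= 1).astype(np.int8)
    haps[1::2] = (sub == 2).astype(np.int8)
    het = sub == 1
    flip = rng.random(het.shape) < 0.5
    swap = het & flip
    h1, h2 = haps[0::2].copy(), haps[1::2].copy()
    h1[swap], h2[swap] = 0, 1
    haps[0::2], haps[1::2] = h1, h2

    n_carriers = int(round(spec.final_freq * 2 * n_t))
    carriers = rng.choice(2 * n_t, size=n_carriers, replace=False)
    template = haps[carriers[0]].copy() if n_carriers else haps[0].copy()
    template[np.flatnonzero(site_idx == sweep_j)[0]] = 1

    d = np.abs(pos - matrix.sites["pos"].iloc[sweep_j]).astype(float)
    p_drag = np.exp(-d / spec.sigma_bp)
    dragged = rng.random((n_carriers, len(site_idx))) < p_drag[None, :]
    for row, hap_i in enumerate(carriers):
        haps[hap_i, dragged[row]] = template[dragged[row]]

    new_sub = (haps[0::2] + haps[1::2]).astype(np.int8)
    new_sub[sub < 0] = -1  # keep originally missing calls missing
    dosage[np.ix_(target_idx, site_idx)] = new_sub

    truth = {
        "sweep_site_index": int(sweep_j),
        "sweep_pos": int(matrix.sites["pos"].iloc[sweep_j]),
        "chrom": spec.chrom,
        "target_pop": spec.target_pop,
        "carriers": carriers,
        "template": template,
        "escape_scale_bp": spec.sigma_bp,
    }
    return GenotypeMatrix(dosage, matrix.samples, matrix.sites), truth


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def emit_caller_vcfs(
    matrix: GenotypeMatrix,
    out_dir: str | os.PathLike,
    profiles: list[CallerProfile] | None = None,
    seed: int = 0,
    shared_fp_rate: float = 0.05,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Re-emit the true sites through per-caller error channels.

    Besides each caller's private artifacts, a shared artifact pool (fraction
    ``shared_fp_rate`` of true sites) is emitted by at least two callers so
    that some artifacts survive the consensus stage and exercise the
    recalibration model.  Returns ``{caller: vcf_path}`` and a truth table
    labelling every emitted (chrom, pos) as true or artifact.
    """
    if profiles is None:
        profiles = default_caller_profiles()
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    samples = matrix.samples
    n, m = matrix.n_samples, matrix.n_sites
    chroms = matrix.sites["chrom"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    true_keys = set(zip(chroms.tolist(), positions.tolist()))

    chrom_max = {c: int(positions[chroms == c].max()) + 10_000
                 for c in pd.unique(chroms)}

    def _artifact_positions(count: int, occupied: set) -> list[tuple[str, int]]:
        out = []
        chrom_list = list(chrom_max)
        while len(out) < count:
            c = chrom_list[rng.integers(0, len(chrom_list))]
            p = int(rng.integers(1, chrom_max[c] + 1))
            if (c, p) in occupied or (c, p) in true_keys:
                continue
            occupied.add((c, p))
            out.append((c, p))
        return out

    def _artifact_site(chrom: str, pos: int):
        """Caller-independent part of an artifact: alleles and genotypes."""
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        f = rng.uniform(0.01, 0.25)
        dos = rng.binomial(2, f, size=n)
        return chrom, pos, ref, alt, dos

    def _artifact_record(site, prof: CallerProfile) -> VariantRecord:
        chrom, pos, ref, alt, dos = site
        genos = [
            Genotype(
                int(d > 0),
                int(d > 1),
                float(np.clip(rng.normal(*prof.gq_artifact), 0, 99)),
                float(_clip01(rng.normal(*prof.gp_artifact))),
            )
            for d in dos
        ]
        anns = {}
        for k, (mu, sd) in prof.annotation_laws.items():
            shift = 0.0
            if rng.random() < prof.artifact_mode_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                shift = sign * prof.artifact_shift_sd * sd
            anns[k] = float(rng.normal(mu, sd) + shift)
        qual = float(max(0.0, rng.normal(*prof.qual_artifact)))
        return VariantRecord(chrom, pos, ref, (alt,), qual, anns, genos)

    # shared artifact pool: each member emitted by >=2 callers with a common
    # allele/genotype configuration, so some artifacts survive the consensus
    occupied: set = set()
    n_shared = rng.binomial(m, shared_fp_rate)
    shared_sites = [
        _artifact_site(c, p) for c, p in _artifact_positions(n_shared, occupied)
    ]
    shared_callers = [
        rng.choice(len(profiles), size=rng.integers(2, len(profiles) + 1),
                   replace=False)
        for _ in shared_sites
    ]

    paths: dict[str, str] = {}
    truth_rows: list[tuple[str, int, bool]] = []
    for c, p in true_keys:
        truth_rows.append((c, p, True))

    for ci, prof in enumerate(profiles):
        records: list[VariantRecord] = []
        emit = rng.random(m) >= prof.fn_rate
        quals = np.maximum(0.0, rng.normal(*prof.qual_true, size=m))
        gq = np.clip(rng.normal(*prof.gq_true, size=(n, m)), 0, 99)
        gp = _clip01(rng.normal(*prof.gp_true, size=(n, m)))
        ann_vals = {
            k: rng.normal(mu, sd, size=m)
            for k, (mu, sd) in prof.annotation_laws.items()
        }
        for j in range(m):
            if not emit[j]:
                continue
            genos = []
            for i in range(n):
                d = matrix.dosage[i, j]
                if d < 0:
                    genos.append(Genotype(-1, -1, None, None))
                else:
                    genos.append(
                        Genotype(int(d > 0), int(d > 1),
                                 float(gq[i, j]), float(gp[i, j]))
                    )
            records.append(
                VariantRecord(
                    str(chroms[j]),
                    int(positions[j]),
                    str(matrix.sites["ref"].iloc[j]),
                    (str(matrix.sites["alt"].iloc[j]),),
                    float(quals[j]),
                    {k: float(v[j]) for k, v in ann_vals.items()},
                    genos,
                    caller_id=prof.name,
                )
            )
        n_private = rng.binomial(m, prof.fp_rate)
        for chrom, pos in _artifact_positions(n_private, occupied):
            rec = _artifact_record(_artifact_site(chrom, pos), prof)
            rec.caller_id = prof.name
            records.append(rec)
            truth_rows.append((chrom, pos, False))
        for site, callers in zip(shared_sites, shared_callers):
            if ci in callers:
                rec = _artifact_record(site, prof)
                rec.caller_id = prof.name
                records.append(rec)
        records.sort(key=lambda r: (r.chrom, r.pos))
        path = os.path.join(out_dir, f"{prof.name}.vcf")
        write_vcf(records, path, samples)
        paths[prof.name] = path

    for site in shared_sites:
        truth_rows.append((site[0], site[1], False))
    truth = (
        pd.DataFrame(truth_rows, columns=["chrom", "pos", "is_true"])
        .drop_duplicates(subset=["chrom", "pos"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return paths, truth


def simulate_mtdna(
    ref_length: int,
    n_sequences: int,
    mutation_rate: float,
    hypervariable_window: tuple[int, int] | None = None,
    rate_multiplier: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """Independent-substitution mtDNA alignment with a hypervariable window.

    Positions are 1-based; inside ``hypervariable_window`` (inclusive) the
    per-sequence substitution rate is ``mutation_rate * rate_multiplier``.
    The truth record lists every position where any sequence mutated.
    """
    rng = np.random.default_rng(seed)
    ref = rng.choice(_BASES, size=ref_length)
    rates = np.full(ref_length, mutation_rate)
    if hypervariable_window is not None:
        lo, hi = hypervariable_window
        rates[lo - 1 : hi] = mutation_rate * rate_multiplier
    rates = np.clip(rates, 0.0, 1.0)
    seqs: dict[str, str] = {}
    mutated = np.zeros(ref_length, dtype=bool)
    for i in range(n_sequences):
        mut = rng.random(ref_length) < rates
        seq = ref.copy()
        if mut.any():
            for j in np.flatnonzero(mut):
                seq[j] = rng.choice([b for b in "ACGT" if b != ref[j]])
            mutated |= mut
        seqs[f"mt_{i:03d}"] = "".join(seq)
    truth = {
        "reference": "".join(ref),
        "mutated_positions": (np.flatnonzero(mutated) + 1).tolist(),
    }
    return seqs, truth
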