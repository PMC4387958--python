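"""Readers and writers for the fixed dialects the pipeline touches.

Supported formats: a VCF v4.2 subset (CHROM, POS, REF, ALT, QUAL, the seven
recalibration INFO annotations, FORMAT ``GT:GQ:GP``), BED3+1 / 1-based TSV
gene tables, a two-column population map, and FASTA for mtDNA alignments.

Internal coordinates are 1-based inclusive everywhere (VCF-native); BED input
is converted at the boundary.  A missing numeric annotation is represented as
an absent key, never as zero — downstream imputation is explicit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: INFO keys carried through the recalibration model, in canonical order.
ANNOTATION_KEYS = (
    "QD",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
    "FS",
    "DP",
    "InbreedingCoefficient",
)


class FormatError(ValueError):
    """Malformed file content (header, field syntax, coordinates)."""


class OrderError(ValueError):
    """Records are not in (chrom, pos) sorted order."""


@dataclass
class Genotype:
    """One diploid call: allele indices (−1 = missing), GQ (phred), GP (prob)."""

    a1: int
    a2: int
    gq: float | None = None
    gp: float | None = None

    @property
    def missing(self) -> bool:
        return self.a1 < 0 or self.a2 < 0

    def dosage(self) -> int:
        """Count of non-reference alleles; −1 if the call is missing."""
        if self.missing:
            return -1
        return int(self.a1 > 0) + int(self.a2 > 0)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    site_qual: float
    annotations: dict[str, float] = field(default_factory=dict)
    genotypes: list[Genotype] = field(default_factory=list)
    caller_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if self.site_qual < 0:
            raise FormatError(f"site_qual must be >= 0, got {self.site_qual}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GenotypeMatrix:
    """Samples × sites allele-dosage matrix with site metadata.

    ``dosage`` holds alternate-allele counts per diploid genotype
    (0, 1, 2) with −1 marking missing calls.  ``sites`` is a DataFrame with
    columns ``chrom, pos, ref, alt, is_snp`` aligned to the dosage columns.
    """

    dosage: np.ndarray  # (n_samples, n_sites), int8
    samples: list[str]
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[idx], [self.samples[i] for i in idx], self.sites
        )

    def subset_sites(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.samples,
            self.sites.iloc[idx].reset_index(drop=True),
        )


def _check_sorted(chrom_pos: list[tuple[str, int]]) -> None:
    seen_chroms: set[str] = set()
    prev_chrom, prev_pos = None, -1
    for chrom, pos in chrom_pos:
        if chrom != prev_chrom:
            if chrom in seen_chroms:
                raise OrderError(
                    f"unsorted input: chromosome {chrom} reappears at {chrom}:{pos}"
                )
            if prev_chrom is not None:
                seen_chroms.add(prev_chrom)
            prev_chrom, prev_pos = chrom, pos
        elif pos < prev_pos:
            raise OrderError(
                f"unsorted input: {chrom}:{pos} follows {prev_chrom}:{prev_pos}"
            )
        else:
            prev_pos = pos


def read_vcf(path: str | os.PathLike, caller_id: str | None = None):
    """Read a VCF into ``(records, samples)``.

    Records come back in the file's order, which must be (chrom, pos)
    sorted; an unsorted file raises :class:`OrderError` naming the first
    offending record.  Missing genotypes yield missing-dosage entries; INFO
    annotations absent from a record stay absent from its dict.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        anns: dict[str, float] = {}
        for key in ANNOTATION_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                anns[key] = float(val)
        gqs = v.gt_quals if samples else None
        gp_arr = None
        if samples:
            try:
                gp_arr = v.format("GP")
            except KeyError:
                gp_arr = None
        genos: list[Genotype] = []
        for i in range(len(samples)):
            a = v.genotypes[i]
            a1 = int(a[0]) if a[0] is not None and a[0] >= 0 else -1
            a2 = int(a[1]) if len(a) > 2 and a[1] is not None and a[1] >= 0 else -1
            gq = None
            if gqs is not None and gqs[i] >= 0:
                gq = float(gqs[i])
            gp = None
            if gp_arr is not None and not np.isnan(gp_arr[i][0]):
                gp = float(gp_arr[i][0])
            genos.append(Genotype(a1, a2, gq, gp))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                site_qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                annotations=anns,
                genotypes=genos,
                caller_id=caller_id,
            )
        )
    vcf.close()
    _check_sorted([(r.chrom, r.pos) for r in records])
    return records, samples


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype consistency score">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias phred score">',
    '##INFO=<ID=DP,Number=1,Type=Float,Description="Total depth">',
    '##INFO=<ID=InbreedingCoefficient,Number=1,Type=Float,Description="Inbreeding coefficient">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality (phred)">',
    '##FORMAT=<ID=GP,Number=1,Type=Float,Description="Probability of the called genotype">',
]


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(
    records: list[VariantRecord], path: str | os.PathLike, samples: list[str]
) -> None:
    """Write records as an uncompressed VCF v4.2 subset re-readable by read_vcf."""
    _check_sorted([(r.chrom, r.pos) for r in records])
    contigs: list[str] = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER_LINES[0] + "\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        for line in _VCF_HEADER_LINES[1:]:
            fh.write(line + "\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + samples) + "\n")
        for r in records:
            if len(r.genotypes) != len(samples):
                raise FormatError(
                    f"{r.chrom}:{r.pos} has {len(r.genotypes)} genotypes for "
                    f"{len(samples)} samples"
                )
            info = (
                ";".join(
                    f"{k}={_fmt_float(r.annotations[k])}"
                    for k in ANNOTATION_KEYS
                    if k in r.annotations
                )
                or "."
            )
            fields = [
                r.chrom,
                str(r.pos),
                ".",
                r.ref,
                ",".join(r.alts),
                _fmt_float(r.site_qual),
                ".",
                info,
                "GT:GQ:GP",
            ]
            for g in r.genotypes:
                gt = "./." if g.missing else f"{g.a1}/{g.a2}"
                gq = "." if g.gq is None else _fmt_float(g.gq)
                gp = "." if g.gp is None else _fmt_float(g.gp)
                fields.append(f"{gt}:{gq}:{gp}")
            fh.write("\t".join(fields) + "\n")


def records_to_matrix(
    records: list[VariantRecord], samples: list[str]
) -> GenotypeMatrix:
    """Collapse records into a GenotypeMatrix (first ALT allele as ``alt``)."""
    n, m = len(samples), len(records)
    dosage = np.full((n, m), -1, dtype=np.int8)
    meta = {"chrom": [], "pos": [], "ref": [], "alt": [], "is_snp": []}
    for j, r in enumerate(records):
        for i, g in enumerate(r.genotypes):
            dosage[i, j] = g.dosage()
        meta["chrom"].append(r.chrom)
        meta["pos"].append(r.pos)
        meta["ref"].append(r.ref)
        meta["alt"].append(r.alts[0] if r.alts else ".")
        meta["is_snp"].append(r.is_snp)
    return GenotypeMatrix(dosage, list(samples), pd.DataFrame(meta))


def read_gene_table(
    path: str | os.PathLike, convention: str = "bed"
) -> list[GeneInterval]:
    """Read gene intervals; ``convention`` is ``"bed"`` (0-based half-open,
    columns chrom/start/end/name) or ``"tsv"`` (gene/chrom/start/end,
    1-based inclusive).  Output is always 1-based inclusive."""
    if convention not in ("bed", "tsv"):
        raise ValueError(f"unknown convention {convention!r}")
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            if convention == "bed":
                chrom, start, end, gid = parts[0], int(parts[1]), int(parts[2]), parts[3]
                gi = GeneInterval(gid, chrom, start + 1, end)
            else:
                gid, chrom, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
                gi = GeneInterval(gid, chrom, start, end)
            if gi.gene_id in seen:
                raise FormatError(f"{path}:{ln}: duplicate gene_id {gi.gene_id}")
            seen.add(gi.gene_id)
            genes.append(gi)
    return genes


def write_gene_table(genes: list[GeneInterval], path: str | os.PathLike,
                     convention: str = "bed") -> None:
    with open(path, "w") as fh:
        for g in genes:
            if convention == "bed":
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
            else:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\n")


def read_population_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV mapping sample id → population label."""
    pops: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns")
            sample, pop = parts
            if sample in pops:
                raise FormatError(f"{path}:{ln}: duplicate sample {sample}")
            pops[sample] = pop
    return pops


def write_population_map(pops: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, pop in pops.items():
            fh.write(f"{sample}\t{pop}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (upper-cased)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
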