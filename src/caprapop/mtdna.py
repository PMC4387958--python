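"""Mitochondrial alignment statistics.

Operates on equal-length aligned sequences.  Only the four unambiguous
nucleotides count as states: a column varying only through gaps or ambiguity
codes is not segregating, and two sequences identical at every mutually
unambiguous position collapse into one haplotype (an N matches either state).
Positions are 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

_STATES = frozenset("ACGT")


class AlignmentError(ValueError):
    """Sequences of unequal length."""


@dataclass
class HaplotypeSet:
    sequences: dict[str, str]
    segregating_positions: list[int]
    partition: list[list[str]]  # groups of sample ids with identical sequences

    @property
    def n_haplotypes(self) -> int:
        return len(self.partition)


def _check_aligned(sequences: dict[str, str]) -> int:
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
    return lengths.pop() if lengths else 0


def segregating_sites(sequences: dict[str, str]) -> list[int]:
    """1-based positions where ≥2 distinct unambiguous states occur."""
    length = _check_aligned(sequences)
    seqs = [s.upper() for s in sequences.values()]
    out = []
    for j in range(length):
        states = {s[j] for s in seqs} & _STATES
        if len(states) >= 2:
            out.append(j + 1)
    return out


def _compatible(a: str, b: str) -> bool:
    """Identical over positions where both carry an unambiguous state."""
    return all(
        x == y or x not in _STATES or y not in _STATES for x, y in zip(a, b)
    )


def collapse_haplotypes(sequences: dict[str, str]) -> HaplotypeSet:
    """Merge sequences identical over their non-ambiguous positions.

    Greedy in input order: each sequence joins the first existing haplotype
    it is compatible with, otherwise founds a new one.
    """
    _check_aligned(sequences)
    reps: list[str] = []  # representative sequence per haplotype
    partition: list[list[str]] = []
    for name, seq in sequences.items():
        seq = seq.upper()
        for k, rep in enumerate(reps):
            if _compatible(seq, rep):
                partition[k].append(name)
                # refine the representative with any newly unambiguous state
                reps[k] = "".join(
                    a if a in _STATES else b for a, b in zip(rep, seq)
                )
                break
        else:
            reps.append(seq)
            partition.append([name])
    return HaplotypeSet(dict(sequences), segregating_sites(sequences), partition)


def extract_region(
    sequences: dict[str, str], start: int, end: int
) -> dict[str, str]:
    """Columns ``start..end`` inclusive (1-based); length = end − start + 1."""
    length = _check_aligned(sequences)
    if not 1 <= start <= end <= length:
        raise ValueError(f"region {start}..{end} outside alignment of {length}")
    return {name: s[start - 1 : end] for name, s in sequences.items()}


def region_share(
    sequences: dict[str, str], start: int, end: int
) -> tuple[float, float]:
    """(variant share, length share) of a sub-region of the alignment.

    Variant share: segregating sites falling inside the region over all
    segregating sites; length share: region length over alignment length.
    """
    length = _check_aligned(sequences)
    seg = segregating_sites(sequences)
    if not seg:
        variant_share = 0.0
    else:
        inside = sum(1 for p in seg if start <= p <= end)
        variant_share = inside / len(seg)
    return variant_share, (end - start + 1) / length


def share_from_counts(n_region: int, n_total: int) -> float:
    if n_total == 0:
        raise ValueError("no segregating sites")
    return n_region / n_total
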