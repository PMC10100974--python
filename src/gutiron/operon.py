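"""hmu operon survey logic: homology calls, conservation patterns, synteny.

The six-gene heme-uptake operon *hmuYRSTUV* of Bacteroidetes genomes is
scored per genome as a 6-character string over {0, 1, 2} (absent /
present once / duplicated), ordered hmuY, R, S, T, U, V.  Homology is
called from global pairwise percent identity at a 30 % threshold, and
synteny is assessed from gene coordinates: colocalization on one contig
within a gap budget, with gene order matching the canonical operon
(forward or reverse).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HMU_GENES",
    "AA_ALPHABET",
    "ProteinSeq",
    "Alignment",
    "GeneLocus",
    "ConservationPattern",
    "SyntenyReport",
    "Hit",
    "global_align",
    "percent_identity",
    "detect_homologs",
    "conservation_pattern",
    "survey_genome",
    "tally_patterns",
    "check_synteny",
]

#: Canonical operon gene order.
HMU_GENES = ("hmuY", "hmuR", "hmuS", "hmuT", "hmuU", "hmuV")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class ProteinSeq:
    """An identified amino-acid sequence (20-letter alphabet plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if self.residues and not _VALID_RESIDUES.match(self.residues):
            bad = sorted(set(self.residues) - set(AA_ALPHABET + "X"))
            raise ValueError(f"invalid residues {bad} in sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment: two equal-length gapped strings + score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class GeneLocus:
    """One gene's coordinates, 1-based inclusive."""

    gene: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"malformed coordinates for {self.gene}: start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ConservationPattern:
    """Per-genome copy-number string over {0,1,2}, ordered hmuY..hmuV."""

    genome_id: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) != 6 or any(c not in "012" for c in self.pattern):
            raise ValueError(f"pattern must be 6 chars over {{0,1,2}}, got {self.pattern!r}")


@dataclass(frozen=True)
class SyntenyReport:
    genome_id: str
    colocalized: bool
    max_gap_bp: int
    order_preserved: bool
    observed_order: tuple[str, ...]


@dataclass(frozen=True)
class Hit:
    """A homology hit of a proteome member against a bait."""

    id: str
    identity: float


def global_align(
    a: ProteinSeq,
    b: ProteinSeq,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Needleman–Wunsch optimal global alignment with linear gap cost.

    Dynamic programming over the full (len(a)+1) × (len(b)+1) score
    lattice with traceback preference diagonal > up (gap in b) > left
    (gap in a), which makes the reported alignment deterministic among
    co-optimal ones.  The score is the unique DP optimum.
    """
    sa, sb = a.residues, b.residues
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    n, m = len(sa), len(sb)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        prev, cur = score[i - 1], score[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if sa[i - 1] == sb[j - 1] else mismatch)
            cur[j] = max(diag, prev[j] + gap, cur[j - 1] + gap)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (match if sa[i - 1] == sb[j - 1] else mismatch)
            if np.isclose(score[i, j], diag):
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    return Alignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score[n, m]),
    )


def percent_identity(alignment: Alignment) -> float:
    """100 × identical columns / alignment length (gaps count in the denominator)."""
    length = len(alignment.aligned_a)
    if length == 0:
        raise ValueError("zero-length alignment")
    ident = sum(
        1
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
        if x == y and x != "-"
    )
    return 100.0 * ident / length


def detect_homologs(
    bait: ProteinSeq, proteome: Sequence[ProteinSeq], threshold: float = 30.0
) -> list[Hit]:
    """All proteome members at ≥ threshold % global identity to the bait.

    Returned sorted by identity descending (id ascending on ties).  An
    empty proteome yields an empty hit list.
    """
    if not (0 < threshold <= 100):
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    hits = []
    for seq in proteome:
        ident = percent_identity(global_align(bait, seq))
        if ident >= threshold:
            hits.append(Hit(id=seq.id, identity=ident))
    return sorted(hits, key=lambda h: (-h.identity, h.id))


def conservation_pattern(
    genome_id: str, hits_per_bait: Sequence[Sequence[Hit]]
) -> ConservationPattern:
    """Score six bait searches (hmuY..hmuV order) as a 0/1/2 pattern string.

    0 = no hit, 1 = exactly one hit, 2 = two or more copies.
    """
    if len(hits_per_bait) != 6:
        raise ValueError(f"expected 6 bait results (hmuYRSTUV), got {len(hits_per_bait)}")
    chars = [("0" if not h else "1" if len(h) == 1 else "2") for h in hits_per_bait]
    return ConservationPattern(genome_id=genome_id, pattern="".join(chars))


def survey_genome(
    genome_id: str,
    baits: Mapping[str, ProteinSeq],
    proteome: Sequence[ProteinSeq],
    threshold: float = 30.0,
) -> ConservationPattern:
    """Run all six bait searches against one proteome and score the pattern."""
    missing = [g for g in HMU_GENES if g not in baits]
    if missing:
        raise ValueError(f"missing bait sequences for {missing}")
    hits = [detect_homologs(baits[g], proteome, threshold) for g in HMU_GENES]
    return conservation_pattern(genome_id, hits)


def tally_patterns(patterns: Sequence[ConservationPattern]) -> list[tuple[str, int]]:
    """Exact multiset counts of pattern strings, most frequent first."""
    counts = Counter(p.pattern for p in patterns)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def check_synteny(
    loci: Sequence[GeneLocus], max_gap_bp: int = 20000, genome_id: str = ""
) -> SyntenyReport:
    """Assess colocalization and gene-order conservation of hmu loci.

    Colocalized: all loci on one contig with every adjacent intergenic gap
    ≤ ``max_gap_bp``.  Order preserved: the genomic order of the present
    genes (by start coordinate) equals the canonical hmuYRSTUV order
    restricted to those genes, in either orientation (a reverse-strand
    operon reads back-to-front).  Duplicated genes break strict order.
    """
    if len(loci) < 2:
        raise ValueError(f"need at least 2 loci, got {len(loci)}")
    ordered = sorted(loci, key=lambda x: (x.contig, x.start))
    observed = tuple(x.gene for x in ordered)

    one_contig = len({x.contig for x in loci}) == 1
    max_gap = 0
    if one_contig:
        for prev, nxt in zip(ordered, ordered[1:]):
            max_gap = max(max_gap, nxt.start - prev.end - 1)
    colocalized = one_contig and max_gap <= max_gap_bp

    present = [g for g in HMU_GENES if g in observed]
    canonical = tuple(present)
    order_ok = observed == canonical or observed == canonical[::-1]
    return SyntenyReport(
        genome_id=genome_id,
        colocalized=colocalized,
        max_gap_bp=max_gap,
        order_preserved=order_ok,
        observed_order=observed,
    )
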