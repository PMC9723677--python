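"""Genome-bin quality scoring, ANI estimation and dereplication.

Quality of a metagenome-assembled genome (MAG) is scored as
``Q = completeness − 4 × contamination`` (both in percent); bins with
``Q > 40`` pass the inclusion filter. Redundant bins of the same strain are
identified by average nucleotide identity (ANI): pairs with ANI above 99%
are dereplicated keeping the higher-quality bin. ANI is estimated
alignment-free from canonical k-mer sets via the Mash distance
``D = -(1/k) ln(2J / (1 + J))`` with ``ANI = 100 (1 - D)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import Contig, revcomp

__all__ = [
    "QcRecord",
    "AniEstimate",
    "quality_score",
    "filter_by_quality",
    "estimate_ani",
    "dereplicate",
    "genome_stats",
]


@dataclass
class QcRecord:
    """Per-genome quality record; completeness/contamination in percent."""

    genome_id: str
    completeness: float
    contamination: float
    quality: float = field(init=False)
    gc: float | None = None
    size_bp: int | None = None

    def __post_init__(self) -> None:
        self.quality = quality_score(self.completeness, self.contamination)


def quality_score(completeness: float, contamination: float) -> float:
    """Q = completeness − 4 × contamination (percent; may be negative)."""
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValueError(f"contamination {contamination} negative")
    return completeness - 4.0 * contamination


def filter_by_quality(
    records: list[QcRecord], threshold: float = 40.0
) -> list[QcRecord]:
    """Keep records with quality strictly above the threshold."""
    return [r for r in records if r.quality > threshold]


# ---------------------------------------------------------------------------
# ANI


def _canonical_kmers(contigs: list[Contig], k: int) -> set[str]:
    kmers: set[str] = set()
    for contig in contigs:
        seq = contig.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            kmers.add(kmer if kmer <= rc else rc)
    return kmers


@dataclass
class AniEstimate:
    genome_a: str
    genome_b: str
    jaccard: float
    distance: float
    ani: float
    k: int
    unrelated: bool = False


def estimate_ani(
    genome_a: tuple[str, list[Contig]],
    genome_b: tuple[str, list[Contig]],
    k: int = 21,
) -> AniEstimate:
    """Estimate ANI between two genomes from canonical k-mer Jaccard.

    Strand-canonical k-mers make the estimate invariant to reverse
    complementation; identical genomes give ANI = 100. Disjoint k-mer sets
    (J = 0) are reported as ANI 0 with the ``unrelated`` flag.
    """
    id_a, contigs_a = genome_a
    id_b, contigs_b = genome_b
    for gid, contigs in ((id_a, contigs_a), (id_b, contigs_b)):
        size = sum(len(c) for c in contigs)
        if size < 10 * k:
            raise ValueError(f"genome {gid} shorter than {10 * k} bp")
    set_a = _canonical_kmers(contigs_a, k)
    set_b = _canonical_kmers(contigs_b, k)
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    j = inter / union if union else 0.0
    if j == 0.0:
        return AniEstimate(id_a, id_b, 0.0, math.inf, 0.0, k, unrelated=True)
    d = -(1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return AniEstimate(id_a, id_b, j, d, 100.0 * (1.0 - d), k)


# ---------------------------------------------------------------------------
# dereplication


def dereplicate(
    records: list[QcRecord],
    ani_pairs: dict[frozenset[str], float],
    ani_threshold: float = 99.0,
) -> tuple[list[QcRecord], dict[str, str]]:
    """Greedy best-quality-first dereplication.

    Records are visited by descending quality (ties: lexicographic id); one
    is kept iff its ANI to every already-kept genome is <= the threshold
    (the rule is strictly ">99%"), which guarantees the kept set is pairwise
    non-redundant. Returns the kept records and a discarded → representative
    map. A missing ANI value for a needed pair raises ``KeyError``.
    """
    order = sorted(records, key=lambda r: (-r.quality, r.genome_id))
    kept: list[QcRecord] = []
    discarded: dict[str, str] = {}
    for rec in order:
        rep = None
        for prev in kept:
            key = frozenset((rec.genome_id, prev.genome_id))
            if key not in ani_pairs:
                raise KeyError(
                    f"missing ANI for pair ({rec.genome_id}, {prev.genome_id})"
                )
            if ani_pairs[key] > ani_threshold:
                rep = prev.genome_id
                break
        if rep is None:
            kept.append(rec)
        else:
            discarded[rec.genome_id] = rep
    return kept, discarded


# ---------------------------------------------------------------------------
# basic stats


def genome_stats(contigs: list[Contig]) -> tuple[float | None, int]:
    """GC fraction (N excluded from the denominator) and total size in bp.

    Returns ``(None, size)`` when the genome has no non-N bases."""
    if not contigs:
        raise ValueError("at least one contig required")
    gc = at = n_total = 0
    for contig in contigs:
        seq = contig.seq
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        n_total += len(seq)
    if gc + at == 0:
        return None, n_total
    return gc / (gc + at), n_total
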