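"""Genomic interval sets and permutation-based overlap enrichment.

Implements the peak-level enrichment test used to ask whether ChIP-seq peak
sets (e.g. PRC2 or NuRD subunits) fall on G-quadruplex-forming regions more
often than chance: peaks are re-placed uniformly at random within their own
chromosome many times, the peak-overlap count is recorded each time, and an
add-one empirical p value compares the observed count with the null
distribution.

Coordinates are BED-convention throughout: 0-based, half-open ``[start,
end)``; book-ended intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import TableFormatError


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval; strand is optional and purely decorative."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise TableFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EnrichmentResult:
    """Observed overlap count, its permutation null, and the empirical p."""

    observed_overlap: int
    permuted_overlaps: np.ndarray
    n_perm: int
    empirical_p: float
    seed: int


def validate_genome(genome: Mapping[str, int]) -> dict[str, int]:
    g = {str(c): int(l) for c, l in genome.items()}
    for chrom, length in g.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
    return g


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ records; column 6, when present, is kept as the strand."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(f"BED line with fewer than 3 fields: {line!r}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chrom<TAB>length table."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, length = line.split()[:2]
            genome[chrom] = int(length)
    return validate_genome(genome)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    """Group to a (n, 2) start/end array per chromosome, sorted by start."""
    buckets: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for chrom, pairs in buckets.items()
    }


def merge_stranded_peaks(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of overlapping intervals, ignoring strand.

    Intervals sharing >= 1 bp are combined; book-ended intervals (half-open
    coordinates, zero overlap) stay separate.  Output is sorted and pairwise
    non-overlapping; idempotent.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        arr = _by_chrom([iv for iv in intervals if iv.chrom == chrom])[chrom]
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s < cur_e:  # strict: book-ended intervals are kept apart
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return merged


def _count_against(
    starts: np.ndarray, ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Count query intervals hitting a merged, sorted target set (vectorized).

    With the target non-overlapping and sorted, a query [s, e) overlaps some
    target iff the first target whose end exceeds s starts before e.
    """
    idx = np.searchsorted(b_ends, starts, side="right")
    inside = idx < len(b_starts)
    hits = np.zeros(len(starts), dtype=bool)
    hits[inside] = b_starts[idx[inside]] < ends[inside]
    return int(hits.sum())


def count_overlaps(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Number of intervals in ``a`` with >= 1 bp overlap with any interval in ``b``.

    Each ``a`` interval is counted at most once however many ``b`` intervals
    it touches, so the result never exceeds ``len(a)``.
    """
    if not a or not b:
        return 0
    b_merged = _by_chrom(merge_stranded_peaks(list(b)))
    total = 0
    for chrom, arr in _by_chrom(a).items():
        if chrom not in b_merged:
            continue
        tgt = b_merged[chrom]
        total += _count_against(arr[:, 0], arr[:, 1], tgt[:, 0], tgt[:, 1])
    return total


def permute_intervals(
    a: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Re-place every interval uniformly at random within its own chromosome.

    Lengths and per-chromosome counts are preserved; placed intervals may
    overlap each other.  Deterministic given the seed.
    """
    g = validate_genome(genome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[GenomicInterval] = []
    for iv in a:
        if iv.chrom not in g:
            raise ValueError(f"chromosome {iv.chrom!r} absent from genome table")
        room = g[iv.chrom] - iv.length
        if room < 0:
            raise ValueError(
                f"interval of length {iv.length} does not fit chromosome {iv.chrom}"
            )
        start = int(rng.integers(0, room + 1))
        out.append(GenomicInterval(iv.chrom, start, start + iv.length))
    return out


def permutation_enrichment(
    chip: Sequence[GenomicInterval],
    g4: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for overlap enrichment of ``chip`` peaks in ``g4`` peaks.

    The statistic is the number of chip peaks overlapping the (strand-merged)
    g4 set.  Under the null each chip peak is re-placed uniformly within its
    chromosome; the add-one empirical p is
    ``(1 + #{permutations >= observed}) / (1 + n_perm)``, never below
    ``1/(n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g = validate_genome(genome)
    observed = count_overlaps(chip, g4)
    g4_merged = _by_chrom(merge_stranded_peaks(list(g4)))
    # pre-group chip lengths per chromosome for vectorized re-placement
    length_lists: dict[str, list[int]] = {}
    for iv in chip:
        if iv.chrom not in g:
            raise ValueError(f"chromosome {iv.chrom!r} absent from genome table")
        if iv.length > g[iv.chrom]:
            raise ValueError(
                f"interval of length {iv.length} does not fit chromosome {iv.chrom}"
            )
        length_lists.setdefault(iv.chrom, []).append(iv.length)
    chip_by_chrom = {
        c: np.asarray(lengths, dtype=np.int64) for c, lengths in length_lists.items()
    }
    rng = np.random.default_rng(seed)
    permuted = np.zeros(n_perm, dtype=np.int64)
    for i in range(n_perm):
        count = 0
        for chrom, lengths in chip_by_chrom.items():
            starts = rng.integers(0, g[chrom] - lengths + 1)
            if chrom in g4_merged:
                tgt = g4_merged[chrom]
                count += _count_against(starts, starts + lengths, tgt[:, 0], tgt[:, 1])
        permuted[i] = count
    p = (1 + int((permuted >= observed).sum())) / (1 + n_perm)
    return EnrichmentResult(
        observed_overlap=observed,
        permuted_overlaps=permuted,
        n_perm=n_perm,
        empirical_p=p,
        seed=seed if isinstance(seed, int) else -1,
    )
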