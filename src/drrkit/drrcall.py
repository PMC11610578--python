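"""Differential reference region (DRR) calling.

A DRR is a segment of a template reference genome, strictly larger than the
configured minimum (default 10 kbp), that carries no alignment from a query
genome once known assembly gaps are excluded. The caller works on exact
per-base interval arithmetic: the union of aligned target intervals is
complemented against the sequence dictionary, assembly gaps are subtracted,
and the surviving segments are size-filtered. Gap subtraction happens before
size filtering, so a gap can split an uncovered run into two sub-threshold
pieces — this mirrors excluding gap regions from the coverage analysis
before regions are identified.

Multi-way comparisons ("which template bases are missing from every query")
are computed as exact Venn partitions over the per-query DRR interval sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .config import Config, DEFAULT_CONFIG
from .formats import AlignmentBlock, GenomicInterval, ValidationError

__all__ = [
    "IntervalSet",
    "DRRecord",
    "DRRSummary",
    "covered_intervals",
    "call_drrs",
    "summarize_drrs",
    "shared_missing",
]


# ---------------------------------------------------------------------------
# IntervalSet: sorted disjoint intervals per sequence
# ---------------------------------------------------------------------------

def _merge(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting (start, end) pairs into sorted disjoint runs."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    out = [pairs[0]]
    for s, e in pairs[1:]:
        ls, le = out[-1]
        if s <= le:
            if e > le:
                out[-1] = (ls, e)
        else:
            out.append((s, e))
    return out


@dataclass
class IntervalSet:
    """A set of genomic bases: per sequence, sorted disjoint half-open runs."""

    runs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        by_seq: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
        return cls({seq: _merge(pairs) for seq, pairs in by_seq.items()})

    def intervals(self) -> Iterator[GenomicInterval]:
        for seq in sorted(self.runs):
            for s, e in self.runs[seq]:
                yield GenomicInterval(seq, s, e)

    def total_bp(self) -> int:
        return sum(e - s for pairs in self.runs.values() for s, e in pairs)

    def is_empty(self) -> bool:
        return all(not pairs for pairs in self.runs.values())

    def union(self, other: "IntervalSet") -> "IntervalSet":
        seqs = set(self.runs) | set(other.runs)
        return IntervalSet(
            {
                seq: _merge(self.runs.get(seq, []) + other.runs.get(seq, []))
                for seq in seqs
            }
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for seq in set(self.runs) & set(other.runs):
            a, b = self.runs[seq], other.runs[seq]
            res: list[tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    res.append((s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[seq] = res
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for seq, a in self.runs.items():
            b = other.runs.get(seq, [])
            if not b:
                if a:
                    out[seq] = list(a)
                continue
            res: list[tuple[int, int]] = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j][1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k][0] < e:
                    bs, be = b[k]
                    if cur < bs:
                        res.append((cur, bs))
                    cur = max(cur, be)
                    if be >= e:
                        break
                    k += 1
                if cur < e:
                    res.append((cur, e))
            if res:
                out[seq] = res
        return IntervalSet(out)

    def complement(self, seq_lengths: Mapping[str, int]) -> "IntervalSet":
        """All bases of the sequence dictionary not in this set."""
        out: dict[str, list[tuple[int, int]]] = {}
        for seq, length in seq_lengths.items():
            pairs = self.runs.get(seq, [])
            res: list[tuple[int, int]] = []
            cur = 0
            for s, e in pairs:
                if e > length or s < 0:
                    raise ValidationError(
                        f"interval {seq}:{s}-{e} outside sequence length {length}"
                    )
                if cur < s:
                    res.append((cur, s))
                cur = max(cur, e)
            if cur < length:
                res.append((cur, length))
            if res:
                out[seq] = res
        return IntervalSet(out)

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Number of bases of ``iv`` covered by this set."""
        total = 0
        for s, e in self.runs.get(iv.seq_id, []):
            if s >= iv.end:
                break
            total += max(0, min(e, iv.end) - max(s, iv.start))
        return total

    def nearest_distance(self, iv: GenomicInterval) -> int | None:
        """Gap in bp to the nearest run on the same sequence (0 if overlapping)."""
        best: int | None = None
        for s, e in self.runs.get(iv.seq_id, []):
            if s < iv.end and iv.start < e:
                return 0
            d = s - iv.end if iv.end <= s else iv.start - e
            if best is None or d < best:
                best = d
        return best


# ---------------------------------------------------------------------------
# DRR records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DRRecord:
    """A called differential reference region on the template genome."""

    drr_id: str
    interval: GenomicInterval
    template_id: str
    query_id: str

    @property
    def size(self) -> int:
        return self.interval.size


@dataclass(frozen=True)
class DRRSummary:
    n_regions: int
    total_bp: int
    min_bp: int | None
    median_bp: int | None
    max_bp: int | None

    @property
    def total_mbp(self) -> float:
        return self.total_bp / 1e6


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def covered_intervals(
    blocks: Iterable[AlignmentBlock],
    min_mapq: int = 0,
    seq_lengths: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Union of template (target) intervals of alignment blocks with
    mapq >= ``min_mapq``. Strand is irrelevant: any aligned base is covered."""
    ivs = []
    for b in blocks:
        if b.mapq < min_mapq:
            continue
        if seq_lengths is not None:
            length = seq_lengths.get(b.target_id)
            if length is None:
                raise ValidationError(f"unknown target sequence {b.target_id!r}")
            if b.target_end > length:
                raise ValidationError(
                    f"block {b.target_id}:{b.target_start}-{b.target_end} "
                    f"exceeds sequence length {length}"
                )
        ivs.append(b.target_interval)
    return IntervalSet.from_intervals(ivs)


def call_drrs(
    covered: IntervalSet,
    seq_lengths: Mapping[str, int],
    gaps: IntervalSet | None = None,
    cfg: Config = DEFAULT_CONFIG,
    template_id: str = "template",
    query_id: str = "query",
) -> list[DRRecord]:
    """Call DRRs: complement of coverage, minus assembly gaps, size-filtered.

    Returns records sorted by (sequence, start) with deterministic ids
    ``DRR_<seq>_<start>``. The size filter is strict: a segment must be
    larger than ``cfg.min_drr_size``.
    """
    gaps = gaps or IntervalSet()
    for iv in gaps.intervals():
        length = seq_lengths.get(iv.seq_id)
        if length is None or iv.end > length:
            raise ValidationError(
                f"gap {iv.seq_id}:{iv.start}-{iv.end} outside sequence bounds"
            )
    uncovered = covered.complement(seq_lengths)
    candidate = uncovered.subtract(gaps)
    out = [
        DRRecord(
            drr_id=f"DRR_{iv.seq_id}_{iv.start}",
            interval=iv,
            template_id=template_id,
            query_id=query_id,
        )
        for iv in candidate.intervals()
        if iv.size > cfg.min_drr_size
    ]
    return out


def summarize_drrs(drrs: Iterable[DRRecord]) -> DRRSummary:
    """Count / total / min / median / max of DRR sizes.

    The median is the lower of the two central values for even counts, so it
    is always an observed size. An empty input yields zeros with undefined
    (None) order statistics.
    """
    sizes = sorted(d.size for d in drrs)
    n = len(sizes)
    if n == 0:
        return DRRSummary(0, 0, None, None, None)
    return DRRSummary(
        n_regions=n,
        total_bp=sum(sizes),
        min_bp=sizes[0],
        median_bp=sizes[(n - 1) // 2],
        max_bp=sizes[-1],
    )


def shared_missing(
    drr_sets: Mapping[str, IntervalSet],
) -> tuple[IntervalSet, dict[frozenset[str], int]]:
    """Multi-way overlap of per-query DRR sets on one template.

    Returns the intersection (template bases missing from *every* query) and
    the exclusive Venn partition sizes in bp, keyed by the subset of queries
    each region of the template is missing from. Partition sizes sum to the
    size of the union of all sets.
    """
    if len(drr_sets) < 2:
        raise ValueError("shared_missing requires at least two query DRR sets")
    names = sorted(drr_sets)
    partitions: dict[frozenset[str], int] = {}
    seqs = set()
    for s in drr_sets.values():
        seqs |= set(s.runs)
    for seq in seqs:
        bounds: set[int] = set()
        for s in drr_sets.values():
            for a, b in s.runs.get(seq, []):
                bounds.add(a)
                bounds.add(b)
        edges = sorted(bounds)
        for a, b in zip(edges, edges[1:]):
            members = frozenset(
                q
                for q in names
                if any(s <= a and b <= e for s, e in drr_sets[q].runs.get(seq, []))
            )
            if members:
                partitions[members] = partitions.get(members, 0) + (b - a)
    inter = drr_sets[names[0]]
    for q in names[1:]:
        inter = inter.intersect(drr_sets[q])
    return inter, partitions


def drrs_to_interval_set(drrs: Iterable[DRRecord]) -> IntervalSet:
    return IntervalSet.from_intervals(d.interval for d in drrs)
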