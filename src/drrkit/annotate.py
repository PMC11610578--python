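"""Repeat and genomic-context annotation of DRRs.

Each DRR is intersected with RepeatMasker features to yield per-class and
total repeat fractions (the union of all features governs the total, so
overlapping annotations never push it above 1), and flagged for centromere
proximity and segmental-duplication overlap. A cohort-level report buckets
the annotated regions: share fully repetitive, share near a centromere,
share inside a segmental duplication, and a decile histogram of repeat
fraction.

All fractions come from exact integer base counts; "100% repetitive" means
the repeat union tiles every base of the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .config import Config, DEFAULT_CONFIG
from .drrcall import DRRecord, IntervalSet
from .formats import REPEAT_CLASSES, RepeatFeature

__all__ = [
    "RepeatComposition",
    "ContextFlags",
    "repeat_composition",
    "context_flags",
    "bucket_report",
]


@dataclass(frozen=True)
class RepeatComposition:
    """Fraction of a DRR's bases covered by each repeat class and by any repeat."""

    class_fractions: dict[str, float] = field(default_factory=dict)
    total_repeat_fraction: float = 0.0

    @property
    def unmasked_fraction(self) -> float:
        return 1.0 - self.total_repeat_fraction

    @property
    def fully_repetitive(self) -> bool:
        return self.total_repeat_fraction == 1.0


@dataclass(frozen=True)
class ContextFlags:
    fully_repetitive: bool
    near_centromere: bool
    in_segdup: bool


def repeat_composition(
    drr: DRRecord, repeats: Sequence[RepeatFeature]
) -> RepeatComposition:
    """Per-class and total repeat fractions of a DRR.

    Per-class fractions use the union of that class's features; the total uses
    the union across all classes, so classes may overlap and per-class
    fractions can sum to more than the total. Integer bp arithmetic: a DRR is
    fully repetitive only if repeat features tile every base.
    """
    size = drr.size
    overlapping = [r for r in repeats if r.interval.overlaps(drr.interval)]
    class_fractions: dict[str, float] = {}
    for klass in REPEAT_CLASSES:
        members = [r.interval for r in overlapping if r.repeat_class == klass]
        if not members:
            continue
        bp = IntervalSet.from_intervals(members).overlap_bp(drr.interval)
        if bp:
            class_fractions[klass] = bp / size
    total_bp = IntervalSet.from_intervals(
        r.interval for r in overlapping
    ).overlap_bp(drr.interval)
    return RepeatComposition(
        class_fractions=class_fractions,
        total_repeat_fraction=total_bp / size,
    )


def context_flags(
    drr: DRRecord,
    composition: RepeatComposition,
    centromeres: IntervalSet,
    segdups: IntervalSet,
    cfg: Config = DEFAULT_CONFIG,
) -> ContextFlags:
    """Centromere proximity (within ``cfg.context_window`` bp, overlap counts
    as distance 0), segmental-duplication overlap (>=1 bp), and full
    repetitiveness (exact tiling)."""
    d = centromeres.nearest_distance(drr.interval)
    near_cen = d is not None and d <= cfg.context_window
    in_sd = segdups.overlap_bp(drr.interval) >= 1
    return ContextFlags(
        fully_repetitive=composition.fully_repetitive,
        near_centromere=near_cen,
        in_segdup=in_sd,
    )


def bucket_report(
    drrs: Sequence[DRRecord],
    compositions: Sequence[RepeatComposition],
    flags: Sequence[ContextFlags],
) -> pd.DataFrame:
    """Cohort summary of annotated DRRs.

    One row per statistic: shares of regions that are fully repetitive, near a
    centromere, or inside a segmental duplication, followed by a decile
    histogram of total repeat fraction (counts; the deciles sum to the number
    of regions, with fraction 1.0 counted in the top decile).
    """
    if not (len(drrs) == len(compositions) == len(flags)):
        raise ValueError("drrs, compositions and flags must align")
    n = len(drrs)
    if n == 0:
        return pd.DataFrame(columns=["statistic", "value"])
    rows: list[tuple[str, float]] = [
        ("n_regions", float(n)),
        ("share_fully_repetitive", sum(f.fully_repetitive for f in flags) / n),
        ("share_near_centromere", sum(f.near_centromere for f in flags) / n),
        ("share_in_segdup", sum(f.in_segdup for f in flags) / n),
    ]
    decile_counts = [0] * 10
    for comp in compositions:
        idx = min(int(comp.total_repeat_fraction * 10), 9)
        decile_counts[idx] += 1
    for i, count in enumerate(decile_counts):
        rows.append((f"repeat_frac_decile_{i * 10}_{(i + 1) * 10}", float(count)))
    return pd.DataFrame(rows, columns=["statistic", "value"])


def annotate_drrs(
    drrs: Sequence[DRRecord],
    repeats: Sequence[RepeatFeature],
    centromeres: Iterable | None = None,
    segdups: Iterable | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Convenience: one annotated row per DRR (used by the CLI)."""
    cen = (
        centromeres
        if isinstance(centromeres, IntervalSet)
        else IntervalSet.from_intervals(centromeres or [])
    )
    sd = (
        segdups
        if isinstance(segdups, IntervalSet)
        else IntervalSet.from_intervals(segdups or [])
    )
    rows = []
    for drr in drrs:
        comp = repeat_composition(drr, repeats)
        fl = context_flags(drr, comp, cen, sd, cfg)
        row = {
            "drr_id": drr.drr_id,
            "seq_id": drr.interval.seq_id,
            "start": drr.interval.start,
            "end": drr.interval.end,
            "size_bp": drr.size,
            "total_repeat_fraction": comp.total_repeat_fraction,
            "unmasked_fraction": comp.unmasked_fraction,
            "fully_repetitive": fl.fully_repetitive,
            "near_centromere": fl.near_centromere,
            "in_segdup": fl.in_segdup,
        }
        for klass in REPEAT_CLASSES:
            row[f"frac_{klass}"] = comp.class_fractions.get(klass, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
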