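"""Population presence of DRRs from short-read depth, plus read-mapping summaries.

Per sample, the length-weighted mean depth across a DRR decides its status:
depth strictly between the lower (8x) and upper (100x) bounds supports one or
more genomic copies being present; depth at or below the lower bound means the
sequence is absent from that genome; depth at or above the upper bound flags a
collapsed repeat and the region is not called for that sample. Per cohort,
the fraction of present samples (over *all* samples, no_call included in the
denominator) classifies a DRR as not_detected (zero present), rare (<=5%) or
common (>5%), with a high-frequency flag above 90%.

Mapping summaries report, per DRR, the fraction of overlapping primary reads
with mapping quality strictly above the threshold and the fraction that are
multimapping (aligned to more than one location).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import Config, DEFAULT_CONFIG
from .drrcall import DRRecord
from .formats import DepthTrack, ReadRecord

__all__ = [
    "PresenceCall",
    "PopulationClass",
    "MappingSummary",
    "mean_depth",
    "classify_presence",
    "population_class",
    "mapping_summary",
]

PRESENT = "present"
ABSENT = "absent"
NO_CALL = "no_call"


@dataclass(frozen=True)
class PresenceCall:
    sample_id: str
    drr_id: str
    mean_depth: float
    status: str


@dataclass(frozen=True)
class PopulationClass:
    drr_id: str
    n_present: int
    n_total: int
    presence_frac: float
    population_class: str  # not_detected | rare | common
    high_frequency: bool


@dataclass(frozen=True)
class MappingSummary:
    drr_id: str
    n_reads: int
    frac_mapq_gt_threshold: float | None
    frac_multimapping: float | None

    @property
    def defined(self) -> bool:
        return self.n_reads > 0


def mean_depth(drr: DRRecord, track: DepthTrack) -> float:
    """Length-weighted mean depth of the track over the DRR interval.

    Template bases with no depth step count as depth 0, so a sparse track
    over part of a DRR dilutes its mean.
    """
    iv = drr.interval
    total = 0.0
    for step_iv, depth in track.steps:
        if step_iv.seq_id != iv.seq_id:
            continue
        ov = step_iv.overlap_bp(iv)
        if ov:
            total += depth * ov
    return total / iv.size


def classify_presence(depth: float, cfg: Config = DEFAULT_CONFIG) -> str:
    """Present iff lo < depth < hi; absent iff depth <= lo; no_call iff depth >= hi."""
    if depth >= cfg.presence_hi:
        return NO_CALL
    if depth <= cfg.presence_lo:
        return ABSENT
    return PRESENT


def call_presence(
    drr: DRRecord, track: DepthTrack, cfg: Config = DEFAULT_CONFIG
) -> PresenceCall:
    d = mean_depth(drr, track)
    return PresenceCall(track.sample_id, drr.drr_id, d, classify_presence(d, cfg))


def population_class(
    calls: Sequence[PresenceCall], cfg: Config = DEFAULT_CONFIG
) -> PopulationClass:
    """Cohort class from per-sample calls for one DRR.

    no_call samples stay in the denominator: the presence fraction is
    n_present over the full cohort size.
    """
    if not calls:
        raise ValueError("population_class requires at least one presence call")
    drr_ids = {c.drr_id for c in calls}
    if len(drr_ids) != 1:
        raise ValueError(f"calls span multiple DRRs: {sorted(drr_ids)}")
    n_total = len(calls)
    n_present = sum(c.status == PRESENT for c in calls)
    frac = n_present / n_total
    if n_present == 0:
        klass = "not_detected"
    elif frac <= cfg.common_frac:
        klass = "rare"
    else:
        klass = "common"
    return PopulationClass(
        drr_id=calls[0].drr_id,
        n_present=n_present,
        n_total=n_total,
        presence_frac=frac,
        population_class=klass,
        high_frequency=frac > cfg.high_frac,
    )


def mapping_summary(
    drr: DRRecord, reads: Iterable[ReadRecord], cfg: Config = DEFAULT_CONFIG
) -> MappingSummary:
    """Mapping-quality and multimapping fractions over reads spanning a DRR.

    Supplementary records are excluded; a read counts if its primary interval
    overlaps the DRR by at least one base. With zero overlapping reads the
    fractions are undefined (None) and ``defined`` is False.
    """
    hits = [
        r
        for r in reads
        if not r.is_supplementary and r.interval.overlaps(drr.interval)
    ]
    n = len(hits)
    if n == 0:
        return MappingSummary(drr.drr_id, 0, None, None)
    return MappingSummary(
        drr_id=drr.drr_id,
        n_reads=n,
        frac_mapq_gt_threshold=sum(r.mapq > cfg.mapq_threshold for r in hits) / n,
        frac_multimapping=sum(r.is_multimapping for r in hits) / n,
    )
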