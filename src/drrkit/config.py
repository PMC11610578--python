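"""Pipeline-wide thresholds, collected in one dataclass.

Defaults encode the published analysis conditions: DRRs are uncovered template
regions strictly larger than 10 kbp after assembly-gap exclusion; a region
counts as present in a short-read sample when its mean depth lies strictly
between 8x and 100x (above 100x indicates a collapsed repeat and is not
called); a region is common in the cohort above 5% presence and
high-frequency above 90%; read mapping quality is summarized against a
threshold of 20; centromere proximity uses a 10 kbp window. Junction-level
thresholds drive the repair-mechanism cascade: >=2 bp of microhomology points
to microhomology-mediated end joining, a junction unbalance of >=100 bp or
>=3 junctions to replicative (MMBIR-like) mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Config:
    # DRR calling
    min_drr_size: int = 10_000          # bp, strict >
    min_mapq_for_coverage: int = 0      # alignment blocks below this are ignored

    # per-sample presence from depth
    presence_lo: float = 8.0            # x; depth <= lo -> absent
    presence_hi: float = 100.0          # x; depth >= hi -> no_call (collapsed repeat)

    # cohort classification
    common_frac: float = 0.05           # presence fraction above which a DRR is common
    high_frac: float = 0.90             # presence fraction above which it is high-frequency

    # read summaries
    mapq_threshold: int = 20            # fraction of reads with mapq strictly above this

    # genomic context
    context_window: int = 10_000        # bp to a centromere to count as "near"

    # junction mechanism cascade
    mmej_min_mh: int = 2                # bp microhomology for MMEJ
    mmbir_unbalance: int = 100          # bp junction indel magnitude for MMBIR
    complex_min_junctions: int = 3      # junction count for complex MMBIR
    nahr_min_identity: float = 0.95     # paralog identity for NAHR
    min_anchor: int = 15                # bp exact anchor required on each flank

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.presence_lo < self.presence_hi:
            raise ValueError("presence_lo must be < presence_hi")
        if not 0 < self.common_frac < self.high_frac < 1:
            raise ValueError("need 0 < common_frac < high_frac < 1")
        if self.min_drr_size < 0:
            raise ValueError("min_drr_size must be >= 0")


DEFAULT_CONFIG = Config()
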