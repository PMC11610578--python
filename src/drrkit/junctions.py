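"""Breakpoint-junction resolution and DSB-repair mechanism inference.

A rearrangement junction joins two reference locations; the derivative
sequence spanning it either overlaps both reference flanks by a short
identical stretch (microhomology), carries extra bases present in neither
flank (an insertion, templated from nearby reference sequence or random), or
joins them bluntly. Given the derivative and the two flanks — flank A as the
reference sequence ending at the A-side breakpoint, flank B beginning at the
B-side breakpoint, both oriented 5'->3' exactly as they appear in the
derivative (the caller reverse-complements flank B for inverted segments) —
resolution is pure exact string matching:

* ``a_end``  = length of the longest derivative prefix equal to a suffix of
  flank A (the maximal exact extension from the A side);
* ``b_start`` = derivative offset of the longest derivative suffix equal to a
  prefix of flank B.

``b_start < a_end`` yields microhomology ``derivative[b_start:a_end]``;
``b_start > a_end`` an insertion ``derivative[a_end:b_start]``; equality a
blunt joint. Microhomology and insertion are therefore mutually exclusive by
construction. Ties in breakpoint placement under microhomology are resolved
by reporting the leftmost (maximally A-extended) placement.

Mechanism inference is a rule cascade over the resolved junctions of one
rearrangement: NAHR when both breakpoints of a junction fall in same-family
repeats of sufficient paralog identity; complex MMBIR at three or more
junctions; MMBIR when any junction shows a large (>=100 bp) indel unbalance;
MMEJ at >=2 bp microhomology; otherwise NHEJ. Insertions of the sizes seen at
non-replicative junctions (up to ~90 nt, random or templated) do not by
themselves imply a replicative mechanism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .config import Config, DEFAULT_CONFIG
from .formats import RepeatFeature

__all__ = [
    "JunctionInput",
    "JunctionCall",
    "RearrangementCall",
    "JunctionResolutionError",
    "AmbiguousAnchorError",
    "resolve_junction",
    "classify_insertion",
    "junction_indels",
    "inversion_span",
    "infer_mechanism",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = re.compile(r"^[ACGTN]+$")

NHEJ = "NHEJ"
MMEJ = "MMEJ"
MMBIR = "MMBIR"
COMPLEX_MMBIR = "complex_MMBIR"
NAHR = "NAHR"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class JunctionResolutionError(ValueError):
    """The derivative could not be anchored to a flank."""


class AmbiguousAnchorError(JunctionResolutionError):
    """The outer anchor matches the flank at several positions."""

    def __init__(self, side: str, candidates: list[int]):
        self.side = side
        self.candidates = candidates
        super().__init__(
            f"anchor on side {side} places ambiguously at offsets {candidates}"
        )


@dataclass(frozen=True)
class JunctionInput:
    """One junction: derivative sequence plus oriented reference flanks.

    ``pos_a``/``pos_b`` are 1-based reference breakpoint coordinates (the
    convention of breakpoint tables); ``strand_b`` records the orientation of
    the B segment in the derivative ("-" for an inverted segment, whose flank
    the caller has already reverse-complemented).
    """

    derivative_seq: str
    flank_a: str
    flank_b: str
    pos_a: int = 0
    pos_b: int = 0
    strand_b: str = "+"

    def __post_init__(self) -> None:
        for label, seq in (
            ("derivative_seq", self.derivative_seq),
            ("flank_a", self.flank_a),
            ("flank_b", self.flank_b),
        ):
            if not seq or not _VALID.match(seq.upper()):
                raise ValueError(f"{label} must be a non-empty ACGTN string")


@dataclass(frozen=True)
class JunctionCall:
    """Resolved junction: microhomology XOR insertion (blunt = neither)."""

    microhomology_len: int
    microhomology_seq: str
    insertion_len: int
    insertion_seq: str
    insertion_kind: str  # none | templated | random | unclassified
    anchor_a_len: int
    anchor_b_len: int
    pos_a: int = 0
    pos_b: int = 0

    def __post_init__(self) -> None:
        if self.microhomology_len > 0 and self.insertion_len > 0:
            raise ValueError("microhomology and insertion are mutually exclusive")


@dataclass
class RearrangementCall:
    """A rearrangement (e.g. an inversion) as its resolved junctions plus
    derived quantities."""

    junctions: list[JunctionCall]
    side_indels: dict[str, int] = field(default_factory=dict)  # side -> signed bp
    span_bp: int = 0
    span_mbp_rounded: int = 0
    chrom_fraction: float = 0.0
    mechanism: str | None = None


# ---------------------------------------------------------------------------
# Junction resolution
# ---------------------------------------------------------------------------

def _check_anchor_unique(anchor: str, flank: str, side: str) -> None:
    hits = [m.start() for m in re.finditer(f"(?={re.escape(anchor)})", flank)]
    if not hits:
        raise JunctionResolutionError(
            f"anchor on side {side} ({anchor[:20]}...) not found in flank"
        )
    if len(hits) > 1:
        raise AmbiguousAnchorError(side, hits)


def resolve_junction(j: JunctionInput, min_anchor: int = 15) -> JunctionCall:
    """Resolve microhomology/insertion at a junction by maximal exact extension.

    Requires an exact, unique anchor of at least ``min_anchor`` bp at the
    outer end of each flank; failure raises :class:`JunctionResolutionError`,
    ambiguity :class:`AmbiguousAnchorError` listing the candidate offsets.
    """
    der = j.derivative_seq.upper()
    fa = j.flank_a.upper()
    fb = j.flank_b.upper()
    if len(der) < 2 * min_anchor:
        raise JunctionResolutionError(
            f"derivative shorter than twice the anchor ({len(der)} < {2 * min_anchor})"
        )
    _check_anchor_unique(der[:min_anchor], fa, "A")
    _check_anchor_unique(der[-min_anchor:], fb, "B")

    # a_end: longest derivative prefix equal to a flank-A suffix
    a_end = 0
    for k in range(min(len(der), len(fa)), 0, -1):
        if der[:k] == fa[-k:]:
            a_end = k
            break
    # b_start: longest derivative suffix equal to a flank-B prefix
    m = 0
    for k in range(min(len(der), len(fb)), 0, -1):
        if der[-k:] == fb[:k]:
            m = k
            break
    b_start = len(der) - m
    if a_end < min_anchor:
        raise JunctionResolutionError(
            f"A-side extension ({a_end} bp) below the {min_anchor} bp anchor"
        )
    if m < min_anchor:
        raise JunctionResolutionError(
            f"B-side extension ({m} bp) below the {min_anchor} bp anchor"
        )

    if b_start < a_end:
        mh = der[b_start:a_end]
        call = JunctionCall(
            microhomology_len=len(mh),
            microhomology_seq=mh,
            insertion_len=0,
            insertion_seq="",
            insertion_kind="none",
            anchor_a_len=a_end,
            anchor_b_len=m,
            pos_a=j.pos_a,
            pos_b=j.pos_b,
        )
    elif b_start > a_end:
        ins = der[a_end:b_start]
        call = JunctionCall(
            microhomology_len=0,
            microhomology_seq="",
            insertion_len=len(ins),
            insertion_seq=ins,
            insertion_kind="unclassified",
            anchor_a_len=a_end,
            anchor_b_len=m,
            pos_a=j.pos_a,
            pos_b=j.pos_b,
        )
    else:
        call = JunctionCall(0, "", 0, "", "none", a_end, m, j.pos_a, j.pos_b)
    assert not (call.microhomology_len > 0 and call.insertion_len > 0)
    return call


def classify_insertion(
    insertion_seq: str,
    reference_window_seqs: Sequence[str],
    min_identity: float = 0.90,
) -> str:
    """Label junction-inserted bases as templated or random.

    Templated means the full insertion, or its reverse complement, occurs in
    at least one of the reference windows around the breakpoints — exactly,
    or at >= ``min_identity`` identity over its full length (edit-distance
    search). Otherwise the insertion is random.
    """
    if not insertion_seq:
        raise ValueError("classify_insertion requires a non-empty insertion")
    windows = [w.upper() for w in reference_window_seqs if w]
    if not windows:
        raise ValueError("classify_insertion requires at least one reference window")
    ins = insertion_seq.upper()
    queries = [ins, revcomp(ins)]
    for w in windows:
        for q in queries:
            if q in w:
                return "templated"
    max_dist = int(len(ins) * (1.0 - min_identity))
    if max_dist > 0:
        for w in windows:
            for q in queries:
                res = edlib.align(q, w, mode="HW", task="distance", k=max_dist)
                if res["editDistance"] != -1:
                    return "templated"
    return "random"


# ---------------------------------------------------------------------------
# Junction geometry
# ---------------------------------------------------------------------------

def junction_indels(
    j1_coords: tuple[int, int],
    j2_coords: tuple[int, int],
    microhomologies: tuple[int, int] = (0, 0),
    orientation: str = "-",
) -> dict[str, int]:
    """Signed per-side indels of a two-junction rearrangement.

    Coordinates are 1-based breakpoint positions ``(pos_a, pos_b)`` per
    junction, already left-aligned under microhomology (the convention
    :func:`resolve_junction` reports). Per side, with first-junction
    coordinate ``c1`` and second-junction coordinate ``c2``, the signed indel
    is ``-(c2 - c1 - 1)``: bases strictly between adjacent breakpoints belong
    to neither derivative segment (a deletion, negative), while breakpoints
    that overshoot each other duplicate the overlapped bases in both segments
    (positive). Adjacent coordinates (``c2 == c1 + 1``) give a clean joint.
    """
    if orientation not in "+-":
        raise ValueError(f"bad orientation {orientation!r}")
    a1, b1 = j1_coords
    a2, b2 = j2_coords
    del microhomologies  # already folded into left-aligned coordinates
    return {
        "A": -(a2 - a1 - 1),
        "B": -(b2 - b1 - 1),
    }


def inversion_span(
    pos_a: int, pos_b: int, chrom_length: int
) -> tuple[int, int, float]:
    """Span of an inversion from its two breakpoints.

    Returns (span in bp, span in Mbp rounded half away from zero, fraction of
    the chromosome). Positions are 1-based, on one chromosome.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if pos_a == pos_b:
        raise ValueError("breakpoints coincide")
    span = abs(pos_b - pos_a)
    mbp = int(span / 1e6 + 0.5)  # spans are positive: +0.5 rounds half away from zero
    return span, mbp, span / chrom_length


# ---------------------------------------------------------------------------
# Mechanism inference
# ---------------------------------------------------------------------------

def infer_mechanism(
    r: RearrangementCall,
    repeat_context: Sequence[tuple[RepeatFeature | None, RepeatFeature | None, float]]
    | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> str:
    """Classify the likely formation mechanism of a rearrangement.

    Rule cascade, first match wins:

    1. NAHR — some junction has both breakpoints inside same-family repeats
       with paralog identity >= ``cfg.nahr_min_identity``;
    2. complex MMBIR — >= ``cfg.complex_min_junctions`` junctions;
    3. MMBIR — any side indel with magnitude >= ``cfg.mmbir_unbalance`` bp;
    4. MMEJ — maximal junction microhomology >= ``cfg.mmej_min_mh`` bp;
    5. NHEJ otherwise.

    ``repeat_context`` optionally supplies, per junction, the repeat features
    at each breakpoint and their pairwise identity.
    """
    if any(j.insertion_len > 0 and j.insertion_kind == "unclassified" for j in r.junctions):
        raise ValueError("classify insertions before inferring the mechanism")
    if not r.junctions:
        raise ValueError("rearrangement has no resolved junctions")

    if repeat_context:
        for rep_a, rep_b, identity in repeat_context:
            if (
                rep_a is not None
                and rep_b is not None
                and rep_a.repeat_name == rep_b.repeat_name
                and identity >= cfg.nahr_min_identity
            ):
                return NAHR
    if len(r.junctions) >= cfg.complex_min_junctions:
        return COMPLEX_MMBIR
    if any(abs(v) >= cfg.mmbir_unbalance for v in r.side_indels.values()):
        return MMBIR
    max_mh = max(j.microhomology_len for j in r.junctions)
    if max_mh >= cfg.mmej_min_mh:
        return MMEJ
    return NHEJ
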