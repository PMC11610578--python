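"""Synthetic inputs with known truth for every pipeline stage.

The generator emulates the study conditions end to end without any download:

* a template/query reference pair differing only by implanted segments larger
  than 10 kbp (the query is the template with those segments deleted), with
  tandem-repeat arrays inside the implants at a configurable repeat fraction,
  assembly-gap N-runs in the shared sequence, and an identity PAF whose
  blocks tile exactly the shared, non-gap sequence;
* a short-read depth panel over the implanted regions: per sample and region
  a presence genotype drawn at a per-region allele frequency, with 100-bp
  BedGraph steps drawn Poisson around ~30x (present), ~1x (absent) or >100x
  (collapsed repeat), plus per-read SAM-style summaries carrying the
  configured multimapping fraction (~1.3%) and mapping-quality mix (~20%
  above MAPQ 20);
* derivative junction sequences with engineered microhomology or insertions
  (templated from a breakpoint window, possibly reverse-complemented, or
  random).

Every stream derives from one integer seed; identical configurations emit
byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .drrcall import IntervalSet
from .formats import (
    AlignmentBlock,
    DepthTrack,
    GenomicInterval,
    ReadRecord,
    RepeatFeature,
    write_bed,
    write_depth_bedgraph,
    write_paf,
)
from .junctions import JunctionInput, revcomp

__all__ = [
    "SimConfig",
    "ReferencePairSim",
    "DepthPanelSim",
    "JunctionSim",
    "TruthSet",
    "simulate_reference_pair",
    "emit_truth_paf",
    "simulate_depth_panel",
    "simulate_junction",
    "write_reference_pair",
    "write_depth_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # reference pair
    n_chroms: int = 2
    chrom_len: int = 300_000
    n_drrs: int = 3
    drr_size_range: tuple[int, int] = (12_000, 20_000)
    drr_repeat_fraction_range: tuple[float, float] = (0.3, 1.0)
    n_gaps_per_chrom: int = 1
    gap_len: int = 2_000
    gc: float = 0.41
    # depth panel
    n_samples: int = 50
    depth_present_mean: float = 30.0
    depth_absent_mean: float = 1.0
    depth_collapsed_mean: float = 150.0
    collapsed_frac: float = 0.0
    presence_allele_freq_range: tuple[float, float] = (0.1, 0.9)
    depth_step: int = 100
    n_read_samples: int = 5
    reads_per_drr: int = 40
    read_len: int = 150
    multimap_frac: float = 0.013
    mapq_gt20_frac: float = 0.20
    # junctions
    flank_len: int = 150
    window_len: int = 1_000
    mh_range: tuple[int, int] = (0, 10)
    ins_range: tuple[int, int] = (0, 50)
    templated_prob: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.drr_size_range
        if not 0 < lo <= hi:
            raise ValueError("bad drr_size_range")
        flo, fhi = self.drr_repeat_fraction_range
        if not 0 <= flo <= fhi <= 1:
            raise ValueError("bad drr_repeat_fraction_range")
        if self.n_chroms < 1 or self.chrom_len < 1:
            raise ValueError("need at least one chromosome of positive length")


@dataclass
class ReferencePairSim:
    template: dict[str, str]
    query: dict[str, str]
    truth: list[GenomicInterval]          # implanted segments, template coords
    gaps: list[GenomicInterval]           # N-runs shared by both genomes
    repeats: list[RepeatFeature]          # RepeatMasker-style implant annotation
    template_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.template_lengths:
            self.template_lengths = {k: len(v) for k, v in self.template.items()}


@dataclass
class DepthPanelSim:
    tracks: list[DepthTrack]
    genotypes: np.ndarray                 # (n_samples, n_drrs): 0 absent, 1 present, 2 collapsed
    drr_ids: list[str]
    allele_freqs: np.ndarray              # per DRR
    reads: dict[str, list[ReadRecord]]    # sample_id -> read summaries
    seq_lengths: dict[str, int]


@dataclass
class JunctionSim:
    junction: JunctionInput
    windows: list[str]                    # reference windows around both breakpoints
    mh_len: int
    ins_len: int
    ins_kind: str                         # none | templated | random
    ins_seq: str


@dataclass
class TruthSet:
    """Bundle of the truth records matching one simulated input set."""

    drr_intervals: list[GenomicInterval] = field(default_factory=list)
    genotypes: np.ndarray | None = None
    junctions: list[JunctionSim] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _place_segments(
    rng: np.random.Generator, chrom_len: int, sizes: list[int], margin: int
) -> list[int]:
    """Deterministic non-overlapping placement: segments in order, separated
    (and offset from chromosome ends) by at least ``margin``, with the slack
    distributed uniformly at random."""
    n = len(sizes)
    occupied = sum(sizes) + (n + 1) * margin
    slack = chrom_len - occupied
    if slack < 0:
        raise ValueError(
            f"cannot pack {sum(sizes)} bp of segments into {chrom_len} bp chromosome"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    starts = []
    cursor = margin
    for i, size in enumerate(sizes):
        start = cursor + int(cuts[i]) - (int(cuts[i - 1]) if i else 0)
        # re-derive cumulatively so segments stay ordered and spaced
        starts.append(start)
        cursor = start + size + margin
    return starts


def simulate_reference_pair(cfg: SimConfig) -> ReferencePairSim:
    """Template/query genome pair differing by implanted segments.

    The query equals the template with the implanted (truth) segments
    deleted. Implants carry a tandem-repeat array covering the configured
    repeat fraction of their length, recorded as RepeatMasker-style simple
    repeats; N-run assembly gaps are placed in the shared sequence and
    recorded in the gap list. Total implant size must stay below half the
    genome.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.drr_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_drrs)]
    if sum(sizes) >= cfg.n_chroms * cfg.chrom_len / 2:
        raise ValueError("implanted segments exceed half the genome; infeasible packing")

    template: dict[str, str] = {}
    query: dict[str, str] = {}
    truth: list[GenomicInterval] = []
    gaps: list[GenomicInterval] = []
    repeats: list[RepeatFeature] = []

    per_chrom: dict[int, list[int]] = {i: [] for i in range(cfg.n_chroms)}
    for i, size in enumerate(sizes):
        per_chrom[i % cfg.n_chroms].append(size)

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = list(_random_seq(rng, cfg.chrom_len, cfg.gc))
        kinds = ["drr"] * len(per_chrom[ci]) + ["gap"] * cfg.n_gaps_per_chrom
        segment_sizes = per_chrom[ci] + [cfg.gap_len] * cfg.n_gaps_per_chrom
        order = rng.permutation(len(segment_sizes))
        kinds = [kinds[i] for i in order]
        segment_sizes = [segment_sizes[i] for i in order]
        starts = _place_segments(rng, cfg.chrom_len, segment_sizes, margin=2_000)
        implant_ivs: list[GenomicInterval] = []
        for j, size in enumerate(segment_sizes):
            s = starts[j]
            iv = GenomicInterval(chrom, s, s + size)
            if kinds[j] == "drr":
                implant_ivs.append(iv)
                frac = float(
                    rng.uniform(*cfg.drr_repeat_fraction_range)
                )
                rep_bp = int(round(frac * size))
                if rep_bp > 0:
                    motif_len = int(rng.integers(2, 7))
                    motif = _random_seq(rng, motif_len, 0.5)
                    array = (motif * (rep_bp // motif_len + 1))[:rep_bp]
                    seq[s : s + rep_bp] = list(array)
                    repeats.append(
                        RepeatFeature(
                            GenomicInterval(chrom, s, s + rep_bp),
                            "Simple_repeat",
                            f"({motif})n",
                        )
                    )
            else:
                seq[s : s + size] = ["N"] * size
                gaps.append(iv)
        template[chrom] = "".join(seq)
        implant_ivs.sort()
        truth.extend(implant_ivs)
        keep = IntervalSet.from_intervals(implant_ivs).complement({chrom: cfg.chrom_len})
        query[chrom] = "".join(
            template[chrom][s:e] for s, e in keep.runs.get(chrom, [(0, cfg.chrom_len)])
        )
    truth.sort()
    gaps.sort()
    return ReferencePairSim(template, query, truth, gaps, repeats)


def emit_truth_paf(pair: ReferencePairSim) -> list[AlignmentBlock]:
    """Identity alignment blocks for all shared, non-gap sequence.

    One block per maximal shared segment between gap/implant boundaries,
    exact coordinates, mapq 60, matches = block length. Calling DRRs on these
    blocks (with the gap list excluded) returns exactly the truth intervals.
    """
    blocks: list[AlignmentBlock] = []
    truth_set = IntervalSet.from_intervals(pair.truth)
    gap_set = IntervalSet.from_intervals(pair.gaps)
    for chrom, length in pair.template_lengths.items():
        shared = truth_set.complement({chrom: length}).subtract(gap_set)
        implants = truth_set.runs.get(chrom, [])
        qlen = len(pair.query[chrom])
        for s, e in shared.runs.get(chrom, []):
            removed_before = sum(ie - is_ for is_, ie in implants if ie <= s)
            qs = s - removed_before
            blocks.append(
                AlignmentBlock(
                    query_id=chrom,
                    query_len=qlen,
                    query_start=qs,
                    query_end=qs + (e - s),
                    strand="+",
                    target_id=chrom,
                    target_len=length,
                    target_start=s,
                    target_end=e,
                    matches=e - s,
                    block_len=e - s,
                    mapq=60,
                )
            )
    return blocks


def simulate_depth_panel(
    truth: list[GenomicInterval],
    cfg: SimConfig,
    seq_lengths: dict[str, int] | None = None,
) -> DepthPanelSim:
    """Per-sample depth tracks, presence genotypes and read summaries over the
    truth regions.

    Per region an allele frequency is drawn once; per sample the genotype is
    Bernoulli at that frequency and the 100-bp depth steps are Poisson with
    the configured present/absent mean. A configurable fraction of regions is
    marked collapsed (every sample sees the collapsed mean, above the no-call
    cutoff). Read summaries are generated for the first ``n_read_samples``
    samples with the configured multimapping and mapping-quality mix.
    """
    if cfg.n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(cfg.seed + 1)
    n_drrs = len(truth)
    drr_ids = [f"DRR_{iv.seq_id}_{iv.start}" for iv in truth]
    freqs = rng.uniform(*cfg.presence_allele_freq_range, size=n_drrs)
    collapsed = rng.random(n_drrs) < cfg.collapsed_frac

    genotypes = np.zeros((cfg.n_samples, n_drrs), dtype=np.int8)
    tracks: list[DepthTrack] = []
    reads: dict[str, list[ReadRecord]] = {}
    for si in range(cfg.n_samples):
        sample_id = f"S{si + 1:03d}"
        steps: list[tuple[GenomicInterval, float]] = []
        sample_reads: list[ReadRecord] = []
        for di, iv in enumerate(truth):
            if collapsed[di]:
                genotypes[si, di] = 2
                lam = cfg.depth_collapsed_mean
            else:
                g = int(rng.random() < freqs[di])
                genotypes[si, di] = g
                lam = cfg.depth_present_mean if g else cfg.depth_absent_mean
            for pos in range(iv.start, iv.end, cfg.depth_step):
                end = min(pos + cfg.depth_step, iv.end)
                steps.append(
                    (GenomicInterval(iv.seq_id, pos, end), float(rng.poisson(lam)))
                )
            if si < cfg.n_read_samples:
                n_reads = cfg.reads_per_drr if genotypes[si, di] != 0 else max(
                    1, cfg.reads_per_drr // 20
                )
                for ri in range(n_reads):
                    start = int(
                        rng.integers(
                            max(0, iv.start - cfg.read_len + 1), iv.end - 1
                        )
                    )
                    multi = rng.random() < cfg.multimap_frac
                    if multi:
                        n_aln = int(rng.integers(2, 6))
                        mapq = 0
                    else:
                        n_aln = 1
                        mapq = (
                            int(rng.integers(21, 61))
                            if rng.random() < cfg.mapq_gt20_frac
                            else int(rng.integers(0, 21))
                        )
                    sample_reads.append(
                        ReadRecord(
                            read_id=f"{sample_id}_{drr_ids[di]}_r{ri}",
                            mapq=mapq,
                            interval=GenomicInterval(
                                iv.seq_id, start, start + cfg.read_len
                            ),
                            n_alignments=n_aln,
                        )
                    )
        steps.sort(key=lambda sd: (sd[0].seq_id, sd[0].start))
        tracks.append(DepthTrack(sample_id=sample_id, steps=steps).validate())
        if sample_reads:
            reads[sample_id] = sample_reads
    if seq_lengths is None:
        seq_lengths = {}
        for iv in truth:
            seq_lengths[iv.seq_id] = max(
                seq_lengths.get(iv.seq_id, 0), iv.end + cfg.read_len
            )
    return DepthPanelSim(
        tracks=tracks,
        genotypes=genotypes,
        drr_ids=drr_ids,
        allele_freqs=freqs,
        reads=reads,
        seq_lengths=dict(seq_lengths),
    )


def simulate_junction(
    cfg: SimConfig,
    mh: int | None = None,
    ins: int | None = None,
    ins_kind: str | None = None,
    seed: int | None = None,
) -> JunctionSim:
    """One engineered breakpoint junction with known microhomology/insertion.

    Exactly one of microhomology and insertion may be nonzero; when neither
    is forced, the lengths are drawn from the configured ranges with the
    mutual-exclusion constraint. Templated insertions are copied from one of
    the breakpoint windows (reverse-complemented half the time); random
    insertions are rejection-sampled to have no full-length match (either
    strand) in the windows. Insertions shorter than 8 bp are always templated
    — any such k-mer occurs by chance in a kbp-scale window, so "random" is
    not constructible.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if mh is None and ins is None:
        if rng.random() < 0.5:
            mh, ins = int(rng.integers(*cfg.mh_range)), 0
        else:
            mh, ins = 0, int(rng.integers(*cfg.ins_range))
    mh = int(mh or 0)
    ins = int(ins or 0)
    if mh > 0 and ins > 0:
        raise ValueError("microhomology and insertion are mutually exclusive")

    flank_a = _random_seq(rng, cfg.flank_len, 0.5)
    flank_b = _random_seq(rng, cfg.flank_len, 0.5)
    if mh > 0:
        flank_b = flank_a[-mh:] + flank_b[mh:]
    # windows: reference sequence around each breakpoint, flank included
    pad = max(0, (cfg.window_len - cfg.flank_len) // 2)
    window_a = _random_seq(rng, pad, 0.5) + flank_a + _random_seq(rng, pad, 0.5)
    window_b = _random_seq(rng, pad, 0.5) + flank_b + _random_seq(rng, pad, 0.5)
    windows = [window_a, window_b]

    ins_seq = ""
    kind = "none"
    if ins > 0:
        if ins_kind is None:
            if ins < 8:
                ins_kind = "templated"
            else:
                ins_kind = "templated" if rng.random() < cfg.templated_prob else "random"
        kind = ins_kind
        if kind == "templated":
            src = windows[int(rng.integers(0, 2))]
            start = int(rng.integers(0, len(src) - ins + 1))
            ins_seq = src[start : start + ins]
            if rng.random() < 0.5:
                ins_seq = revcomp(ins_seq)
        elif kind == "random":
            for _ in range(200):
                cand = _random_seq(rng, ins, 0.5)
                if all(
                    cand not in w and revcomp(cand) not in w for w in windows
                ):
                    ins_seq = cand
                    break
            else:
                raise RuntimeError(
                    f"could not construct a {ins} bp random insertion absent "
                    "from the breakpoint windows"
                )
        else:
            raise ValueError(f"unknown insertion kind {kind!r}")

    derivative = flank_a + ins_seq + flank_b[mh:]
    junction = JunctionInput(
        derivative_seq=derivative,
        flank_a=flank_a,
        flank_b=flank_b,
        pos_a=100_000,
        pos_b=200_000,
        strand_b="-",
    )
    return JunctionSim(
        junction=junction,
        windows=windows,
        mh_len=mh,
        ins_len=ins,
        ins_kind=kind,
        ins_seq=ins_seq,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


_RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching  repeat         "
    " position in repeat\n"
    "score   div. del. ins.  sequence  begin  end   (left)   repeat    class/family  "
    " begin  end (left)  ID\n"
    "\n"
)


def _write_repeatmasker_out(repeats: list[RepeatFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats, start=1):
            iv = r.interval
            klass = (
                r.repeat_class
                if r.repeat_class in ("Simple_repeat", "Low_complexity", "Satellite")
                else f"{r.repeat_class}/generic"
            )
            fh.write(
                f"  463  1.3  0.6  1.7  {iv.seq_id}  {iv.start + 1}  {iv.end}  (0)  +"
                f"  {r.repeat_name}  {klass}  1  {iv.size}  (0)  {i}\n"
            )


def write_reference_pair(pair: ReferencePairSim, outdir: str | os.PathLike) -> None:
    """Emit template/query FASTA, truth + gap BED, RepeatMasker .out, .fai and PAF."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    _write_fasta(pair.template, os.path.join(outdir, "template.fa"))
    _write_fasta(pair.query, os.path.join(outdir, "query.fa"))
    write_bed(pair.truth, os.path.join(outdir, "truth.bed"))
    if pair.gaps:
        write_bed(pair.gaps, os.path.join(outdir, "gaps.bed"))
    _write_repeatmasker_out(pair.repeats, os.path.join(outdir, "repeats.out"))
    with open(os.path.join(outdir, "template.fa.fai"), "w") as fh:
        for name, length in pair.template_lengths.items():
            fh.write(f"{name}\t{length}\t0\t80\t81\n")
    write_paf(emit_truth_paf(pair), os.path.join(outdir, "truth.paf"))


def _write_sam(reads: list[ReadRecord], seq_lengths: dict[str, int], path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length} for name, length in sorted(seq_lengths.items())
        ],
    }
    order = {name: i for i, name in enumerate(sorted(seq_lengths))}
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for r in reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = r.read_id
            a.reference_id = order[r.interval.seq_id]
            a.reference_start = r.interval.start
            a.mapping_quality = r.mapq
            a.cigarstring = f"{r.interval.size}M"
            a.query_sequence = "A" * r.interval.size
            a.flag = 2048 if r.is_supplementary else 0
            a.set_tag("NH", r.n_alignments)
            sam.write(a)


def write_depth_panel(panel: DepthPanelSim, outdir: str | os.PathLike) -> None:
    """Emit one BedGraph per sample, SAM read summaries, and the genotype matrix."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for track in panel.tracks:
        write_depth_bedgraph(
            track, os.path.join(outdir, f"{track.sample_id}.bedgraph")
        )
    for sample_id, sample_reads in panel.reads.items():
        _write_sam(
            sample_reads,
            panel.seq_lengths,
            os.path.join(outdir, f"{sample_id}.sam"),
        )
    with open(os.path.join(outdir, "genotypes.tsv"), "w") as fh:
        fh.write("sample_id\t" + "\t".join(panel.drr_ids) + "\n")
        for track, row in zip(panel.tracks, panel.genotypes):
            fh.write(track.sample_id + "\t" + "\t".join(map(str, row)) + "\n")


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
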