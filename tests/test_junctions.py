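"""Junction resolution, insertion classification, spans, mechanism cascade."""

import pytest

from drrkit import (
    AmbiguousAnchorError,
    Config,
    GenomicInterval,
    JunctionCall,
    JunctionInput,
    JunctionResolutionError,
    RearrangementCall,
    RepeatFeature,
    classify_insertion,
    infer_mechanism,
    inversion_span,
    junction_indels,
    resolve_junction,
    revcomp,
)


def overlap_scan_oracle(der, fa, fb):
    """Independent exhaustive scan: maximal prefix/suffix extensions."""
    a_end = max(
        (k for k in range(1, min(len(der), len(fa)) + 1) if der[:k] == fa[-k:]),
        default=0,
    )
    m = max(
        (k for k in range(1, min(len(der), len(fb)) + 1) if der[-k:] == fb[:k]),
        default=0,
    )
    return a_end, len(der) - m


class TestResolveJunction:
    def test_two_bp_microhomology(self):
        fa, fb = "ACGTACGTAA", "AACCGGTT"
        der = "ACGTACGTAACCGGTT"
        assert overlap_scan_oracle(der, fa, fb) == (10, 8)
        call = resolve_junction(JunctionInput(der, fa, fb), min_anchor=6)
        assert (call.microhomology_len, call.microhomology_seq) == (2, "AA")
        assert call.insertion_len == 0
        assert (call.anchor_a_len, call.anchor_b_len) == (10, 8)

    def test_three_bp_insertion(self):
        fa, fb = "ACGTACGT", "CCGGTTAA"
        der = "ACGTACGTTTTCCGGTTAA"
        call = resolve_junction(JunctionInput(der, fa, fb), min_anchor=5)
        assert (call.insertion_len, call.insertion_seq) == (3, "TTT")
        assert call.microhomology_len == 0

    def test_blunt_junction(self):
        fa = "GATTACAGATTACAAT"
        fb = "CCTTGGAACCTTGGTA"
        call = resolve_junction(JunctionInput(fa + fb, fa, fb), min_anchor=8)
        assert (call.microhomology_len, call.insertion_len) == (0, 0)
        assert call.insertion_kind == "none"

    def test_anchor_failure_raises(self):
        fa, fb = "ACGTACGTAC" * 3, "TTGGCCAATT" * 3
        with pytest.raises(JunctionResolutionError):
            resolve_junction(
                JunctionInput("GGGGGGGGGGGGGGGGGGGGGGGGGGGGGG", fa, fb),
                min_anchor=10,
            )

    def test_ambiguous_anchor_lists_candidates(self):
        fa = "ACGTACGTACGTACGT"  # 4-periodic: 8-mers place at many offsets
        fb = "TTGGCCAATTGGCCAA"
        with pytest.raises(AmbiguousAnchorError) as exc:
            resolve_junction(JunctionInput(fa + fb, fa, fb), min_anchor=8)
        assert len(exc.value.candidates) > 1

    def test_mutual_exclusion_enforced_on_construction(self):
        with pytest.raises(ValueError):
            JunctionCall(2, "AA", 3, "TTT", "random", 10, 10)

    def test_microhomology_reported_leftmost(self):
        # flank A's suffix extends through the homologous bases: the call
        # reports the maximal A-extension, i.e. the leftmost B breakpoint
        fa = "GGATCCGGATCCGGTTAGCA"
        fb = "GCATTCGACCTGATCGAAGT"
        der = fa + fb[3:]  # 3 bp engineered microhomology "GCA"
        call = resolve_junction(JunctionInput(der, fa, fb), min_anchor=10)
        assert call.anchor_a_len == len(fa)
        assert call.microhomology_seq == "GCA"


class TestClassifyInsertion:
    WINDOW = "GATTACACCATGGTTACGAGACCATTGGCGCGTATATCCGGATCGGCCATGCAT"

    def test_exact_hit_is_templated(self):
        assert classify_insertion("ACCATTGGCGCG", [self.WINDOW]) == "templated"

    def test_revcomp_hit_is_templated(self):
        assert classify_insertion(revcomp("ACCATTGGCGCG"), [self.WINDOW]) == "templated"

    def test_no_match_is_random(self):
        # 23 nt with no full-length (nor >=90% identity) hit in the window
        assert classify_insertion("T" * 23, [self.WINDOW]) == "random"

    def test_ninety_percent_identity_is_templated(self):
        sub = self.WINDOW[10:40]  # 30 nt; corrupt 2 bases (93% identity)
        mutated = sub[:5] + ("A" if sub[5] != "A" else "C") + sub[6:20] \
            + ("G" if sub[20] != "G" else "T") + sub[21:]
        assert classify_insertion(mutated, [self.WINDOW]) == "templated"

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            classify_insertion("ACGT", [])


class TestJunctionIndels:
    def test_five_bp_deletion(self):
        out = junction_indels((1000, 5000), (1006, 5001))
        assert out["A"] == -5

    def test_three_bp_duplication(self):
        out = junction_indels((1000, 5000), (998, 5001))
        assert out["A"] == +3

    def test_clean_inversion_zero(self):
        out = junction_indels((1000, 5000), (1001, 5001))
        assert out == {"A": 0, "B": 0}

    def test_b_side_same_convention(self):
        out = junction_indels((1000, 5000), (1001, 5341))
        assert out["B"] == -340


class TestInversionSpan:
    @pytest.mark.parametrize(
        "pos_a,pos_b,mbp",
        [
            (42125501, 127429118, 85),   # 85 303 617 bp
            (51032755, 94376921, 43),
            (32945545, 58051150, 25),    # 25 105 605 bp
            (9982025, 58312124, 48),
            (63951601, 97962156, 34),
            (7340601, 47883888, 41),
            (77056693, 150079672, 73),   # lower bound of an ambiguous breakpoint
        ],
    )
    def test_published_breakpoints_round_to_printed_mbp(self, pos_a, pos_b, mbp):
        span, rounded, _ = inversion_span(pos_a, pos_b, 250_000_000)
        assert rounded == mbp
        assert span == abs(pos_b - pos_a)

    def test_fraction_of_chromosome(self):
        span, mbp, frac = inversion_span(1, 1_000_001, 2_000_000)
        assert (span, mbp, frac) == (1_000_000, 1, 0.5)

    def test_rounding_half_away_from_zero(self):
        assert inversion_span(1, 1_500_001, 10_000_000)[1] == 2

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            inversion_span(5, 5, 1_000)
        with pytest.raises(ValueError):
            inversion_span(1, 10, 0)


def jc(mh=0, ins=0, kind=None):
    if kind is None:
        kind = "none" if ins == 0 else "random"
    return JunctionCall(
        microhomology_len=mh,
        microhomology_seq="N" * mh,
        insertion_len=ins,
        insertion_seq="N" * ins,
        insertion_kind=kind,
        anchor_a_len=50,
        anchor_b_len=50,
    )


def rearrangement(junctions, indels):
    return RearrangementCall(junctions=junctions, side_indels=indels)


class TestInferMechanism:
    def test_mmej_from_microhomology(self, cfg):
        r = rearrangement([jc(mh=2), jc(mh=3)], {"A1": 8, "B1": -2})
        assert infer_mechanism(r, cfg=cfg) == "MMEJ"

    def test_nhej_without_microhomology(self, cfg):
        r = rearrangement([jc(), jc()], {"B": -14})
        assert infer_mechanism(r, cfg=cfg) == "NHEJ"

    def test_mmbir_from_large_unbalance(self, cfg):
        r = rearrangement(
            [jc(ins=23, kind="templated"), jc(mh=2)], {"A": 1, "B": -335}
        )
        assert infer_mechanism(r, cfg=cfg) == "MMBIR"

    def test_complex_mmbir_from_junction_count(self, cfg):
        juncs = [jc(ins=n, kind="random") for n in (90, 61, 18, 16)] + [jc(mh=2)]
        r = rearrangement(juncs, {})
        assert infer_mechanism(r, cfg=cfg) == "complex_MMBIR"

    def test_insertions_alone_do_not_trigger_mmbir(self, cfg):
        r = rearrangement(
            [jc(mh=1), jc(ins=32, kind="random")], {"A": -5, "B": -8}
        )
        assert infer_mechanism(r, cfg=cfg) == "NHEJ"

    def test_nahr_requires_identity(self, cfg):
        rep_a = RepeatFeature(GenomicInterval("chr1", 0, 1000), "LINE", "L1PA3")
        rep_b = RepeatFeature(GenomicInterval("chr1", 50_000, 51_000), "LINE", "L1PA3")
        r = rearrangement([jc(mh=5), jc(mh=5)], {})
        assert infer_mechanism(r, [(rep_a, rep_b, 0.97)], cfg) == "NAHR"
        assert infer_mechanism(r, [(rep_a, rep_b, 0.90)], cfg) == "MMEJ"

    def test_unclassified_insertion_rejected(self, cfg):
        r = rearrangement([jc(ins=10, kind="unclassified")], {})
        with pytest.raises(ValueError):
            infer_mechanism(r, cfg=cfg)

    def test_cascade_order_complex_beats_indel(self, cfg):
        juncs = [jc(ins=20, kind="random")] * 3
        r = rearrangement(juncs, {"A": -500})
        assert infer_mechanism(r, cfg=cfg) == "complex_MMBIR"
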