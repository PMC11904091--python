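import pytest
from hypothesis import given, strategies as st

from trioscope import (
    GeneModel,
    Genotype,
    MotifScores,
    Region,
    SpliceScores,
    TrioVariant,
    in_window,
    infer_consequence,
    intron_offset,
    max_delta,
    percent_motif_variation,
    screen_variant,
)
from trioscope.models import PredictedEffect, SpliceEvent

# two-exon model: exon1 [100,200), intron [200,1000), exon2 [1000,1100)
PLUS = GeneModel("G1", "T1", "chr1", "+", [(100, 200), (1000, 1100)])
MINUS = GeneModel("G2", "T2", "chr1", "-", [(100, 200), (1000, 1100)])


class TestIntronOffset:
    @pytest.mark.parametrize(
        "pos,model,expected",
        [
            (203, PLUS, (3, Region.INTRONIC)),  # 3 bases past the donor
            (995, PLUS, (-6, Region.INTRONIC)),  # 6 bases before the acceptor
            (201, PLUS, (1, Region.CANONICAL_SPLICE_SITE)),
            (202, PLUS, (2, Region.CANONICAL_SPLICE_SITE)),
            (1000, PLUS, (-1, Region.CANONICAL_SPLICE_SITE)),
            (150, PLUS, (None, Region.EXONIC)),
            (50, PLUS, (None, Region.INTERGENIC)),
            (2000, PLUS, (None, Region.INTERGENIC)),
            # minus strand: donor sits at the genomic-right exon
            (1000, MINUS, (1, Region.CANONICAL_SPLICE_SITE)),
            (995, MINUS, (6, Region.INTRONIC)),
            (203, MINUS, (-3, Region.INTRONIC)),
        ],
    )
    def test_geometry(self, pos, model, expected):
        assert intron_offset(pos, model) == expected

    @given(
        st.integers(0, 1),  # strand flag
        st.integers(3, 40),  # exon1 len
        st.integers(8, 60),  # intron len
        st.integers(3, 40),  # exon2 len
        st.integers(1, 200),  # probe index within span
    )
    def test_strand_reflection_symmetry(self, sflag, e1, ilen, e2, probe):
        """Reflecting model and position through a point while flipping the
        strand preserves the transcript-oriented offset."""
        start = 50
        exons = [(start, start + e1), (start + e1 + ilen, start + e1 + ilen + e2)]
        strand = "+" if sflag else "-"
        fwd = GeneModel("G", "T", "chr1", strand, exons)
        span = fwd.span
        pos = span[0] + (probe % (span[1] - span[0])) + 1  # 1-based within span
        mirror = 10_000
        refl_exons = [(mirror - e, mirror - s) for s, e in exons]
        refl = GeneModel("G", "T", "chr1", "-" if strand == "+" else "+", refl_exons)
        refl_pos = mirror - pos + 1
        assert intron_offset(pos, fwd) == intron_offset(refl_pos, refl)


class TestWindow:
    @pytest.mark.parametrize(
        "offset,window,expected",
        [(-6, 150, True), (151, 150, False), (None, 150, True), (150, 150, True)],
    )
    def test_in_window(self, offset, window, expected):
        assert in_window(offset, window) is expected

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            in_window(5, 0)


class TestMaxDelta:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            (SpliceScores(ds_al=0.97, ds_ag=0.80), 0.97),
            (SpliceScores(ds_dl=0.05), 0.05),
            (SpliceScores(), 0.0),
        ],
    )
    def test_aggregate(self, scores, expected):
        assert max_delta(scores) == pytest.approx(expected)
        for v in (scores.ds_ag, scores.ds_al, scores.ds_dg, scores.ds_dl):
            assert max_delta(scores) >= v


class TestPercentMotifVariation:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (9.5, 1.43, -84.95),
            (7.47, 5.46, -26.91),
            (5.96, -1.06, -117.79),
            (7.77, 3.32, -57.27),
            (4.2, 4.2, 0.0),
        ],
    )
    def test_values(self, ref, alt, expected):
        assert percent_motif_variation(MotifScores(ref, alt)) == pytest.approx(expected, abs=0.005)

    def test_zero_reference_undefined(self):
        with pytest.raises(ValueError):
            percent_motif_variation(MotifScores(0.0, 1.0))

    @given(
        st.floats(0.1, 50),
        st.floats(-50, 50),
        st.floats(0.1, 20),
    )
    def test_scale_invariance(self, ref, alt, c):
        base = percent_motif_variation(MotifScores(ref, alt))
        scaled = percent_motif_variation(MotifScores(c * ref, c * alt))
        assert scaled == pytest.approx(base, abs=0.02)


def _variant(offset, region, scores=None, pos=994):
    return TrioVariant(
        "chr1",
        pos,
        "A",
        "G",
        Genotype.HET,
        Genotype.HOM_REF,
        Genotype.HOM_REF,
        gene="G1",
        region=region,
        intron_offset=offset,
        splice=scores,
    )


class TestInferConsequence:
    def test_deep_acceptor_gain_extends_exon(self):
        """A dominant acceptor gain 6 bases into the intron pulls 5 intronic
        bases into the transcript."""
        v = _variant(-6, Region.INTRONIC)
        scores = SpliceScores(ds_al=0.13, dp_al=-6, ds_ag=0.9, dp_ag=-1)
        cons = infer_consequence(v, scores)
        assert cons.event == SpliceEvent.ACCEPTOR_GAIN
        assert cons.predicted_effect == PredictedEffect.EXON_EXTENSION
        assert cons.affected_length_bp == 5

    def test_donor_loss_near_donor_retains_intron(self):
        v = _variant(3, Region.INTRONIC, pos=203)
        cons = infer_consequence(v, SpliceScores(ds_dl=0.38, dp_dl=-3))
        assert cons.event == SpliceEvent.DONOR_LOSS
        assert cons.predicted_effect == PredictedEffect.INTRON_RETENTION

    def test_canonical_acceptor_loss_retains_intron(self):
        v = _variant(-1, Region.CANONICAL_SPLICE_SITE, pos=999)
        cons = infer_consequence(v, SpliceScores(ds_al=0.97, dp_al=1, ds_ag=0.80, dp_ag=20))
        assert cons.event == SpliceEvent.ACCEPTOR_LOSS
        assert cons.predicted_effect == PredictedEffect.INTRON_RETENTION

    def test_negligible_deltas_yield_none(self):
        v = _variant(-6, Region.INTRONIC)
        cons = infer_consequence(v, SpliceScores())
        assert cons.event == SpliceEvent.NONE
        assert cons.predicted_effect == PredictedEffect.UNKNOWN


TABLE_DELTA_SETS = [
    SpliceScores(ds_al=0.97, dp_al=1, ds_ag=0.80, dp_ag=20),  # canonical acceptor
    SpliceScores(ds_dl=0.05, dp_dl=1),  # exonic missense, weak signal
    SpliceScores(ds_dl=0.38, dp_dl=-3),  # near-donor intronic
    SpliceScores(ds_al=0.13, dp_al=-6, ds_ag=0.9, dp_ag=-1),  # deep acceptor
]


class TestScreen:
    def test_intronic_high_delta_passes(self):
        v = _variant(-6, Region.INTRONIC, SpliceScores(ds_ag=0.9, dp_ag=-1))
        ok, tags = screen_variant(v)
        assert ok and "spliceai_delta" in tags

    def test_intronic_low_delta_fails(self):
        v = _variant(-50, Region.INTRONIC, SpliceScores(ds_ag=0.1))
        ok, tags = screen_variant(v)
        assert not ok

    def test_exonic_always_evaluated(self):
        v = _variant(None, Region.EXONIC, SpliceScores(ds_dl=0.05))
        ok, tags = screen_variant(v)
        assert ok and "exonic" in tags

    def test_outside_window_fails_even_with_high_delta(self):
        v = _variant(200, Region.INTRONIC, SpliceScores(ds_dl=0.9))
        ok, tags = screen_variant(v)
        assert not ok and "outside_window" in tags

    def test_three_of_four_worked_delta_sets_pass_threshold(self):
        passing = [s for s in TABLE_DELTA_SETS if max_delta(s) > 0.2]
        assert len(passing) == 3

    def test_pangolin_rescue_tagged_not_gating(self):
        scores = SpliceScores(ds_dl=0.05, pangolin_gain=0.0, pangolin_gain_pos=0, pangolin_loss=0.22, pangolin_loss_pos=1)
        v = _variant(40, Region.INTRONIC, scores)
        ok, tags = screen_variant(v)
        assert not ok and "pangolin_rescue" in tags

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_monotone_in_delta_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        variants = [
            _variant(off, Region.INTRONIC, SpliceScores(ds_ag=d))
            for off, d in [(-6, 0.9), (-50, 0.1), (30, 0.5), (140, 0.25)]
        ]
        admitted_hi = {id(v) for v in variants if screen_variant(v, hi)[0]}
        admitted_lo = {id(v) for v in variants if screen_variant(v, lo)[0]}
        assert admitted_hi <= admitted_lo
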