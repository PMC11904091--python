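"""Splice-screen worked variants: offsets, delta scores, and consequences.

Recreates the four worked screening configurations: a canonical acceptor
substitution, a weak exonic missense, a near-donor intronic change, and a
deep acceptor-region change that creates a novel acceptor. Prints the
maximum delta (screened at > 0.2), the motif-score change, and the
predicted transcript consequence.
"""

from trioscope import (
    Genotype as G,
    MotifScores,
    Region,
    SpliceScores,
    TrioVariant,
    infer_consequence,
    max_delta,
    percent_motif_variation,
    screen_variant,
)

cases = [
    ("canonical acceptor", -1, Region.CANONICAL_SPLICE_SITE,
     SpliceScores(ds_al=0.97, dp_al=1, ds_ag=0.80, dp_ag=20), MotifScores(9.5, 1.43)),
    ("exonic missense", None, Region.EXONIC,
     SpliceScores(ds_dl=0.05, dp_dl=1), MotifScores(7.47, 5.46)),
    ("near-donor intronic", 3, Region.INTRONIC,
     SpliceScores(ds_dl=0.38, dp_dl=-3), MotifScores(5.96, -1.06)),
    ("deep acceptor region", -6, Region.INTRONIC,
     SpliceScores(ds_al=0.13, dp_al=-6, ds_ag=0.9, dp_ag=-1), MotifScores(7.77, 3.32)),
]

for label, offset, region, scores, motif in cases:
    v = TrioVariant("chr1", 1000, "A", "G", G.HET, G.HOM_REF, G.HOM_REF,
                    region=region, intron_offset=offset, splice=scores)
    ok, tags = screen_variant(v)
    cons = infer_consequence(v, scores)
    print(
        f"{label:22s} offset={str(offset):5s} max_delta={max_delta(scores):.2f} "
        f"pass={ok!s:5s} motif_change={percent_motif_variation(motif):+.2f}% "
        f"effect={cons.predicted_effect.value}"
    )
# A negative motif change means the alternate allele weakens the splice
# motif; the deep acceptor gain predicts a 5-bp exon extension.
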