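"""Splice-screening geometry and consequence inference.

This module owns the only place where 1-based variant positions meet 0-based
half-open exon intervals: :func:`intron_offset` computes the HGVS-style
offset of an intronic position from its nearest exon-intron boundary in
transcript orientation (+n downstream of a donor, -n upstream of an
acceptor). The screening rule mirrors intron-inclusive exome reanalysis:
exonic and canonical-splice-site (+/-1, +/-2) variants always enter
evaluation, while deeper intronic variants within a fixed window of the
boundary (default 150 bp) must show a splice-prediction delta above
threshold (default 0.2, maximum of the four SpliceAI deltas).
"""

from __future__ import annotations

from typing import Optional, Tuple

from .models import (
    GeneModel,
    MotifScores,
    PredictedEffect,
    Region,
    SpliceConsequence,
    SpliceEvent,
    SpliceScores,
    TrioVariant,
)

DEFAULT_DELTA_THRESHOLD = 0.2
DEFAULT_WINDOW_BP = 150
CANONICAL_BP = 2


def intron_offset(variant_pos: int, gene_model: GeneModel) -> Tuple[Optional[int], Region]:
    """Offset of a 1-based genomic position from the nearest exon boundary.

    Returns (offset, region): (None, exonic) inside an exon, (None,
    intergenic) outside the transcript span, otherwise a signed HGVS-style
    offset in transcript orientation — +n for the n-th intronic base after a
    donor site, -n for the n-th base before an acceptor. |offset| in {1, 2}
    is a canonical splice site. Ties at the intron midpoint resolve to the
    donor side. Strand-aware: genomic left/right swap roles on '-'.
    """
    p0 = variant_pos - 1  # 0-based index of the variant base
    span_start, span_end = gene_model.span
    if not (span_start <= p0 < span_end):
        return None, Region.INTERGENIC
    exons = gene_model.exons
    for start, end in exons:
        if start <= p0 < end:
            return None, Region.EXONIC
    # find flanking exons of the containing intron
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 <= p0 < s2:
            dist_left = p0 - e1 + 1  # bases past the genomic-left exon end
            dist_right = s2 - p0  # bases before the genomic-right exon start
            if gene_model.strand == "+":
                donor_offset, acceptor_offset = dist_left, -dist_right
                donor_dist, acceptor_dist = dist_left, dist_right
            else:
                donor_offset, acceptor_offset = dist_right, -dist_left
                donor_dist, acceptor_dist = dist_right, dist_left
            offset = donor_offset if donor_dist <= acceptor_dist else acceptor_offset
            region = (
                Region.CANONICAL_SPLICE_SITE
                if abs(offset) <= CANONICAL_BP
                else Region.INTRONIC
            )
            return offset, region
    raise AssertionError("unreachable: position inside span but in no exon or intron")


def annotate_gene_context(variants, gene_models) -> list:
    """Fill gene/transcript/region/intron_offset on variants from gene models.

    The first model (by genomic order) whose span contains the variant wins;
    variants outside every model become intergenic.
    """
    by_chrom = {}
    for m in gene_models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for models in by_chrom.values():
        models.sort(key=lambda m: m.span[0])
    for v in variants:
        v.region = Region.INTERGENIC
        v.intron_offset = None
        for m in by_chrom.get(v.chrom, []):
            off, region = intron_offset(v.pos, m)
            if region != Region.INTERGENIC:
                v.gene = m.gene
                v.transcript = m.transcript
                v.region = region
                v.intron_offset = off
                break
    return list(variants)


def in_window(offset: Optional[int], window_bp: int = DEFAULT_WINDOW_BP) -> bool:
    """True iff the variant is exonic (offset None) or within window_bp of a
    boundary."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    return offset is None or abs(offset) <= window_bp


def max_delta(scores: SpliceScores) -> float:
    """Maximum of the four SpliceAI deltas (the screening aggregate)."""
    return max(scores.ds_ag, scores.ds_al, scores.ds_dg, scores.ds_dl)


def percent_motif_variation(motif: MotifScores) -> float:
    """Percent change of the maximum-entropy motif score, ref -> alt.

    100 * (alt - ref) / |ref|, rounded to 2 decimals; the absolute-value
    denominator keeps the sign meaningful when the reference score is
    negative. Undefined for ref_score == 0.
    """
    if motif.ref_score == 0:
        raise ValueError("percent variation undefined for ref_score == 0")
    return round(100.0 * (motif.alt_score - motif.ref_score) / abs(motif.ref_score), 2)


_EVENTS = (
    (SpliceEvent.ACCEPTOR_GAIN, "ds_ag"),
    (SpliceEvent.ACCEPTOR_LOSS, "ds_al"),
    (SpliceEvent.DONOR_GAIN, "ds_dg"),
    (SpliceEvent.DONOR_LOSS, "ds_dl"),
)

_EPS = 1e-12


def dominant_event(scores: SpliceScores) -> SpliceEvent:
    """The delta type with the largest score; 'none' if all are ~0.

    Ties resolve in the fixed order acceptor_gain, acceptor_loss,
    donor_gain, donor_loss.
    """
    best_event, best = SpliceEvent.NONE, _EPS
    for event, attr in _EVENTS:
        v = getattr(scores, attr)
        if v > best:
            best_event, best = event, v
    return best_event


def infer_consequence(
    variant: TrioVariant, scores: SpliceScores, gene_model: Optional[GeneModel] = None
) -> SpliceConsequence:
    """Infer the predicted splicing outcome from the dominant delta event and
    the variant's intron offset.

    Rules: loss of the adjacent canonical site (donor loss downstream of a
    donor, acceptor loss upstream of an acceptor, or either loss for an
    exonic variant) predicts intron retention; an acceptor gain in the
    intron upstream of a canonical acceptor predicts an exon extension whose
    length is |offset| - 1 — the variant base acting as the G of a novel AG
    acceptor, so the intronic bases between the novel and the canonical
    acceptor enter the transcript. Other geometries return unknown rather
    than guessing.
    """
    offset = variant.intron_offset
    if offset is None and gene_model is not None:
        offset, _ = intron_offset(variant.pos, gene_model)
    event = dominant_event(scores)
    if event == SpliceEvent.NONE:
        return SpliceConsequence(SpliceEvent.NONE, PredictedEffect.UNKNOWN)
    if event == SpliceEvent.DONOR_LOSS and (offset is None or offset > 0):
        return SpliceConsequence(event, PredictedEffect.INTRON_RETENTION)
    if event == SpliceEvent.ACCEPTOR_LOSS and (offset is None or offset < 0):
        return SpliceConsequence(event, PredictedEffect.INTRON_RETENTION)
    if event == SpliceEvent.ACCEPTOR_GAIN and offset is not None and offset < -CANONICAL_BP:
        return SpliceConsequence(
            event, PredictedEffect.EXON_EXTENSION, affected_length_bp=abs(offset) - 1
        )
    return SpliceConsequence(event, PredictedEffect.UNKNOWN)


def screen_variant(
    variant: TrioVariant,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> Tuple[bool, frozenset]:
    """Splice-screening decision with evidence tags.

    Passes iff the variant lies within the boundary window AND (it is exonic
    or at a canonical splice site, OR its maximum SpliceAI delta exceeds the
    threshold). Tags record which clause fired; a 'pangolin_rescue' tag is
    added (evidence only, never gating) when Pangolin gain/loss exceeds the
    threshold while SpliceAI fails it.
    """
    tags = set()
    if not in_window(variant.intron_offset, window_bp):
        return False, frozenset({"outside_window"})
    delta = max_delta(variant.splice) if variant.splice is not None else 0.0
    spliceai_pass = delta > delta_threshold
    if variant.region in (Region.EXONIC, Region.CANONICAL_SPLICE_SITE):
        tags.add(variant.region.value)
        if spliceai_pass:
            tags.add("spliceai_delta")
        return True, frozenset(tags)
    if spliceai_pass:
        return True, frozenset({"spliceai_delta"})
    s = variant.splice
    if s is not None:
        pang = max(s.pangolin_gain or 0.0, s.pangolin_loss or 0.0)
        if pang > delta_threshold:
            tags.add("pangolin_rescue")
    tags.add("below_delta_threshold")
    return False, frozenset(tags)
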