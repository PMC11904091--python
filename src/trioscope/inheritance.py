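"""Trio inheritance classification and compound-heterozygote detection.

The classifier is a total, deterministic decision table over
(chromosome class, proband sex, trio genotypes). It is GT-only by design:
no allele-depth mosaicism modelling, no read-backed phasing — phase for
compound heterozygotes is resolved purely by parental transmission, and a
variant carried by both parents yields an ambiguous pair rather than being
dropped.
"""

from __future__ import annotations

import itertools

from .models import (
    CompoundHetPair,
    Genotype,
    InheritanceCall,
    InheritanceModel as M,
    Pedigree,
    PhaseConfidence,
    Sex,
    TrioVariant,
)

_UNCLASSIFIABLE = InheritanceCall(M.UNCLASSIFIABLE, PhaseConfidence.CERTAIN)


def _chrom_class(chrom: str) -> str:
    c = chrom.removeprefix("chr").upper()
    if c == "X":
        return "chrX"
    if c in ("Y", "M", "MT"):
        return "other"
    return "autosome"


def _alt_dose(gt: Genotype) -> int:
    """Alt-allele count carried by a genotype (hemizygous counts once)."""
    return {
        Genotype.HOM_REF: 0,
        Genotype.HET: 1,
        Genotype.HOM_ALT: 2,
        Genotype.HEMI_REF: 0,
        Genotype.HEMI_ALT: 1,
    }[gt]


def _diploid_gametes(gt: Genotype) -> set:
    """Set of alleles (0=ref, 1=alt) a diploid parent can transmit."""
    return {
        Genotype.HOM_REF: {0},
        Genotype.HET: {0, 1},
        Genotype.HOM_ALT: {1},
        Genotype.HEMI_REF: {0},
        Genotype.HEMI_ALT: {1},
    }[gt]


def classify_trio_genotype(variant: TrioVariant, pedigree: Pedigree) -> InheritanceCall:
    """Classify one variant's trio inheritance pattern.

    De novo requires the proband to carry the alt with both parents
    reference; a genotype combination that no gamete pairing can produce is a
    Mendelian error. Missing genotypes, non-carriers, chrY/MT records, and
    het variants whose transmitting parent cannot be determined (both parents
    carriers) are unclassifiable.
    """
    p, m, f = variant.proband_gt, variant.mother_gt, variant.father_gt
    if Genotype.MISSING in (p, m, f):
        return _UNCLASSIFIABLE

    cls = _chrom_class(variant.chrom)
    if cls == "other":
        return _UNCLASSIFIABLE

    if cls == "autosome":
        return _classify_autosomal(p, m, f)

    if pedigree.proband_sex == Sex.MALE:
        return _classify_x_male(p, m, f)
    if pedigree.proband_sex == Sex.FEMALE:
        return _classify_x_female(p, m, f)
    return _UNCLASSIFIABLE  # X-linked classification needs proband sex


def _classify_het_proband(mg: set, fg: set, de_novo_model) -> InheritanceCall:
    """Shared het-proband logic: one alt allele whose source must be found."""
    mother_carries, father_carries = 1 in mg, 1 in fg
    if not mother_carries and not father_carries:
        return InheritanceCall(de_novo_model)
    maternal_possible = mother_carries and 0 in fg
    paternal_possible = father_carries and 0 in mg
    if maternal_possible and paternal_possible:
        return InheritanceCall(M.UNCLASSIFIABLE, PhaseConfidence.AMBIGUOUS)
    if maternal_possible:
        return InheritanceCall(M.INHERITED_MATERNAL_HET)
    if paternal_possible:
        return InheritanceCall(M.INHERITED_PATERNAL_HET)
    # parents carry alt but no gamete pairing yields a het child
    return InheritanceCall(M.MENDELIAN_ERROR)


def _classify_autosomal(p: Genotype, m: Genotype, f: Genotype) -> InheritanceCall:
    if p in (Genotype.HEMI_REF, Genotype.HEMI_ALT):
        return _UNCLASSIFIABLE  # hemizygous call on an autosome
    mg, fg = _diploid_gametes(m), _diploid_gametes(f)
    dose = _alt_dose(p)
    if dose == 0:
        if 0 in mg and 0 in fg:
            return _UNCLASSIFIABLE  # non-carrier
        return InheritanceCall(M.MENDELIAN_ERROR)  # a hom_alt parent must transmit
    if dose == 2:
        if 1 in mg and 1 in fg:
            return InheritanceCall(M.AUTOSOMAL_RECESSIVE_HOM)
        return InheritanceCall(M.MENDELIAN_ERROR)  # hom_alt with a hom_ref parent
    return _classify_het_proband(mg, fg, M.DE_NOVO_AUTOSOMAL)


def _x_coerce_male(gt: Genotype) -> Genotype:
    """Normalize a male's X genotype to hemizygous; het males are left as-is
    (pseudo-autosomal or artefactual) and handled by the caller."""
    return {
        Genotype.HOM_REF: Genotype.HEMI_REF,
        Genotype.HOM_ALT: Genotype.HEMI_ALT,
        Genotype.HEMI_REF: Genotype.HEMI_REF,
        Genotype.HEMI_ALT: Genotype.HEMI_ALT,
        Genotype.HET: Genotype.HET,
    }[gt]


def _classify_x_male(p: Genotype, m: Genotype, f: Genotype) -> InheritanceCall:
    p = _x_coerce_male(p)
    if p == Genotype.HET:
        return _UNCLASSIFIABLE  # diploid male X call: ambiguous
    mg = _diploid_gametes(m)  # son's X comes from the mother
    carries = p == Genotype.HEMI_ALT
    if not carries:
        if 0 not in mg:
            return InheritanceCall(M.MENDELIAN_ERROR)  # hom_alt mother must transmit alt
        return _UNCLASSIFIABLE
    if 1 in mg:
        return InheritanceCall(M.X_HEMIZYGOUS_MATERNAL)
    return InheritanceCall(M.X_HEMIZYGOUS_DE_NOVO)


def _classify_x_female(p: Genotype, m: Genotype, f: Genotype) -> InheritanceCall:
    if p in (Genotype.HEMI_REF, Genotype.HEMI_ALT):
        return _UNCLASSIFIABLE  # haploid call for a female proband
    f = _x_coerce_male(f)
    if f == Genotype.HET:
        return _UNCLASSIFIABLE  # diploid paternal X call: ambiguous
    mg = _diploid_gametes(m)
    fg = _diploid_gametes(f)  # father transmits his single X to every daughter
    dose = _alt_dose(p)
    if dose == 0:
        if 0 in mg and 0 in fg:
            return _UNCLASSIFIABLE
        return InheritanceCall(M.MENDELIAN_ERROR)
    if dose == 2:
        if 1 in mg and 1 in fg:
            # X-linked recessive homozygote; the enum's single recessive label
            return InheritanceCall(M.AUTOSOMAL_RECESSIVE_HOM)
        return InheritanceCall(M.MENDELIAN_ERROR)
    return _classify_het_proband(mg, fg, M.DE_NOVO_X)


def _parental_carriage(v: TrioVariant) -> tuple:
    return (v.mother_gt.carries_alt(), v.father_gt.carries_alt())


def detect_compound_het(variants_in_gene, pedigree: Pedigree) -> list:
    """Detect trans candidate pairs among proband-het variants in one gene.

    Every pair with a possible (maternal, paternal) transmission assignment
    is emitted; if either partner is carried by both parents the assignment
    is not unique and the pair is flagged ambiguous. Variants carried by
    neither parent (apparent de novo) do not form inherited pairs. Pairs are
    ordered by genomic position.
    """
    variants = [v for v in variants_in_gene if v.proband_gt == Genotype.HET]
    genes = {v.gene for v in variants}
    if len(genes) > 1:
        raise ValueError(f"variants span multiple genes: {sorted(g or '?' for g in genes)}")
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    pairs = []
    for v1, v2 in itertools.combinations(variants, 2):
        if v1.pos == v2.pos:
            continue
        m1, f1 = _parental_carriage(v1)
        m2, f2 = _parental_carriage(v2)
        # assignment: v1 maternal & v2 paternal, or vice versa
        a = m1 and f2
        b = m2 and f1
        if not (a or b):
            continue
        ambiguous = (m1 and f1) or (m2 and f2)
        if a:
            maternal, paternal = v1, v2
        else:
            maternal, paternal = v2, v1
        pairs.append(
            CompoundHetPair(
                gene=v1.gene,
                maternal_variant=maternal,
                paternal_variant=paternal,
                ambiguity_flag=ambiguous,
            )
        )
    return pairs


def mendelian_error_rate(variants, pedigree: Pedigree) -> float:
    """Fraction of classifiable variants called mendelian_error (QC metric)."""
    variants = list(variants)
    if not variants:
        raise ValueError("mendelian_error_rate requires a non-empty variant sequence")
    calls = [classify_trio_genotype(v, pedigree).model for v in variants]
    classifiable = [c for c in calls if c != M.UNCLASSIFIABLE]
    if not classifiable:
        return 0.0
    return sum(1 for c in classifiable if c == M.MENDELIAN_ERROR) / len(classifiable)
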