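import itertools

import pytest
from hypothesis import given, strategies as st

from trioscope import (
    Genotype,
    TrioVariant,
    classify_trio_genotype,
    detect_compound_het,
    mendelian_error_rate,
)
from trioscope.models import InheritanceModel as M, PhaseConfidence

G = Genotype
X_MODELS = {M.DE_NOVO_X, M.X_HEMIZYGOUS_DE_NOVO, M.X_HEMIZYGOUS_MATERNAL}


def _v(chrom, p, m, f, pos=100, gene="G1"):
    return TrioVariant(chrom, pos, "C", "A", p, m, f, gene=gene)


class TestDecisionTable:
    @pytest.mark.parametrize(
        "chrom,trio,proband,mother,father,expected",
        [
            # de novo hemizygous on X in a male proband
            ("chrX", "male_trio", G.HEMI_ALT, G.HOM_REF, G.HEMI_REF, M.X_HEMIZYGOUS_DE_NOVO),
            # maternally inherited het on an autosome
            ("chr8", "male_trio", G.HET, G.HET, G.HOM_REF, M.INHERITED_MATERNAL_HET),
            # homozygous recessive: both parents het carriers
            ("chr8", "male_trio", G.HOM_ALT, G.HET, G.HET, M.AUTOSOMAL_RECESSIVE_HOM),
            # non-carrier proband
            ("chr8", "male_trio", G.HOM_REF, G.HET, G.HOM_REF, M.UNCLASSIFIABLE),
            # autosomal de novo
            ("chr8", "female_trio", G.HET, G.HOM_REF, G.HOM_REF, M.DE_NOVO_AUTOSOMAL),
            # female X de novo (both parents reference)
            ("chrX", "female_trio", G.HET, G.HOM_REF, G.HEMI_REF, M.DE_NOVO_X),
            # X carrier mother transmits to son
            ("chrX", "male_trio", G.HEMI_ALT, G.HET, G.HEMI_REF, M.X_HEMIZYGOUS_MATERNAL),
            # impossible: hom_alt child of two hom_ref parents
            ("chr8", "male_trio", G.HOM_ALT, G.HOM_REF, G.HOM_REF, M.MENDELIAN_ERROR),
            # impossible: hom_ref child of a hom_alt parent
            ("chr8", "male_trio", G.HOM_REF, G.HOM_ALT, G.HOM_REF, M.MENDELIAN_ERROR),
            # missing parental genotype
            ("chr8", "male_trio", G.HET, G.MISSING, G.HOM_REF, M.UNCLASSIFIABLE),
        ],
    )
    def test_examples(self, chrom, trio, proband, mother, father, expected, request):
        ped = request.getfixturevalue(trio)
        call = classify_trio_genotype(_v(chrom, proband, mother, father), ped)
        assert call.model == expected

    def test_both_parent_carriers_ambiguous(self, male_trio):
        call = classify_trio_genotype(_v("chr8", G.HET, G.HET, G.HET), male_trio)
        assert call.model == M.UNCLASSIFIABLE
        assert call.phase_confidence == PhaseConfidence.AMBIGUOUS

    def test_chry_passes_through_unclassifiable(self, male_trio):
        call = classify_trio_genotype(_v("chrY", G.HEMI_ALT, G.HOM_REF, G.HEMI_REF), male_trio)
        assert call.model == M.UNCLASSIFIABLE


class TestExhaustiveness:
    def test_every_combination_maps_to_exactly_one_model(self, male_trio, female_trio):
        """Total decision table: any genotype triple on any chromosome class
        yields one model, X-specific models only on chrX."""
        gts = list(Genotype)
        for chrom in ("chr3", "chrX"):
            for ped in (male_trio, female_trio):
                for p, m, f in itertools.product(gts, repeat=3):
                    call = classify_trio_genotype(_v(chrom, p, m, f), ped)
                    again = classify_trio_genotype(_v(chrom, p, m, f), ped)
                    assert call == again
                    assert isinstance(call.model, M)
                    if chrom != "chrX":
                        assert call.model not in X_MODELS

    def test_mother_father_symmetry_autosomal(self, male_trio):
        """Swapping parental genotypes swaps maternal/paternal inherited
        calls and leaves de novo and error calls unchanged."""
        swap = {
            M.INHERITED_MATERNAL_HET: M.INHERITED_PATERNAL_HET,
            M.INHERITED_PATERNAL_HET: M.INHERITED_MATERNAL_HET,
        }
        diploid = [G.HOM_REF, G.HET, G.HOM_ALT, G.MISSING]
        for p, m, f in itertools.product(diploid, repeat=3):
            fwd = classify_trio_genotype(_v("chr5", p, m, f), male_trio)
            rev = classify_trio_genotype(_v("chr5", p, f, m), male_trio)
            assert rev.model == swap.get(fwd.model, fwd.model)


def brute_force_compound_het(variants):
    """Independent oracle: enumerate all het pairs with distinct positions
    and keep those with a possible opposite-parent transmission assignment."""
    hets = [v for v in variants if v.proband_gt == G.HET]
    pairs = []
    for v1, v2 in itertools.combinations(
        sorted(hets, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)), 2
    ):
        if v1.pos == v2.pos:
            continue
        found = False
        ambiguous = False
        for mat, pat in ((v1, v2), (v2, v1)):
            if mat.mother_gt.carries_alt() and pat.father_gt.carries_alt():
                found = True
        if found:
            for v in (v1, v2):
                if v.mother_gt.carries_alt() and v.father_gt.carries_alt():
                    ambiguous = True
            pairs.append((v1.pos, v2.pos, ambiguous))
    return pairs


class TestCompoundHet:
    def test_trans_pair_detected(self, male_trio):
        stop_gain = _v("chr8", G.HET, G.HET, G.HOM_REF, pos=100)
        intronic = _v("chr8", G.HET, G.HOM_REF, G.HET, pos=500)
        (pair,) = detect_compound_het([stop_gain, intronic], male_trio)
        assert pair.maternal_variant.pos == 100
        assert pair.paternal_variant.pos == 500
        assert not pair.ambiguity_flag

    def test_cis_by_transmission_yields_nothing(self, male_trio):
        v1 = _v("chr8", G.HET, G.HET, G.HOM_REF, pos=100)
        v2 = _v("chr8", G.HET, G.HET, G.HOM_REF, pos=500)
        assert detect_compound_het([v1, v2], male_trio) == []

    def test_cross_product_count(self, male_trio):
        maternal = [_v("chr8", G.HET, G.HET, G.HOM_REF, pos=100 + i) for i in range(3)]
        paternal = [_v("chr8", G.HET, G.HOM_REF, G.HET, pos=500 + i) for i in range(2)]
        pairs = detect_compound_het(maternal + paternal, male_trio)
        assert len(pairs) == 6
        assert not any(p.ambiguity_flag for p in pairs)

    def test_both_parent_carrier_flags_ambiguous(self, male_trio):
        shared = _v("chr8", G.HET, G.HET, G.HET, pos=100)
        paternal = _v("chr8", G.HET, G.HOM_REF, G.HET, pos=500)
        (pair,) = detect_compound_het([shared, paternal], male_trio)
        assert pair.ambiguity_flag

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 8),  # position
                st.sampled_from([G.HOM_REF, G.HET]),  # mother
                st.sampled_from([G.HOM_REF, G.HET]),  # father
            ),
            max_size=8,
        )
    )
    def test_matches_brute_force_oracle(self, spec):
        ped = __import__("trioscope").Pedigree("F", "p", "m", "f")
        seen = set()
        variants = []
        for pos, mgt, fgt in spec:
            if pos in seen:
                continue
            seen.add(pos)
            variants.append(_v("chr2", G.HET, mgt, fgt, pos=pos))
        got = sorted(
            (
                min(p.maternal_variant.pos, p.paternal_variant.pos),
                max(p.maternal_variant.pos, p.paternal_variant.pos),
                p.ambiguity_flag,
            )
            for p in detect_compound_het(variants, ped)
        )
        expected = sorted(
            (min(a, b), max(a, b), amb) for a, b, amb in brute_force_compound_het(variants)
        )
        assert got == expected


class TestMendelianErrorRate:
    def test_consistent_variants_zero(self, male_trio):
        vs = [_v("chr1", G.HET, G.HET, G.HOM_REF, pos=i + 1) for i in range(5)]
        assert mendelian_error_rate(vs, male_trio) == 0.0

    def test_single_impossible_variant_one(self, male_trio):
        vs = [_v("chr1", G.HOM_ALT, G.HOM_REF, G.HOM_REF)]
        assert mendelian_error_rate(vs, male_trio) == 1.0

    def test_empty_input_rejected(self, male_trio):
        with pytest.raises(ValueError):
            mendelian_error_rate([], male_trio)

    def test_planted_error_rate_recovered(self):
        """A cohort generated with 5% Mendelian errors measures ~5%."""
        from tests.conftest import prepare_cohort
        from trioscope import SimConfig

        cohort = prepare_cohort(
            SimConfig(seed=7, n_trios=10, mendelian_error_rate=0.05, planted_spec=())
        )
        rates = [
            mendelian_error_rate(t.variants, t.pedigree) for t in cohort.trios
        ]
        pooled = sum(rates) / len(rates)
        # 1200 background variants: 3 sigma of binomial(0.05) ~ 0.019
        assert abs(pooled - 0.05) < 0.02
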