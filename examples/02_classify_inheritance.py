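"""Classify trio inheritance for a handful of hand-built genotype patterns.

Shows the genotype decision table at work: de novo calls need both parents
reference, hemizygous X calls depend on proband sex, and impossible allele
configurations come back as Mendelian errors.
"""

from trioscope import Genotype as G, Pedigree, Sex, TrioVariant, classify_trio_genotype

male = Pedigree("FAM", "boy", "mum", "dad", Sex.MALE)

patterns = [
    ("chr7", G.HET, G.HOM_REF, G.HOM_REF, "rare de novo missense"),
    ("chr7", G.HET, G.HET, G.HOM_REF, "transmitted from the mother"),
    ("chr7", G.HOM_ALT, G.HET, G.HET, "recessive homozygote"),
    ("chrX", G.HEMI_ALT, G.HOM_REF, G.HEMI_REF, "de novo hemizygous on X"),
    ("chrX", G.HEMI_ALT, G.HET, G.HEMI_REF, "carrier mother, affected son"),
    ("chr7", G.HOM_ALT, G.HOM_REF, G.HOM_REF, "impossible configuration"),
]

for chrom, p, m, f, label in patterns:
    v = TrioVariant(chrom, 1000, "C", "T", p, m, f)
    call = classify_trio_genotype(v, male)
    print(f"{label:35s} {chrom:5s} -> {call.model.value} ({call.phase_confidence.value})")
# The model is what the downstream steps filter on: de novo and hemizygous
# calls are diagnostic on their own, inherited hets only in trans pairs.
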