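"""Synthetic trio cohorts with the statistical structure the pipeline assumes.

The generator stands in for an unshared clinical cohort. It emits, per
cohort: non-overlapping gene models on synthetic contigs (chr1..chr5, chrX),
a constraint table in which X-linked disease categories have systematically
lower LOEUF than autosomal-dominant genes, phenotype gene panels, per-trio
joint VCFs with background polymorphisms and planted diagnostic variants,
a truth table keying every planted variant to its intended inheritance
model and step of discovery, and a cohort ledger.

No reference FASTA is emitted: REF/ALT bases are drawn uniformly and the
pipeline never consults a reference. Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as _io
from .models import (
    CaseRecord,
    CohortLedger,
    DiagnosisStage,
    GeneAnnotation,
    GeneModel,
    Genotype,
    InheritanceModel as M,
    Outcome,
    Pedigree,
    Sex,
    SpliceScores,
    TrioVariant,
)

AUTOSOMES = ("chr1", "chr2", "chr3", "chr4", "chr5")

# per-category LOEUF (mean, sd); X disease categories sit well below AD
DEFAULT_LOEUF_BY_CATEGORY = {
    "AD": (0.60, 0.20),
    "ADR": (0.55, 0.20),
    "AR": (0.90, 0.25),
    "A_other": (1.00, 0.30),
    "XLD": (0.15, 0.08),
    "XLR": (0.15, 0.08),
    "XLDR": (0.15, 0.08),
    "X_other": (0.45, 0.25),
}

_CATEGORY_MODES = {
    "AD": frozenset({"AD"}),
    "ADR": frozenset({"ADR"}),
    "AR": frozenset({"AR"}),
    "A_other": frozenset(),
    "XLD": frozenset({"XLD"}),
    "XLR": frozenset({"XLR"}),
    "XLDR": frozenset({"XLDR"}),
    "X_other": frozenset(),
}


@dataclass(frozen=True)
class PlantSpec:
    """One planted scenario: inheritance model, variant geometry, splice
    signal strength, and host-gene category."""

    name: str
    model: M  # for compound het: the maternal partner's model slot
    region_class: str  # exonic | canonical_splice_site | intronic
    delta_level: str  # high | low | none
    gene_category: str
    intron_offset: Optional[int] = None
    require_low_loeuf: bool = False
    compound_het: bool = False
    panel: Optional[str] = None
    intended_stage: DiagnosisStage = DiagnosisStage.INITIAL


# Worked scenarios mirroring the four reanalysis case patterns plus plain
# initially-diagnosed and undiagnosed cases. One scenario per trio, cycling.
DEFAULT_PLANT_CYCLE = (
    PlantSpec(  # plain rare de novo missense in an unconstrained gene
        name="initial_de_novo_exonic",
        model=M.DE_NOVO_AUTOSOMAL,
        region_class="exonic",
        delta_level="none",
        gene_category="A_other",
        intended_stage=DiagnosisStage.INITIAL,
    ),
    PlantSpec(  # canonical acceptor-site de novo in a constrained XLD gene
        name="x_canonical_acceptor",
        model=M.DE_NOVO_X,
        region_class="canonical_splice_site",
        delta_level="high",
        gene_category="XLD",
        intron_offset=-1,
        require_low_loeuf=True,
        intended_stage=DiagnosisStage.STEP1,
    ),
    PlantSpec(  # hemizygous exonic missense in a constrained XLR gene
        name="x_exonic_hemizygous",
        model=M.X_HEMIZYGOUS_MATERNAL,
        region_class="exonic",
        delta_level="low",
        gene_category="XLR",
        require_low_loeuf=True,
        intended_stage=DiagnosisStage.STEP1,
    ),
    PlantSpec(  # compound het: exonic stop-gain + intronic donor-loss partner
        name="panel_compound_het",
        model=M.INHERITED_MATERNAL_HET,
        region_class="exonic",
        delta_level="high",
        gene_category="AR",
        intron_offset=3,
        compound_het=True,
        panel="meckel",
        intended_stage=DiagnosisStage.STEP2,
    ),
    PlantSpec(  # de novo hemizygous deep acceptor-region variant, low LOEUF
        name="x_intronic_acceptor_gain",
        model=M.X_HEMIZYGOUS_DE_NOVO,
        region_class="intronic",
        delta_level="high",
        gene_category="XLD",
        intron_offset=-6,
        require_low_loeuf=True,
        intended_stage=DiagnosisStage.STEP3,
    ),
    PlantSpec(  # nothing diagnostic planted
        name="undiagnosed",
        model=M.UNCLASSIFIABLE,
        region_class="intronic",
        delta_level="none",
        gene_category="A_other",
        intended_stage=DiagnosisStage.UNDIAGNOSED,
    ),
)


@dataclass
class SimConfig:
    seed: int = 1
    n_trios: int = 30
    n_genes: int = 60
    exons_per_gene: tuple = (2, 20)
    exon_len: tuple = (50, 300)
    intron_len: tuple = (500, 5000)
    background_variants_per_trio: int = 120
    planted_spec: tuple = DEFAULT_PLANT_CYCLE
    novel_af_fraction: float = 0.3  # point mass at AF 0
    af_range: tuple = (1e-4, 0.5)  # log-uniform for the common component
    loeuf_by_category: dict = field(default_factory=lambda: dict(DEFAULT_LOEUF_BY_CATEGORY))
    mendelian_error_rate: float = 0.0
    x_gene_fraction: float = 0.2
    intergene_gap: int = 10_000
    all_female_probands: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.exons_per_gene, self.exon_len, self.intron_len):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        if not 0 <= self.mendelian_error_rate <= 1:
            raise ValueError("mendelian_error_rate must be in [0, 1]")
        if not 0 <= self.novel_af_fraction <= 1:
            raise ValueError("novel_af_fraction must be in [0, 1]")


@dataclass
class TrioSim:
    trio_id: str
    pedigree: Pedigree
    variants: list
    phenotype: Optional[str] = None


@dataclass
class Cohort:
    config: SimConfig
    gene_models: list
    constraint_table: dict  # gene -> GeneAnnotation
    panels: dict  # panel name -> set of genes
    trios: list  # list[TrioSim]
    truth: pd.DataFrame
    ledger: CohortLedger


def _rand_base(rng, exclude=None):
    bases = [b for b in "ACGT" if b != exclude]
    return bases[rng.integers(len(bases))]


def generate_gene_models(config: SimConfig, rng=None) -> list:
    """Tile non-overlapping genes across chr1..chr5 and chrX, both strands."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_x = max(1, int(round(config.n_genes * config.x_gene_fraction)))
    chrom_of = ["chrX"] * n_x + [
        AUTOSOMES[i % len(AUTOSOMES)] for i in range(config.n_genes - n_x)
    ]
    cursor = {c: 10_000 for c in AUTOSOMES + ("chrX",)}
    models = []
    for i, chrom in enumerate(chrom_of):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursor[chrom]
        exons = []
        for j in range(n_exons):
            length = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if j < n_exons - 1:
                pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        cursor[chrom] = pos + config.intergene_gap
        gene = f"GENE{i + 1:04d}"
        models.append(
            GeneModel(gene=gene, transcript=f"TX{i + 1:04d}", chrom=chrom, strand=strand, exons=exons)
        )
    return models


def generate_constraint_table(config: SimConfig, models, rng=None) -> dict:
    """Assign inheritance categories consistent with chromosome placement and
    sample LOEUF per category (X disease categories stochastically below AD)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    x_cats = ("XLD", "XLR", "XLDR", "X_other")
    a_cats = ("AD", "ADR", "AR", "A_other")
    table = {}
    xi = ai = 0
    for m in models:
        if m.chrom == "chrX":
            cat = x_cats[xi % len(x_cats)]
            xi += 1
            chrom_class = "chrX"
        else:
            cat = a_cats[ai % len(a_cats)]
            ai += 1
            chrom_class = "autosome"
        mean, sd = config.loeuf_by_category[cat]
        loeuf = float(np.clip(rng.normal(mean, sd), 0.01, None))
        table[m.gene] = GeneAnnotation(
            gene=m.gene, chrom_class=chrom_class, loeuf=round(loeuf, 3), modes=_CATEGORY_MODES[cat]
        )
    return table


def sample_category_loeuf(category: str, n: int, config: Optional[SimConfig] = None, rng=None):
    """Sample n LOEUF values from one category's distribution (for the
    constraint-comparison studies)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mean, sd = config.loeuf_by_category[category]
    return np.clip(rng.normal(mean, sd, size=n), 0.01, None)


def _genomic_pos_for_offset(model: GeneModel, intron_index: int, offset: int) -> int:
    """1-based genomic position of a transcript-oriented intron offset within
    intron `intron_index` (between exon i and i+1 in genomic order)."""
    e1_end = model.exons[intron_index][1]
    s2 = model.exons[intron_index + 1][0]
    if model.strand == "+":
        return e1_end + offset if offset > 0 else s2 + 1 + offset
    return s2 + 1 - offset if offset > 0 else e1_end - offset


def _exonic_pos(model: GeneModel, rng) -> int:
    start, end = model.exons[int(rng.integers(len(model.exons)))]
    return int(rng.integers(start, end)) + 1


def _mid_intron_index(model: GeneModel) -> int:
    return (len(model.exons) - 1) // 2


def _high_splice(offset: Optional[int], rng) -> SpliceScores:
    """A strong splice signal consistent with the variant geometry."""
    score = float(np.round(rng.uniform(0.5, 0.95), 2))
    if offset is None or offset > 0:  # donor side (or exonic): donor loss
        return SpliceScores(ds_dl=score, dp_dl=int(-(offset or 1)))
    if offset < -2:  # deep acceptor side: novel acceptor gain
        return SpliceScores(
            ds_ag=score, dp_ag=-1, ds_al=float(np.round(rng.uniform(0.05, 0.3), 2)), dp_al=offset
        )
    return SpliceScores(ds_al=score, dp_al=1)  # canonical acceptor loss


def _low_splice(rng) -> SpliceScores:
    # background deltas concentrated below 0.1, rare excursions past 0.2
    val = float(np.round(rng.beta(1.0, 30.0), 3))
    channel = int(rng.integers(4))
    kwargs = [{"ds_ag": val}, {"ds_al": val}, {"ds_dg": val}, {"ds_dl": val}][channel]
    return SpliceScores(**kwargs)


_PLANT_GENOTYPES = {
    M.DE_NOVO_AUTOSOMAL: (Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF),
    M.DE_NOVO_X: (Genotype.HET, Genotype.HOM_REF, Genotype.HEMI_REF),
    M.X_HEMIZYGOUS_DE_NOVO: (Genotype.HEMI_ALT, Genotype.HOM_REF, Genotype.HEMI_REF),
    M.X_HEMIZYGOUS_MATERNAL: (Genotype.HEMI_ALT, Genotype.HET, Genotype.HEMI_REF),
    M.INHERITED_MATERNAL_HET: (Genotype.HET, Genotype.HET, Genotype.HOM_REF),
    M.INHERITED_PATERNAL_HET: (Genotype.HET, Genotype.HOM_REF, Genotype.HET),
    M.AUTOSOMAL_RECESSIVE_HOM: (Genotype.HOM_ALT, Genotype.HET, Genotype.HET),
}

_X_MODELS = frozenset(
    {M.DE_NOVO_X, M.X_HEMIZYGOUS_DE_NOVO, M.X_HEMIZYGOUS_MATERNAL}
)
_MALE_X_MODELS = frozenset({M.X_HEMIZYGOUS_DE_NOVO, M.X_HEMIZYGOUS_MATERNAL})


def _pick_gene(models, constraint, category: str, require_low_loeuf: bool, used: set, rng):
    candidates = [
        m
        for m in models
        if m.gene not in used
        and _category_of(constraint[m.gene]) == category
        and (not require_low_loeuf or constraint[m.gene].loeuf <= 0.35)
        and len(m.exons) >= 2
    ]
    if not candidates:
        raise ValueError(
            f"no unused gene of category {category!r}"
            + (" with LOEUF <= 0.35" if require_low_loeuf else "")
        )
    return candidates[int(rng.integers(len(candidates)))]


def _category_of(ann: GeneAnnotation) -> str:
    from .constraint import mode_category

    return mode_category(ann)


def _plant_variants(spec: PlantSpec, model: GeneModel, rng, used_pos: set) -> list:
    """Materialize one scenario as concrete TrioVariant(s) with AF 0."""
    out = []
    intron_i = _mid_intron_index(model)

    def _mk(pos, gts, splice):
        ref = _rand_base(rng)
        alt = _rand_base(rng, exclude=ref)
        v = TrioVariant(
            chrom=model.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            proband_gt=gts[0],
            mother_gt=gts[1],
            father_gt=gts[2],
            gene=model.gene,
            population_af=0.0,
            splice=splice,
        )
        used_pos.add((model.chrom, pos))
        return v

    if spec.region_class == "exonic":
        pos = _exonic_pos(model, rng)
        while (model.chrom, pos) in used_pos:
            pos = _exonic_pos(model, rng)
    else:
        pos = _genomic_pos_for_offset(model, intron_i, spec.intron_offset)

    splice = None
    if spec.delta_level == "high":
        off = spec.intron_offset if spec.region_class != "exonic" else None
        splice = _high_splice(off, rng)
    elif spec.delta_level == "low":
        splice = _low_splice(rng)
    out.append(_mk(pos, _PLANT_GENOTYPES[spec.model], splice))

    if spec.compound_het:
        # intronic partner inherited from the other parent, strong donor signal
        partner_pos = _genomic_pos_for_offset(model, intron_i, spec.intron_offset or 3)
        partner_model = (
            M.INHERITED_PATERNAL_HET
            if spec.model == M.INHERITED_MATERNAL_HET
            else M.INHERITED_MATERNAL_HET
        )
        out.append(
            _mk(partner_pos, _PLANT_GENOTYPES[partner_model], _high_splice(spec.intron_offset or 3, rng))
        )
    return out


def _background_variant(models, config: SimConfig, proband_sex: Sex, rng, used_pos: set) -> TrioVariant:
    """One background polymorphism: Mendelian-consistent single-parent het
    transmission (or a planted Mendelian error at the configured rate).

    Novel (AF 0) background sits in non-canonical intronic positions — the
    space the reanalysis newly opens up — while frequency-carrying background
    may be exonic or intronic.
    """
    model = models[int(rng.integers(len(models)))]
    novel = rng.random() < config.novel_af_fraction
    if novel:
        af = 0.0
        intron_i = _mid_intron_index(model)
        intron_len = model.exons[intron_i + 1][0] - model.exons[intron_i][1]
        max_off = max(3, min(intron_len - 3, 400))
        offset = int(rng.integers(3, max_off + 1)) * (1 if rng.random() < 0.5 else -1)
        pos = _genomic_pos_for_offset(model, intron_i, offset)
        splice = _low_splice(rng)
    else:
        lo, hi = config.af_range
        af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        pos = _exonic_pos(model, rng)
        splice = None
    attempts = 0
    while (model.chrom, pos) in used_pos and attempts < 50:
        pos += 1
        attempts += 1
    used_pos.add((model.chrom, pos))

    on_x = model.chrom == "chrX"
    male = proband_sex == Sex.MALE
    error = rng.random() < config.mendelian_error_rate
    if error:
        if on_x and male:
            # hom_alt mother must transmit the alt to her son
            gts = (Genotype.HEMI_REF, Genotype.HOM_ALT, Genotype.HEMI_REF)
        else:
            gts = (Genotype.HOM_ALT, Genotype.HOM_REF, Genotype.HOM_REF)
    elif on_x and male:
        if rng.random() < 0.5:
            gts = (Genotype.HEMI_ALT, Genotype.HET, Genotype.HEMI_REF)
        else:
            gts = (Genotype.HEMI_REF, Genotype.HET, Genotype.HEMI_REF)
    else:
        maternal = rng.random() < 0.5
        proband = Genotype.HET
        if maternal:
            gts = (proband, Genotype.HET, Genotype.HOM_REF)
        else:
            gts = (proband, Genotype.HOM_REF, Genotype.HET)
    ref = _rand_base(rng)
    alt = _rand_base(rng, exclude=ref)
    return TrioVariant(
        chrom=model.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        proband_gt=gts[0],
        mother_gt=gts[1],
        father_gt=gts[2],
        gene=model.gene,
        population_af=round(af, 6),
        splice=splice,
    )


_OUTCOME_CYCLE = tuple(Outcome)
_PHENOTYPE_CYCLE = (
    "multiple_anomalies",
    "hydrops_fetalis",
    "skeletal_disorder",
    "cardiovascular",
    "joubert",
)


def generate_trio_cohort(config: SimConfig, models, constraint_table) -> tuple:
    """Generate per-trio variant sets, the truth table, and the ledger.

    Each trio receives one scenario from config.planted_spec (cycling) plus
    Mendelian-consistent background. Planted variants get AF 0 and the exact
    trio genotype pattern of their model; the truth table records the key,
    model, and intended step of discovery of every planted variant.
    """
    rng = np.random.default_rng(config.seed + 2)
    specs = config.planted_spec
    if config.all_female_probands and any(
        s.model in _MALE_X_MODELS for s in specs
    ):
        raise ValueError("cannot plant male-hemizygous X models in an all-female-proband cohort")

    trios, truth_rows, cases = [], [], []
    for t in range(config.n_trios):
        spec = specs[t % len(specs)] if specs else None
        trio_id = f"trio{t + 1:03d}"
        if config.all_female_probands:
            sex = Sex.FEMALE
        elif spec is not None and spec.model in _MALE_X_MODELS:
            sex = Sex.MALE
        elif spec is not None and spec.model == M.DE_NOVO_X:
            sex = Sex.FEMALE
        else:
            sex = Sex.MALE if t % 2 == 0 else Sex.FEMALE
        ped = Pedigree(
            family_id=trio_id,
            proband_id=f"{trio_id}_p",
            mother_id=f"{trio_id}_m",
            father_id=f"{trio_id}_f",
            proband_sex=sex,
        )
        used_pos: set = set()
        variants = []
        used_genes: set = set()
        phenotype = None
        if spec is not None and spec.intended_stage != DiagnosisStage.UNDIAGNOSED:
            gene_model = _pick_gene(
                models, constraint_table, spec.gene_category, spec.require_low_loeuf, used_genes, rng
            )
            used_genes.add(gene_model.gene)
            planted = _plant_variants(spec, gene_model, rng, used_pos)
            variants.extend(planted)
            phenotype = spec.panel
            for v in planted:
                truth_rows.append(
                    {
                        "trio_id": trio_id,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "gene": v.gene,
                        "scenario": spec.name,
                        "intended_model": _intended_model(spec, v, planted).value,
                        "intended_stage": _intended_variant_stage(spec, v, planted).value,
                        "case_stage": spec.intended_stage.value,
                    }
                )
        for _ in range(config.background_variants_per_trio):
            variants.append(_background_variant(models, config, sex, rng, used_pos))
        variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        trios.append(TrioSim(trio_id=trio_id, pedigree=ped, variants=variants, phenotype=phenotype))
        cases.append(
            CaseRecord(
                case_id=trio_id,
                outcome=_OUTCOME_CYCLE[t % len(_OUTCOME_CYCLE)],
                phenotype_category=phenotype or _PHENOTYPE_CYCLE[t % len(_PHENOTYPE_CYCLE)],
                diagnosis_stage=spec.intended_stage if spec else DiagnosisStage.UNDIAGNOSED,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "trio_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene",
            "scenario",
            "intended_model",
            "intended_stage",
            "case_stage",
        ],
    )
    return trios, truth, CohortLedger(cases=cases)


def _intended_variant_stage(spec: PlantSpec, v: TrioVariant, planted) -> DiagnosisStage:
    """Step at which this particular variant should be admitted.

    For a compound het the exonic partner is visible to the initial
    (step-0) analysis; only the intronic partner waits for the panel step,
    which is when the case as a whole becomes diagnosable.
    """
    if spec.compound_het and v is planted[0] and spec.region_class == "exonic":
        return DiagnosisStage.INITIAL
    return spec.intended_stage


def _intended_model(spec: PlantSpec, v: TrioVariant, planted) -> M:
    if not spec.compound_het or v is planted[0]:
        return spec.model
    return (
        M.INHERITED_PATERNAL_HET
        if spec.model == M.INHERITED_MATERNAL_HET
        else M.INHERITED_MATERNAL_HET
    )


def default_panels(models, constraint_table, truth: pd.DataFrame, rng=None) -> dict:
    """Panels for the phenotype-driven step: each panel holds its planted
    genes plus a few unrelated AR genes."""
    panels = {"meckel": set(), "hydrops": set()}
    for _, row in truth[truth["scenario"] == "panel_compound_het"].iterrows():
        panels["meckel"].add(row["gene"])
    ar_genes = [g for g, a in constraint_table.items() if "AR" in a.modes][:4]
    panels["meckel"].update(ar_genes[:2])
    panels["hydrops"].update(ar_genes[2:4])
    return {k: v for k, v in panels.items() if v}


def simulate_cohort(config: Optional[SimConfig] = None) -> Cohort:
    """End-to-end cohort generation under one seed."""
    config = config or SimConfig()
    models = generate_gene_models(config)
    constraint_table = generate_constraint_table(config, models)
    trios, truth, ledger = generate_trio_cohort(config, models, constraint_table)
    panels = default_panels(models, constraint_table, truth)
    return Cohort(
        config=config,
        gene_models=models,
        constraint_table=constraint_table,
        panels=panels,
        trios=trios,
        truth=truth,
        ledger=ledger,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the cohort as plain-text VCF/PED/BED/TSV files (deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = AUTOSOMES + ("chrX",)
    _io.write_gene_models_bed(cohort.gene_models, out / "genes.bed")

    gene_chrom = {m.gene: m.chrom for m in cohort.gene_models}
    rows = []
    for gene in sorted(cohort.constraint_table):
        a = cohort.constraint_table[gene]
        rows.append(
            {
                "gene": gene,
                "chrom": gene_chrom.get(gene, "chrX" if a.chrom_class == "chrX" else "chr1"),
                "loeuf": a.loeuf,
                "modes": ",".join(sorted(a.modes)),
            }
        )
    pd.DataFrame(rows).to_csv(out / "constraint.tsv", sep="\t", index=False)

    panel_rows = [
        {"panel": p, "gene": g} for p in sorted(cohort.panels) for g in sorted(cohort.panels[p])
    ]
    pd.DataFrame(panel_rows, columns=["panel", "gene"]).to_csv(
        out / "panels.tsv", sep="\t", index=False
    )

    ped_lines = []
    for trio in cohort.trios:
        p = trio.pedigree
        sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[p.proband_sex]
        ped_lines.append(f"{p.family_id} {p.proband_id} {p.father_id} {p.mother_id} {sex_code} 2")
        ped_lines.append(f"{p.family_id} {p.father_id} 0 0 1 1")
        ped_lines.append(f"{p.family_id} {p.mother_id} 0 0 2 1")
        _io.write_trio_vcf(trio.variants, p, out / f"{trio.trio_id}.vcf", contigs=contigs)
    (out / "cohort.ped").write_text("\n".join(ped_lines) + "\n")

    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    ledger_rows = [
        {
            "case_id": c.case_id,
            "outcome": c.outcome.value,
            "phenotype_category": c.phenotype_category,
            "diagnosis_stage": c.diagnosis_stage.value,
        }
        for c in cohort.ledger.cases
    ]
    pd.DataFrame(ledger_rows).to_csv(out / "ledger.tsv", sep="\t", index=False)


def read_ledger(path) -> CohortLedger:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cases = [
        CaseRecord(
            case_id=r.case_id,
            outcome=Outcome(r.outcome),
            phenotype_category=r.phenotype_category,
            diagnosis_stage=DiagnosisStage(r.diagnosis_stage),
        )
        for r in df.itertuples(index=False)
    ]
    return CohortLedger(cases=cases)


def bundled_cohort_ledger() -> CohortLedger:
    """The packaged study-scale ledger: 128 cases — 51 diagnosed at the
    initial analysis, then 2 rescued at step 1, 1 at step 2, and 1 at step 3
    among the 77 initially undiagnosed; 73 remain undiagnosed.

    Per-case outcome and phenotype labels are synthetic placeholders; only
    the stage totals are meaningful.
    """
    stages = (
        [DiagnosisStage.INITIAL] * 51
        + [DiagnosisStage.STEP1] * 2
        + [DiagnosisStage.STEP2]
        + [DiagnosisStage.STEP3]
        + [DiagnosisStage.UNDIAGNOSED] * 73
    )
    cases = [
        CaseRecord(
            case_id=f"case{i + 1:03d}",
            outcome=_OUTCOME_CYCLE[i % len(_OUTCOME_CYCLE)],
            phenotype_category=_PHENOTYPE_CYCLE[i % len(_PHENOTYPE_CYCLE)],
            diagnosis_stage=stage,
        )
        for i, stage in enumerate(stages)
    ]
    return CohortLedger(cases=cases)
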