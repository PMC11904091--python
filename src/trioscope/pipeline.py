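"""Stepwise reanalysis orchestration and cohort yield accounting.

The flow mirrors a stepwise trio-exome reanalysis:

* step 0 — the initial-analysis baseline: exonic and canonical-splice-site
  (+/-2 bp) variants, frequency- and inheritance-filtered;
* step 1 — constraint reprioritization: step-0-scope variants in
  constraint-gated genes (LOEUF <= threshold) with dominant or X-linked
  inheritance modes, ranked by ascending LOEUF;
* step 2 — phenotype-panel screening: all variants (introns included) in
  disease-specific panel genes, splice-screened, no constraint requirement;
* step 3 — genome-wide constrained intronic screening: variants in any
  constraint-gated gene within the boundary window, splice-screened,
  restricted to de novo / X-linked inheritance models.

A variant admitted at one step is never re-emitted at a later step; a
step-0-scope variant that passes the step-1 gate is reported at step 1 (its
most specific admitting step). A case is "diagnosed" at the first step that
admits a candidate whose inheritance fits a plausible disease model — a de
novo, homozygous-recessive, or hemizygous call, or an inherited het that
completes a trans compound-heterozygous pair. Inherited single hets are
listed as candidates but are not diagnostic on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import constraint as _constraint
from . import inheritance as _inheritance
from . import splice as _splice
from .models import (
    CandidateVariant,
    CohortLedger,
    DiagnosisStage,
    Genotype,
    InheritanceModel as M,
    Pedigree,
    Region,
    Step,
)

DIAGNOSTIC_MODELS = frozenset(
    {
        M.DE_NOVO_AUTOSOMAL,
        M.DE_NOVO_X,
        M.X_HEMIZYGOUS_DE_NOVO,
        M.X_HEMIZYGOUS_MATERNAL,
        M.AUTOSOMAL_RECESSIVE_HOM,
    }
)

DEFAULT_STEP3_MODELS = frozenset(
    {M.DE_NOVO_AUTOSOMAL, M.DE_NOVO_X, M.X_HEMIZYGOUS_DE_NOVO, M.X_HEMIZYGOUS_MATERNAL}
)

_STEP1_CATEGORIES = frozenset({"AD", "ADR", "XLD", "XLR", "XLDR"})
_X_DE_NOVO = frozenset({M.DE_NOVO_X, M.X_HEMIZYGOUS_DE_NOVO})


@dataclass
class PipelineConfig:
    loeuf_threshold: float = _constraint.DEFAULT_LOEUF_THRESHOLD
    delta_threshold: float = _splice.DEFAULT_DELTA_THRESHOLD
    window_bp: int = _splice.DEFAULT_WINDOW_BP
    max_af: float = 1e-4
    panels: dict = field(default_factory=dict)
    step3_models: frozenset = DEFAULT_STEP3_MODELS

    def __post_init__(self) -> None:
        if self.loeuf_threshold <= 0 or self.delta_threshold <= 0 or self.window_bp <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.max_af <= 1:
            raise ValueError("max_af must be in [0, 1]")


def frequency_filter(variants, max_af: float):
    """Keep variants at or below max_af; unknown frequency is treated as
    novel (absence from the population database is the operative filter)."""
    if not 0 <= max_af <= 1:
        raise ValueError("max_af must be in [0, 1]")
    return [v for v in variants if v.population_af is None or v.population_af <= max_af]


def _call(variant, pedigree):
    cached = variant.extra_annotations.get("inheritance_call")
    if cached is None:
        cached = _inheritance.classify_trio_genotype(variant, pedigree)
        variant.extra_annotations["inheritance_call"] = cached
    return cached


def _annotation(variant):
    return variant.extra_annotations.get("gene_annotation")


def _candidate(variant, pedigree, step, config, tags=frozenset()):
    cons = None
    if variant.splice is not None and _splice.max_delta(variant.splice) > 0:
        cons = _splice.infer_consequence(variant, variant.splice)
    return CandidateVariant(
        variant=variant,
        inheritance=_call(variant, pedigree),
        gene_annotation=_annotation(variant),
        step=step,
        consequence=cons,
        evidence_tags=tags,
    )


def step0_initial(variants, pedigree: Pedigree, config: PipelineConfig):
    """Initial-analysis baseline: rare exonic / canonical-splice-site
    variants with a classifiable, Mendelian-consistent inheritance call."""
    out = []
    for v in frequency_filter(variants, config.max_af):
        if v.region not in (Region.EXONIC, Region.CANONICAL_SPLICE_SITE):
            continue
        call = _call(v, pedigree)
        if call.model in (M.MENDELIAN_ERROR, M.UNCLASSIFIABLE):
            continue
        out.append(_candidate(v, pedigree, Step.STEP0, config, frozenset({v.region.value})))
    return out


def step1_constraint(step0_candidates, pedigree: Pedigree, config: PipelineConfig):
    """Constraint reprioritization of the step-0 scope.

    Admits candidates whose gene passes the LOEUF gate and whose mode
    category is dominant or X-linked; chrX genes without curated modes
    (X_other) are admitted when the call is de novo, reflecting that
    strongly constrained non-disease-annotated X genes are plausible new
    disease genes. Output is ordered by ascending LOEUF.
    """
    out = []
    for c in step0_candidates:
        ann = c.gene_annotation
        if not _constraint.passes_constraint_gate(ann, config.loeuf_threshold):
            continue
        cat = _constraint.mode_category(ann)
        admitted = cat in _STEP1_CATEGORIES or (
            cat == "X_other" and c.inheritance.model in _X_DE_NOVO
        )
        if not admitted:
            continue
        out.append(
            CandidateVariant(
                variant=c.variant,
                inheritance=c.inheritance,
                gene_annotation=ann,
                step=Step.STEP1,
                consequence=c.consequence,
                evidence_tags=c.evidence_tags | {"loeuf_gate"},
            )
        )
    out.sort(key=lambda c: (c.gene_annotation.loeuf, c.variant.chrom, c.variant.pos))
    return out


def step2_panel(
    variants, phenotype: str, pedigree: Pedigree, config: PipelineConfig, exclude_keys=frozenset()
):
    """Phenotype-driven panel screening over all regions, introns included.

    Panel membership replaces the constraint requirement; intronic records
    must still pass the splice screen (window + delta threshold).
    """
    if phenotype not in config.panels:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; configured panels: {sorted(config.panels)}"
        )
    panel_genes = config.panels[phenotype]
    out = []
    for v in frequency_filter(variants, config.max_af):
        if v.key in exclude_keys or v.gene not in panel_genes:
            continue
        call = _call(v, pedigree)
        if call.model in (M.MENDELIAN_ERROR, M.UNCLASSIFIABLE):
            continue
        ok, tags = _splice.screen_variant(v, config.delta_threshold, config.window_bp)
        if not ok:
            continue
        out.append(_candidate(v, pedigree, Step.STEP2, config, tags | {f"panel:{phenotype}"}))
    out.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt))
    return out


def step3_constrained_genomewide(
    variants, pedigree: Pedigree, config: PipelineConfig, exclude_keys=frozenset()
):
    """Genome-wide intron-inclusive screening of constraint-gated genes,
    restricted to the configured (default de novo / X-linked) inheritance
    models."""
    out = []
    for v in frequency_filter(variants, config.max_af):
        if v.key in exclude_keys:
            continue
        if not _constraint.passes_constraint_gate(_annotation(v), config.loeuf_threshold):
            continue
        call = _call(v, pedigree)
        if call.model not in config.step3_models:
            continue
        ok, tags = _splice.screen_variant(v, config.delta_threshold, config.window_bp)
        if not ok:
            continue
        out.append(_candidate(v, pedigree, Step.STEP3, config, tags | {"loeuf_gate"}))
    out.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt))
    return out


def _has_diagnostic(new_candidates, earlier_candidates, pedigree) -> bool:
    """A step is diagnostic if it admits a fitting-model candidate or
    completes a trans compound-het pair with this or earlier steps'
    admissions."""
    if any(c.inheritance.model in DIAGNOSTIC_MODELS for c in new_candidates):
        return True
    pool = list(earlier_candidates) + list(new_candidates)
    new_keys = {c.variant.key for c in new_candidates}
    by_gene = {}
    for c in pool:
        if c.variant.gene and c.variant.proband_gt == Genotype.HET:
            by_gene.setdefault(c.variant.gene, []).append(c.variant)
    for gene_variants in by_gene.values():
        if len(gene_variants) < 2:
            continue
        for pair in _inheritance.detect_compound_het(gene_variants, pedigree):
            keys = {pair.maternal_variant.key, pair.paternal_variant.key}
            if keys & new_keys:
                return True
    return False


@dataclass
class ReanalysisReport:
    """Per-step candidates, per-step input/output counts, and the stage at
    which the case reached a diagnostic admission."""

    candidates: dict  # Step -> list[CandidateVariant]
    counts: dict  # step name -> {"in": int, "out": int}
    diagnosis_stage: DiagnosisStage

    def all_candidates(self):
        return [c for step in Step for c in self.candidates.get(step, [])]


def run_reanalysis(
    variants,
    pedigree: Pedigree,
    config: PipelineConfig,
    phenotype: Optional[str] = None,
) -> ReanalysisReport:
    """Execute step 0 -> 1 -> 2 (when a phenotype maps to a panel) -> 3.

    The case exits the flow at the first step with a diagnostic admission;
    later steps are not run. Variants admitted at step k are never
    re-emitted later, and step-0-scope variants promoted by the step-1 gate
    are reported once, at step 1.
    """
    variants = list(variants)
    n_in = len(variants)
    scope0 = step0_initial(variants, pedigree, config)
    step1 = step1_constraint(scope0, pedigree, config)
    step1_keys = {c.variant.key for c in step1}
    step0 = [c for c in scope0 if c.variant.key not in step1_keys]

    candidates = {Step.STEP0: step0, Step.STEP1: step1, Step.STEP2: [], Step.STEP3: []}
    counts = {
        "step0": {"in": n_in, "out": len(step0)},
        "step1": {"in": len(scope0), "out": len(step1)},
        "step2": {"in": 0, "out": 0},
        "step3": {"in": 0, "out": 0},
    }

    stage = DiagnosisStage.UNDIAGNOSED
    if _has_diagnostic(step0, [], pedigree):
        stage = DiagnosisStage.INITIAL
    elif _has_diagnostic(step1, step0, pedigree):
        stage = DiagnosisStage.STEP1

    admitted = step1_keys | {c.variant.key for c in step0}

    if stage == DiagnosisStage.UNDIAGNOSED and phenotype is not None and phenotype in config.panels:
        step2 = step2_panel(variants, phenotype, pedigree, config, exclude_keys=admitted)
        candidates[Step.STEP2] = step2
        counts["step2"] = {"in": n_in, "out": len(step2)}
        admitted |= {c.variant.key for c in step2}
        if _has_diagnostic(step2, step0 + step1, pedigree):
            stage = DiagnosisStage.STEP2

    if stage == DiagnosisStage.UNDIAGNOSED:
        step3 = step3_constrained_genomewide(variants, pedigree, config, exclude_keys=admitted)
        candidates[Step.STEP3] = step3
        counts["step3"] = {"in": n_in, "out": len(step3)}
        if _has_diagnostic(step3, step0 + step1 + candidates[Step.STEP2], pedigree):
            stage = DiagnosisStage.STEP3

    return ReanalysisReport(candidates=candidates, counts=counts, diagnosis_stage=stage)


@dataclass
class YieldTable:
    n_cases: int
    n_initial: int
    n_reanalysis: int
    n_undiagnosed_after_initial: int
    initial_yield_pct: float
    reanalysis_yield_pct: float
    by_outcome: pd.DataFrame
    by_phenotype: pd.DataFrame
    by_stage: pd.DataFrame


def tally_yield(ledger: CohortLedger) -> YieldTable:
    """Cohort-level diagnostic yield accounting.

    Initial yield = initially diagnosed / all cases; reanalysis yield =
    cases rescued in steps 1-3 / cases left undiagnosed by the initial
    analysis. Percentages are reported to one decimal.
    """
    if len(ledger) == 0:
        raise ValueError("tally_yield requires a non-empty ledger")
    df = pd.DataFrame(
        {
            "case_id": [c.case_id for c in ledger.cases],
            "outcome": [c.outcome.value for c in ledger.cases],
            "phenotype": [c.phenotype_category for c in ledger.cases],
            "stage": [c.diagnosis_stage.value for c in ledger.cases],
        }
    )
    n = len(df)
    n_initial = int((df["stage"] == DiagnosisStage.INITIAL.value).sum())
    reanalysis_stages = {
        DiagnosisStage.STEP1.value,
        DiagnosisStage.STEP2.value,
        DiagnosisStage.STEP3.value,
    }
    n_re = int(df["stage"].isin(reanalysis_stages).sum())
    n_undx = n - n_initial
    df["diagnosed"] = df["stage"] != DiagnosisStage.UNDIAGNOSED.value

    def _breakdown(col):
        g = df.groupby(col, sort=True)["diagnosed"].agg(n="count", n_diagnosed="sum").reset_index()
        g["diagnosed_pct"] = (100.0 * g["n_diagnosed"] / g["n"]).round(1)
        return g

    by_stage = df.groupby("stage", sort=True).size().rename("n").reset_index()
    return YieldTable(
        n_cases=n,
        n_initial=n_initial,
        n_reanalysis=n_re,
        n_undiagnosed_after_initial=n_undx,
        initial_yield_pct=round(100.0 * n_initial / n, 1),
        reanalysis_yield_pct=round(100.0 * n_re / n_undx, 1) if n_undx else 0.0,
        by_outcome=_breakdown("outcome"),
        by_phenotype=_breakdown("phenotype"),
        by_stage=by_stage,
    )
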