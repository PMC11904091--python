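"""Core domain types shared across the pipeline.

Coordinate conventions: variant positions are 1-based (VCF native); gene-model
exon intervals are 0-based half-open (BED native). The only place the two meet
is intron-offset computation in :mod:`trioscope.splice`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_REF = "hemi_ref"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)


class Region(enum.Enum):
    EXONIC = "exonic"
    CANONICAL_SPLICE_SITE = "canonical_splice_site"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


class InheritanceModel(enum.Enum):
    DE_NOVO_AUTOSOMAL = "de_novo_autosomal"
    DE_NOVO_X = "de_novo_x"
    INHERITED_MATERNAL_HET = "inherited_maternal_het"
    INHERITED_PATERNAL_HET = "inherited_paternal_het"
    AUTOSOMAL_RECESSIVE_HOM = "autosomal_recessive_hom"
    X_HEMIZYGOUS_DE_NOVO = "x_hemizygous_de_novo"
    X_HEMIZYGOUS_MATERNAL = "x_hemizygous_maternal"
    MENDELIAN_ERROR = "mendelian_error"
    UNCLASSIFIABLE = "unclassifiable"


class PhaseConfidence(enum.Enum):
    CERTAIN = "certain"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class InheritanceCall:
    model: InheritanceModel
    phase_confidence: PhaseConfidence = PhaseConfidence.CERTAIN


@dataclass(frozen=True)
class Pedigree:
    """One proband-mother-father trio.

    ``proband_sex`` is required before any X-chromosome classification: male
    probands are hemizygous on X, so the genotype decision table differs.
    """

    family_id: str
    proband_id: str
    mother_id: str
    father_id: str
    proband_sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError("pedigree requires three distinct sample ids")


@dataclass
class SpliceScores:
    """SpliceAI delta scores with pre-mRNA positions, optional Pangolin deltas.

    A delta position (``dp_*``) is only meaningful when the matching delta
    score is positive; positions are signed offsets relative to the variant.
    """

    ds_ag: float = 0.0
    ds_al: float = 0.0
    ds_dg: float = 0.0
    ds_dl: float = 0.0
    dp_ag: int = 0
    dp_al: int = 0
    dp_dg: int = 0
    dp_dl: int = 0
    pangolin_gain: Optional[float] = None
    pangolin_gain_pos: Optional[int] = None
    pangolin_loss: Optional[float] = None
    pangolin_loss_pos: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class MotifScores:
    """Maximum-entropy splice-motif scores (log-odds scale, may be negative)."""

    ref_score: float
    alt_score: float


class SpliceEvent(enum.Enum):
    ACCEPTOR_LOSS = "acceptor_loss"
    ACCEPTOR_GAIN = "acceptor_gain"
    DONOR_LOSS = "donor_loss"
    DONOR_GAIN = "donor_gain"
    NONE = "none"


class PredictedEffect(enum.Enum):
    INTRON_RETENTION = "intron_retention"
    EXON_EXTENSION = "exon_extension"
    EXON_TRUNCATION = "exon_truncation"
    EXON_SKIPPING_POSSIBLE = "exon_skipping_possible"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SpliceConsequence:
    event: SpliceEvent
    predicted_effect: PredictedEffect
    affected_length_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.affected_length_bp is not None and self.predicted_effect not in (
            PredictedEffect.EXON_EXTENSION,
            PredictedEffect.EXON_TRUNCATION,
        ):
            raise ValueError(
                "affected_length_bp only applies to exon extension/truncation"
            )


@dataclass
class TrioVariant:
    """One normalized variant (single alt) with trio genotypes and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    proband_gt: Genotype = Genotype.MISSING
    mother_gt: Genotype = Genotype.MISSING
    father_gt: Genotype = Genotype.MISSING
    gene: Optional[str] = None
    transcript: Optional[str] = None
    region: Optional[Region] = None
    intron_offset: Optional[int] = None
    population_af: Optional[float] = None
    splice: Optional[SpliceScores] = None
    extra_annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_x(self) -> bool:
        return self.chrom.lstrip("chr").upper() == "X"


@dataclass
class GeneModel:
    """Exon structure of one transcript; exons are 0-based half-open genomic
    intervals sorted by start regardless of strand."""

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: list  # list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty exon interval ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("overlapping exons")
            prev_end = end

    @property
    def span(self) -> tuple:
        """(start, end) 0-based half-open genomic span including introns."""
        return (self.exons[0][0], self.exons[-1][1])


MODE_LABELS = ("AD", "AR", "ADR", "XLD", "XLR", "XLDR", "other")


@dataclass
class GeneAnnotation:
    """Per-gene constraint and inheritance-mode annotation.

    ``loeuf`` may be absent: many genes have no constraint score, and such
    genes can never pass the constraint gate but remain eligible for
    phenotype-panel screening.
    """

    gene: str
    chrom_class: str  # "autosome" | "chrX"
    loeuf: Optional[float] = None
    modes: frozenset = frozenset()
    panels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.chrom_class not in ("autosome", "chrX"):
            raise ValueError("chrom_class must be 'autosome' or 'chrX'")
        if self.loeuf is not None and self.loeuf < 0:
            raise ValueError("loeuf must be non-negative")
        bad = set(self.modes) - set(MODE_LABELS)
        if bad:
            raise ValueError(f"unknown inheritance modes: {sorted(bad)}")
        if self.chrom_class == "autosome" and set(self.modes) & {"XLD", "XLR", "XLDR"}:
            raise ValueError(f"autosomal gene {self.gene} with X-linked mode")


@dataclass(frozen=True)
class CompoundHetPair:
    gene: str
    maternal_variant: TrioVariant
    paternal_variant: TrioVariant
    ambiguity_flag: bool = False


class Step(enum.Enum):
    STEP0 = "step0"
    STEP1 = "step1"
    STEP2 = "step2"
    STEP3 = "step3"


@dataclass
class CandidateVariant:
    """A variant that survived a pipeline step, with provenance."""

    variant: TrioVariant
    inheritance: InheritanceCall
    gene_annotation: Optional[GeneAnnotation]
    step: Step
    consequence: Optional[SpliceConsequence] = None
    evidence_tags: frozenset = frozenset()


class Outcome(enum.Enum):
    LIVEBIRTH = "livebirth"
    NEONATAL_DEATH = "neonatal_death"
    FETAL_DEATH = "fetal_death"
    TERMINATION = "termination"
    OTHER = "other"


class DiagnosisStage(enum.Enum):
    INITIAL = "initial"
    STEP1 = "step1"
    STEP2 = "step2"
    STEP3 = "step3"
    UNDIAGNOSED = "undiagnosed"


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    outcome: Outcome
    phenotype_category: str
    diagnosis_stage: DiagnosisStage


@dataclass
class CohortLedger:
    """Per-case diagnostic outcome for cohort-level yield accounting."""

    cases: list  # list[CaseRecord]

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            raise ValueError("case_ids must be unique")

    def __len__(self) -> int:
        return len(self.cases)
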