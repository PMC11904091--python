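"""Readers and writers for the external formats the pipeline touches.

VCF parsing is delegated to cyvcf2; everything here normalizes records into
:class:`~trioscope.models.TrioVariant` and friends. Multiallelic records are
split into one variant per alt allele but are not otherwise normalized (no
indel left-alignment): the pipeline consumes pre-called, pre-normalized VCFs.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from cyvcf2 import VCF

from .models import (
    CandidateVariant,
    GeneAnnotation,
    GeneModel,
    Genotype,
    Pedigree,
    Sex,
    SpliceScores,
    TrioVariant,
)

logger = logging.getLogger(__name__)

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}


def read_pedigree(path, family_id: Optional[str] = None) -> Pedigree:
    """Read a 6-column PED file and return the first complete trio.

    A complete trio is a row whose paternal and maternal ids are both set
    (non-"0"). Sex is decoded from column 5 (1=male, 2=female, else unknown).
    With ``family_id`` given, only that family's rows are considered.
    """
    rows = []
    seen_ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED row with fewer than 6 columns: {line!r}")
            fam, iid, fat, mot, sex = fields[0], fields[1], fields[2], fields[3], fields[4]
            if iid in seen_ids:
                raise ValueError(f"duplicate sample id in PED: {iid}")
            seen_ids.add(iid)
            rows.append((fam, iid, fat, mot, sex))

    for fam, iid, fat, mot, sex in rows:
        if family_id is not None and fam != family_id:
            continue
        if fat != "0" and mot != "0":
            return Pedigree(
                family_id=fam,
                proband_id=iid,
                mother_id=mot,
                father_id=fat,
                proband_sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
            )
    raise ValueError("incomplete trio: no individual with both parent ids set")


def _is_haploid_chrom(chrom: str) -> bool:
    c = chrom.removeprefix("chr").upper()
    return c in ("X", "Y")


def _decode_genotype(
    alleles, alt_index: int, chrom: str, is_male: bool, sample: str
) -> Genotype:
    """Decode cyvcf2 allele indices for one sample against one alt allele.

    ``alt_index`` is the 1-based allele number of the alt under consideration;
    other alt alleles count as ref for this split. Haploid calls and male
    diploid calls on X are coerced to hemizygous genotypes.
    """
    if any(a < 0 for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        if _is_haploid_chrom(chrom):
            if is_male or is_male is None:
                return Genotype.HEMI_ALT if n_alt else Genotype.HEMI_REF
            logger.warning(
                "haploid genotype for female/diploid sample %s on %s; treating as diploid",
                sample,
                chrom,
            )
            return Genotype.HET if n_alt else Genotype.HOM_REF
        logger.warning("haploid genotype on autosome for sample %s; treating as diploid", sample)
        return Genotype.HET if n_alt else Genotype.HOM_REF
    if _is_haploid_chrom(chrom) and is_male:
        # male X: '1/1' (common caller output) coerced to hemizygous
        return Genotype.HEMI_ALT if n_alt else Genotype.HEMI_REF
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_ALT


def parse_spliceai(info_value: str, alt: str, alt_index: int) -> Optional[SpliceScores]:
    """Parse a SpliceAI INFO string (10-field pipe-delimited dialect).

    Format per entry: ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL,
    one comma-separated entry per alt allele. Returns (scores, gene) packed in
    SpliceScores with the gene symbol stashed by the caller.
    """
    if not info_value:
        return None
    entries = str(info_value).replace("−", "-").split(",")
    chosen = None
    for e in entries:
        if e.split("|", 1)[0] == alt:
            chosen = e
            break
    if chosen is None:
        idx = alt_index - 1
        chosen = entries[idx] if idx < len(entries) else entries[0]
    fields = chosen.split("|")
    if len(fields) != 10:
        logger.warning("malformed SpliceAI entry %r; ignoring", chosen)
        return None

    def _f(x):
        return float(x) if x not in ("", ".") else 0.0

    def _i(x):
        return int(x) if x not in ("", ".") else 0

    scores = SpliceScores(
        ds_ag=_f(fields[2]),
        ds_al=_f(fields[3]),
        ds_dg=_f(fields[4]),
        ds_dl=_f(fields[5]),
        dp_ag=_i(fields[6]),
        dp_al=_i(fields[7]),
        dp_dg=_i(fields[8]),
        dp_dl=_i(fields[9]),
    )
    scores._gene = fields[1] or None  # stashed for the caller
    return scores


def _parse_pangolin(info_value: str, scores: Optional[SpliceScores]) -> Optional[SpliceScores]:
    """Parse our PANGOLIN dialect: 'gain_score:pos|loss_score:pos'."""
    if not info_value:
        return scores
    if scores is None:
        scores = SpliceScores()
    try:
        gain_part, loss_part = str(info_value).replace("−", "-").split("|")
        g, gp = gain_part.split(":")
        l, lp = loss_part.split(":")
        scores.pangolin_gain = float(g)
        scores.pangolin_gain_pos = int(gp)
        scores.pangolin_loss = float(l)
        scores.pangolin_loss_pos = int(lp)
    except ValueError:
        logger.warning("malformed PANGOLIN entry %r; ignoring", info_value)
    return scores


def read_trio_vcf(path, pedigree: Pedigree) -> list:
    """Read a joint trio VCF into a sorted list of TrioVariant.

    Multiallelic records are split into one TrioVariant per alt allele. GT is
    parsed accepting '/' and '|' separators; haploid and male-X diploid calls
    decode to hemizygous genotypes. SpliceAI and PANGOLIN INFO strings become
    SpliceScores; AF becomes population_af. Output is sorted by
    (chrom, pos, ref, alt).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    needed = [pedigree.proband_id, pedigree.mother_id, pedigree.father_id]
    missing = [s for s in needed if s not in samples]
    if missing:
        raise ValueError(f"sample mismatch: pedigree samples {missing} absent from VCF header")
    idx = {name: samples.index(name) for name in needed}
    is_male = pedigree.proband_sex == Sex.MALE

    out = []
    for rec in vcf:
        alts = rec.ALT or []
        gts = rec.genotypes  # [[a1, a2, phased], ...] or [[a, phased], ...]
        af_raw = rec.INFO.get("AF")
        spliceai_raw = rec.INFO.get("SpliceAI")
        pangolin_raw = rec.INFO.get("PANGOLIN")
        for k, alt in enumerate(alts):
            alt_index = k + 1

            def _sample_gt(name, male):
                g = gts[idx[name]]
                alleles = list(g[:-1])
                return _decode_genotype(alleles, alt_index, rec.CHROM, male, name)

            proband_gt = _sample_gt(pedigree.proband_id, is_male)
            mother_gt = _sample_gt(pedigree.mother_id, False)
            # father is male by definition: hemizygous on X/Y
            father_gt = _sample_gt(pedigree.father_id, True)

            af = None
            if af_raw is not None:
                af = float(af_raw[k]) if isinstance(af_raw, tuple) else float(af_raw)

            splice = parse_spliceai(spliceai_raw, alt, alt_index) if spliceai_raw else None
            gene = getattr(splice, "_gene", None) if splice is not None else None
            splice = _parse_pangolin(pangolin_raw, splice)

            out.append(
                TrioVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    proband_gt=proband_gt,
                    mother_gt=mother_gt,
                    father_gt=father_gt,
                    gene=gene,
                    population_af=af,
                    splice=splice,
                )
            )
    out.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return out


_GT_ENCODE = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.HEMI_REF: "0",
    Genotype.HEMI_ALT: "1",
    Genotype.MISSING: "./.",
}

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=SpliceAI,Number=.,Type=String,Description="SpliceAI deltas: ALT|GENE|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL">',
    '##INFO=<ID=PANGOLIN,Number=.,Type=String,Description="Pangolin deltas: gain_score:pos|loss_score:pos">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def spliceai_info_string(v: TrioVariant) -> Optional[str]:
    s = v.splice
    if s is None:
        return None
    gene = v.gene or "."
    return (
        f"{v.alt}|{gene}|{s.ds_ag:.2f}|{s.ds_al:.2f}|{s.ds_dg:.2f}|{s.ds_dl:.2f}"
        f"|{s.dp_ag}|{s.dp_al}|{s.dp_dg}|{s.dp_dl}"
    )


def write_trio_vcf(variants, pedigree: Pedigree, path, contigs=None) -> None:
    """Write TrioVariants as an uncompressed VCF 4.2 text file.

    Output is byte-deterministic for a given input; round-tripping through
    :func:`read_trio_vcf` preserves (chrom, pos, ref, alt, genotypes).
    """
    lines = list(VCF_HEADER_LINES)
    if contigs:
        for c in contigs:
            lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join([pedigree.proband_id, pedigree.mother_id, pedigree.father_id])
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info_parts = []
        if v.population_af is not None:
            info_parts.append(f"AF={v.population_af:.6g}")
        sai = spliceai_info_string(v)
        if sai:
            info_parts.append(f"SpliceAI={sai}")
        s = v.splice
        if s is not None and s.pangolin_gain is not None:
            info_parts.append(
                f"PANGOLIN={s.pangolin_gain}:{s.pangolin_gain_pos}"
                f"|{s.pangolin_loss}:{s.pangolin_loss_pos}"
            )
        info = ";".join(info_parts) or "."
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    info,
                    "GT",
                    _GT_ENCODE[v.proband_gt],
                    _GT_ENCODE[v.mother_gt],
                    _GT_ENCODE[v.father_gt],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path) -> list:
    """Read BED exon models (name field 'gene|transcript') into GeneModels."""
    per_tx = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED line {lineno}: expected 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"BED line {lineno}: interval start >= end ({start}, {end})")
            gene, _, tx = name.partition("|")
            key = (gene, tx or gene, chrom, strand)
            per_tx.setdefault(key, []).append((start, end))
    models = []
    for (gene, tx, chrom, strand), exons in per_tx.items():
        models.append(GeneModel(gene=gene, transcript=tx, chrom=chrom, strand=strand, exons=exons))
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene))
    return models


def write_gene_models_bed(models, path) -> None:
    lines = []
    for m in sorted(models, key=lambda m: (m.chrom, m.span[0], m.gene)):
        for start, end in m.exons:
            lines.append(f"{m.chrom}\t{start}\t{end}\t{m.gene}|{m.transcript}\t0\t{m.strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotation_table(path, kind: str):
    """Read a TSV annotation table.

    kind='constraint' -> {gene: GeneAnnotation}; kind='panel' ->
    {panel_name: set(genes)}; kind='frequency' -> {(chrom,pos,ref,alt): af}.
    """
    if kind not in ("constraint", "panel", "frequency"):
        raise ValueError(f"unknown annotation table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)

    if kind == "constraint":
        required = {"gene", "chrom", "loeuf", "modes"}
        if not required <= set(df.columns):
            raise ValueError(f"constraint table must have columns {sorted(required)}")
        out = {}
        for row in df.itertuples(index=False):
            loeuf = None if pd.isna(row.loeuf) or row.loeuf == "" else float(row.loeuf)
            modes = frozenset(
                m for m in str(row.modes).split(",") if m and m != "nan"
            ) if not pd.isna(row.modes) else frozenset()
            chrom_class = "chrX" if str(row.chrom).removeprefix("chr").upper() == "X" else "autosome"
            ann = GeneAnnotation(gene=row.gene, chrom_class=chrom_class, loeuf=loeuf, modes=modes)
            if row.gene in out:
                if out[row.gene].loeuf != ann.loeuf:
                    raise ValueError(f"ambiguous annotation: conflicting LOEUF for gene {row.gene}")
                continue
            out[row.gene] = ann
        return out

    if kind == "panel":
        required = {"panel", "gene"}
        if not required <= set(df.columns):
            raise ValueError("panel table must have columns ['gene', 'panel']")
        out = {}
        for row in df.itertuples(index=False):
            out.setdefault(row.panel, set()).add(row.gene)
        return out

    required = {"chrom", "pos", "ref", "alt", "af"}
    if not required <= set(df.columns):
        raise ValueError(f"frequency table must have columns {sorted(required)}")
    return {
        (row.chrom, int(row.pos), row.ref, row.alt): float(row.af)
        for row in df.itertuples(index=False)
    }


_REPORT_COLUMNS = [
    "step",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "region",
    "intron_offset",
    "inheritance",
    "phase_confidence",
    "loeuf",
    "population_af",
    "max_delta",
    "ds_ag",
    "ds_al",
    "ds_dg",
    "ds_dl",
    "pangolin_gain",
    "pangolin_loss",
    "consequence_event",
    "predicted_effect",
    "affected_length_bp",
    "evidence_tags",
]


def _candidate_row(c: CandidateVariant) -> dict:
    v = c.variant
    s = v.splice
    from .splice import max_delta  # local import to avoid cycle

    return {
        "step": c.step.value,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "gene": v.gene,
        "transcript": v.transcript,
        "region": v.region.value if v.region else None,
        "intron_offset": v.intron_offset,
        "inheritance": c.inheritance.model.value,
        "phase_confidence": c.inheritance.phase_confidence.value,
        "loeuf": c.gene_annotation.loeuf if c.gene_annotation else None,
        "population_af": v.population_af,
        "max_delta": max_delta(s) if s is not None else None,
        "ds_ag": s.ds_ag if s else None,
        "ds_al": s.ds_al if s else None,
        "ds_dg": s.ds_dg if s else None,
        "ds_dl": s.ds_dl if s else None,
        "pangolin_gain": s.pangolin_gain if s else None,
        "pangolin_loss": s.pangolin_loss if s else None,
        "consequence_event": c.consequence.event.value if c.consequence else None,
        "predicted_effect": c.consequence.predicted_effect.value if c.consequence else None,
        "affected_length_bp": c.consequence.affected_length_bp if c.consequence else None,
        "evidence_tags": ";".join(sorted(c.evidence_tags)),
    }


def write_report(candidates, path, format: str = "tsv") -> None:
    """Write candidate variants as TSV or JSON, deterministically ordered by
    (step, chrom, pos, alt)."""
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    rows = [_candidate_row(c) for c in candidates]
    rows.sort(key=lambda r: (r["step"], r["chrom"], r["pos"], r["alt"]))
    if format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1, default=str)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_REPORT_COLUMNS, delimiter="\t")
        writer.writeheader()
        for r in rows:
            writer.writerow({k: ("" if v is None else v) for k, v in r.items()})
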