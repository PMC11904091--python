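# Methods

## The model

`trioscope` treats a sequenced parent–offspring trio as three jointly
genotyped samples and reduces variant interpretation to three orthogonal
filters, applied stepwise:

1. **Inheritance.** Each variant's trio genotype triple is mapped through a
   total decision table over (chromosome class, proband sex, genotypes). De
   novo calls require the proband to carry the alternate allele with both
   parents homozygous reference; a genotype configuration no gamete pairing
   can produce is a Mendelian error; anything uninformative (missing
   genotypes, non-carriers, chrY/MT, het variants whose transmitting parent
   cannot be identified because both parents carry the allele) is
   unclassifiable and excluded from inheritance-gated steps while remaining
   in the raw table. The classifier is GT-only: no allele-depth mosaicism
   model and no read-backed phasing. Compound heterozygotes are phased
   purely by parental transmission — every (possibly-maternal,
   possibly-paternal) het pair in one gene is emitted, flagged ambiguous
   when either partner is carried by both parents.
2. **Constraint.** Genes are gated on LOEUF ≤ 0.35 (inclusive boundary; the
   threshold is a config parameter). Genes without a score fail the gate but
   are never dropped from the phenotype-panel step, which is
   phenotype-driven rather than constraint-driven.
3. **Splice signal.** Exonic and canonical ±1/±2 variants always enter
   evaluation. Intronic variants must lie within a fixed window of an
   exon–intron boundary (default 150 bp per boundary) *and* have a maximum
   SpliceAI delta (over acceptor/donor gain/loss) above 0.2. The maximum is
   used as the aggregate because single dominant events are what the scores
   flag; Pangolin deltas are carried as corroborating evidence only and
   never gate a variant (a `pangolin_rescue` tag records disagreement).

### Orchestration semantics

Steps run 0 → 1 → 2 → 3 with three rules chosen where the design was open:

* **Promotion.** Step 1's scope is exactly step 0's output, so a variant
  passing the constraint gate is reported once, at step 1 — its most
  specific admitting step — rather than twice. Step 1 also admits
  unannotated chrX genes (`X_other`) when the call is de novo, since
  strongly constrained non-disease-annotated X genes are plausible novel
  disease genes.
* **Diagnostic admission.** "Diagnosed" means a step admitted a candidate
  whose inheritance fits a plausible disease model: de novo (autosomal or
  X), hemizygous (de novo or maternal), recessive homozygous, or an
  inherited het completing a trans compound-het pair with a candidate from
  the same or an earlier step. A lone inherited het in a recessive gene is
  a candidate but not a diagnosis — which is exactly why a panel-step
  intronic partner can convert an initially non-diagnostic exonic stop-gain
  into a step-2 diagnosis. The case exits the flow at its first diagnostic
  step; later steps are not run. ACMG-style classification is out of scope;
  reports are candidate lists with evidence tags.
* **Frequency.** Variants with population AF above `max_af` (default 1e-4,
  a conventional rare-disease cutoff; the source study does not print its
  own) are removed everywhere; an absent AF is treated as novel, since
  absence from the population database is the operative filter.

### Splice-consequence inference

The dominant event is the delta type with the largest score. Loss of the
adjacent canonical site (donor loss downstream of a donor, acceptor loss
upstream of an acceptor, or either loss for an exonic variant) predicts
intron retention. An acceptor gain at intron offset −n (n > 2) predicts an
exon extension of n − 1 bp: the convention is that the variant base is the
G of a novel AG acceptor dinucleotide, so the intronic bases between the
novel and the canonical acceptor enter the transcript (offset −6 → 5 bp).
Other geometries return `unknown` rather than guessing. Consequence
inference keys on the variant's intron offset, not on the delta positions,
whose sign conventions vary between annotation sources.

### Motif-score change

The maximum-entropy splice-motif score change is reported as
`100 × (alt − ref) / |ref|`, rounded to two decimals. The absolute-value
denominator keeps the sign meaningful when the reference score is negative
(a motif score is a log-odds and can legitimately be < 0); the quantity is
undefined at ref = 0 and raises.

### Coordinates

VCF positions are 1-based; gene models are 0-based half-open BED intervals;
the two meet only inside `intron_offset`, which returns HGVS-style offsets
in transcript orientation (+n after a donor, −n before an acceptor,
strand-aware, ties at the intron midpoint resolving to the donor side).
Multiallelic records are split per alt but not left-aligned — the pipeline
consumes pre-called, pre-normalized VCFs. Male X diploid calls (`1/1`) are
coerced to hemizygous; a haploid call for a female proband is warned about
and treated as diploid.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `loeuf_threshold` | 0.35 | — | constraint gate for haploinsufficiency-driven prioritization |
| `delta_threshold` | 0.2 | — | SpliceAI screening cutoff (max of four deltas) |
| `window_bp` | 150 | bp | intronic screening distance per exon–intron boundary |
| `max_af` | 1e-4 | fraction | rare-disease population-frequency cutoff |
| `step3_models` | de novo + X-linked | — | genome-wide step focuses on dominant-acting models |

## The synthetic cohort

The generator emulates the *conditions* of a clinical trio cohort, not its
sequences: six contigs (chr1–chr5, chrX), non-overlapping multi-exon genes
on both strands (2–20 exons of 50–300 bp, introns of 0.5–5 kb), a
constraint table whose X-linked disease categories draw LOEUF from
N(0.15, 0.08) against N(0.60, 0.20) for AD and N(0.90, 0.25) for AR
(clipped ≥ 0.01) — reproducing the X-versus-AD constraint gap — and
per-trio VCFs containing:

* one planted scenario per trio, cycling through: a plain exonic de novo
  (initial diagnosis), a canonical-site X de novo and a hemizygous exonic
  missense in constrained X genes (step-1 rescues), a compound het with an
  intronic donor-loss partner in a panel gene (step-2 rescue), a de novo
  hemizygous acceptor-gain at offset −6 in a constrained X gene (step-3
  rescue), and an undiagnosed case;
* background polymorphisms, 30% novel (AF 0) and 70% with log-uniform AF on
  [1e-4, 0.5], transmitted as single-parent-carrier hets (Mendelian errors
  planted at a configurable rate). Novel background is placed at
  non-canonical intronic positions with SpliceAI deltas drawn from
  Beta(1, 30) — concentrated below 0.1 with rare excursions past the 0.2
  threshold — while frequency-carrying background is exonic. This reflects
  a cohort entering reanalysis: rare exonic candidates were already
  adjudicated by the initial analysis, and the intron space is where new
  signal (and new false-positive risk) lives. It also makes each planted
  variant's intended step of discovery well defined.

What the generator does **not** model: real human gene coordinates,
sequence context (no FASTA; REF/ALT are random bases), linkage between
variants, mosaicism, indels, CNVs, and population structure. Passing the
recovery tests therefore demonstrates that the *logic* of the stepwise
filters is correct under the stated conditions — not that the thresholds
are clinically optimal on real exomes.

The bundled study-scale ledger encodes the cohort totals of the motivating
study design (128 cases; 51 initially diagnosed; of the 77 remaining, 2
rescued at step 1, 1 at step 2, 1 at step 3), yielding 39.8% initial and
5.2% reanalysis yield. Its per-case outcome and phenotype labels are
synthetic placeholders; only the stage totals are meaningful.

## Numerical choices and degenerate inputs

* Welch's *t* test is delegated to `scipy.stats.ttest_ind(equal_var=False)`
  with Welch–Satterthwaite degrees of freedom; both groups constant and
  equal gives t = 0, p = 1; groups smaller than 2 raise. Pairwise
  category comparisons report raw two-sided p-values plus a labelled
  Bonferroni-adjusted column.
* The dominant splice event uses a fixed tie-break order (acceptor gain,
  acceptor loss, donor gain, donor loss) and treats deltas below 1e-12 as
  absent.
* `percent_motif_variation` is scale-invariant under positive scaling of
  both scores.
* All generator randomness flows through one `numpy` Generator per
  concern, seeded from `SimConfig.seed`; identical configs produce
  byte-identical output files.

## Problem sizes

The test suite simulates cohorts of 30 trios (120 background variants
each, the default) for end-to-end recovery and 100 trios (60 background
variants each) for the filter-monotonicity and step-exclusivity sweeps;
the Welch null-calibration uses 1,000 replicates of 30-vs-30 samples.
These sizes give stable statistics for every assertion while keeping the
full suite in the seconds range.

## Known limitations

* Phase is transmission-based only; a truly de novo het paired with an
  inherited het is never called compound heterozygous.
* The spec's inheritance vocabulary has no dedicated label for an X-linked
  recessive homozygous female, which is reported under the single
  recessive-homozygous label, nor for a het whose carrier parent cannot be
  determined, which is reported unclassifiable with ambiguous phase.
* The 150 bp window is symmetric and fixed per boundary; variable
  ("average") windows are not modelled.
* SpliceAI/Pangolin scores are consumed as annotations; the package never
  runs the networks, and the maximum-entropy model behind motif scores is
  not fitted here — only the score *change* is computed.
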