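# Methods

This note documents the models and procedures implemented in
`ctdna_horizon`, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Duplex consensus model

A duplex read family is one original cfDNA template molecule: a UID plus
replicate reads from each of its two strands. Calling proceeds in three
layers:

1. **Strand consensus.** Per strand, the plurality base over the replicate
   reads, requiring `min_reads_per_strand` (default 2) reads and a
   plurality agreement of `min_agreement` (default 0.9); ties or
   insufficient reads yield "ambiguous". These are conventional duplex
   thresholds and are configuration, not constants.
2. **Molecule call.** With both strand consensuses present: the same
   non-reference base on both strands is `duplex_mutant`; both reference is
   `duplex_reference`; different bases is `discordant` (the signature of
   single-strand damage — never counted as mutant). Exactly one consensus
   is `single_strand_only`; none is `uncalled`. The five statuses partition
   the molecules covering a site.
3. **Site call.** Distinct mutant molecules = distinct UIDs called
   `duplex_mutant` for the queried alt; evaluable = mutant + reference
   molecules; MAF = mutant / evaluable (undefined and flagged at zero
   evaluable). Any mutant molecule in the matched leukocyte library sets
   the matched-normal exclusion flag (germline/CHIP signature). Sites with
   < `min_normal_templates` (default 1000) evaluable normal molecules or
   < `min_evaluable` (default 100) evaluable plasma molecules are flagged,
   not auto-excluded; both thresholds are judgement defaults exposed in
   `CallParams`.

Why duplex works, quantitatively: with per-read error e = 1e-3 and ~4 reads
per strand, a wrong *consensus* on one strand needs coordinated errors
(~e²-scale); a wrong *duplex* call needs both strands wrong in the same way,
which only a genuine double-strand event can produce efficiently. The
generator's error taxonomy mirrors this: per-read sequencing errors
(independent), single-strand damage applied to one random strand of a
template, and double-strand artifacts that alter both strands and are
indistinguishable from true mutations by construction. The measured duplex
background therefore converges to the double-strand artifact rate (default
1e-7 per template) while single-strand calling's background sits near the
single-strand damage rate (1e-5) — the contrast asserted in the tests.

## Targeted panel

The panel is an annotation object: regions with gene and role
(oncogene/tumor suppressor), a hotspot lookup keyed by (chrom, pos, alt),
and a tumor-suppressor gene set. A call is *oncogenic* iff it matches a
hotspot or is a truncating variant inside a tumor-suppressor region.
Positivity requires ≥ 2 distinct duplex-confirmed mutant molecules in at
least one retained (oncogenic, not normal-excluded) mutation; the
"per-mutation vs summed across mutations" reading of the threshold is a
config switch (`per_mutation`, default true, the literal reading). Both
mutant molecules must be duplex-confirmed; single-strand support never
counts.

The shipped default panel layout (121 regions over 40 genes named after
canonical drivers, 1–2 hotspots per oncogene region) is synthetic: the
logic is the point, not the coordinates, and any real annotation can be
supplied as BED + hotspot table or YAML.

## Bespoke panel design

From plasma-vs-leukocyte WGS pileups:

* **Candidate caller** — a deliberate simplification of a full somatic
  caller: retain sites with plasma VAF ≥ 0.005, plasma alt reads ≥ 4,
  normal depth ≥ 15 and zero normal alt reads. The 0.5% VAF bound is the
  assay's stated applicability limit; the others are count-caller
  judgement defaults exposed in `CandidateParams`.
* **Exclusion cascade** — five filters with per-candidate verdicts:
  repeats, difficult alignments and SNP positions (mask **or** annotation
  flag; either evidence source excludes), hard-to-amplify regions (flag;
  operationalised in the generator as extreme GC), and CpG transitions
  computed from sequence context (C→T followed by G, or G→A preceded by C),
  never from a mask.
* **Selection** — rank by plasma VAF descending, ties broken by genomic
  coordinate (deterministic and input-order invariant), cap at 96 (the
  multiplex size). Ranking by VAF alone stands in for "VAF plus sequencing
  quality"; the quality dimension is carried by the min-alt/min-depth gates
  rather than a composite score.
* **Bona-fide validation** — a candidate is scored only if duplex-confirmed
  in the participant's plasma (≥ 1 mutant molecule, both strands), with
  zero mutant molecules in deep leukocyte duplex data and zero in an
  unrelated cancer-free control's plasma. The leukocyte check removes
  CHIP and residual germline; the unrelated-control check removes
  recurrent, position-specific artifacts that are plasma-intrinsic and
  therefore invisible to the leukocyte comparison. Candidates without
  coverage in a validation library are flagged unevaluable, not assumed
  clean.
* **Personalized calling** — only bona-fide mutations are scored; one
  mutant molecule anywhere on the panel is a positive. With n mutations of
  per-mutation detection probability q, sample-level sensitivity is
  ≈ 1 − (1−q)^n — the sensitivity-gain property the tests verify against
  simulation. The per-sample MAF aggregate is the mean over *detected*
  mutations (switchable to all bona-fide mutations via `maf_over`). At low
  expected molecule counts this conditional mean is upward-biased, which
  compresses measured Early/Very-Early fold-changes relative to their
  configured truth; the reports therefore treat fold-changes as
  descriptive statistics of the assay, not unbiased estimators.
* **Alternate normal** — when leukocytes are unavailable the Very Early
  plasma can serve as the matched normal (its neoplastic content is
  negligible); `simulate_wgs_pileups(..., normal_source="very_early_plasma")`
  reproduces this workaround, including its known blind spot for CHIP.

## Tumor-fraction HMM

An openly simplified estimator in the ichorCNA mold. Counts in fixed bins
(5 Mb at full genome scale; 500 kb on the scaled default genome so the bin
*count* stays comparable) are normalized as log2(count / sample median)
minus a panel-of-normals per-bin median (controls only; default n = 124,
configurable down to 20 for fast tests). The HMM has copy-number states
{1, 2, 3, 4}, Gaussian emissions with mean log2((t·c + (1−t)·2)/2) and one
shared variance, self-transition probability 0.99, and a start distribution
strongly favoring the neutral state. EM alternates forward–backward
posteriors with a bounded 1-D update of t ∈ (0, 0.5] and a closed-form
variance update; it is restarted from normal-fraction initialisations
{0.95, 0.99, 0.995, 0.999} (t₀ = 0.05 … 0.001) and the best-likelihood
restart wins. Ploidy is fixed at 2, autosomes only, no subclonal states.
Positive = t ≥ 0.03.

Numerical choices worth knowing:

* **The neutral state's mean is 0 for every t**, so a profile with no
  aneuploid segments carries no information about t and EM simply stays
  near its initialisation. The fitted t is therefore reported as 0 (and the
  sample negative) whenever the Viterbi path assigns fewer than
  `min_aneuploid_bins` (default 5) bins to non-neutral states. This guard
  is what makes the estimator specific at t = 0.
* The t bound at 0.5 and the 4-copy state cap keep EM identifiable at low
  tumor content (an unbounded t can explain a gain of 3 as a smaller gain
  of 4); both are configurable.
* Transition/start parameters are this module's own; convergence is
  declared at a log-likelihood change < 1e-3 (max 50 iterations), with the
  best iterate returned and flagged if unconverged.
* No GC or mappability correction is implemented because the paired
  generator introduces no GC bias; against real WIG/readCounter data these
  corrections would be required upstream.

## Cohort decision flow

Per participant: targeted panel on the Early plasma; if negative, the
aneuploidy screen on Early low-depth bins (never both arms); if
Early-positive and the MAF proxy exceeds the 0.5% feasibility cutoff,
bespoke design + validation, then personalized scoring of the Early and
Very Early samples. For aneuploidy-only positives the MAF proxy is the
estimated tumor fraction / 2 (the expected clonal MAF at that tumor
fraction) — such participants always clear the cutoff since positivity
already requires t ≥ 0.03. Missing Very Early samples propagate as
"Sample not available"; personalized-negative Very Early samples as
"Mutation not detectable"; fold-changes are "Not applicable" when the Very
Early MAF is zero or undefined, and the median fold is taken over defined
ratios only (even counts: midpoint of the central pair). Report rounding:
MAFs to 2 decimals in percent, ratios to 1 decimal, confidence bounds to
whole percent.

**Blinding.** No calling stage reads case/control labels. The panel of
normals and the unrelated validation control are dedicated synthetic
normals outside the cohort, so the flow never needs a labeled control's
data; a label-permutation test asserts that every calling output is
invariant under label shuffling. Sensitivity (k/n over cases) uses the
Wilson score interval (`statsmodels` wilson `proportion_confint`, with
exact 0/1 boundary handling).

## What the generator emulates — and what it does not

Emulated: template-molecule sampling per site (order 10³ per 5 mL plasma,
default 1500; leukocyte libraries default 6000), duplex families with
strand loss (default 0.1/strand) and Poisson replicate reads (mean 4), the
three error classes above, germline variants (dosage 0.5/1.0, flagged as
polymorphisms), CHIP clones shared between leukocytes and plasma (cell
fraction ≤ 0.3, occasionally at oncogenic hotspots so the leukocyte
exclusion is load-bearing), clonal somatic mutations at plasma MAF
t·cf/2, cohort-recurrent plasma-only artifact sites (only the
unrelated-control check can reject them), plasma-only WGS library
artifacts, segment-level aneuploidy as whole/part-chromosome gains and
losses, and overdispersed bin counts (negative binomial, mean 50,000
reads/bin ~ 5 Mb windows at ~1× with ~100 bp reads, variance ≈ 1.25 μ).

Not emulated: fragment-level sequence (no FASTQ, alignment, or mapping
ambiguity), GC/mappability bias, PCR duplicate structure beyond replicate
counts, indels and multi-nucleotide variants, UID collisions, subclonal
copy-number structure, and inter-site dependence. Consequently, passing
tests demonstrate that the *decision logic and estimators* behave correctly
under the stated statistical model — they do not certify performance
against real sequencing artifacts, which are richer than three error rates.

The benchmark scenario (26 cases / 26 controls, eight shedders: seven with
1–3 panel driver mutations at Early MAFs 0.33–26.3% and fold-decreases of
8.6–79 where the Very Early sample stayed detectable, one aneuploidy-only
case at tumor fraction 0.06, one case without a Very Early sample) is an
emulation of the reference study design in `datasets.py`, not a fit to its
data. Cases beyond the configured shedders are non-shedding (tumor
fraction 0) but still carry somatic mutations, as real undetected cancers
would; controls carry only germline and CHIP truth.

Scale: the default genome is 22 autosomes × 10 Mb. All rates and per-site
quantities are scale-free; only the *number* of genomic bins and the
genome-wide mutation inventory are reduced. Problem sizes used by the test
suite and acceptance script (500 sites × 1500 templates per MAF point, 10⁶
control molecules for background rates, 50 seeds for tumor-fraction
recovery) were chosen so the statistical assertions have comfortable power
at interactive runtimes.

## Known limitations

* The candidate caller is a count threshold, not a genotype-likelihood
  caller; at 80× plasma depth it recovers few true mutations below ~2% VAF
  (binomial P(alt ≥ 4) is the binding constraint), so low-MAF participants
  get small panels — the same cost-driven limitation that makes the assay
  "applicable above 0.5% MAF" with deeper WGS.
* Detected-mutation MAF aggregates are conditionally biased upward near the
  single-molecule detection floor (see above).
* The HMM's tumor-fraction estimate is undefined without copy-number
  evidence; a tumor that sheds without aneuploidy is invisible to this arm
  by construction.
* Wilson intervals are reported for the cohort's 26 cases; with eight
  positives the interval is wide (17–50%), and the synthetic cohort's
  sensitivity is configured, not discovered.
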