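# ctdna-horizon

Tumor-naive circulating-tumor-DNA (ctDNA) detection, implemented as a
tested, reusable pipeline with a seeded synthetic cfDNA cohort generator so
that every stage runs end to end without any sequencing data.

## The problem

Multicancer early detection (MCED) tests look for tumor-derived DNA in
blood plasma, often years before clinical diagnosis. At that horizon the
mutant allele fraction (MAF) of ctDNA can be orders of magnitude below the
error rate of ordinary sequencing, and no tumor tissue exists yet to tell a
test which mutations to look for. This package implements, at desk scale,
the analysis workflow of a tumor-naive MCED strategy:

1. **Duplex consensus calling** (`ctdna_horizon.duplex`) — every original
   cfDNA template molecule is tagged with a UID and both of its strands
   (Watson and Crick) are sequenced independently. A molecule is scored
   mutant only when both strand consensuses agree on the same non-reference
   base; requiring concordance suppresses single-strand errors (polymerase
   miscalls, strand-specific damage) by orders of magnitude. MAF = mutant
   molecules / evaluable molecules.
2. **Targeted driver panel** (`ctdna_horizon.targeted`) — a fixed multiplex
   panel (synthetic default: 121 regions across 40 driver genes) screened
   with the duplex caller. A mutation counts only if it is oncogenic (a
   hotspot, or truncating in a tumor suppressor) and absent from the matched
   leukocytes, which removes germline variants and clonal hematopoiesis
   (CHIP). Positive = any retained mutation with **≥ 2** distinct mutant
   molecules.
3. **Aneuploidy screening** (`ctdna_horizon.cna`) — low-depth WGS read
   counts in fixed genomic bins, normalized against a panel of normals, fed
   to a copy-number HMM whose state *c* has emission mean
   log2((t·c + (1−t)·2)/2) at tumor fraction *t*. EM over a grid of
   low-tumor-fraction initialisations estimates *t*; positive = *t* ≥ 0.03.
4. **Bespoke (personalized) panel design** (`ctdna_horizon.bespoke`) — from
   high-depth plasma WGS against ~30x leukocyte WGS, candidate somatic
   mutations are called by counts, filtered (repeats, hard alignments,
   hard-to-amplify regions, SNP positions, CpG transitions), ranked by
   plasma VAF and capped at 96. Each candidate is *bona fide* only if
   duplex-confirmed in plasma, absent in deep leukocyte duplex data, and
   absent in an unrelated control's plasma. On this panel a **single**
   mutant molecule is a positive — the sensitivity needed to find the same
   tumor ~3 years earlier, when MAFs are 8–80× lower.
5. **Cohort orchestration** (`ctdna_horizon.cohort`) — the decision flow
   over a case-control cohort (targeted panel → aneuploidy for the
   negatives → personalized panel for the positives with MAF > 0.5%),
   longitudinal Early / Very Early MAF fold-changes, and sensitivity /
   specificity with the Wilson score interval.

The synthetic generator (`ctdna_horizon.simulate`) emulates the data these
stages consume: duplex read families with strand-asymmetric error modes
(per-read errors 1e-3, single-strand damage 1e-5, double-strand artifacts
1e-7 per template), germline/CHIP/somatic variants at their expected allele
fractions (a clonal somatic mutation at tumor fraction *t* has plasma MAF
*t*/2), WGS pileups with plasma-only artifacts, and overdispersed bin
counts consistent with segment-level aneuploidy.

## Worked example

The benchmark scenario is a 26-case / 26-control cohort in which eight
cases shed detectable ctDNA at the Early timepoint (seven through panel
driver mutations with MAFs 0.33–26%, one through aneuploidy only):

```python
from ctdna_horizon import (
    simulate_cohort, run_cohort, RunParams, benchmark_scenario,
)

cohort = simulate_cohort(benchmark_scenario(seed=0))
outcomes, summary = run_cohort(cohort, RunParams())
print(summary.summary())
```

```
Cohort summary
============================================================
cases / controls                26 / 26
positives among cases           8
positives among controls        0
sensitivity                     31% (8 of 26; 95% CI: 17 to 50%)
median Early/Very Early fold    19.9
  P001: 0 of 16 panel mutations detected at Very Early (0%)
  P002: 4 of 6 panel mutations detected at Very Early (67%)
  P005: 2 of 9 panel mutations detected at Very Early (22%)
  P006: 40 of 40 panel mutations detected at Very Early (100%)
  P007: 1 of 1 panel mutations detected at Very Early (100%)
  P008: 0 of 37 panel mutations detected at Very Early (0%)
```

All eight configured shedders are detected and no control scores positive;
the sensitivity line is the Wilson interval for 8/26. Per participant, the
personalized panel re-scores the Very Early sample (drawn ~3 years before
the Early one): high shedders keep nearly all panel mutations detectable
(P006), low shedders lose most or all of them, and the fold column in the
report tables quantifies the MAF drop. `run_cohort(..., out_dir=...)`
additionally writes `outcomes.tsv`, a summary table, a per-positive report
table, a paired-MAF plot, and a JSON-lines log of every stage decision.

The same stages are exposed on the command line:

```bash
ctdna-horizon init-config --out scenario.yaml
ctdna-horizon simulate --config scenario.yaml --out cohort/ --seed 0
ctdna-horizon run-cohort --in cohort/ --out results/
```

plus stage subcommands (`call-duplex`, `call-targeted`, `design-panel`,
`call-panel`, `make-pon`, `cna`) operating on VCF/BED/TSV files.

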