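# Methods

## Case definition and stratification

A cohort member is a school-aged child with high myopia (HM): spherical
equivalent refraction SER = sphere + cylinder/2 of −6.00 D or less in both
eyes, with decimal visual acuity below 1.0.  Eligibility is enforced at
load time (`--no-eligibility-check` style escape hatch via
`eligibility_check=False` exists for synthetic edge cases).

Severity strata partition the HM range of SER:

| stratum | SER (D) |
|---|---|
| CHM (common) | −8.00 ≤ SER ≤ −6.00 |
| UM (ultra) | −10.00 ≤ SER < −8.00 |
| EM (extreme) | SER < −10.00 |

Boundary values belong to the milder group (−8.00 → CHM, −10.00 → UM), so
the three half-intervals are disjoint and cover (−∞, −6].  Grade bands are
primary (age ≤ 11), junior (12–14) and senior (≥ 15); an explicit grade
column takes precedence over age when present.

Which eye's SER defines a participant's severity stratum is genuinely
open — clinical reports differ, and per-eye analyses are the usual
robustness check.  We expose it as configuration
(`eye ∈ {right, left, mean, worse}`, default right) and always emit
per-eye sensitivity strata in the report, so the choice is visible rather
than baked in.

## Filter cascade

Thresholds, with defaults and rationale:

- `dp_min = 10`, `gq_min = 20` — standard exome joint-calling floor for a
  usable genotype; comparisons are strict (`DP = 10` is kept).
- allele balance in (0.2, 0.8) for heterozygous calls, strict on both
  sides; a het call with zero summed allelic depth cannot be checked and
  is masked.  Masking is idempotent and applies before any frequency is
  computed.
- `maf_threshold = 0.005` against each of three external databases and the
  in-cohort AF.  A database that has never seen the allele contributes no
  evidence of commonness, so a missing frequency is treated as 0 — the
  usual rare-disease convention.  Exclusion is strict (`maf > 0.005`), so
  an allele at exactly 0.005 survives.
- the in-cohort AF uses post-QC genotypes: masked calls drop out of both
  the allele count and the allele number.  On non-PAR X, males contribute
  one allele; a male alternate call counts one.

Consequence classes: PTV = {frameshift, splice acceptor, splice donor,
stop gained, start lost}; synonymous only in the absence of a PTV term;
everything else "other".  Unknown terms are logged once and treated as
other.  Known variants (user-supplied chrom/pos/ref/alt list) bypass the
PTV-class requirement but pass through QC, rarity and inheritance
unchanged — whether they should also skip QC is unknowable from the
available description, and applying the full cascade is the conservative
reading.

Inheritance-mode consistency removes configurations that cannot explain a
recessive or dominant disease: single het hits in AR genes and homozygous
hits in AD genes.  Two or more distinct het hits in one AR gene in one
sample are presumed compound heterozygous (in trans); without trio phasing
this overcalls when both hits are on one haplotype, which is a known and
accepted bias of case-only designs.  A het hit co-occurring with a hom hit
in the same AR gene is counted as part of a multi-hit genotype.  X-linked
genes: hemizygous males qualify; females follow the AR-style rule by
default, switchable per gene to dominant for female-limited X-linked
genes (e.g. ARR3-type inheritance) via `xl_female_dominant_genes`.

## ACMG 2015 engine

Only evidence derivable from the pipeline's own inputs is assigned
automatically:

- **PVS1** — PTV consequence in a gene whose disease mechanism is loss of
  function (`lof_mechanism_genes`; default: all panel genes).
- **PM2** — every available external MAF ≤ 1 × 10⁻⁴ (or absent).  The
  cutoff is configurable; automated classifiers use values between 0 and
  10⁻⁴ and none is canonical.
- **BA1** — any external MAF > 0.05; **BS1** — any external MAF above the
  rare-variant threshold (0.005) but not in BA1 territory.  BA1 and BS1
  are mutually exclusive by construction: the stand-alone code subsumes
  the strong one.

All other codes (segregation, de novo, functional, computational
consensus) need data a case-only cohort lacks and are accepted from an
optional per-variant evidence TSV.

The combiner implements the full 2015 table: Pathogenic = PVS1 + (≥1 PS |
≥2 PM | PM+PP | ≥2 PP), or ≥2 PS, or 1 PS + (≥3 PM | 2 PM+≥2 PP |
1 PM+≥4 PP); Likely pathogenic = PVS1+1 PM, 1 PS+1–2 PM, 1 PS+≥2 PP,
≥3 PM, 2 PM+≥2 PP, or 1 PM+≥4 PP; Benign = BA1 or ≥2 BS; Likely benign =
1 BS+1 BP or ≥2 BP.  No rule fired, or rules fired on both sides
(contradictory evidence) → VUS.  The combiner is a total, order-independent
function of the evidence set and is tested exhaustively against an
independently transcribed rule table over all 1024 subsets of a 10-code
universe.

By default only P/LP/VUS hits count toward the yield
(`include_benign=False`): a reference analysis that retains a small number
of benign-classified alleles in its variant list leaves ambiguous whether
they contributed to carrier counts, and excluding them is the defensible
default.

## Statistics

The involved-variants yield of a stratum is carriers/n, where a carrier
has ≥ 1 qualifying hit.  The Cochran-Armitage statistic uses scores
(1, 2, 3) for CHM < UM < EM; the statistic is invariant under affine score
transformations, so equal spacing is a convention, not an assumption.
Z is signed (positive = yield rises with severity) and the p-value is
two-sided from the standard normal.  Degenerate tables (no carriers or all
carriers) return Z = 0, p = 1 with a warning; empty strata are excluded
from trend tests.  Z² equals the Pearson trend chi-square (N·r² on
subject-level score/carrier vectors), which the tests verify on random
tables, and the asymptotic p agrees with a conditional permutation mid-p
at 300 per group within Monte-Carlo error.

2×2 contrasts use the Pearson χ² without continuity correction by default
(`yates` flag available).  The multiple-testing threshold is α/m with
default 0.05/4 = 0.0125, covering the four analyses (right eye, left eye,
PTV, synonymous).  Note that 0.05/4 is 0.0125, not 0.01; reports print the
computed value.

The synonymous negative control runs rare synonymous alleles through the
identical cascade (including inheritance filtering) and the same trend
machinery; under a severity-flat generation rate its trend should be null.

## Synthetic-cohort generator

The generator emulates a case-only HM screening cohort:

- **Strata** — nine grade × severity cells; severity groups of equal size
  (default 2000) split across grades by the cohort's grade mix (5.71% /
  31.70% / 62.59%), with carrier probabilities 7.66% / 8.70% / 11.90% for
  CHM / UM / EM and a male fraction of 52.74%.
- **Phenotypes** — SER is sampled uniformly within each severity
  interval (EM truncated at −15 D), which makes group assignment exact by
  construction; cylinder is uniform in [−3, 0] and sphere back-computed.
- **Carriers** — each carrier receives either a known variant (probability
  0.49, matching the roughly even split between known-variant and novel
  PTV diagnoses) or a private PTV consistent with the gene's mode: AD het,
  AR hom or two distinct hets (probability 0.5 each), XL-male hemizygous.
  Known variants live in AD genes and are shared by at most
  ⌊0.005 · 2N⌋ carriers so they stay under the rarity cutoff.
- **Decoys** — non-carriers receive, with probability 0.15, one
  non-qualifying allele (single AR het, AD hom, externally common PTV, or
  off-class missense); a few shared VQSR-failing, low-complexity-region
  and multi-allelic records exercise the site prefilter and decomposition.
- **Negative control** — each sample independently carries a rare
  synonymous het in an AD gene with probability 0.05, flat across
  severity.
- **Sequencing model** — DP ~ max(20, Poisson(60)), GQ uniform 30–99, het
  allele fraction uniform in (0.3, 0.7); `qc_corruption` pushes a chosen
  fraction of alternate calls below one QC threshold (DP, GQ or AB) and
  flags them in the ground truth.
- **External MAFs** — injected rare alleles are absent from each database
  with probability 0.5, otherwise log-uniform up to 5 × 10⁻³; common
  decoys uniform in [0.01, 0.5].

The ground truth recomputes constructively — not via the pipeline code —
which calls must survive: QC flags, site status, the post-QC AF, class or
known status, and the per-gene inheritance rule.  With no corruption the
pipeline's qualifying-hit set must equal it exactly, and does, across
seed-swept replicates.

What the generator does **not** model: linkage disequilibrium, phasing,
sequencing error profiles, population structure, relatedness, CNVs/SVs,
and genes with mixed or uncertain inheritance.  Passing tests therefore
demonstrate correctness of the filtering and statistics under clean,
well-specified inputs, not robustness to the full messiness of real exome
data.

The bundled 75-gene panel (16 nonsyndromic HM / 27 eye syndrome /
32 systemic syndrome) is a synthetic reconstruction with plausible modes,
sufficient for exercising every code path; it is not a curated clinical
panel.

## Problem sizes

The default simulation scale — 2000 samples per severity group for
study-scale replicates, ~500 samples for seed-swept cascade-equivalence
sweeps, 10⁵ draws for the permutation comparison, 100 seeded replicates
for the trend/control contrast — keeps the whole suite fast while leaving
binomial standard errors (~0.6 percentage points per group at n = 2000)
small relative to the 4.2-point CHM→EM yield gradient.  The replicate
sweep uses the generator's carrier model directly (the binomial layer that
the file-level path provably reproduces), with one full file-level
replicate per run confirming the end-to-end contrast.

A cohort-scale caveat: reference values of the trend statistics
(e.g. Z ≈ 2.55 overall) depend on group denominators that are not public;
they are not reproducible from printed marginals and are not targets of
this package's checks, which instead verify the statistic against
closed-form and permutation oracles.

## Numerical notes

- Frequencies print in two-decimal scientific notation (8.05 × 10⁻⁵ for a
  singleton het among 6215 diploid samples, 1.61 × 10⁻⁴ for a hom).
- Multi-allelic records are decomposed before filtering; allelic depths
  are reassigned per alternate allele; a genotype with any missing allele
  is missing for every decomposed row.
- Yield percentages are rounded half-even to two decimals only at the
  reporting boundary; all internal computation is on proportions.
- All generator randomness flows from a single integer seed through
  `numpy.random.default_rng`; fixed seed ⇒ byte-identical output files.
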