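# Methods

## Model of the data

A-to-I editing is observed only through mismatches between aligned reads
and the genomic reference: a reference adenosine with G-carrying reads, or
— when the read derives from the antisense strand representation — a
reference thymidine with C-carrying reads. The pipeline is deliberately
reference-base-driven: it never infers read strand, and classifies a
column solely by its reference base (A with G reads, T with C reads).
These are the same two signatures that enter the Alu Editing Index, so the
caller and the index are consistent by construction. Non-canonical
mismatches (A→C, A→T, T→A, T→G) are treated as noise.

All analysis is restricted to Alu intervals because inverted Alu pairs
host the overwhelming majority of human editing; restricting the
denominator to Alu A/T bases is what makes the AEI comparable across
samples with different coverage profiles.

## Filtering cascade and its rationale

- **Multimapped reads** are removed by flag *or* MAPQ < 20. Spliced
  aligners emit multimappers as secondary records with low MAPQ, so the
  two prongs overlap; treating either as disqualifying reproduces the
  published behaviour without re-running an aligner.
- **PCR duplicates**: flagged records are dropped; unflagged reads sharing
  (contig, start, CIGAR, strand) are collapsed to one representative —
  the highest mean base quality, ties broken by read name. The
  representative choice is unspecified in standard dedup tools; this rule
  is deterministic and auditable.
- **Junction reads** are split at N CIGAR operations into
  reference-contiguous segments; per-base evidence is preserved exactly
  (verified against a per-base reference walk).
- **Read-start masking** (default 5 bases) is applied in *sequencing*
  orientation — for reverse-strand alignments the sequencer's first bases
  sit at the 3′ end of the stored sequence — because the artifact being
  suppressed (random-hexamer mispriming) happens at the sequencing start.
  Masked bases keep their position (read length unchanged) but carry a
  sentinel quality of −1 and can never enter a pileup, regardless of the
  base-quality threshold.
- **Base quality ≥ 25** is enforced at pileup time, per base.

The mapped-read count used for normalisation is fixed at load time
(primary, non-duplicate, mapped records) and is *not* recomputed after
filtering: it is the sequencing-depth denominator, not a post-filter
statistic.

## Site calling

The caller counts mismatches directly instead of running a
genotype-likelihood caller: a site needs depth ≥ 5, ≥ 2 reads of the
canonical edited base, a position outside the known-SNP mask, and a
non-canonical mismatch fraction ≤ 10% (columns above that are likely
mapping artifacts). Direct counting is deterministic, and the AEI is
independent of the caller by construction since it sums over all Alu A/T
columns — matches included — whether or not a site was called. All three
thresholds are configurable (`CallParams`).

Heterozygous A/G SNPs look exactly like 50%-edited sites; the mask is
therefore load-bearing, and the test suite asserts zero calls at masked
positions across simulations (and that without the mask, miscalls do
occur).

## Statistics

- **Wilcoxon signed-rank, one-sided.** The a-priori hypothesis is that
  deaminase depletion reduces editing, so the default alternative is
  "knockdown < control". Zero differences are dropped; ties among nonzero
  |differences| get midranks. For n ≤ 25 with distinct |differences| the
  exact null distribution is computed by the generating-polynomial
  convolution over rank subsets — identical to enumerating all 2^n sign
  assignments (the test oracle does exactly that at small n); otherwise
  the normal approximation with continuity and tie correction is used.
  At n = 5 donors the only rejection at α = 0.05 is the all-reduced
  pattern, p = 1/32 ≈ 0.031 — the exact test is conservative.
- **Donor effect as a blocking factor.** Per gene, the model
  `value = μ + condition + donor + ε` is fitted by ordinary least squares
  (numpy closed form, one shared design for all genes). For balanced
  complete designs the condition estimates coincide with those of a
  donor-random-effect mixed model, and for two conditions the contrast
  t-test is exactly the paired t-test (asserted to 1e-10 in the suite).
  This trades REML variance components for determinism; with ≥ 3 donors
  and an (almost) complete design nothing is lost at these sizes. Fewer
  than two donors observed in two conditions is an error.
- **Multiplicity.** BH step-up across genes, per contrast. Pairwise
  contrasts are each reported in full rather than Tukey-adjusted; the
  studentized-range step would change only within-gene adjustment and is
  noted as a departure in the result metadata (`results_to_frame` keeps
  one row per unit × contrast).

## Normalisation

Editing events are counted as (called site, sample) pairs and scaled to
**events per million mapped reads**. Only "normalise to sequencing depth"
is externally prescribed; the 10^6 scale is this package's choice for
interpretability and is recorded in the normalised-output header. Unique
site counts are reported separately (`GeneEditingTable.unique_sites`)
since "number of events" is ambiguous between site×sample occurrences and
distinct sites. Gene assignment uses the full genomic span (introns
included) because Alu editing is predominantly intronic/3′-UTR; sites in
overlapping genes credit every gene, with multiply-assigned events
tallied in the table's report fields.

## The simulator: what it emulates, what it does not

Emulated: gene-embedded Alu intervals on a uniform-random toy genome;
editing sites planted at Alu A/T positions with condition-dependent
frequencies and per-donor multiplicative scalars; heterozygous SNPs
(allele fraction 0.5) disjoint from editing sites, installed into the
known-SNP mask; per-base substitution errors; exact-copy flagged PCR
duplicates; secondary (multimapped) records at MAPQ 1; junction reads
with 50–500 bp intron gaps; base qualities uniform in 30–40 with a 2%
fraction in 10–24 to exercise the quality filter; single-end reads,
half flagged reverse.

Defaults state the simulated world of the end-to-end checks: 10 genes on
~100 kb, 20 Alu intervals of 300 bp, 200 editing sites at frequency 0.25
(control) vs 0.10 (knockdown), 50 SNPs, depth 50×, error rate 0.1%,
duplicate rate 5%, multimap rate 5%, junction rate 10%, five donors with
scalars {1.0, 0.9, 1.1, 0.95, 1.05}. A fixed seed makes the SAM output
byte-identical.

Not emulated: paired-end fragments (the per-segment filtering and pileup
logic is identical), indels, quality-score miscalibration, strand-specific
library structure, alignment error (reads are emitted aligned, so
coordinates are exact), expression-level variation between genes, and
reference repeats that would cause genuine mapping ambiguity. A green
end-to-end test therefore establishes the correctness of the *counting and
inference machinery* on reads whose alignments are true — not robustness
to alignment artifacts, which is an aligner property.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; conversions
  happen only at file boundaries (VCF/GTF are 1-based on disk).
- An AEI with zero informative bases raises an error rather than
  returning 0 — an undefined index must not masquerade as "no editing".
- All paired differences zero → degenerate-data error (the signed-rank
  test is undefined); a sample with zero mapped reads but nonzero events →
  inconsistency error; zero-read zero-event samples normalise to 0.
- Reference-N columns are skipped with a log message; N read bases never
  enter counts.
- CIGARs whose first or last reference-consuming operation is N are
  rejected as malformed.
- Editing frequency is stored as the exact ratio edited/depth; the sites
  VCF round-trips by recomputing it from the integer INFO fields.

## Known limitations

- The caller's evidence thresholds (5× depth, 2 edited reads) are
  pragmatic defaults, not estimates; at very low coverage, sensitivity
  depends on them strongly.
- The blocked linear model assumes homoscedastic residuals across
  conditions and will diverge from a REML mixed model on unbalanced
  designs with many missing cells.
- Normalising events to mapped reads does not account for gene-level
  expression changes: a gene whose transcript disappears loses "events"
  without any change in per-molecule editing. The AEI, computed over
  covered bases, is the complementary per-base measure.
- Hyper-editing clusters, non-Alu sites and C-to-U editing are out of
  scope.
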