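# Methods

This note documents the models implemented in `reversionscan`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions that were genuinely open.

## Coding model and frame arithmetic

A gene is represented by one canonical `CodingTranscript`: an exon layout
(1-based inclusive genomic intervals covering exactly the CDS, ordered 5'→3'
in transcript orientation) plus the coding-strand CDS. All internal
coordinates are 1-based HGVS-style `c.` positions; VCF's anchored-base indel
convention is converted at the I/O boundary by suffix-then-prefix allele
trimming. Trimming canonicalises most representations; full left-alignment
across long repeat runs is not performed, so a deletion inside a repeat may
project to an equivalent (sequence-identical) but differently anchored
coordinate. All downstream logic operates on spliced sequences, so verdicts
are unaffected; only printed coordinates can shift within a repeat.

Variant projection respects strand (alleles are reverse-complemented on
minus-strand transcripts), returns nothing for intronic positions, clips
deletions to the coding interval, and raises on a reference-allele mismatch
(corrupt input). Mutation application allows overlapping lesions only in one
biologically meaningful configuration: a deletion that fully encompasses
another change absorbs it (a large somatic deletion removing the germline
lesion); any partial overlap is rejected as an ambiguous haplotype.

Consequence classification is frameshift iff the net length shift is not a
multiple of 3; frameshift notation follows the `X{codon}Yfs*N` pattern with
the codon index `ceil(cds_start / 3)` and `N` the offset of the novel stop in
the shifted frame, computed by actually translating the mutated sequence
(standard nuclear code, first in-frame stop terminates).

## Reversion detection

Three gates, in order:

1. **Window.** Somatic indels whose first affected codon is within ±200
   codons of the germline lesion's first affected codon. The window is
   symmetric because documented reversions occur both up- and downstream;
   the bound is configurable. Substitutions are admitted only when the
   germline variant is a nonsense codon (a reversion point mutation
   restoring a sense codon).
2. **Phase.** Read-pair phasing requires at least three fragments carrying
   the alternate allele at both sites, and additionally a cis majority over
   conflicting (alt/ref) fragments — the conservative tie-break chosen here
   for sequencing artifacts; the underlying support threshold is a hard
   invariant. A fragment whose germline site is removed by the somatic
   deletion is coded `deleted` and is uninformative, which is exactly why
   encompassing deletions get the fallback: cis is inferred when the
   overlapping segment has minor copy number 0 and the observed germline VAF
   is within ±0.10 (configurable) of the loss-of-wild-type expectation —
   if only the mutant allele remains, it is the only possible substrate for
   the somatic deletion. A trans verdict (≥ 3 trans fragments, zero cis) is
   an output extension beyond the cis certification and is flagged as such.
3. **Frame.** The doubly mutated CDS must carry a combined net shift of
   0 mod 3 over the surviving lesions and translate from ATG to a stop at
   its natural end with no premature stop anywhere. Checking the whole
   translation (rather than only the bridged region) is deliberate:
   restoration must yield a full-length open reading frame.

Mechanism labels: `encompassing_deletion` when the somatic deletion absorbs
the germline lesion, `delins` when the somatic side is a
deletion-plus-insertion, `compensating_indel` otherwise. Multiple calls per
patient are allowed (polyclonal reversion).

## Zygosity and expected VAF

The specimen is a mixture of tumor cells (purity p) with integer
allele-specific copy state and normal cells contributing two copies:

    E[VAF](p, t, m) = m·p / (t·p + 2·(1 − p))

The mutated copy number m is chosen by maximising the binomial likelihood of
the observed alt-read count over m ∈ {1..t}; `biallelic_loss_of_wt` requires
minor copy 0 and m = t. This pure-somatic mixture form is also used for
germline VAF consistency in the LOH phasing fallback; it ignores the one
mutant copy contributed by contaminating normal cells at a germline site,
which biases the expectation downward at low purity. The ±0.10 consistency
window absorbs this at moderate purity, and the synthetic generator draws
VAFs from the same model, so round trips are exact by construction. Gene-level
biallelic status additionally accepts a LoF mutation co-occurring with a
homozygous deletion, a fusion, or a second somatic LoF mutation. Sex
chromosomes are out of scope (the normal compartment is always diploid);
variants without a unique overlapping segment are indeterminate.

## HRD scar scores

Computed on a profile smoothed by removing segments shorter than 3 Mb and
re-merging adjacent equal-state segments. Merging bridges gaps only up to the
3 Mb smoothing length: removed segments are by construction shorter than
that, while an unbounded merge would fuse distinct same-state scars across a
whole arm and silently change telomere/centromere relationships.

* **LST**: breakpoints between consecutive same-arm segments, both ≥ 10 Mb,
  with differing (total, minor) state. Segments overlapping the centromere
  belong to no arm, so centromere-straddling transitions never count.
* **HRD-LOH**: segments with minor copy 0, total copy ≥ 1 (homozygous
  deletions are not LOH), length > 15 Mb, not spanning a whole chromosome.
* **NtAI**: allelically imbalanced segments (2·minor ≠ total) reaching a
  contig end without crossing the centromere; no minimum length by default.

Thresholds (3 / 10 / 15 Mb) follow the canonical published definitions of the
three scores and are configuration values; the goal is fidelity to those
definitions, not bit-compatibility with any particular segmentation-suite
release, whose version-specific deviations are acknowledged. HRD-sum is the
exact unweighted component sum on every input. Purity-decile summaries use
rank-based quantile bins (median, Q1, Q3 per bin; ≥ 10 records required).

## Mutational signatures

Catalogs use the canonical 96 channels (six pyrimidine substitution classes ×
5' base × 3' base); purine-reference substitutions are folded onto the
pyrimidine strand by reverse complement. Exposures maximise the multinomial
log-likelihood via EM with the update
`w_k ← w_k · Σ_c x_c S_kc / (Σ_j w_j S_jc) / N`, uniform initialisation,
convergence at a log-likelihood gain below 1e−8, at most 10,000 iterations —
deterministic, with per-iteration monotonicity asserted. No sparsity penalty
or signature pre-selection is applied, and no exome-territory channel
renormalisation (a configuration hook exists in the matrix input: supply a
renormalised matrix). The signature matrix is an input TSV (96 channels × K
columns); tests and evaluation use synthetic well-separated matrices, so no
external signature database is required anywhere.

## Cohort statistics

Prevalence percentages are rounded half-up to one decimal, the convention
that reproduces printed figures exactly. Rate comparisons use the two-sided
Fisher exact test (probability-mass criterion), delegated to
`scipy.stats.fisher_exact` and cross-checked in the test suite against an
exhaustive hypergeometric enumeration to 1e−12. Durations are summarised by
median/min/max with the mean-of-middle-two convention for even counts.

## Synthetic-data generator

The generator emulates the study conditions: ~30% canonical BRCA-associated
lineages (breast, ovarian, prostate, pancreas), germline carrier rates of
5.5% in that group and 1.4% elsewhere, a 0.4 : 0.6 BRCA1 : BRCA2 carrier
split, platinum exposure in half the cohort, and a reversion rate among
platinum-exposed carriers defaulting to the observed order of magnitude
(≈ 11/846 ≈ 1.3%); recovery experiments raise this rate (0.30, with a 0.25
polyclonal fraction) so that 2000-patient cohorts contain planted positives
of every mechanism class — a test-design choice about coverage, not a claim
about prevalence. Planted reversions are verified at generation time by an
independent splice-and-translate check, and planted lesions keep a 6-nt
buffer from each other so indel re-alignment can never create a partial
overlap. Background somatic noise includes frameshift indels inside the
search window that carry trans or no read-pair support, which the phasing
gate must reject.

Reference transcripts are random CDSs (600 codons for BRCA1 on the minus
strand, 800 for BRCA2 on the plus strand — reduced lengths that keep the
±200-codon window meaningful while making whole-cohort scans fast), split
over three exons on one contig per gene.

Scar-count profiles plant one event per chromosome arm on a uniform
synthetic build (200 Mb contigs, 95–105 Mb centromeres), so planted events
cannot interact through smoothing; each event is then dropped independently
with probability 1 − s(purity), where s is a logistic detection sensitivity
(midpoint 0.5, slope 10 by default; `None` means s ≡ 1). The logistic
mechanism is a declared stand-in for the real purity-dependence of
copy-number event detection; it exists to make the qualitative
purity-attenuation trend testable, not to model any particular caller.
Signature catalogs are multinomial draws from a known mixture; the default
mixture weight (0.44) mirrors the scale of reported HRD-signature fractions.

What passing tests therefore show: the pipeline recovers exactly what was
planted under its own generative assumptions (noise-free read pairs, exact
VAFs, clean segment profiles, one transcript per gene). What they do not
show: robustness to alignment artifacts, multi-nucleotide repeat ambiguity
beyond trimming, subclonal copy number, splice-region reversions, or real
caller error profiles — all out of scope by design.

## Problem sizes used in the evaluation experiments

Brute-force ORF equivalence uses 500 random CDSs (≤ 300 nt) with exhaustive
somatic deletions ≤ 6 nt (~5·10⁵ comparisons); the phasing audit 10,000
random configurations; end-to-end recovery three 2000-patient cohorts; scar
recovery 100 seeds; the purity trend 200 tumors; signature recovery 50
Monte-Carlo draws of 10,000 mutations; zygosity recovery 500 loci at depth
100–300. These sizes give stable, reproducible measurements at interactive
runtimes.

## Known limitations

* One canonical transcript per gene; no isoform resolution, splice-site
  effects, or UTR variants.
* No structural-variant (rearrangement-mediated) reversions.
* The LOH phasing fallback inherits the clonality assumption: a "clonal"
  loss-of-wild-type event is operationalised purely as the VAF-consistency
  window, since no quantitative clonality criterion is defined.
* The C-terminal last-exon filter needs per-gene domain bounds supplied in
  configuration; no default bounds are shipped.
* Headline per-sample values from protected patient data (e.g. specific
  HRD-sums or signature fractions) are not reproducible here; the evaluation
  is property-based against planted ground truth plus printed-count
  arithmetic.
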