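# Methods

## The problem this package models

Shotgun proteomics searches MS/MS spectra against a protein database; a
peptide absent from that database is invisible no matter how abundant it is.
Integrating RNA-seq from the same tissue fixes this: each sample's observed
variants and splice events are applied to the reference transcript models,
translated, and appended to the search space, producing a *sample-specific
protein database*. Peptides identified only against these augmented entries
("non-reference" peptides) are direct protein-level evidence for
single-amino-acid variants (SAAVs) or unannotated transcript isoforms.
`varipept` implements that workflow for a two-group (case/control) tissue
cohort — database construction, peptide classification, spectral-count
quantification, differential testing, splice-variant usage testing, and
gene-set / interaction-network statistics — together with a synthetic-study
generator so the full chain is testable without any external data.

## Sample-specific databases

Transcript models carry the coding exon chain in 0-based half-open genomic
coordinates (GTF and VCF are converted at the I/O boundary only). Per
sample, the database is the canonical proteome plus:

- one `saav` record per transcript hit by ≥1 non-synonymous SNV of that
  sample. All of a sample's variants on a transcript are substituted jointly
  before translation, so multiple hits in one codon produce the codon that
  actually carries both changes. Synonymy is decided on the translated
  product: a transcript with only synonymous variants adds no record.
- one `novel_isoform` record per novel-exon event listing the sample. An
  exon whose length is a multiple of 3 is treated as in-frame.

Only SNVs are supported; indels are rejected with an explicit error. A
premature stop codon truncates the protein and raises a warning rather than
aborting — peptides upstream of the stop remain valid search evidence. The
canonical set is always a subset of every sample database (augmentation is
strictly additive), and FASTA headers encode provenance machine-readably:
`>{protein_id}|{provenance}|{source_transcript}|{gene_id}|{sample_id}[|{annotations}]`.
A `confirmed_gene_model` provenance label is reserved for externally
validated gene models but never emitted.

## Digestion and peptide classification

Tryptic digestion cleaves C-terminal to K/R except before proline, with at
most 2 missed cleavages and peptide length 7–35 by default (field-standard
shotgun settings; all overridable). Digestion is implemented directly — the
deterministic positional ordering and the plain cleavage predicate are part
of the module contract — and is checked in the tests against both an
exhaustive substring-enumeration oracle and pyteomics.

Classification compares each observed peptide against two hash indexes built
under one matching convention: the canonical digest and the union of sample
digests. Isoleucine and leucine are isobaric, so by default peptides are
compared with I collapsed to L; this can only merge would-be novel peptides
into the reference set, never the reverse, which protects against false
novelty claims (strict matching is a flag). Categories:

- `reference_unique` / `reference_ambiguous` — in the canonical digest,
  split by the number of genes whose proteins contain the peptide. Only
  uniquely mapping peptides are quantified at gene level.
- `nonref_saav` — absent from canonical, present only in SAAV records.
- `nonref_novel_isoform` — absent from canonical, present in ≥1 novel
  isoform record. A peptide explainable by both a SAAV and a novel isoform
  takes this label (deterministic tie-break; the ambiguity is visible in the
  index).
- `unmatched` — absent everywhere; reported, never silently dropped.

## Quantification, filters, normalization

Gene-level spectral counts sum the PSMs of `reference_unique` peptides;
ambiguous and non-reference peptides contribute to no gene. Two rules
operate on **raw** integer counts (thresholds are integer PSM counts, so
filtering precedes normalization):

- presence filter: keep features with ≥`min_psm` (3) counts in at least
  `min_case` (5) case samples or `min_control` (4) control samples;
- group exclusivity: a non-reference peptide is case-exclusive when every
  control count is zero, it is present (count > 0) in ≥4 case samples and
  totals ≥5 PSMs; symmetrically for controls.

Upper-quartile normalization divides each sample by the 75th percentile of
its **nonzero** counts (linear/type-7 interpolation), with factors rescaled
to geometric mean one. Stated this precisely so runs are reproducible
bit-for-bit: the convention is idempotent on the normalized view (factors
return 1 within 1e-12) and equivariant under per-sample rescaling.

## Differential expression

Counts are modeled as negative binomial with variance mu + phi mu^2.

- *Dispersion*: per-feature method of moments on depth-adjusted counts,
  pooled within groups — phi_hat = max(0, (s^2 − mu)/mu^2) — then averaged
  50/50 with the 10%-trimmed mean of all raw estimates. The shrinkage
  stabilizes the noisy per-feature moments at n = 10 vs 8; simulations in
  the test suite recover phi = 0.4 within [0.2, 0.6] and stay below 0.05 on
  Poisson data.
- *Test*: conditional exact test on the case/control split of the feature
  total. Group sums are NB with mean lambda·S_g and dispersion phi/n_g
  (S_g = summed scale factors, the effective library size; equal per-sample
  means within a group are assumed, which holds after normalization). The
  two-sided p sums the probabilities of all splits no more likely than the
  observed one (minimum-likelihood ordering — well defined for asymmetric
  discrete nulls and symmetric under label exchange). At phi = 0 this
  reduces exactly to the conditional binomial test. A zero total gives
  p = 1.
- log2 fold-changes use normalized group means with pseudo-count 0.5;
  Benjamini–Hochberg controls FDR (0.05 for the main list, 0.01 for the
  network view). Transcript concordance takes proteins below the FDR cutoff
  whose transcript p < 0.05 with a matching fold-change sign.

Measured on the simulation design (NB phi = 0.3, 10 vs 8, 2000 features, 20
replicates; computed by the acceptance tests): null type-I error ≈ 0.05
(required window [0.03, 0.07]), realized false-discovery proportion ≤ 0.10
at FDR < 0.05 with 10% planted |log2fc| = 2 effects, power ≥ 0.70. Two-group
testing is deliberately unadjusted — no covariates (e.g. age/sex) enter the
model.

## Exon usage

Usage is the inclusion fraction inclusion/total at the event locus per
sample; 0/0 is missing (the sample is excluded), and any per-sample
numerator/denominator pair is accepted, so junction-read and
transcript-quantification definitions both fit. The group comparison is a
two-sided Mann–Whitney U test: the exact permutation null when the pooled
sample size is ≤ 25 and the data are tie-free, otherwise the tie-corrected
normal approximation with continuity correction. Exact p-values double the
smaller tail (capped at 1) and match a full-enumeration oracle for all
pooled sizes ≤ 12 in the tests.

## Enrichment and network statistics

Over-representation is the one-sided hypergeometric upper tail with BH
adjustment across sets; the background universe defaults to the
post-filter quantified genes (the detected proteome), not the whole
annotation, which corrects for detection bias. Sets are intersected with
the universe first; disjoint sets are excluded with a warning.

Network statistics run on a generic undirected edge list with per-edge
evidence labels (`database` / `experimental` / `both`); labels are carried
through but not filtered by default. Within-set degrees are computed on the
differential set's induced subgraph. The connectivity permutation test
draws `n_perm` uniform subsets of the universe with the differential set's
size and reports p = (1 + #{null ≥ observed}) / (n_perm + 1) — the add-one
estimator never returns 0 and p is reproducible for a fixed seed.

## The synthetic study

Defaults emulate the study design end to end: 10 cases vs 8 controls; ~30
genes with 2–4 coding exons each (split at codon boundaries), CDS beginning
ATG and ending at a stop, every third gene (including the novel-exon host)
on the minus strand; NB(mu = 20, phi = 0.3) PSM counts per peptide with
|log2fc| = 2 effects on 15% of genes; per-(sample, gene) coding SNVs at rate
0.25, restricted to sense, non-I/L alternate codons so every planted SAAV is
non-synonymous, non-truncating and MS-detectable; and one in-frame 714-nt
novel exon (238 residues) planted in an intron of the minus-strand host
gene, included in case samples with probability 0.9 and control samples with
probability 0.1. The exon's residues are arranged in 8–12-residue tryptic
blocks ending in K/R so junction-spanning peptides of observable length
exist by construction. Usage counts draw total locus reads ~ Poisson(60)
and inclusion reads ~ Binomial(total, 0.45 for carriers, 0.02 background).
Transcript counts reuse the NB machinery with a configurable
`concordant_fraction` (default 0.5 — neither stated by the emulated design
nor derivable, chosen so concordant and discordant genes both occur);
non-concordant true-DE genes get the opposite transcript sign so both
extremes (0 and 1) are exactly constructible. Network inputs are an
Erdos–Renyi edge list (density 0.08) with a clique planted on up to 8 true
DE genes, and gene sets partitioning the genome with one set collecting the
true DE genes plus three bystanders.

Everything is a pure function of (config, seed): per-stage RNG substreams
are spawned from one seed sequence, so identical configs give byte-identical
output files, and changing one stage's parameters does not reshuffle another
stage's draws.

What the generator does **not** emulate: identification error and decoy
statistics (the PSM table is error-free by construction), peptide
detectability/ionization efficiency (every admissible tryptic peptide of a
quantified gene is observable), retention times and spectra, read-level
RNA-seq evidence (inclusion is an explicit flag, not modeled read support),
genotype phasing/heterozygosity, UTRs and non-coding transcripts, and
realistic gene/protein length and homology structure. Passing tests
therefore demonstrate correctness of the analysis logic under the stated
count model — not robustness to search-engine errors or to real proteome
redundancy.

## Numerical and degenerate-input choices

- Upper-quartile factor: percentile of nonzero counts, linear interpolation;
  an all-zero sample is a hard error naming the sample.
- Exact-test two-sidedness: minimum-likelihood ordering with a 1e-9
  relative tolerance when comparing split probabilities (guards against
  floating-point ties); probabilities computed in log space and normalized.
- Dispersion: mu = 0 features get phi_hat = 0; fewer than 2 samples per
  group is an error.
- Mann–Whitney: ties force the asymptotic path regardless of sample size;
  missing values are removed first and an empty group afterwards is an
  error.
- Classification: peptides with non-standard symbols are a validation
  error; unmatched peptides get their own category.
- Variants: REF mismatch against the genome is a hard error with the
  1-based position; a variant outside the coding exons is skipped with a
  warning.
- Pipeline: stage failures abort with the stage named, earlier outputs are
  preserved; report JSON uses sorted keys, and the two timestamp fields are
  the only non-deterministic content.

## Problem sizes used by the checks

The packaged checks run the default 30-gene, 18-sample study for end-to-end
properties (a full run takes well under a second of compute for simulation
plus a few seconds for classification and testing), 2000 features x 20
replicates for the differential-test calibration, 100 seeded replicates for
the usage-test power check, and 999 permutations for network connectivity.
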