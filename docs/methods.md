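# Methods

## Scientific setting

Carbon catabolite repression (CCR) makes microbial communities throttle
cellulose degradation when simple sugars are abundant: high glucose
represses cellulase expression, and β-glucosidase — the rate-limiting final
step that hydrolyses cellobiose to glucose — becomes the pivot of the
community's response. Within the GH1 family, some β-glucosidases remain
active at high glucose ("glucose tolerant"); these carry a conserved
tryptophan and leucine pair in the active-site region (Trp168/Leu173 in the
reference numbering used here). The analysis this package implements asks
whether communities differentially regulate the two functional groups:
up-regulating glucose-tolerant genes and down-regulating non-tolerant genes
under high glucose relative to an additive-free control.

## Tolerance classification

Nucleotide genes are translated in all six frames; each frame is split at
stop codons and stop-free segments of ≥ 100 aa are kept (amplicons of the
expected 1100–1200 bp yield one clean ~370 aa frame). Every candidate is
aligned to the reference protein with an end-gap-free global (semi-global)
alignment, BLOSUM62, affine gaps (open 10, extend 1); the best-scoring
candidate wins, with ties broken by frame order so the result is
deterministic. Walking the aligned columns gives a map from 1-based
ungapped reference positions to query residues. The call rule is exact:
`glucose_tolerant` iff position 168 reads W **and** 173 reads L;
`non_tolerant` if both positions are covered but differ; `indeterminate`
when the alignment fails the quality gates (identity ≥ 30% over ≥ 150
residue-pair columns), a discriminating position falls in a gap, or an
ambiguity character sits there. Indeterminate genes are excluded from all
downstream ratios and group means rather than being coerced into a group.

The bundled reference (`data/gh1_reference_synthetic.fasta`) is a
constructed stand-in protein, not a database sequence: it exists so the
rule is testable out of the box, carries W168/L173 by construction, and is
meant to be replaced by any curated glucose-tolerant GH1 protein via
`ReferenceProfile` (positions configurable).

## Transcription efficiency and relative TE

For read-abundance tables, per-gene values are first normalised within each
sample by the sum over the *characterised gene universe* — the genes with a
classifiable (non-indeterminate) sequence — so rows sum to one over that
universe. Transcription efficiency is the transcript-per-gene-copy ratio

    TE(g, t) = RNA(g, t) / DNA(g, t)

computed on normalised relative abundances (read data) or directly on copy
numbers (qPCR data; `normalize=False`). The inverse convention is one flag
away (`direction="dna_over_rna"`). qPCR triplicates are collapsed by
arithmetic mean *before* the ratio (ratio of means), which keeps TE stable
when single replicate denominators approach zero. TE is undefined (NaN)
where the DNA denominator is zero.

The treatment effect on a gene is the relative TE against the control CK:

    relative TE = (TE_treatment − TE_ck) / TE_ck

A gene transcribed identically in treatment and control scores 0; a planted
multiplicative effect f on TE scores exactly f − 1 when the data are
noiseless copy numbers. Genes with zero or undefined control TE are
excluded and logged — the statistic does not exist for them. Group
summaries average relative TE over genes (one gene, one vote) within the
tolerant and non-tolerant groups per treatment and report n, mean, SD and
the signed group difference.

Two numerical caveats are intrinsic to the statistic and documented rather
than hidden:

1. **Jensen bias under noise.** With multiplicative mean-one noise on each
   measurement, the observed TE ratio is f·exp(ε) with
   ε ~ N(0, 4s²), s² = ln(1+CV²), so E[relative TE] = f·e^{2s²} − 1, not
   f − 1 (for any nondegenerate positive noise, E[X]E[1/X] > 1). At the
   default CV = 20% the factor e^{2s²} ≈ 1.08. The recovery checks in
   `calibration.py` therefore compare Monte-Carlo means to this closed
   form; log TE ratios are unbiased for log f and exactly normal under the
   noise model, which is why the null-calibration test operates on logs.
2. **Compositionality of read data.** Per-sample normalisation makes TE
   ratios carry a common pool factor when the planted effects shift total
   RNA between treatments. The factor cancels nowhere but is shared by all
   genes in a treatment, so group *ordering* and group *differences in
   sign* are unaffected; exact f − 1 recovery holds on the copy-number
   path.

Glucose-tolerant gene ratios are reported unweighted (#GT / #called) and
abundance-weighted (Σw over GT / Σw over called), e.g. with RNA relative
abundances as weights to obtain the expressed-fraction variant. Relative
enzyme activity is the plain percentage against the glucose-free baseline,
with a non-monotonicity flag (not an error) across the 50/100/200 mM
gradient.

## Cross-mapping

Metagenome- and metatranscriptome-derived gene sets are matched by
reciprocal best hits: identity is computed on an end-gap-free global
nucleotide alignment (match +2, mismatch −3, gap open 5, extend 2), with
terminal gap columns excluded so fragments match their extensions at 100%.
A candidate hit only counts when the aligned span covers ≥ 50% of the
shorter sequence; without this gate, end-gap-free alignment of unrelated
sequences (e.g. opposite strands) reports near-perfect identity over a
short dovetail overlap. Pairs are retained when they are mutual best hits
at ≥ 95% identity (threshold configurable); ties break deterministically by
identity, then aligned columns, then lexicographic id. Protein-level
matching can be had by passing translated sequences.

## Co-occurrence networks

Taxa × samples abundance tables yield signed graphs: Spearman (default; the
Pearson option matches a strictly linear reading) correlations between all
taxa pairs, edges retained when |r| ≥ r_min (default 0.8) **and** a
permutation p-value ≤ α (default 0.05, 1,000 permutations). The p-value is
(1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm); one shared permutation set is
used for all pairs, so the edge set is fully determined by the seed, and
both gates are monotone (raising r_min or lowering α never adds edges).
This fixed-threshold + permutation procedure is a deliberate, documented
replacement for random-matrix-theory threshold selection, which is a
platform-specific procedure outside this package's scope. Zero-variance
taxa are excluded and listed. Topology statistics: node/edge counts, sign
balance, mean degree, and the sign-blind global clustering coefficient
3×triangles / connected triples.

## Synthetic data

The generator plants known truth at the study's own scale and writes it
alongside every dataset:

- **Sequences** — each gene copies the reference protein with substitutions
  at non-discriminating positions (default rate 0.05; rates ≥ 0.5 are
  refused as they would destroy detectable homology), keeps (tolerant) or
  ablates (non-tolerant) the W168/L173 pair, is reverse-translated with
  uniform synonymous codon choice and placed on a random strand. Default
  100 genes, half tolerant.
- **Abundance tables** — per-gene DNA abundance is lognormal (log-SD 1);
  expected RNA = DNA × baseTE × effect, with baseTE lognormal (log-SD 0.5)
  and effect = f_up (default 2) for tolerant genes and f_down (default 0.5)
  for non-tolerant genes in the 200 mmol/L-glucose treatments, 1 elsewhere.
  Defaults were chosen to make recovery decisive at 100 genes. Observed
  values get mean-one lognormal noise (default CV 20%), are scaled to the
  sequencing depth (10⁶) and rounded to counts for the read-style tables;
  qPCR tables are absolute copy numbers in triplicate without rescaling.
- **Network blocks** — two 5-taxon blocks driven by one latent factor with
  alternating sign plus N(0, 0.1) noise over 20 samples: positive
  correlations within blocks, negative across.

All randomness flows from one integer seed through numpy's PCG64
generator; identical seed and configuration reproduce every output file
byte-identically. The generator emulates the statistical structure of the
study design, not its biology: no phylogenetic signal beyond the single
reference backbone, no PCR/chimera artefacts, no overdispersed count noise
(a rounding-based count model rather than read-level simulation), and
treatment effects that are exactly multiplicative on TE. Passing recovery
tests therefore demonstrate that the statistics recover the effects they
define under their own assumptions — not that those assumptions hold in
compost metagenomes.

## Validation design and problem sizes

The test-suite checks run at deliberate desk scales: classifier fidelity on
200 genes (substitution rate 0.05), noiseless relative-TE algebra on 20
genes, stochastic effect recovery at 50 genes/group × 1,000 Monte-Carlo
replicates, type-I calibration at 500 replicates (Welch test on log TE
ratios, nominal α = 0.05), cross-mapping on a 50-gene set with 5 planted
≥95% copies and 5 ~85% copies against a brute-force Hamming/RBH oracle, and
network recovery on the two-block design with 1,000 permutations. Alignment
scores are checked against an independent Gotoh dynamic program written
from the recurrences in the test suite.

## Known limitations

- The two-residue rule is taken as given; the package does not validate it
  against enzyme kinetics or discover alternative discriminating residues.
- Relative TE is undefined for genes silent in the control; studies with
  many CK-silent genes need a different contrast (the exclusion log makes
  the loss visible).
- Read-abundance TE inherits compositional effects (see above).
- The co-occurrence procedure tests marginal pairwise association only; it
  does not control for indirect correlations or compositional constraints.
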