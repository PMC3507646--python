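# Methods

## The model

Two closely related species share many proteins whose conserved regions
differ only by biochemically conservative replacements.  The pipeline
quantifies that flexibility per gene with the identical match ratio
`i/(i+h)` over the best translated local alignment of each unigene pair,
where a column is *identical* (i) when both rows carry the same standard
residue, a *homologous substitution* (h) when the residues differ but
score positively under BLOSUM62, a *mismatch* (m) otherwise (including any
X or stop), and a *gap* (g) when either row is gapped.  Gap and mismatch
columns never enter the ratio; the conserved-region length in nucleotides
is `3·(i+h+m)`, i.e. gap columns are excluded from the span.

Assumptions: substitution events are independent across codon sites;
conservativeness is fully captured by the sign of the BLOSUM62 entry; one
best high-scoring segment pair per unigene pair carries the signal (no
multi-HSP combination, flagged in reports).  Pairing is one-way best hit
per query, ties broken by lexicographically smallest subject id.

## Translated alignment

The internal aligner stands in for translated search tools at desk scale:
six-frame translation by the standard code (ambiguity codons become X
unless all resolutions agree), peptides split at stop codons so no
alignment crosses a stop, and exact affine-gap Smith–Waterman over every
segment pair of all 36 frame combinations.  There is no k-mer seeding or
composition-based rescaling.  Traceback ties prefer the diagonal move,
then the gap-in-subject, then the gap-in-query, making alignments
reproducible bit-for-bit.  For production-scale data the pipeline instead
ingests external search output (BLAST-style tabular rows extended with the
two aligned strings).

Parameters and defaults:

| parameter | default | why |
|---|---|---|
| substitution matrix | BLOSUM62 (NCBI integers) | the matrix the midline convention is defined on |
| gap open / extend | 11 / 1 (length-k gap costs 11 + k) | the common protein-search default |
| Karlin–Altschul λ, K | 0.267, 0.041 | standard gapped-BLOSUM62 constants; `E = K·m·n·e^(−λS)` with m, n the nucleotide lengths |
| min query length | 600 nt | full-scale filter; desk-scale runs on 100-codon genes use 150 nt |
| pair E-value ceiling | 1e-30 | full-scale filter, boundary inclusive |
| min conserved region | 80 nt (≥ 27 residue columns) | region lengths are reported in bp |
| split fraction | 0.15 per tail, `floor(f·N)` per side | floor is the only rounding consistent with selecting 952 from 3,177 |
| annotation ceiling | strictly < 1e-10 | classification threshold is exclusive |

## Synthetic data: what it emulates, and what not

`simulate_homolog_pair` draws an ancestral residue per codon site and
evolves the partner copy by a three-way spectrum (identical /
conservative / radical), with synonymous codons uniform and optional
whole-codon indels; the expected ratio is `p_i/(p_i+p_c)`.  Under BLOSUM62
three residues — C, G and P — have no positive off-diagonal partner, so a
conservative substitution away from them is impossible; ancestral states
at substitutable sites are therefore drawn from the remaining 17 residues,
and the generator raises rather than silently reclassifying if a
conservative event is ever requested for a partnerless residue.  Site
events are logged, so every expected statistic (ratio, column counts) is
computable from the log alone — the internal oracle used by the
recovery tests.

The panel, target-dataset and EST generators plant, respectively,
per-function spectra (function labelled high-substitution when its
expected ratio lies below the panel median), per-(gene, dataset) presence
flags (present genes appear as spectrum-mutated homologs, genome-like
datasets fragment them into ≥ 2 exon-like pieces joined by random
spacers), and cluster assignments (ESTs are copies of an exemplar with at
most 1% of bases substituted).

Deliberately **not** modelled: codon-usage bias, rate heterogeneity along
the gene, realistic indel length distributions, dN/dS-style selection,
sequencing error profiles, chimeric or mis-assembled unigenes.  Passing
recovery tests therefore demonstrates the pipeline's correctness and
statistical calibration under the stated generative model, not robustness
to every artefact of real EST data.

## Design choices where the design was open

- **"Top 15%" naming.** The ranked list is sorted ascending by ratio; the
  low-ratio tail is named *high-substitution* ("conserved" in the sense of
  conservative substitutions) and the high-ratio tail *low-substitution*
  ("identical"), so class names never depend on sort direction.
- **One function per gene.** A gene maps to its best-E-value annotation
  only (ties to the lexicographically smaller function name); multi-domain
  genes are not fractionally assigned.
- **All-one-class functions.** `log2(c/i)` is finite only when both counts
  are positive; otherwise the row carries an `all_one_class` flag and a
  sign (+1 all high-substitution, −1 all low-substitution), the analogue
  of an infinite odds ratio.
- **OR-rule direction.** "Passing the threshold" means `evalue ≤ ceiling`;
  ceilings are configured per dataset (1e-10 schistosome, 1e-30
  *S. mediterranea* at full scale).
- **Rarefaction protocol.** The accumulation curve is defined as repeated
  subsampling without replacement on an explicit size grid (default N/20
  steps, 20 replicates), with every replicate stream derived from one
  seed.  The clusterer is injectable: tests use the planted-truth label
  clusterer; the default greedy single-linkage clusterer (edit-distance
  identity ≥ 95% over ≥ 80% overlap, via edlib) is an explicit stand-in
  for assembly software, not a reimplementation of it.
- **Large-panel pairing.** The 100-run sign-recovery study aligns each
  query to its known cognate subject (the generator's pairing); a separate
  test shows the all-vs-all search recovers exactly that pairing in the
  presence of unrelated decoys.  This keeps the repeated study at
  60 alignments per run instead of 3,600 with no loss of coverage.

## Numerical notes

- Ratios, means and percentages are computed at full precision; two-decimal
  ratios, one-decimal percentages and whole-percent conservation fractions
  are display conventions applied only at rendering time.
- The score DP is exact integer arithmetic (numba-compiled); E-values may
  underflow to 0.0 for very high scores, which is harmless since all
  comparisons are one-sided ceilings.
- An alignment with `i+h = 0` has an undefined ratio; such pairs are
  excluded and logged, never scored as 0 or 1.
- Depth histogram bins are `{1}` and `(2^(k−1), 2^k]` for k ≥ 1; the bin
  edges partition the positive integers exactly.
- The closed-form accumulation expectation uses log-gamma binomial
  coefficients, `E[k] = Σ_c (1 − C(N−s_c, k)/C(N, k))`, to avoid overflow.

## Problem sizes

The test suite and acceptance script run the statistical studies at
desk scale: 100-codon genes, 30 genes per function, 100 seeded runs for
sign recovery, 100 pairs of 300 codons per ratio regime, 12-gene
conservation plans with 5 decoys per dataset, and 34-sequence EST
collections with 40 rarefaction replicates.  These sizes give the studies
comfortable statistical power (binomial standard errors a factor ≥ 3
below the planted effect sizes) while keeping a full run in minutes.

## Known limitations

- The aligner's O(mn) dynamic programme is not meant for genome-scale
  searches; real studies should feed external tabular search results in.
- Karlin–Altschul constants are not recalibrated for the affine penalties;
  the pipeline accepts raw-score thresholds where E-value calibration
  would matter.
- The ontology roll-up consumes a user-supplied edge list; it does not
  interpret GO relationship types (is_a vs part_of) or evidence codes.
- The transcript-concordance figure that excludes two subcategories is
  not reproduced: the exclusion rule is ambiguous (numerator vs
  denominator), so the summariser reports raw per-dataset counts and
  leaves that reading to the user.
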