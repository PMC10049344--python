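# Methods

This note documents the models, defaults and design choices behind
mtrkit, and what the synthetic-data tests do and do not establish about
real data.

## Coordinate frame and variant identity

All scores live on the codon index of a single protein-coding
transcript per gene (`GeneModel`: ordered DNA codons, no internal
stops, translation checked against the stored protein sequence). Which
transcript represents a multi-transcript gene is the caller's choice
and is recorded in `transcript_id`; variants whose reference amino acid
disagrees with the gene model are rejected with a logged count rather
than silently kept, because transcript mismatches are a known source of
silent annotation error.

Variants are unique on `(gene_id, codon_index, ref_aa, alt_aa)` plus an
optional `codon_change` component. The extra component matters for the
tolerance denominator: at pure amino-acid resolution every synonymous
SNV of a codon collapses onto one key (ref = alt), which would deflate
observed synonymous counts and inflate MTR. Amino-acid-level sources
(de novo lists, clinical variant tables) leave it unset; nucleotide-
resolved sources (the population generator, population variant tables)
set it. Sets being subtracted or intersected must share one convention.
Multi-nucleotide and indel records are dropped on reading with a count;
the analysis is missense-only.

## MTR

`MTR_i = [obs_mis/(obs_mis+obs_syn)] / [exp_mis/(exp_mis+exp_syn)]`
over a symmetric window of 41 (v1) or 21 (v2) codons centred on *i*.

- Expected counts enumerate the 9 single-nucleotide substitutions of
  each window codon under the standard genetic code; nonsense
  possibilities are excluded from both numerator and denominator. The
  possibility count is unweighted — no CpG/trinucleotide mutability
  model and no sequencing-coverage correction (deliberately out of
  scope; a mutability-calibrated expectation is the natural extension).
- Windows are clipped to `[1, L]` at the termini, so terminal codons
  keep (asymmetric) scores rather than being dropped.
- Observed variants are counted as distinct variant keys, not allele
  counts; duplicated input records cannot change a score.
- A focal codon whose window holds no observed variants is missing
  (NaN), not 0 or 1: the ratio is undefined there, and downstream
  tallies count only positions "with a valid score".
- The intolerance cutoff is the pooled q-th percentile (default q=25)
  of all non-missing values, lower-interpolation convention, with
  *strict* `score < cutoff` classification. The shipped absolute
  default 0.78 is the published exome-wide quartile value; synthetic
  exomes produce their own quartile (typically 0.80–0.86 under the
  default generator), so the pipeline reports both.

`compute_mtr` is vectorised (cumulative window sums of integer counts)
and is tested bit-for-bit against a naive per-window recount, which is
possible because both routes form identical integer sums before the
same two divisions.

## Structures, mapping and MTR3D

PDB files are read through gemmi: first model, one chain, waters and
ligands skipped, highest-occupancy altloc conformer kept, insertion
codes preserved as part of the residue identity ("52" vs "52A"). The
representative atom is Cα (configurable); residues lacking it keep
their atoms for surface area but are excluded from spatial work.

Sequence→structure mapping is a global alignment (Biopython
PairwiseAligner; match 1, mismatch 0, gap open −2, extend −0.5, free
end gaps) so partial structures pair only the residues they cover;
`match_fraction` is the identity over paired positions. Structure
selection prefers experimental over homology models, then the highest
match fraction, ties broken by larger coverage then lexicographic id;
when a specific variant is being scored, candidates covering its
position are considered first, since different partial structures best
fit different variants.

MTR3D applies the MTR ratio to the codon set mapped to residues within
the spatial radius of the focal residue. The radius is a free parameter
(default 8 Å Cα–Cα, surfaced in the config and report header) because
the defining radius of the published spatial score is not restated in
the source material; the extended-chain construction (below) makes the
choice testable. Unmapped neighbours contribute to neither observed nor
expected sums, keeping the ratio internally consistent; unmapped codons
are missing.

Relative solvent accessibility is Shrake–Rupley SASA (960 golden-spiral
sphere points, probe 1.4 Å, element van der Waals radii from gemmi)
normalised by Tien-style theoretical per-residue maxima. The sampling
is checked against the closed-form area of an isolated sphere (≤1%
quadrature error).

## MTRX

A scikit-learn random forest (500 trees, fixed seed 20230307 by
default) over four features: MTR v1, MTR v2, MTR3D, RSA. The published
consensus model's weights and training set are not recoverable, so the
package ships the trainable combiner plus recipes: the self-test trains
on a noise-free rule (deleterious iff MTR v2 < 0.5) and must reach
≥95% held-out accuracy; the pipeline trains on planted ground truth
from alternate genes and scores all genes. Rows with any missing
feature are excluded from training and score as missing. Every model
carries its provenance (features, seed, tree count, out-of-bag and
holdout estimates), and fixed seeds make scores bit-reproducible.

## Conservation

Column score = base-2 Jensen–Shannon divergence between the column's
pseudocounted amino-acid distribution and the BLOSUM62 marginal
frequencies (configurable to uniform), bounded in [0, 1]. Defaults
follow the established alignment-conservation conventions: pseudocount
1/50 per letter, columns with >30% gaps masked as missing, flank
smoothing `score_i = 0.5·jsd_i + 0.5·mean(jsd of ≤3 flanking columns
each side, excluding i, missing flanks skipped)`. The implementation is
tested to 1e-12 against an independent JSD route
(`scipy.spatial.distance.jensenshannon` squared).

Note the orientation: conservation is high where columns do not vary,
MTR is low where missense is depleted, so across a gene the two tracks
correlate *negatively* on the raw scales (the sign flips if MTR is
rank-inverted into a damaging orientation first).

## Enrichment statistics

- Rank scores: tie-averaged ranks mapped min→0, max→1 over non-missing
  entries; predictors whose raw scale runs low = damaging (MTR family,
  SIFT, FATHMM, PROVEAN, LRT) are inverted before ranking so higher
  rank always means more damaging.
- Fractions intolerant use strict inequality in the damaging direction
  and are printed as integer percents, rounded half away from zero
  (91/276 → 33%).
- Group tests default to the two-sample Wilcoxon rank-sum
  (Mann–Whitney U, two-sided): the compared cohorts are independent and
  of unequal size, for which a signed-rank test is undefined; a
  signed-rank option exists for genuinely paired designs. Sidedness is
  configurable; two-sided is the default.
- Correlation matrices are Spearman over pairwise-complete rows with
  per-cell n recorded; columns with <3 complete pairs against every
  other column are excluded with a warning.
- Raw p-values are reported per predictor; a Benjamini–Hochberg column
  is available but off by default.

## Synthetic study conditions

The default `SyntheticCohortSpec` fixes the study conditions emulated
throughout the tests: 34 panel genes of 300–600 codons; one contiguous
depleted region per gene covering 25% of its codons where the per-SNV
missense observation probability is multiplied by 0.2 (synonymous
unaffected); population density 1.0 expected observed
missense+synonymous variants per codon outside regions (each of the ~9
possible SNVs observed with probability density/9 — deep-population
sampling scale, with no allele-frequency spectrum or trinucleotide
mutation-rate structure); case cohort of 276 unique missense variants
drawn 3× preferentially from depleted regions; control cohorts of 454
and 762 drawn uniformly. All generators are pure functions of
(parameters, seed).

Toy structures are Cα-only chains: `extended` (3.8 Å spacing), `helix`
(ideal α-helix: 100°/residue, 1.5 Å rise, 2.3 Å radius), `packed`
(lattice ball, residue 1 buried) and `folded_contact_pairs` (a single
hairpin placing requested residue pairs at a requested distance;
requests inconsistent with one hairpin raise). The extended chain is
the key testing device: with the radius set to ±10 codons its spatial
neighborhoods equal the 21-codon sequence window, so MTR3D must equal
MTR v2 exactly — a strong equivalence the suite asserts bit-for-bit.
Note that on an ideal α-helix Cα(i,i+3) ≈ 5.05 Å is *closer* than
Cα(i,i+2) ≈ 5.43 Å, so no radius selects exactly ±2 sequence
neighbours there; helix neighborhoods are validated against a
brute-force distance oracle instead.

Alignments take the gene's protein as the reference row and mutate the
other rows per column (substitution rate ×0.1 inside conserved blocks,
per-cell gap rate). The generator emulates conservation depth only; it
has no phylogenetic correlation between rows.

**What passing tests show.** The suite demonstrates that the scoring
machinery recovers planted depletion (precision/recall ≈ 0.88 at the
pooled-quartile rule under the default conditions), that case cohorts
enriched in planted regions separate from controls (fractions and
rank-sum p-values), and that the test statistics are calibrated (null
p-values uniform by KS). It does not certify real-data performance:
real population variation has mutability structure, coverage gaps and
allele-frequency effects the generator deliberately omits, and the
published exome-wide quantities (the 0.78 cutoff itself, real
conservation–MTR correlations, per-predictor p-values, the published
consensus weights) require the real cohort and population downloads.
The pipeline recomputes all of them when such inputs are supplied.

## Numerical choices and degenerate inputs

- Missingness is NaN throughout; every consumer (percentiles, ranks,
  correlations, fractions) restricts to non-missing values and reports
  the n it used.
- Percentile: numpy `method="lower"`; classification strict `<` (or
  strict `>` for scores oriented upward).
- Zero-variance inputs to correlation are flagged `undefined`, not
  raised; fewer than 3 joint observations raise.
- An empty cohort column yields `fraction_pct = None` with a warning
  rather than a division error.
- Region-recovery precision/recall ignore missing-score codons.
- Problem sizes in the shipped checks (gene counts, replicate counts,
  alignment depths, tree counts) are chosen to keep the full suite and
  the acceptance script in the minutes range on one CPU while leaving
  the statistical assertions comfortably powered; all are parameters,
  not constants.

## Known limitations

- No mutability/coverage model behind the expected counts (documented
  above) — scores on real data should be interpreted relative to a
  recalibrated expectation where possible.
- One chain per analysis; no quaternary assemblies, no mmCIF.
- The conservation module consumes alignments; it does not build them.
- The consensus combiner is a recipe, not a reproduction of published
  weights; its absolute scores are meaningful only relative to its own
  training labels.
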