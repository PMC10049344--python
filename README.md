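# mtrkit

Regional missense-intolerance scoring and case/control enrichment
statistics for disease gene panels, built for studies of severe
early-onset disorders — the motivating case is developmental and
epileptic encephalopathies (DEEs), where pathogenic de novo missense
variants cluster in functionally constrained regions of a few dozen
genes and must be separated from the background variation every exome
carries.

## What it computes

**Missense Tolerance Ratio (MTR).** For a focal codon *i* and a window
of codons *W* (41 codons for v1, 21 for v2, clipped at the gene ends):

```
MTR_i = [ obs_mis / (obs_mis + obs_syn) ] / [ exp_mis / (exp_mis + exp_syn) ]
```

where the expected counts enumerate all single-nucleotide substitutions
of the window's codons under the standard genetic code (nonsense
excluded) and the observed counts are distinct missense/synonymous
variants seen in a reference population. MTR ≈ 1 means the region
tolerates missense variation; MTR « 1 flags missense depletion.
Positions in the top quartile of intolerance (exome-wide, the published
cutoff is MTR < 0.78) are called intolerant.

**MTR3D.** The same ratio, but the window is the set of residues within
a distance radius (default 8 Å, Cα–Cα) of the focal residue in the
protein's tertiary structure, reached through a sequence↔structure
residue mapping with the best-matching experimental structure preferred
over homology models. This catches constraint that is clustered in 3D
but dispersed in sequence.

**MTRX.** A random-forest consensus over MTR v1, MTR v2, MTR3D and
relative solvent accessibility (Shrake–Rupley SASA over per-residue
maxima), emitting P(deleterious) in [0, 1]. No published weights are
shipped; the combiner trains on labels you provide and records its
training provenance.

**Conservation.** Per-column Jensen–Shannon divergence of alignment
columns against the BLOSUM62 background (base-2, bounded in [0, 1]),
with gap masking and flank smoothing.

**Enrichment statistics.** Percentile rank scores with a common
damaging orientation, fractions of each cohort beyond a threshold
(reported as rounded integer percents), two-sample Wilcoxon rank-sum
tests of case vs control score distributions, and pairwise Spearman
correlation matrices over predictors.

A fully seeded synthetic-data module generates every input — genes,
depleted population variation, enriched case cohorts, toy structures
with controllable contact topology, alignments with conserved blocks —
so the whole pipeline runs and is tested with no downloads.

## Worked example

```bash
python examples/01_sequence_mtr.py
```

```
gene length: 400 codons, 308 observed population variants
mean MTR(41) inside planted region : 0.525
mean MTR(41) outside               : 1.064
25th-percentile cutoff             : 0.819
region codons below cutoff         : 94%
```

A 100-codon region where missense observations were suppressed fivefold
scores near 0.5 while the rest of the gene sits at 1; 94% of the planted
region falls below the gene's own intolerance cutoff. The other
`examples/` scripts walk the remaining capabilities (spatial scoring,
the consensus combiner, conservation, cohort enrichment, the full
pipeline), one each, printing the numbers they compute.

The end-to-end analysis is also a shell command:

```bash
mtrkit run --seed 21 --out report/
```

which writes `report.json`, human-readable TSVs of the enrichment and
group-test tables, and a lollipop-plot data export. On the reduced
eight-gene study of `examples/06_full_pipeline.py` the case cohort
shows 42% of variants in intolerant regions against 25%/23% for the two
control cohorts, with a rank-sum p ≈ 6e-07 — the qualitative enrichment
signature the study design plants.

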