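# strpop

Genome-wide short tandem repeat (STR) population analysis as a tested,
reusable pipeline: building and filtering an STR catalog from sequence,
ingesting and quality-filtering STR genotype calls from VCF, and computing
the population statistics used to compare wild great-ape (sub)species —
absolute STR dosage, Nei's unbiased expected heterozygosity, Slatkin's
R<sub>ST</sub>, sequencing-depth diagnostics and promoter-proximity
annotation with a term over-representation test.  A bundled
stepwise-mutation-model simulator generates complete synthetic cohorts
(reference FASTA with planted repeats, diploid genotypes on a
split/bottleneck demography, depth-dependent call noise and truth
manifests), so every stage is exercisable and testable without sequencing
data.

## Who this is for

Population geneticists and methods developers who want the STR side of a
multi-genome comparison — catalog construction, lobSTR-style call
filtering, diversity/differentiation statistics — as plain, auditable
Python functions with oracle-checked tests, rather than a chain of one-off
scripts around external tools.

## The statistics at the core

**Absolute STR dosage.** For a diploid genotype with allele lengths
*a₁, a₂* (bp) at a locus whose reference allele is *r* bp,

    dosage = (|a1 − r| + |a2 − r|) / 2

and |a − r| for a single (hemizygous) allele.  Genotype 18/22 against a
20 bp reference gives 2; genotype 18/18 against 24 bp gives 6.  Dosage
measures the *extent* of repeat variation and, unlike the variant count,
is robust to sequencing depth.

**Nei's unbiased expected heterozygosity.** Per locus, with *n* genotyped
individuals and allele frequencies *fᵢ*,

    Hl = 2n/(2n−1) · (1 − Σᵢ fᵢ²),    H = Σₗ Hl / N

**Slatkin's R<sub>ST</sub>.** With *S* the average squared allele-size
difference over all pooled pairs of alleles and *S*<sub>W</sub> the
within-subpopulation average,

    RST = (S − SW) / S

the F<sub>ST</sub> analogue appropriate under the stepwise mutation model
(SMM), in which each mutation adds or removes one motif copy.

**Catalog conventions.** The repeat scanner reports motifs of 2–6 bp and
scores arrays per copy (MATCH = 2, MISMATCH = 7, DELTA = 7): a perfect
seven-copy GC array scores 14, the reporting threshold.  Composition
requires ≥ 80% matching nucleotides and ≤ 10% indels; catalog filters keep
arrays of total length ≤ 100 bp and at least 13/20/23/27/27 bp for periods
2–6, resolve overlaps by greatest score at ≥ 20 bp spacing, and exclude
masked (transposon/telomere/centromere) intervals.

## Worked example

Run the numbered analysis drivers on a fresh synthetic cohort (21
individuals from four populations, 600 STR loci, seeded):

```bash
python analysis/01_simulate.py            # writes scratch/synthetic/
python analysis/02_build_catalog.py
python analysis/03_ingest_filter.py
python analysis/04_popgen_stats.py
python analysis/05_promoter_enrichment.py
```

which prints, for the default seed 42:

```
414 / 600 loci carry a true variant (fraction 0.69)
recovered 600/600 planted arrays (100.0%); 600 catalog entries after filtering
kept 594 loci / 3229 calls; variant fraction 0.574 (truth at kept loci 0.694)
"depth_diagnostics": { "rho_count": 0.989, ..., "rho_dosage": 0.285, ... }
"mean_dosage_by_population": { "abelii": 2.05, "morio": 1.88,
                               "pygmaeus": 2.78, "tapanuliensis": 3.95 }
```

Reading the output: the scanner recovers every planted array exactly; the
seven-rule genotype filter keeps about 57% of loci as variant (the truth
fraction at those loci is 0.69 — depth-dependent dropout hides some
variants); sequencing depth almost perfectly predicts an individual's
post-filter variant count (Spearman ρ ≈ 0.99) while mean absolute dosage
stays uncorrelated with depth (ρ ≈ 0.29, p ≈ 0.22) — the motivation for
using dosage as the coverage-robust measure; and the geographically
isolated population (`tapanuliensis`, deepest split) shows the largest
mean dosage, i.e. dosage tracks divergence from the reference genome.

The same stages are exposed as a CLI (`strpop simulate | scan |
filter-catalog | ingest | stats | annotate | all`) for running on your own
FASTA/VCF/BED/TSV inputs.

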