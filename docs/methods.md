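# Methods

This note documents the models, conventions and numerical choices behind
`strpop`, in the spirit of a simulator/statistics package's model
documentation: what is computed, under which assumptions, and what the
synthetic data does and does not emulate.

## Repeat detection and scoring

An STR array is a tandem run of a primitive 2–6 bp motif.  The scanner
seeds a candidate of period *p* at every position where the sequence
equals itself shifted by *p* and reports maximal runs spanning at least
two whole copies.  Consensus motifs that are themselves periodic
(e.g. ACAC as a "4-mer") are discarded, so each array is reported at its
primitive period; homopolymers (period 1) are outside scope.  Windows
containing non-ACGT characters never seed or extend arrays.  Detection
targets perfect runs (partial trailing copies included); candidate arrays
with mismatches or indels — e.g. from an external detector — are still
scored and validated by `score_array` and `check_composition`.

**Per-copy scoring convention.**  With MATCH = 2, MISMATCH = 7, DELTA = 7,
an array's score is

    score = MATCH × (whole copies) − MISMATCH × n_mismatch − DELTA × n_indel

so a perfect seven-copy dimer scores 14, the reporting threshold
(MIN SCORE = 14).  This deliberately differs from a classical per-nucleotide
wraparound alignment score (which would give 2 × 12 = 24 for the same
array): the per-copy convention is the one consistent with the catalog's
stated example, and it is frozen here.  `score_array` aligns an array to
the cyclically repeated consensus with a small dynamic program (penalties
as above, ties resolved toward more completed copies); the copy credit is
the number of consensus wrap-arounds on the optimal path.

**Composition.**  With PM = 80 (percent matches, at least) and PI = 10
(percent indels, at most) over an array of length *L*: matches are
required ≥ ⌈PM·L/100⌉ (ceiling, "at least") and indels ≤ ⌊PI·L/100⌋
(floor, "at most") — e.g. 16 of 20 nucleotides for a ten-copy dimer, and
at most 3 indels in a ten-copy trimer.

**Catalog filters.**  Class rules (period 2–6; total length ≤ 100 bp so a
100 bp read can span the array; per-period minima 13/20/23/27/27 bp),
then overlap resolution — greedy by descending score, ties to the earlier
start then the longer array, keeping arrays whose interval gap is
≥ 20 bp — then mask exclusion (any 1 bp overlap with a masked interval
removes the array).  "20 bp apart" means the gap between interval ends,
not midpoint distance.  The order class → overlap → mask is frozen;
class and mask filters commute, so only the placement of overlap
resolution is consequential, and it runs on class-filtered candidates.
Strand handling: forward strand only; reverse-complement motifs are not
collapsed (canonical rotation collapses rotations only, so GC ≡ CG but
not GC ≡ AT-complement classes).

Coordinates are 0-based half-open throughout, converted to 1-based only
at VCF boundaries.

## Genotype ingestion and filtering

The VCF dialect follows lobSTR-style STR genotypers: REF/ALT carry full
allele sequences (allele length = sequence length, keeping the reader
dialect-agnostic), per-sample `GT:DP:Q:DISTENDS`, per-record
`MOTIF`, `LOCQ` (locus quality) and `LCOV` (mean total read depth).
Multi-allelic records are decomposed per sample into the two called
allele lengths; haploid calls are stored with a single allele and handled
by the hemizygous dosage rule.

The seven filter rules with their published defaults: call quality
≥ 0.8 (`call-log-score`), call coverage ≥ 20 spanning reads (`call-cov`),
|DISTENDS| ≤ 20 (`call-dist-end`); locus quality ≥ 0.8 (`loc-log-score`),
reference allele ≤ 80 bp (`loc-max-ref-length`), mean locus coverage ≥ 20
(`loc-cov`, interpreted as the across-sample mean — the minimum-coverage
reading is strictly a per-call matter handled by `call-cov`), and call
rate ≥ 0.8 (`loc-call-rate`).

**Call-rate semantics.**  The locus call rate is measured on genotypes
the caller emitted (the behaviour of the original filter script), not on
calls surviving the call-level filters.  The two readings differ
materially: requiring ≥ 80% of samples to *survive* call filtering at
every kept locus forces near-saturating pass rates for most of a cohort
and is irreconcilable with the kept-genotype bookkeeping of published
STR catalogs (kept calls ≈ 17% of loci × samples).  The stricter
post-filter variant remains available as
`CallFilterConfig(call_rate_after_filter=True)` and is pinned by a test.

A locus is *variant* when at least one kept call's allele length differs
from the catalog reference length, *invariant* otherwise; the partition
and per-individual variant counts feed the diagnostics.

## Population statistics

* **Absolute dosage**: `(|a₁−r| + |a₂−r|)/2` diploid, `|a−r|`
  single-allele; symmetric in the alleles and translation-invariant.
  Per-individual means are taken over variant loci (scope `"all"` is
  available); individuals with no loci in scope are reported absent, not
  as zero.
* **Nei's unbiased heterozygosity**: `Hl = 2n/(2n−1)(1 − Σ fᵢ²)` —
  identical to the probability that two allele copies drawn *without
  replacement* differ, which is the oracle the tests enumerate exactly.
  Mean `H` over loci is reported with its standard error (per-population
  dispersions in the source literature are reported without stating
  SE vs SD; this package reports the SE and the per-locus table, from
  which either can be formed).
* **Rst**: allele size in base pairs (the statistic is scale-invariant,
  so bp vs copy number is immaterial; bp is frozen for reproducibility).
  `S` is the mean squared difference over all pooled unordered pairs
  (= 2 × sample variance); `S_W` pools within-population pairs weighted
  by pair counts (Slatkin's formulation); an unweighted per-population
  mean is available (`within_weighting="populations"`).  `S = 0` (a
  monomorphic pooled sample) leaves Rst undefined; such loci are excluded
  and counted.  Small balanced samples can give negative Rst — a known
  property of the estimator, not an error.
* **Locus eligibility** for diversity/differentiation: at least two
  distinct non-reference allele lengths observed in *each* analysed
  population.  Note this selects toward mutable loci, so absolute H
  levels on synthetic data are high; comparisons across populations are
  the meaningful output.  Populations are user-supplied; single-individual
  populations cannot satisfy the rule and are excluded from these
  statistics (they still appear in dosage summaries).
* **Depth diagnostics**: Spearman rank correlations (two-sided) of
  per-individual sequencing depth with post-filter variant count and with
  mean absolute dosage; constant inputs yield NaN (undefined), reported
  as such.
* **Group comparisons**: pairwise two-sided Mann-Whitney U (exact for
  small tie-free samples via scipy's automatic method), raw p-values plus
  Benjamini-Hochberg adjusted ones (the source analyses report raw only;
  both are given).

## Promoter annotation and enrichment

Each variant locus is assigned to the gene minimising |STR start − TSS|
on the same sequence (strand ignored; ties broken to the smaller gene id,
deterministically).  The promoter-proximal recurrent gene set per
population group keeps genes with a qualifying locus at ≤ 10 kb whose
variant recurs in ≥ 2 individuals of a *single* population (one
individual in each of two populations does not qualify).  "Promoter" is
operationalised purely as the 10 kb window; strand/upstream-only
refinements are config options defaulting off.  Over-representation per
term uses the one-sided hypergeometric tail against an explicit,
user-supplied gene universe, with the conservative EASE variant
(hit count decremented by one) available; BH-FDR across tested terms;
fold enrichment `(k/|set|)/(K/|universe|)`.  External annotation services
and live GO retrievals are out of scope — term/gene tables are inputs.

## The synthetic cohort

`synthetic_data` generates the full study input set; its defaults are the
package's study conditions.

**Reference and catalog.**  Uniform random background with planted
perfect arrays: motif spectrum {2: 0.78, 3: 0.10, 4: 0.05, 5: 0.04,
6: 0.03} (dimer-dominated, as in real STR catalogs where > 75% of loci
are dimers); per array ≥ 7 whole copies (so every plant clears both the
class minima and the score threshold) plus 0–8 extra copies, capped at
100 bp; plants ≥ 50 bp apart with flanking bases chosen so no array
extends by even one base — the catalog equals exactly what a correct
scanner should find.  Packing infeasibility raises before any output.

**Genotypes.**  Per locus an independent single-tree genealogy of all
sampled lineages is drawn with msprime under a population tree with split
times (generations), per-branch effective sizes and an optional
bottleneck (size × factor between two times).  SMM mutations are dropped
per branch: the event count is Binomial(⌊branch generations⌉, rate) — one
Bernoulli trial per generation — and each event is ±1 motif copy with
equal probability (Rademacher sign).  This is the exact marginal law of
the per-generation SMM walk without a generation loop.  Copy numbers
driven below one reflect at one (logged).  Loci are unlinked; diploids
are two exchangeable lineages (random mating, no inbreeding, no
migration/gene flow).

**Reference allele semantics.**  The catalog reference length is the
allele carried by a hidden extra "assembly" individual sampled in the
reference population; all allele lengths are expressed relative to that
lineage.  This makes divergence from the reference *genome* grow with a
population's split time (as observed for dosage on real data); anchoring
at the tree root would give every population the same expected
divergence (total tree height) and erase that signal.

**Mutation-rate spectrum.**  Per-locus rates default to log-uniform on
[10⁻⁶, 10⁻³] per locus per generation — inside the 10⁻²–10⁻⁶ range
reported for STRs, with the hypermutable top decade excluded because it
would dominate mean dosage at desk scale.  The result is desk-scale mean
dosages of a few bp and a mixture of frozen and polymorphic loci.  A
scalar rate is supported (used by the analytic-law and
parameter-recovery tests); rate 0 is allowed as a degenerate
no-mutation control.

**Default demography** (`orangutan_demography`): four populations of
11 + 1 + 3 + 6 diploids; splits at 1 000 (subspecies), 2 720 (islands)
and 13 600 (basal isolated species) generations; effective sizes
2500/300/500/1200 with 1000–2000 on internal branches; a 10× bottleneck
on the smallest subspecies between 400 and 150 generations ago.  Times
are deliberately desk-scaled (divergence levels, not absolute ages, are
what the statistics see).  Sequencing depths span 10–40× across the 21
individuals and are balanced across populations so depth is not
confounded with divergence from the reference — a study-design choice
that mirrors a cohort filtered at ≥ 10× and keeps the dosage-vs-depth
null interpretable.

**Sequencing-noise layer.**  Per call: total read depth ~ negative
binomial (mean = individual depth, dispersion 40); call coverage = reads
fully spanning the repeat ~ Binomial(total, 0.6) (a 100 bp read must
fully contain an array of up to 100 bp, so spanning fractions well below
one are the physical regime); call quality ~ Beta(2 + 0.6 × coverage, 1)
(quality grows with read support); DISTENDS ~ rounded N(0, 6) truncated
to ±50 (its only contract is exercising the |·| ≤ 20 filter).  The
quality and DISTENDS channels jointly pass ≈ 95% of calls at 30×; the
coverage channel is the depth effect proper, and with `call-cov = 20` it
reproduces the regime in which depth strongly predicts the post-filter
variant count while dosage stays depth-independent.  No call is removed
by the generator itself — dropout happens in the downstream filters,
keeping truth manifests exact.

**What the synthetic data does not emulate**: PCR stutter and allele
dropout biased by genotype, read-level alignment artefacts, linkage,
migration and inbreeding, real mutation-rate determinants (motif, length,
interruptions), and real annotation structure.  Passing tests therefore
validate the *statistics and plumbing* under a faithful SMM null, not
biological effect sizes; headline values from real cohorts (catalog
sizes, per-species dosage/H/Rst levels, specific enriched terms) are not
reproducible from synthetic data and are not targets.

## Problem sizes and determinism

Test and analysis problem sizes are chosen for a laptop-class single CPU:
reference fixtures of 20–100 kb with 40–200 planted loci; cohort
scenarios of 250–1 500 loci and 16–32 diploids; 10–20 replicate seeds for
the stochastic contrasts (the depth-contrast scenario uses 1 500 loci so
that shallow individuals still accumulate enough kept calls for stable
dosage means — with very few calls, heavy-tailed per-locus dosages bias
small-sample means low and leak a spurious depth correlation).  Every
random draw derives from an explicit seed (numpy `SeedSequence` spawning;
msprime seeded separately below 2³¹); identical configurations produce
byte-identical FASTA/VCF/TSV outputs, and the CLI echoes config overrides
and writes machine-readable summaries so any run is reproducible from its
logged config and seed.
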