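"""Synthetic STR datasets: reference with planted repeats, stepwise-mutation
genotypes on a split/bottleneck demography, and depth-dependent call noise.

The generator produces everything the pipeline consumes, so the whole
analysis is testable without any sequencing data:

* a random background sequence with non-overlapping perfect STR arrays
  planted at catalogued coordinates, with a motif-length spectrum dominated
  by dimers (as observed for real STR catalogs);
* diploid genotypes evolving under the stepwise mutation model (SMM): for
  each locus an independent coalescent genealogy of all sampled lineages is
  drawn with msprime under a population tree with split times, per-branch
  effective sizes and an optional bottleneck; each branch then receives a
  binomial number of +-1 motif-unit mutations with Rademacher signs — the
  exact marginal law of a per-generation SMM walk, without the
  generation-by-generation loop;
* the catalog reference allele is the allele carried by a hidden "assembly"
  lineage sampled in the reference population, so divergence from the
  reference genome grows with a population's split time;
* a sequencing-noise layer: total read depth per call (negative binomial
  around the individual's depth), the subset of reads fully spanning the
  repeat as call coverage, coverage-linked call quality and DISTENDS noise
  (the quality/DISTENDS channels pass ~95% of calls at 30x) — inducing the
  depth-dependent dropout the diagnostics measure;
* a truth manifest pinning planted repeats, true genotypes and
  variant/invariant labels.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import msprime
import numpy as np
import pandas as pd

from .genotype_ingest import StrCall

logger = logging.getLogger(__name__)

#: default motif-length spectrum: dimer-dominated, as in real STR catalogs
DEFAULT_MOTIF_SPECTRUM: dict[int, float] = {2: 0.78, 3: 0.10, 4: 0.05,
                                            5: 0.04, 6: 0.03}

_CLASS_MIN_LEN = {2: 13, 3: 20, 4: 23, 5: 27, 6: 27}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_individuals: int
    effective_size: float
    depths: tuple[float, ...]  # per-individual mean sequencing depth (x)

    def __post_init__(self) -> None:
        if len(self.depths) != self.n_individuals:
            raise ValueError(f"{self.name}: need one depth per individual")


@dataclass(frozen=True)
class Split:
    time_gen: float
    derived: tuple[str, ...]
    ancestral: str


@dataclass(frozen=True)
class Bottleneck:
    population: str
    start_gen: float   # older bound (generations ago)
    end_gen: float     # recent bound
    size_factor: float


@dataclass(frozen=True)
class DemographyConfig:
    """Populations, tree topology and SMM parameters for the simulator.

    ``smm_rate`` is either a scalar per-locus per-generation mutation
    probability or a ``(low, high)`` pair from which per-locus rates are
    drawn log-uniformly; rates must stay within [1e-6, 1e-2], the range
    reported for STR loci.  ``seed`` is mandatory: every random draw
    (genealogies, mutations, depth noise) derives from it.
    """

    populations: tuple[PopulationSpec, ...]
    splits: tuple[Split, ...]
    ancestral_sizes: tuple[tuple[str, float], ...]
    reference_population: str
    seed: int
    smm_rate: float | tuple[float, float] = (1e-6, 1e-3)
    bottleneck: Optional[Bottleneck] = None

    def __post_init__(self) -> None:
        rates = (self.smm_rate if isinstance(self.smm_rate, tuple)
                 else (self.smm_rate, self.smm_rate))
        # zero is allowed as a degenerate no-mutation control
        if rates != (0.0, 0.0) and not (1e-6 <= rates[0] <= rates[1]
                                        <= 1e-2):
            raise ValueError("smm_rate must lie within [1e-6, 1e-2] "
                             "(or be exactly 0)")
        names = [p.name for p in self.populations]
        if self.reference_population not in names:
            raise ValueError("reference_population not among populations")
        times = [s.time_gen for s in self.splits]
        if any(t <= 0 for t in times):
            raise ValueError("split times must be positive")
        if sorted(times) != times:
            raise ValueError("splits must be listed oldest-last "
                             "(ascending time)")

    def individual_ids(self) -> list[str]:
        return [f"{p.name}_{k}" for p in self.populations
                for k in range(p.n_individuals)]

    def population_of(self) -> dict[str, str]:
        return {f"{p.name}_{k}": p.name for p in self.populations
                for k in range(p.n_individuals)}

    def depth_of(self) -> dict[str, float]:
        return {f"{p.name}_{k}": p.depths[k] for p in self.populations
                for k in range(p.n_individuals)}


def orangutan_demography(seed: int = 1) -> DemographyConfig:
    """Default study conditions: a four-population great-ape-like history.

    21 diploid individuals (11 + 1 Sumatran, 3 + 6 Bornean), a basal
    isolated-species split, an island split, a recent subspecies split and
    a bottleneck-then-recovery on the smallest subspecies.  Times are
    desk-scaled generations; sequencing depths span 10-40x (a cohort
    filtered at >= 10x coverage), balanced across populations so that
    sequencing depth is not confounded with divergence from the reference.
    """
    return DemographyConfig(
        populations=(
            PopulationSpec("abelii", 11, 2500.0,
                           (12, 15, 18, 21, 24, 26, 28, 31, 34, 37, 40)),
            PopulationSpec("tapanuliensis", 1, 300.0, (25,)),
            PopulationSpec("pygmaeus", 3, 500.0, (10, 26, 38)),
            PopulationSpec("morio", 6, 1200.0, (13, 17, 22, 29, 33, 36)),
        ),
        splits=(
            Split(1000.0, ("pygmaeus", "morio"), "borneo"),
            Split(2720.0, ("abelii", "borneo"), "core"),
            Split(13600.0, ("core", "tapanuliensis"), "root"),
        ),
        ancestral_sizes=(("borneo", 1000.0), ("core", 2000.0),
                         ("root", 2000.0)),
        bottleneck=Bottleneck("pygmaeus", start_gen=400.0, end_gen=150.0,
                              size_factor=0.1),
        reference_population="abelii",
        seed=seed,
    )


# ----------------------------------------------------------------- reference

def _random_primitive_motif(rng: np.random.Generator, period: int) -> str:
    from .repeat_finder import is_primitive
    while True:
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=period))
        if is_primitive(motif):
            return motif


@dataclass
class ReferencePack:
    sequences: dict[str, str]
    catalog: pd.DataFrame
    manifest: dict


def generate_reference(genome_length: int,
                       n_loci: int,
                       motif_spectrum: Optional[Mapping[int, float]] = None,
                       seed: int = 0,
                       sequence_id: str = "chr1",
                       max_extra_copies: int = 8,
                       min_gap: int = 50) -> ReferencePack:
    """Random background with ``n_loci`` non-overlapping perfect STR arrays.

    Arrays meet the catalog class minima and the score threshold (>= 7 whole
    copies), are at least ``min_gap`` bp apart, and their flanking bases are
    chosen so no array extends by even one base — the catalog rows equal
    exactly what a scanner should recover.  Raises ``ValueError`` before any
    output when the requested loci cannot be packed.
    """
    spectrum = dict(motif_spectrum or DEFAULT_MOTIF_SPECTRUM)
    if abs(sum(spectrum.values()) - 1.0) > 1e-9:
        raise ValueError("motif_spectrum fractions must sum to 1")
    rng = np.random.default_rng(seed)

    periods = sorted(spectrum)
    draws = rng.choice(periods, size=n_loci,
                       p=[spectrum[p] for p in periods]) if n_loci else []
    plants = []
    total_repeat_bp = 0
    for p in draws:
        p = int(p)
        base_copies = max(-(-_CLASS_MIN_LEN[p] // p), 7)
        max_copies = 100 // p
        extra = int(rng.integers(
            0, min(max_extra_copies, max_copies - base_copies) + 1))
        copies = base_copies + extra
        motif = _random_primitive_motif(rng, p)
        plants.append((motif, p, copies))
        total_repeat_bp += copies * p

    required = total_repeat_bp + (n_loci + 1) * min_gap
    if required > genome_length:
        raise ValueError(
            f"cannot pack {n_loci} loci ({required} bp needed) into "
            f"{genome_length} bp")

    # distribute the slack over the n_loci + 1 gaps
    slack = genome_length - required
    extra_gaps = rng.multinomial(slack, [1 / (n_loci + 1)] * (n_loci + 1)) \
        if n_loci else np.array([slack])
    seq = rng.integers(0, 4, size=genome_length, dtype=np.int64)

    records = []
    cursor = 0
    for (motif, p, copies), gap_extra in zip(plants, extra_gaps[:-1]):
        cursor += min_gap + int(gap_extra)
        start = cursor
        unit = np.frombuffer(motif.encode(), dtype=np.uint8)
        codes = np.searchsorted(_BASES, unit)  # ACGT already sorted
        arr = np.tile(codes, copies)
        end = start + len(arr)
        seq[start:end] = arr
        # forbid single-base extension on either side
        if start > 0 and seq[start - 1] == codes[-1]:
            choices = [c for c in range(4) if c != codes[-1]]
            seq[start - 1] = choices[int(rng.integers(0, 3))]
        if end < genome_length and seq[end] == codes[0]:
            choices = [c for c in range(4) if c != codes[0]]
            seq[end] = choices[int(rng.integers(0, 3))]
        records.append({
            "locus_id": f"{sequence_id}:{start}", "sequence_id": sequence_id,
            "start": start, "end": end, "motif": motif, "period": p,
            "copy_number": float(copies), "ref_len": end - start,
            "score": 2 * copies})
        cursor = end

    sequence = "".join("ACGT"[c] for c in seq)
    catalog = pd.DataFrame(records, columns=[
        "locus_id", "sequence_id", "start", "end", "motif", "period",
        "copy_number", "ref_len", "score"])
    manifest = {
        "seed": int(seed), "genome_length": int(genome_length),
        "n_loci": int(n_loci),
        "planted": [{k: (int(v) if isinstance(v, (int, np.integer)) else v)
                     for k, v in r.items() if k != "copy_number"}
                    | {"copy_number": float(r["copy_number"])}
                    for r in records],
    }
    return ReferencePack(sequences={sequence_id: sequence}, catalog=catalog,
                         manifest=manifest)


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------- genotypes

def smm_steps(rng: np.random.Generator, generations: float,
              rate: float) -> int:
    """Net SMM displacement (motif copies) over a lineage segment.

    The number of mutation events is Binomial(round(generations), rate) —
    one Bernoulli trial per generation — and each event moves the allele by
    +1 or -1 copy with equal probability, so the net displacement is a
    difference of coin flips.  Exactly the marginal law of the
    per-generation SMM walk.
    """
    n_gen = int(round(generations))
    if n_gen <= 0 or rate <= 0:
        return 0
    n_mut = int(rng.binomial(n_gen, min(rate, 1.0)))
    if n_mut == 0:
        return 0
    return int(2 * rng.binomial(n_mut, 0.5) - n_mut)


def build_msprime_demography(config: DemographyConfig) -> msprime.Demography:
    dem = msprime.Demography()
    for p in config.populations:
        dem.add_population(name=p.name, initial_size=p.effective_size)
    anc = dict(config.ancestral_sizes)
    for s in config.splits:
        dem.add_population(name=s.ancestral, initial_size=anc[s.ancestral])
    if config.bottleneck is not None:
        b = config.bottleneck
        base = {p.name: p.effective_size for p in config.populations}
        dem.add_population_parameters_change(
            time=b.end_gen, population=b.population,
            initial_size=base[b.population] * b.size_factor)
        dem.add_population_parameters_change(
            time=b.start_gen, population=b.population,
            initial_size=base[b.population])
    for s in config.splits:
        dem.add_population_split(time=s.time_gen, derived=list(s.derived),
                                 ancestral=s.ancestral)
    dem.sort_events()
    return dem


ASSEMBLY_ID = "__assembly__"


def simulate_genotypes(catalog: pd.DataFrame,
                       config: DemographyConfig,
                       ) -> tuple[pd.DataFrame, dict]:
    """True diploid genotypes for every catalog locus under the SMM.

    Per locus: an independent single-tree genealogy of all sampled lineages
    (cohort plus one hidden assembly individual in the reference population)
    is simulated under the configured demography; +-1 copy mutations are
    dropped on every branch; allele length = catalog reference length +
    period x (lineage displacement - assembly displacement).  Copy numbers
    driven below one reflect at one (counted in the manifest).  Returns a
    long genotype frame (allele1_len <= allele2_len) and a truth manifest
    with per-individual variant counts and variant/invariant locus labels.
    """
    ss = np.random.SeedSequence(config.seed)
    msp_seed = int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1)) + 1
    rng = np.random.default_rng(ss.spawn(1)[0])

    dem = build_msprime_demography(config)
    samples = [msprime.SampleSet(p.n_individuals, population=p.name,
                                 ploidy=2) for p in config.populations]
    samples.append(msprime.SampleSet(1, population=config.reference_population,
                                     ploidy=2))
    n_loci = len(catalog)
    individual_ids = config.individual_ids() + [ASSEMBLY_ID]

    if isinstance(config.smm_rate, tuple):
        lo, hi = config.smm_rate
        rates = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_loci))
    else:
        rates = np.full(n_loci, float(config.smm_rate))

    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=1,
        num_replicates=n_loci, random_seed=msp_seed)

    rows = []
    n_reflected = 0
    cat = catalog.reset_index(drop=True)
    for locus_idx, ts in enumerate(reps):
        locus = cat.iloc[locus_idx]
        ref_len = int(locus["ref_len"])
        period = int(locus["period"])
        ref_copies = ref_len // period
        rate = float(rates[locus_idx])

        tree = ts.first()
        disp: dict[int, int] = {}
        for u in tree.nodes(order="preorder"):
            parent = tree.parent(u)
            if parent == -1:
                disp[u] = 0
            else:
                disp[u] = disp[parent] + smm_steps(
                    rng, tree.branch_length(u), rate)

        # individual -> its two sample nodes
        ind_nodes = {individual_ids[i.id]: list(i.nodes)
                     for i in ts.individuals()}
        asm_disp = disp[ind_nodes[ASSEMBLY_ID][0]]

        def allele_len(node: int) -> int:
            nonlocal n_reflected
            copies = ref_copies + disp[node] - asm_disp
            if copies < 1:  # reflect at one copy; keeps length >= period
                copies = 2 - copies
                n_reflected += 1
            return ref_len + period * (copies - ref_copies)

        for ind in config.individual_ids():
            a, b = sorted(allele_len(n) for n in ind_nodes[ind])
            rows.append((locus["locus_id"], ind, a, b))

    genotypes = pd.DataFrame(
        rows, columns=["locus_id", "individual_id", "allele1_len",
                       "allele2_len"])
    if n_reflected:
        logger.info("%d allele states reflected at one copy", n_reflected)

    ref_map = dict(zip(cat["locus_id"], cat["ref_len"]))
    is_var = genotypes.apply(
        lambda r: r.allele1_len != ref_map[r.locus_id]
        or r.allele2_len != ref_map[r.locus_id], axis=1) \
        if len(genotypes) else pd.Series(dtype=bool)
    variant_loci = sorted(genotypes.loc[is_var, "locus_id"].unique()) \
        if len(genotypes) else []
    per_ind = genotypes.loc[is_var].groupby("individual_id").size().to_dict() \
        if len(genotypes) else {}
    manifest = {
        "seed": int(config.seed),
        "n_loci": int(n_loci),
        "variant_loci": list(variant_loci),
        "invariant_loci": sorted(set(cat["locus_id"])
                                 - set(variant_loci)),
        "per_individual_variant_counts": {k: int(v)
                                          for k, v in per_ind.items()},
        "n_reflected": int(n_reflected),
        "per_locus_rate": {str(l): float(r)
                           for l, r in zip(cat["locus_id"], rates)},
    }
    return genotypes, manifest


# --------------------------------------------------------------- depth model

@dataclass
class DepthModelResult:
    calls: list[StrCall]
    locus_quality: dict[str, float]
    locus_coverage: dict[str, float]


def apply_depth_model(genotypes: pd.DataFrame,
                      depths: Mapping[str, float],
                      seed: int,
                      nb_dispersion: float = 40.0,
                      spanning_fraction: float = 0.6,
                      quality_base: float = 2.0,
                      quality_slope: float = 0.6,
                      distends_sd: float = 6.0,
                      ) -> DepthModelResult:
    """Attach coverage/quality/DISTENDS noise to true genotypes.

    Total read depth at a call is negative-binomial with mean equal to the
    individual's sequencing depth (dispersion ``nb_dispersion``); the call
    coverage reported to the genotyper is the subset of reads fully spanning
    the repeat, Binomial(total, ``spanning_fraction``).  Call quality grows
    with that support, Beta(quality_base + quality_slope * coverage, 1), and
    DISTENDS is rounded N(0, distends_sd) truncated to +-50; the quality and
    DISTENDS channels jointly pass ~95% of calls at 30x.  The coverage
    channel is the physical depth effect: shallow genomes fail call-cov for
    most calls, inducing the depth-dependent dropout the diagnostics
    measure.  No call is removed here — dropout happens in the downstream
    filters.

    Returns all calls plus per-locus locus quality (LOCQ) draws and the
    mean-total-coverage per locus used for the loc-cov filter.
    """
    rng = np.random.default_rng(seed)
    n = len(genotypes)
    depth_arr = genotypes["individual_id"].map(dict(depths)).to_numpy(float)
    if np.isnan(depth_arr).any():
        raise ValueError("every individual needs a depth")
    k = nb_dispersion
    total = rng.negative_binomial(k, k / (k + depth_arr), size=n)
    cov = rng.binomial(total, spanning_fraction)
    qual = rng.beta(quality_base + quality_slope * cov, 1.0)
    de = np.clip(np.rint(rng.normal(0.0, distends_sd, size=n)), -50, 50)

    calls = [StrCall(individual_id=row.individual_id, locus_id=row.locus_id,
                     allele1_len=int(row.allele1_len),
                     allele2_len=int(row.allele2_len),
                     coverage=int(c), call_quality=float(q),
                     dist_ends=int(d))
             for row, c, q, d in zip(genotypes.itertuples(), cov, qual, de)]

    loci = list(dict.fromkeys(genotypes["locus_id"]))  # first-seen order
    locq = {l: float(q) for l, q in zip(loci, rng.beta(40.0, 1.0,
                                                       size=len(loci)))}
    totals = pd.Series(total, index=genotypes["locus_id"].to_numpy())
    loc_cov = {l: float(v) for l, v in totals.groupby(level=0).mean().items()}
    return DepthModelResult(calls=calls, locus_quality=locq,
                            locus_coverage=loc_cov)


# ----------------------------------------------------------------- VCF write

def _allele_seq(motif: str, length: int) -> str:
    p = len(motif)
    return (motif * (length // p + 1))[:length]


def write_vcf(calls: Sequence[StrCall],
              catalog: pd.DataFrame,
              path: str | Path,
              sample_order: Optional[Sequence[str]] = None,
              locus_quality: Optional[Mapping[str, float]] = None,
              locus_coverage: Optional[Mapping[str, float]] = None) -> None:
    """Write calls as a VCF 4.2 readable by ``genotype_ingest.read_str_vcf``.

    REF/ALT carry full allele sequences built from the catalog motif, so
    allele length round-trips exactly.  Samples without a call at a locus
    are emitted as ``./.``.  Output is byte-stable for identical inputs.
    """
    locus_quality = locus_quality or {}
    cat = catalog.set_index("locus_id")
    by_locus: dict[str, dict[str, StrCall]] = {}
    for c in calls:
        if c.locus_id not in cat.index:
            raise ValueError(f"call at unknown locus {c.locus_id!r}")
        by_locus.setdefault(c.locus_id, {})[c.individual_id] = c
    if sample_order is None:
        sample_order = sorted({c.individual_id for c in calls})

    locus_coverage = locus_coverage or {}
    lines = ["##fileformat=VCFv4.2",
             "##source=strpop-synthetic"]
    for seq_id, grp in cat.groupby("sequence_id", sort=True):
        lines.append(f"##contig=<ID={seq_id},length="
                     f"{int(grp['end'].max()) + 1000}>")
    lines += [
        '##INFO=<ID=MOTIF,Number=1,Type=String,Description="Repeat motif">',
        '##INFO=<ID=LOCQ,Number=1,Type=Float,Description="Locus quality">',
        '##INFO=<ID=LCOV,Number=1,Type=Float,'
        'Description="Mean total read depth at locus">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Coverage">',
        '##FORMAT=<ID=Q,Number=1,Type=Float,Description="Call quality">',
        '##FORMAT=<ID=DISTENDS,Number=1,Type=Integer,'
        'Description="Read end placement score">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_order),
    ]

    ordered = cat.sort_values(["sequence_id", "start"])
    for locus_id, locus in ordered.iterrows():
        locus_calls = by_locus.get(locus_id)
        if locus_calls is None:
            continue
        motif = str(locus["motif"])
        ref_len = int(locus["ref_len"])
        alt_lens = sorted({l for c in locus_calls.values()
                           for l in (c.allele1_len, c.allele2_len)
                           if l is not None and l != ref_len})
        alleles = [ref_len] + alt_lens
        alt_field = ",".join(_allele_seq(motif, l) for l in alt_lens) or "."
        locq = locus_quality.get(locus_id, 1.0)
        info = f"MOTIF={motif};LOCQ={locq:.4f}"
        if locus_id in locus_coverage:
            info += f";LCOV={locus_coverage[locus_id]:.2f}"
        fields = [str(locus["sequence_id"]), str(int(locus["start"]) + 1),
                  str(locus_id), _allele_seq(motif, ref_len), alt_field,
                  ".", "PASS", info, "GT:DP:Q:DISTENDS"]
        for sample in sample_order:
            c = locus_calls.get(sample)
            if c is None:
                fields.append("./.")
                continue
            i1 = alleles.index(c.allele1_len)
            gt = (f"{i1}/{alleles.index(c.allele2_len)}"
                  if c.allele2_len is not None else f"{i1}")
            fields.append(f"{gt}:{c.coverage}:{c.call_quality:.4f}:"
                          f"{c.dist_ends}")
        lines.append("\t".join(fields))

    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ datasets

def generate_dataset(outdir: str | Path,
                     genome_length: int = 200_000,
                     n_loci: int = 400,
                     config: Optional[DemographyConfig] = None,
                     seed: int = 1) -> dict:
    """End-to-end synthetic dataset on disk.

    Writes reference FASTA, catalog TSV, populations TSV (with depth
    column), calls VCF, TSS/annotation tables for the annotation stage, the
    truth manifest JSON and a copy of the run configuration.  Returns the
    manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or orangutan_demography(seed=seed)
    ss = np.random.SeedSequence(seed)
    s_ref, s_depth, s_ann = [int(s.generate_state(1)[0] % (2**31 - 1))
                             for s in ss.spawn(3)]

    pack = generate_reference(genome_length, n_loci, seed=s_ref)
    write_fasta(pack.sequences, outdir / "reference.fa")
    pack.catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)

    genotypes, truth = simulate_genotypes(pack.catalog, config)
    depths = config.depth_of()
    dm = apply_depth_model(genotypes, depths, seed=s_depth)
    write_vcf(dm.calls, pack.catalog, outdir / "calls.vcf",
              sample_order=config.individual_ids(),
              locus_quality=dm.locus_quality,
              locus_coverage=dm.locus_coverage)

    pops = pd.DataFrame(
        [{"individual_id": i, "population_id": p, "depth": depths[i]}
         for i, p in config.population_of().items()])
    pops.to_csv(outdir / "populations.tsv", sep="\t", index=False)

    tss = generate_tss(genome_length, n_genes=max(20, n_loci // 8),
                       seed=s_ann, sequence_id=pack.catalog["sequence_id"]
                       .iloc[0] if n_loci else "chr1")
    pd.DataFrame([asdict(t) for t in tss]).to_csv(
        outdir / "tss.tsv", sep="\t", index=False)
    terms = generate_annotations([t.gene_id for t in tss], n_terms=15,
                                 seed=s_ann + 1)
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term, genes in terms.items():
            for g in genes:
                fh.write(f"{term}\t{g}\n")

    manifest = {"reference": pack.manifest, "genotypes": truth,
                "config": _config_to_dict(config), "seed": int(seed),
                "genome_length": int(genome_length), "n_loci": int(n_loci)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_tss(genome_length: int, n_genes: int, seed: int,
                 sequence_id: str = "chr1"):
    """Random gene TSS records for exercising the annotation stage."""
    from .annotation import TssRecord
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, genome_length + 1),
                                   size=n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    return [TssRecord(f"gene{idx:04d}", sequence_id, int(pos), str(st))
            for idx, (pos, st) in enumerate(zip(positions, strands))]


def generate_annotations(genes: Sequence[str], n_terms: int,
                         seed: int) -> dict[str, list[str]]:
    """Random term -> gene annotation sets over the given gene universe."""
    rng = np.random.default_rng(seed)
    out = {}
    genes = list(genes)
    for t in range(n_terms):
        size = int(rng.integers(3, max(4, len(genes) // 3)))
        members = rng.choice(genes, size=min(size, len(genes)),
                             replace=False)
        out[f"TERM:{t:04d}"] = sorted(str(g) for g in members)
    return out


def _config_to_dict(config: DemographyConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=list))
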