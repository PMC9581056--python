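#!/usr/bin/env python
"""Population statistics of the filtered synthetic cohort.

Computes per-individual variant counts and mean absolute dosage, the
per-population mean dosage with pairwise Mann-Whitney comparisons, Nei's
unbiased heterozygosity and Slatkin's Rst over eligible loci, and the
depth diagnostics (Spearman rho of sequencing depth with variant count and
with mean dosage).  The depth/variant-count correlation should be strong
and the depth/dosage correlation near zero — dosage is the
coverage-robust measure of STR variation.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from strpop import str_stats
from strpop.genotype_ingest import StrCall, classify_loci


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/synthetic"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    geno = pd.read_csv(args.data / "genotypes_long.tsv", sep="\t")
    catalog = pd.read_csv(args.data / "catalog.tsv", sep="\t")
    pops = pd.read_csv(args.data / "populations.tsv", sep="\t")
    pop_map = dict(zip(pops.individual_id, pops.population_id))
    depths = dict(zip(pops.individual_id, pops.depth))

    calls = [StrCall(r.individual_id, r.locus_id, int(r.allele1_len),
                     int(r.allele2_len), 0, 1.0, 0)
             for r in geno.itertuples()]
    variant, invariant, counts = classify_loci(calls, catalog)

    dosages = str_stats.dosage_records(geno, catalog)
    mean_dos = str_stats.mean_dosage_per_individual(
        dosages, variant_loci=variant)
    per_ind = pd.DataFrame(
        [{"individual_id": i, "population_id": pop_map[i],
          "depth": depths[i], "variant_count": counts.get(i, 0),
          "mean_dosage": mean_dos.get(i)} for i in sorted(pop_map)])

    # diversity/differentiation over populations with >= 2 individuals
    # (a single-genome population cannot satisfy the eligibility rule)
    sizes = pops.groupby("population_id").size()
    pop_ids = sorted(sizes[sizes >= 2].index)
    per_locus = str_stats.per_locus_statistics(geno, pop_map, catalog,
                                               pop_ids)
    hl_cols = [c for c in per_locus.columns if c.startswith("Hl_")]
    H = {c[3:]: str_stats.mean_heterozygosity(
        per_locus[c].dropna().tolist()).H
        for c in hl_cols if per_locus[c].notna().any()}

    all_pops = sorted(set(pop_map.values()))
    dos_groups = {p: [v for i, v in mean_dos.items() if pop_map[i] == p]
                  for p in all_pops}
    mwu = str_stats.mann_whitney_compare(
        {p: v for p, v in dos_groups.items() if len(v) >= 2})
    diag = str_stats.depth_diagnostics(counts, mean_dos, depths)

    args.results.mkdir(parents=True, exist_ok=True)
    per_ind.to_csv(args.results / "04_per_individual.tsv", sep="\t",
                   index=False)
    per_locus.to_csv(args.results / "04_per_locus_stats.tsv", sep="\t",
                     index=False)
    mwu.to_csv(args.results / "04_dosage_mwu.tsv", sep="\t", index=False)
    summary = {
        "mean_dosage_by_population": {
            p: float(pd.Series(v).mean()) for p, v in dos_groups.items()
            if v},
        "mean_heterozygosity_by_population": H,
        "mean_rst_across_populations":
            float(per_locus["rst"].dropna().mean())
            if "rst" in per_locus else None,
        "n_eligible_loci": int(len(per_locus)),
        "depth_diagnostics": dataclasses.asdict(diag),
    }
    (args.results / "04_popgen_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
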