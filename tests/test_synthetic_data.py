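"""Synthetic-data generator: planted references, SMM genotype dynamics,
depth model calibration and VCF emission."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from strpop.repeat_finder import find_candidate_arrays
from strpop.synthetic_data import (DEFAULT_MOTIF_SPECTRUM, ASSEMBLY_ID,
                                   Bottleneck, DemographyConfig,
                                   PopulationSpec, Split, apply_depth_model,
                                   generate_reference, orangutan_demography,
                                   simulate_genotypes, smm_steps, write_vcf,
                                   write_fasta)


class TestGenerateReference:
    def test_motif_spectrum_respected(self):
        spectrum = {2: 0.8, 3: 0.1, 4: 0.05, 5: 0.03, 6: 0.02}
        pack = generate_reference(100_000, 200, spectrum, seed=7)
        frac_dimer = (pack.catalog.period == 2).mean()
        # binomial 95% band around 0.8 with n=200
        assert abs(frac_dimer - 0.8) < 2 * np.sqrt(0.8 * 0.2 / 200) + 1e-9

    def test_zero_loci_still_valid(self):
        pack = generate_reference(5_000, 0, seed=1)
        assert len(pack.sequences["chr1"]) == 5_000
        assert pack.catalog.empty

    def test_infeasible_packing_errors_before_output(self):
        with pytest.raises(ValueError):
            generate_reference(2_000, 100, seed=1)

    def test_determinism(self):
        a = generate_reference(30_000, 60, seed=5)
        b = generate_reference(30_000, 60, seed=5)
        assert a.sequences == b.sequences
        assert a.catalog.equals(b.catalog)

    def test_plants_spaced_and_within_class_rules(self):
        pack = generate_reference(60_000, 100, seed=2)
        cat = pack.catalog.sort_values("start")
        gaps = cat.start.values[1:] - cat.end.values[:-1]
        assert (gaps >= 50).all()
        assert (cat.end - cat.start <= 100).all()
        mins = {2: 13, 3: 20, 4: 23, 5: 27, 6: 27}
        assert all(r.end - r.start >= mins[r.period]
                   for r in cat.itertuples())

    def test_scanner_recovers_all_plants(self, small_pack):
        arrays = find_candidate_arrays(small_pack.sequences["chr1"])
        found = {(a.start, a.end) for a in arrays}
        planted = set(zip(small_pack.catalog.start, small_pack.catalog.end))
        assert planted <= found


def null_return_probability(n_gen, rate):
    """P(net displacement 0) for Binomial(n_gen, rate) +-1 steps."""
    ks = np.arange(0, 60)
    pk = binom.pmf(ks, n_gen, rate)
    return float(sum(p * binom.pmf(k // 2, k, 0.5)
                     for k, p in zip(ks, pk) if k % 2 == 0))


class TestSmmSteps:
    def test_zero_rate_or_time_never_moves(self):
        rng = np.random.default_rng(0)
        assert smm_steps(rng, 0, 1e-3) == 0
        assert smm_steps(rng, 1000, 0.0) == 0

    def test_displacement_law_matches_analytic_oracle(self):
        rng = np.random.default_rng(1)
        n = 20_000
        nonzero = sum(smm_steps(rng, 2000, 1e-3) != 0 for _ in range(n)) / n
        expected = 1 - null_return_probability(2000, 1e-3)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(nonzero - expected) < 3 * se

    def test_neutrality_zero_mean(self):
        rng = np.random.default_rng(2)
        draws = np.array([smm_steps(rng, 2000, 1e-3) for _ in range(20_000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean()) < 3 * se


class TestSimulateGenotypes:
    def test_no_mutation_means_all_reference(self, small_pack,
                                             two_pop_config):
        cfg = two_pop_config(seed=3, rate=0.0)
        geno, truth = simulate_genotypes(small_pack.catalog, cfg)
        ref = dict(zip(small_pack.catalog.locus_id,
                       small_pack.catalog.ref_len))
        assert all(r.allele1_len == ref[r.locus_id]
                   and r.allele2_len == ref[r.locus_id]
                   for r in geno.itertuples())
        assert truth["variant_loci"] == []

    def test_determinism(self, small_pack, two_pop_config):
        cfg = two_pop_config(seed=9)
        g1, t1 = simulate_genotypes(small_pack.catalog, cfg)
        g2, t2 = simulate_genotypes(small_pack.catalog, cfg)
        assert g1.equals(g2) and t1 == t2

    def test_allele_lengths_are_valid_motif_multiples(self, small_pack,
                                                      two_pop_config):
        geno, _ = simulate_genotypes(small_pack.catalog,
                                     two_pop_config(seed=5))
        merged = geno.merge(small_pack.catalog, on="locus_id")
        for col in ("allele1_len", "allele2_len"):
            offset = merged[col] - merged.ref_len
            assert ((offset % merged.period) == 0).all()
            assert (merged[col] >= merged.period).all()

    def test_assembly_individual_hidden_from_output(self, small_pack,
                                                    two_pop_config):
        geno, _ = simulate_genotypes(small_pack.catalog,
                                     two_pop_config(seed=6))
        assert ASSEMBLY_ID not in set(geno.individual_id)
        assert set(geno.individual_id) \
            == set(two_pop_config(seed=6).individual_ids())

    def test_mean_dosage_orders_with_split_time(self, small_pack):
        """Divergence from the reference genome grows with split time."""
        from strpop.str_stats import dosage_records
        wins = 0
        for seed in range(4):
            cfg = DemographyConfig(
                populations=(PopulationSpec("ref", 5, 500.0, (30.0,) * 5),
                             PopulationSpec("near", 5, 500.0, (30.0,) * 5),
                             PopulationSpec("far", 5, 500.0, (30.0,) * 5)),
                splits=(Split(500.0, ("ref", "near"), "a1"),
                        Split(8000.0, ("a1", "far"), "a2")),
                ancestral_sizes=(("a1", 500.0), ("a2", 500.0)),
                reference_population="ref", seed=seed, smm_rate=1e-3)
            geno, _ = simulate_genotypes(small_pack.catalog, cfg)
            dos = dosage_records(geno, small_pack.catalog)
            dos["pop"] = dos.individual_id.str.split("_").str[0]
            m = dos.groupby("pop").dosage.mean()
            wins += m["near"] < m["far"]
        assert wins >= 3

    def test_smm_rate_validation(self):
        with pytest.raises(ValueError):
            DemographyConfig(
                populations=(PopulationSpec("p", 2, 100.0, (30.0, 30.0)),),
                splits=(), ancestral_sizes=(), reference_population="p",
                seed=1, smm_rate=0.5)


class TestDepthModel:
    def test_saturating_depth_keeps_almost_everything(self, small_pack,
                                                      two_pop_config):
        from strpop.genotype_ingest import (classify_loci,
                                            filter_calls_and_loci,
                                            locus_qualities)
        cfg = two_pop_config(seed=11)
        geno, truth = simulate_genotypes(small_pack.catalog, cfg)
        depths = {i: 1000.0 for i in cfg.individual_ids()}
        dm = apply_depth_model(geno, depths, seed=12)
        loci = locus_qualities(dm.calls, small_pack.catalog,
                               len(depths), dm.locus_quality,
                               dm.locus_coverage)
        _, kept, _ = filter_calls_and_loci(loci, dm.calls)
        assert len(kept) > 0.98 * len(dm.calls)
        var, _, _ = classify_loci(kept, small_pack.catalog)
        assert var == set(truth["variant_loci"])

    def test_determinism(self, small_pack, two_pop_config):
        cfg = two_pop_config(seed=13)
        geno, _ = simulate_genotypes(small_pack.catalog, cfg)
        depths = cfg.depth_of()
        a = apply_depth_model(geno, depths, seed=1)
        b = apply_depth_model(geno, depths, seed=1)
        assert a.calls == b.calls and a.locus_quality == b.locus_quality

    def test_quality_and_distends_pass_rate_near_95pct_at_30x(self,
                                                              small_pack):
        cfg = orangutan_demography(seed=21)
        geno, _ = simulate_genotypes(small_pack.catalog, cfg)
        depths = {i: 30.0 for i in cfg.individual_ids()}
        dm = apply_depth_model(geno, depths, seed=22)
        ok = np.mean([c.call_quality >= 0.8 and abs(c.dist_ends) <= 20
                      for c in dm.calls])
        assert 0.90 < ok < 0.99


class TestWriteVcf:
    def test_empty_call_set_is_parseable_header(self, tmp_path, small_pack):
        path = tmp_path / "empty.vcf"
        write_vcf([], small_pack.catalog, path, sample_order=["S1"])
        from strpop.genotype_ingest import read_str_vcf
        loci, calls = read_str_vcf(path)
        assert loci == [] and calls == []

    def test_byte_stable_output(self, tmp_path, small_pack,
                                two_pop_config):
        cfg = two_pop_config(seed=17)
        geno, _ = simulate_genotypes(small_pack.catalog, cfg)
        dm = apply_depth_model(geno, cfg.depth_of(), seed=18)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        for p in (p1, p2):
            write_vcf(dm.calls, small_pack.catalog, p,
                      sample_order=cfg.individual_ids(),
                      locus_quality=dm.locus_quality,
                      locus_coverage=dm.locus_coverage)
        assert p1.read_bytes() == p2.read_bytes()

    def test_external_validator_accepts_output(self, tmp_path, small_pack,
                                               two_pop_config):
        cfg = two_pop_config(seed=19)
        geno, _ = simulate_genotypes(small_pack.catalog, cfg)
        dm = apply_depth_model(geno, cfg.depth_of(), seed=20)
        path = tmp_path / "sim.vcf"
        write_vcf(dm.calls, small_pack.catalog, path,
                  sample_order=cfg.individual_ids(),
                  locus_quality=dm.locus_quality,
                  locus_coverage=dm.locus_coverage)
        res = subprocess.run(["bcftools", "view", str(path)],
                             capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        assert "error" not in res.stderr.lower()


class TestDatasetRoundTrip:
    def test_fasta_write_read(self, tmp_path, small_pack):
        from Bio import SeqIO
        path = tmp_path / "ref.fa"
        write_fasta(small_pack.sequences, path)
        rec = next(SeqIO.parse(str(path), "fasta"))
        assert str(rec.seq) == small_pack.sequences["chr1"]

    def test_generate_dataset_manifest(self, tmp_path):
        from strpop.synthetic_data import generate_dataset
        manifest = generate_dataset(tmp_path / "d", genome_length=60_000,
                                    n_loci=80, seed=5)
        files = {p.name for p in (tmp_path / "d").iterdir()}
        assert {"reference.fa", "catalog.tsv", "calls.vcf",
                "populations.tsv", "tss.tsv", "annotations.tsv",
                "manifest.json"} <= files
        stored = json.loads((tmp_path / "d" / "manifest.json").read_text())
        assert stored["genotypes"]["variant_loci"] \
            == manifest["genotypes"]["variant_loci"]
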