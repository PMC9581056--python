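"""Dosage, Nei heterozygosity, Slatkin Rst and the cohort diagnostics,
checked against exact-arithmetic pair-enumeration oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hs

from strpop.str_stats import (AlleleFrequencySpectrum, absolute_dosage,
                              build_afs, depth_diagnostics, dosage_records,
                              eligible_loci, mann_whitney_compare,
                              mean_dosage_per_individual,
                              mean_heterozygosity, nei_heterozygosity, rst)


class TestAbsoluteDosage:
    @pytest.mark.parametrize("a1,a2,ref,expected", [
        (18, 22, 20, 2.0),   # heterozygous worked example
        (18, 18, 24, 6.0),   # homozygous non-reference worked example
        (20, 20, 20, 0.0),   # reference-identical genotype
        (18, None, 24, 6.0),  # hemizygous rule
    ])
    def test_examples(self, a1, a2, ref, expected):
        assert absolute_dosage(a1, a2, ref) == expected

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            absolute_dosage(18, 22, None)

    @given(hs.integers(1, 100), hs.integers(1, 100), hs.integers(1, 100),
           hs.integers(-10, 10))
    def test_symmetry_and_translation_invariance(self, a1, a2, ref, c):
        d = absolute_dosage(a1, a2, ref)
        assert d == absolute_dosage(a2, a1, ref)
        assert d == absolute_dosage(a1 + c, a2 + c, ref + c)
        assert d >= 0


class TestMeanDosage:
    DF = pd.DataFrame({"individual_id": ["I0", "I0", "I1"],
                       "locus_id": ["L0", "L1", "L0"],
                       "dosage": [2.0, 6.0, 0.0]})

    def test_simple_mean(self):
        out = mean_dosage_per_individual(self.DF, scope="all")
        assert out == {"I0": 4.0, "I1": 0.0}

    def test_individual_without_variant_loci_is_absent(self):
        out = mean_dosage_per_individual(self.DF, scope="variant_loci",
                                         variant_loci={"L1"})
        assert out == {"I0": 6.0}


def nei_pair_oracle(counts):
    """P(two copies drawn without replacement differ), exact rationals."""
    total = sum(counts)
    same = sum(Fraction(c * (c - 1), 1) for c in counts)
    return 1 - same / Fraction(total * (total - 1), 1)


class TestNeiHeterozygosity:
    def test_monomorphic_is_zero(self):
        afs = AlleleFrequencySpectrum("l", "p", [20], [8])
        assert nei_heterozygosity(afs) == 0.0

    def test_two_alleles_half_half(self):
        afs = AlleleFrequencySpectrum("l", "p", [20, 22], [2, 2])
        assert nei_heterozygosity(afs) == pytest.approx(2 / 3)

    def test_printed_formula_equals_pair_enumeration(self):
        afs = AlleleFrequencySpectrum("l", "p", [10, 12, 14, 16],
                                      [4, 3, 2, 1])
        assert nei_heterozygosity(afs) == pytest.approx(7 / 9)
        assert nei_heterozygosity(afs) == pytest.approx(
            float(nei_pair_oracle(afs.counts)))

    @given(hs.lists(hs.integers(1, 8), min_size=1, max_size=6))
    def test_formula_matches_oracle_for_any_spectrum(self, counts):
        if sum(counts) % 2:
            counts = counts + [1]
        if sum(counts) < 2:
            counts = counts + [1, 1]
        sizes = list(range(10, 10 + 2 * len(counts), 2))
        afs = AlleleFrequencySpectrum("l", "p", sizes, counts)
        assert nei_heterozygosity(afs) == pytest.approx(
            float(nei_pair_oracle(counts)), abs=1e-12)

    def test_relabeling_invariance_and_split_increase(self):
        a = AlleleFrequencySpectrum("l", "p", [10, 14, 30], [4, 3, 1])
        b = AlleleFrequencySpectrum("l", "p", [98, 12, 50], [4, 3, 1])
        assert nei_heterozygosity(a) == nei_heterozygosity(b)
        split = AlleleFrequencySpectrum("l", "p", [10, 12, 14, 30],
                                        [2, 2, 3, 1])
        assert nei_heterozygosity(split) > nei_heterozygosity(a)

    def test_all_distinct_gives_one(self):
        afs = AlleleFrequencySpectrum("l", "p", [10, 12, 14, 16],
                                      [1, 1, 1, 1])
        assert nei_heterozygosity(afs) == pytest.approx(1.0)


class TestMeanHeterozygosity:
    def test_simple_and_constant(self):
        est = mean_heterozygosity([0.0, 1.0])
        assert (est.H, est.N) == (0.5, 2)
        assert mean_heterozygosity([0.3] * 5).H == pytest.approx(0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_heterozygosity([])


def rst_pair_oracle(pops):
    """Exact-rational double loop over all pooled and within pairs."""
    pooled = [x for v in pops.values() for x in v]
    sq = lambda xs: [Fraction((a - b) ** 2) for a, b in
                     itertools.combinations(xs, 2)]
    S = sum(sq(pooled)) / len(sq(pooled))
    within = [d for v in pops.values() for d in sq(v)]
    SW = sum(within) / len(within)
    return S, SW, (S - SW) / S if S else None


class TestRst:
    def test_complete_fixation_is_one(self):
        d = rst({"p1": [10, 10, 10], "p2": [14, 14]})
        assert d.S_W == 0 and d.rst == 1.0

    def test_identical_balanced_multisets_near_zero(self):
        sizes = [10, 10, 12, 12, 14, 14]
        d = rst({"p1": sizes, "p2": sizes})
        assert abs(d.rst) < 0.15

    def test_worked_fixture_matches_exact_oracle(self):
        pops = {"p1": [10, 10, 12], "p2": [14, 16]}
        d = rst(pops)
        S, SW, val = rst_pair_oracle(pops)
        assert d.S == pytest.approx(float(S))
        assert d.S_W == pytest.approx(float(SW))
        assert d.rst == pytest.approx(float(val))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_up_to_20_copies(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = int(rng.integers(2, 4))
        pops = {f"p{i}": list(rng.integers(8, 30,
                                           size=int(rng.integers(2, 8))))
                for i in range(n_pops)}
        if sum(len(v) for v in pops.values()) > 20:
            pops = {k: v[:6] for k, v in pops.items()}
        d = rst(pops)
        S, SW, val = rst_pair_oracle(pops)
        assert d.S == pytest.approx(float(S), abs=1e-9)
        assert d.S_W == pytest.approx(float(SW), abs=1e-9)
        if val is None:
            assert d.rst is None
        else:
            assert d.rst == pytest.approx(float(val), abs=1e-9)

    def test_translation_and_scale_invariance(self):
        pops = {"p1": [10, 12, 12], "p2": [16, 18]}
        base = rst(pops).rst
        shifted = rst({k: [x + 7 for x in v] for k, v in pops.items()}).rst
        scaled = rst({k: [3 * x for x in v] for k, v in pops.items()}).rst
        assert base == pytest.approx(shifted)
        assert base == pytest.approx(scaled)

    def test_monomorphic_pool_is_undefined(self):
        d = rst({"p1": [10, 10], "p2": [10, 10]})
        assert d.rst is None and d.S == 0

    def test_needs_two_populations_with_two_copies(self):
        with pytest.raises(ValueError):
            rst({"p1": [10, 12]})
        with pytest.raises(ValueError):
            rst({"p1": [10, 12], "p2": [14]})

    def test_population_weighting_option(self):
        pops = {"p1": [10, 10, 12, 14, 30], "p2": [14, 16]}
        pairs = rst(pops, within_weighting="pairs")
        unweighted = rst(pops, within_weighting="populations")
        assert pairs.S_W != unweighted.S_W  # unbalanced sizes separate them


class TestDepthDiagnostics:
    def test_perfect_ranks(self):
        depths = {f"I{i}": 10 + i for i in range(8)}
        counts = {f"I{i}": 5 * i for i in range(8)}
        dos = {f"I{i}": 3.0 + 0.01 * (i % 3) for i in range(8)}
        d = depth_diagnostics(counts, dos, depths)
        assert d.rho_count == pytest.approx(1.0)

    def test_null_depths_rarely_significant(self):
        rng = np.random.default_rng(0)
        depths = {f"I{i}": float(d) for i, d in
                  enumerate(np.linspace(10, 40, 20))}
        hits = 0
        for _ in range(100):
            counts = {i: float(c) for i, c in
                      zip(depths, rng.permutation(20))}
            d = depth_diagnostics(counts, counts, depths)
            hits += d.p_count <= 0.05
        assert hits <= 10  # ~5% expected under the null

    def test_constant_vector_reports_undefined(self):
        depths = {f"I{i}": 20.0 for i in range(6)}
        counts = {f"I{i}": i for i in range(6)}
        d = depth_diagnostics(counts, counts, depths)
        assert math.isnan(d.rho_count)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            depth_diagnostics({}, {}, {"a": 1, "b": 2})


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        df = mann_whitney_compare({"a": [1, 2, 3, 4, 5],
                                   "b": [1, 2, 3, 4, 5]})
        assert df.loc[0, "p_raw"] > 0.9

    def test_separated_groups_exact_p(self):
        df = mann_whitney_compare({"a": [1, 2, 3, 4, 5],
                                   "b": [10, 11, 12, 13, 14]})
        assert df.loc[0, "U"] == 0.0
        assert df.loc[0, "p_raw"] == pytest.approx(0.00793, abs=5e-5)

    def test_degenerate_group_skipped_with_note(self):
        df = mann_whitney_compare({"a": [1, 2, 3], "b": [4.0],
                                   "c": [5, 6, 7]})
        noted = df[df.note != ""]
        assert set(noted.group2) | set(noted.group1) >= {"b"}
        assert df[df.note == ""]["p_raw"].notna().all()

    def test_bh_adjustment_not_below_raw(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": list(rng.normal(i * 0.2, 1, 10))
                  for i in range(4)}
        df = mann_whitney_compare(groups)
        assert (df["p_fdr"] >= df["p_raw"] - 1e-12).all()


class TestPipelineHelpers:
    def test_dosage_records_require_catalog(self):
        geno = pd.DataFrame({"locus_id": ["L0"], "individual_id": ["I0"],
                             "allele1_len": [20], "allele2_len": [22]})
        cat = pd.DataFrame({"locus_id": ["L1"], "ref_len": [20]})
        with pytest.raises(ValueError):
            dosage_records(geno, cat)

    def test_eligibility_requires_two_nonref_alleles_per_population(self):
        cat = pd.DataFrame({"locus_id": ["L0", "L1"], "ref_len": [20, 20]})
        rows = []
        for pop, inds in (("p1", ["a", "b"]), ("p2", ["c", "d"])):
            for ind in inds:
                rows.append(dict(locus_id="L0", individual_id=ind,
                                 allele1_len=22, allele2_len=24))
                # L1 has only one non-reference allele length in p2
                rows.append(dict(locus_id="L1", individual_id=ind,
                                 allele1_len=22 if pop == "p1" else 20,
                                 allele2_len=24 if pop == "p1" else 22))
        geno = pd.DataFrame(rows)
        pops = {"a": "p1", "b": "p1", "c": "p2", "d": "p2"}
        assert eligible_loci(geno, pops, cat, ["p1", "p2"]) == ["L0"]

    def test_build_afs_counts_diploid_copies(self):
        geno = pd.DataFrame({"locus_id": ["L0", "L0"],
                             "individual_id": ["a", "b"],
                             "allele1_len": [20, 22],
                             "allele2_len": [22, 22]})
        afs = build_afs(geno, {"a": "p", "b": "p"}, "L0", "p")
        assert afs.n == 2 and afs.a == 2
        assert dict(zip(afs.allele_sizes, afs.counts)) == {20: 1, 22: 3}
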