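"""Population-genetic statistics for STR genotypes.

Implements:

* **absolute dosage** — the mean absolute base-pair deviation of an
  individual's alleles from the reference allele,
  ``(|a1 - ref| + |a2 - ref|)/2`` for diploid genotypes and ``|a - ref|``
  for a single (hemizygous) allele.  A coverage-robust measure of the
  *extent* of STR variation.
* **Nei's unbiased expected heterozygosity**
  ``Hl = 2n/(2n-1) * (1 - sum_i f_i^2)`` per locus, and the mean ``H`` over
  loci with its standard error.
* **Slatkin's Rst** ``(S - S_W)/S`` where ``S`` is the average squared
  allele-size difference over all pooled pairs of alleles and ``S_W`` the
  within-subpopulation average — the Fst analogue appropriate under the
  stepwise mutation model.
* depth diagnostics (Spearman correlations of sequencing depth with variant
  count and mean dosage) and pairwise Mann-Whitney U comparisons with
  Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DosageRecord:
    individual_id: str
    locus_id: str
    dosage: float


@dataclass
class AlleleFrequencySpectrum:
    """Per-locus, per-population allele counts.

    ``n`` is the number of diploid individuals genotyped, so counts sum to
    ``2n``; ``a`` is the number of distinct allele sizes.
    """

    locus_id: str
    population_id: str
    allele_sizes: list[int]
    counts: list[int]

    def __post_init__(self) -> None:
        if len(self.allele_sizes) != len(self.counts):
            raise ValueError("allele_sizes and counts length mismatch")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        if sum(self.counts) % 2:
            raise ValueError("diploid spectra need an even total allele count")

    @property
    def n(self) -> int:
        return sum(self.counts) // 2

    @property
    def a(self) -> int:
        return len(set(self.allele_sizes))

    @property
    def frequencies(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()


@dataclass
class DiversityEstimate:
    H: float
    se: float
    N: int


@dataclass
class RstDecomposition:
    locus_id: str
    S: float
    S_W: float
    rst: Optional[float]


def absolute_dosage(allele1_len: float,
                    allele2_len: Optional[float],
                    ref_len: float) -> float:
    """Absolute STR dosage of one genotype against the reference allele.

    Diploid: ``(|a1 - ref| + |a2 - ref|)/2``; single-allele (hemizygous or
    collapsed homozygous): ``|a - ref|``.  E.g. genotype 18/22 against a
    20 bp reference gives 2; genotype 18/18 against 24 bp gives 6.
    """
    if ref_len is None or (isinstance(ref_len, float) and math.isnan(ref_len)):
        raise ValueError("reference allele length required (catalog join)")
    if allele2_len is None or (isinstance(allele2_len, float)
                               and math.isnan(allele2_len)):
        return abs(allele1_len - ref_len)
    return (abs(allele1_len - ref_len) + abs(allele2_len - ref_len)) / 2


def dosage_records(genotypes: pd.DataFrame,
                   catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-call dosage table from a long genotype frame joined to the catalog.

    ``genotypes`` columns: locus_id, individual_id, allele1_len, allele2_len;
    ``catalog`` columns: locus_id, ref_len.
    """
    merged = genotypes.merge(catalog[["locus_id", "ref_len"]], on="locus_id",
                             how="left")
    if merged["ref_len"].isna().any():
        missing = merged.loc[merged["ref_len"].isna(), "locus_id"].unique()
        raise ValueError(f"loci missing from catalog: {list(missing)[:5]}")
    merged["dosage"] = [
        absolute_dosage(a1, a2 if pd.notna(a2) else None, r)
        for a1, a2, r in zip(merged["allele1_len"], merged["allele2_len"],
                             merged["ref_len"])]
    return merged[["individual_id", "locus_id", "dosage"]]


def mean_dosage_per_individual(dosages: pd.DataFrame,
                               scope: str = "variant_loci",
                               variant_loci: Optional[set[str]] = None,
                               ) -> dict[str, float]:
    """Mean dosage per individual over loci in scope.

    ``scope`` is ``"variant_loci"`` (restrict to the given variant locus set,
    mirroring the per-individual means over STR *variants*) or ``"all"``.
    Individuals with no loci in scope are absent from the result, not zero.
    """
    df = dosages
    if scope == "variant_loci":
        if variant_loci is None:
            raise ValueError("variant_loci set required for that scope")
        df = df[df["locus_id"].isin(variant_loci)]
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    return df.groupby("individual_id")["dosage"].mean().to_dict()


def nei_heterozygosity(afs: AlleleFrequencySpectrum) -> float:
    """Nei's unbiased expected heterozygosity ``2n/(2n-1) (1 - sum f_i^2)``.

    Equals the probability that two allele copies drawn without replacement
    from the sample differ in size; 0 for a monomorphic locus and 1 only
    when all 2n copies are distinct.
    """
    n = afs.n
    if n < 1:
        raise ValueError("locus with no genotyped individuals")
    f = afs.frequencies
    return (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(f * f)))


def mean_heterozygosity(per_locus: Sequence[float]) -> DiversityEstimate:
    """Mean heterozygosity over loci, with its standard error."""
    if len(per_locus) == 0:
        raise ValueError("no loci supplied")
    arr = np.asarray(per_locus, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return DiversityEstimate(H=float(arr.mean()), se=se, N=len(arr))


def build_afs(genotypes: pd.DataFrame,
              populations: Mapping[str, str],
              locus_id: str,
              population_id: str) -> Optional[AlleleFrequencySpectrum]:
    """Allele-size spectrum of one population at one locus (None if no
    genotyped individual)."""
    sub = genotypes[(genotypes["locus_id"] == locus_id)
                    & genotypes["individual_id"].map(
                        lambda i: populations.get(i) == population_id)]
    sizes: list[int] = []
    for _, row in sub.iterrows():
        sizes.append(int(row["allele1_len"]))
        sizes.append(int(row["allele2_len"]
                         if pd.notna(row["allele2_len"])
                         else row["allele1_len"]))
    if not sizes:
        return None
    uniq, counts = np.unique(sizes, return_counts=True)
    return AlleleFrequencySpectrum(
        locus_id=locus_id, population_id=population_id,
        allele_sizes=[int(u) for u in uniq], counts=[int(c) for c in counts])


def eligible_loci(genotypes: pd.DataFrame,
                  populations: Mapping[str, str],
                  catalog: pd.DataFrame,
                  population_ids: Sequence[str],
                  min_nonref_alleles: int = 2) -> list[str]:
    """Loci carrying >= ``min_nonref_alleles`` distinct non-reference allele
    lengths in *every* listed population (the eligibility rule applied before
    heterozygosity and Rst estimation)."""
    ref_len = dict(zip(catalog["locus_id"], catalog["ref_len"]))
    out = []
    for locus in genotypes["locus_id"].unique():
        ok = True
        for pop in population_ids:
            afs = build_afs(genotypes, populations, locus, pop)
            if afs is None:
                ok = False
                break
            nonref = {s for s in afs.allele_sizes if s != ref_len[locus]}
            if len(nonref) < min_nonref_alleles:
                ok = False
                break
        if ok:
            out.append(locus)
    return out


def _mean_sq_pair_diff(x: np.ndarray) -> float:
    """Average of (x_i - x_j)^2 over unordered pairs = 2 * sample variance."""
    n = len(x)
    if n < 2:
        raise ValueError("need at least two allele copies")
    return 2.0 * float(np.var(x, ddof=1))


def rst(allele_sizes_by_population: Mapping[str, Sequence[float]],
        locus_id: str = "",
        within_weighting: str = "pairs") -> RstDecomposition:
    """Slatkin's Rst = (S - S_W)/S from allele sizes per subpopulation.

    ``S`` averages squared allele-size differences over all pooled unordered
    pairs; ``S_W`` over within-population pairs, pooled weighted by pair
    counts (``within_weighting="pairs"``, the default) or as an unweighted
    mean of per-population averages (``"populations"``).  When every pooled
    allele is identical (S = 0) Rst is undefined and returned as None.
    """
    pops = {k: np.asarray(v, dtype=float)
            for k, v in allele_sizes_by_population.items()}
    if len(pops) < 2 or any(len(v) < 2 for v in pops.values()):
        raise ValueError("need >= 2 populations with >= 2 allele copies each")
    pooled = np.concatenate(list(pops.values()))
    S = _mean_sq_pair_diff(pooled)
    if within_weighting == "pairs":
        num = sum(_mean_sq_pair_diff(v) * (len(v) * (len(v) - 1) / 2)
                  for v in pops.values())
        den = sum(len(v) * (len(v) - 1) / 2 for v in pops.values())
        S_W = num / den
    elif within_weighting == "populations":
        S_W = float(np.mean([_mean_sq_pair_diff(v) for v in pops.values()]))
    else:
        raise ValueError(f"unknown within_weighting {within_weighting!r}")
    value = None if S == 0 else (S - S_W) / S
    return RstDecomposition(locus_id=locus_id, S=S, S_W=S_W, rst=value)


@dataclass
class DepthDiagnostics:
    rho_count: float
    p_count: float
    rho_dosage: float
    p_dosage: float
    n: int


def depth_diagnostics(variant_counts: Mapping[str, float],
                      mean_dosage: Mapping[str, float],
                      depths: Mapping[str, float]) -> DepthDiagnostics:
    """Spearman correlations of sequencing depth with per-individual variant
    count and with mean absolute dosage.

    Individuals present in ``depths`` but absent from a map contribute 0
    variants / are dropped from the dosage correlation.  Constant inputs
    yield NaN correlations (undefined), as scipy reports them.
    """
    inds = sorted(depths)
    if len(inds) < 5:
        raise ValueError("need at least 5 individuals")
    d = np.array([depths[i] for i in inds], dtype=float)
    counts = np.array([variant_counts.get(i, 0) for i in inds], dtype=float)
    rho_c, p_c = stats.spearmanr(d, counts)

    dos_inds = [i for i in inds if i in mean_dosage]
    if len(dos_inds) >= 5:
        dd = np.array([depths[i] for i in dos_inds])
        dos = np.array([mean_dosage[i] for i in dos_inds])
        rho_d, p_d = stats.spearmanr(dd, dos)
    else:
        rho_d, p_d = math.nan, math.nan
    return DepthDiagnostics(rho_count=float(rho_c), p_count=float(p_c),
                            rho_dosage=float(rho_d), p_dosage=float(p_d),
                            n=len(inds))


def mann_whitney_compare(groups: Mapping[str, Sequence[float]],
                         ) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests for every pair of groups.

    Uses the exact null distribution for small tie-free samples (scipy's
    automatic choice) and reports raw p-values plus Benjamini-Hochberg
    adjusted ones.  Pairs with a degenerate group (< 2 values) are skipped
    and flagged in the ``note`` column.
    """
    rows = []
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        x, y = list(groups[g1]), list(groups[g2])
        if len(x) < 2 or len(y) < 2:
            rows.append({"group1": g1, "group2": g2, "U": math.nan,
                         "p_raw": math.nan, "note": "degenerate group"})
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="auto")
        rows.append({"group1": g1, "group2": g2, "U": float(res.statistic),
                     "p_raw": float(res.pvalue), "note": ""})
    df = pd.DataFrame(rows, columns=["group1", "group2", "U", "p_raw",
                                     "note"])
    mask = df["p_raw"].notna()
    df["p_fdr"] = math.nan
    if mask.any():
        df.loc[mask, "p_fdr"] = multipletests(
            df.loc[mask, "p_raw"], method="fdr_bh")[1]
    return df


def per_locus_statistics(genotypes: pd.DataFrame,
                         populations: Mapping[str, str],
                         catalog: pd.DataFrame,
                         population_ids: Sequence[str],
                         loci: Optional[Sequence[str]] = None,
                         ) -> pd.DataFrame:
    """Per-locus Hl (per population) and Rst over the given populations.

    Convenience driver joining the primitives above; loci default to the
    eligibility rule of :func:`eligible_loci`.
    """
    if loci is None:
        loci = eligible_loci(genotypes, populations, catalog, population_ids)
    rows = []
    for locus in loci:
        row: dict[str, object] = {"locus_id": locus}
        sizes_by_pop = {}
        for pop in population_ids:
            afs = build_afs(genotypes, populations, locus, pop)
            if afs is None:
                continue
            row[f"Hl_{pop}"] = nei_heterozygosity(afs)
            sizes_by_pop[pop] = np.repeat(afs.allele_sizes, afs.counts)
        usable = {p: v for p, v in sizes_by_pop.items() if len(v) >= 2}
        if len(usable) >= 2:
            dec = rst(usable, locus_id=locus)
            row.update({"S": dec.S, "S_W": dec.S_W, "rst": dec.rst})
        rows.append(row)
    return pd.DataFrame(rows)
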