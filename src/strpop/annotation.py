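"""Promoter-proximity annotation of STR variants and gene-set enrichment.

Each variant STR locus is assigned to the gene whose transcription start
site (TSS) minimises the absolute distance to the STR start coordinate.
Genes with a *recurrent* variant (seen in at least two individuals of a
single population) within 10 kb of their TSS form the promoter-proximal
gene sets, which are then tested for term over-representation with a
one-sided hypergeometric test (or the conservative EASE variant that
decrements the hit count by one) and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    sequence_id: str
    tss: int  # 1-based position
    strand: str = "+"


@dataclass
class PromoterHit:
    locus_id: str
    gene_id: str
    distance: int


def load_tss_tsv(path: str | Path) -> list[TssRecord]:
    """4-column TSV: gene_id, sequence_id, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t")
    return [TssRecord(str(r.gene_id), str(r.sequence_id), int(r.tss),
                      str(r.strand))
            for r in df.itertuples()]


def load_tss_gff3(path: str | Path, feature: str = "gene") -> list[TssRecord]:
    """TSS from GFF3 gene records: start on '+' strand, end on '-'."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="merge")
    records = []
    for gene in db.features_of_type(feature):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        tss = gene.start if gene.strand != "-" else gene.end
        records.append(TssRecord(gene_id, gene.seqid, int(tss), gene.strand))
    return records


class TssIndex:
    """Sorted-position index for nearest-TSS queries, one list per sequence."""

    def __init__(self, records: Iterable[TssRecord]):
        by_seq: dict[str, list[tuple[int, str]]] = {}
        for r in records:
            by_seq.setdefault(r.sequence_id, []).append((r.tss, r.gene_id))
        self._by_seq = {seq: sorted(v) for seq, v in by_seq.items()}

    def nearest(self, sequence_id: str, pos: int
                ) -> Optional[tuple[str, int]]:
        """(gene_id, distance) of the nearest TSS, or None if the sequence
        has no TSS.  Equidistant ties break to the smaller gene_id."""
        entries = self._by_seq.get(sequence_id)
        if not entries:
            return None
        positions = [t for t, _ in entries]
        i = bisect.bisect_left(positions, pos)
        best: Optional[tuple[int, str]] = None
        for j in range(max(0, i - 1), min(len(entries), i + 1) + 1):
            if j >= len(entries):
                continue
            t, g = entries[j]
            cand = (abs(pos - t), g)
            if best is None or cand < best:
                best = cand
        # neighbours sharing the boundary distance may include equal
        # positions before/after; widen until distance grows
        d0 = best[0]
        j = i - 2
        while j >= 0 and abs(pos - entries[j][0]) <= d0:
            cand = (abs(pos - entries[j][0]), entries[j][1])
            best = min(best, cand)
            j -= 1
        j = i + 2
        while j < len(entries) and abs(pos - entries[j][0]) <= d0:
            cand = (abs(pos - entries[j][0]), entries[j][1])
            best = min(best, cand)
            j += 1
        return best[1], best[0]


def nearest_tss(str_start: int,
                tss_records: Sequence[TssRecord]) -> tuple[str, int]:
    """Nearest TSS to an STR start on one sequence (absolute distance,
    strand ignored).  Ties break to the lexicographically smaller gene."""
    if not tss_records:
        raise ValueError("no TSS records supplied")
    seqs = {r.sequence_id for r in tss_records}
    if len(seqs) > 1:
        raise ValueError("tss_records span multiple sequences")
    best = min((abs(str_start - r.tss), r.gene_id) for r in tss_records)
    return best[1], best[0]


def assign_promoter_hits(variant_loci: pd.DataFrame,
                         tss_records: Iterable[TssRecord],
                         ) -> list[PromoterHit]:
    """Nearest-gene assignment for each variant locus.

    ``variant_loci`` columns: locus_id, sequence_id, start.  Loci on
    sequences without any TSS produce no hit.
    """
    index = TssIndex(tss_records)
    hits = []
    for r in variant_loci.itertuples():
        res = index.nearest(str(r.sequence_id), int(r.start))
        if res is None:
            continue
        hits.append(PromoterHit(str(r.locus_id), res[0], res[1]))
    return hits


def select_promoter_variants(hits: Sequence[PromoterHit],
                             counts: pd.DataFrame,
                             groups: Mapping[str, Sequence[str]],
                             window: int = 10_000,
                             min_individuals: int = 2,
                             ) -> dict[str, list[str]]:
    """Promoter-proximal recurrent gene set per population group.

    ``counts`` columns: locus_id, population_id, n_individuals (number of
    individuals of that population in which the locus is variant).  A gene
    enters group G's set iff some locus maps nearest to it at distance <=
    ``window`` and is variant in >= ``min_individuals`` individuals of a
    *single* population belonging to G (individuals split across
    populations do not pool).
    """
    qual_pops: dict[str, set[str]] = {}
    for r in counts.itertuples():
        if int(r.n_individuals) >= min_individuals:
            qual_pops.setdefault(str(r.locus_id), set()).add(
                str(r.population_id))

    out: dict[str, list[str]] = {}
    for group, pops in groups.items():
        pops = set(pops)
        genes = {h.gene_id for h in hits
                 if h.distance <= window
                 and qual_pops.get(h.locus_id, set()) & pops}
        out[group] = sorted(genes)
    return out


def overrepresentation_test(gene_set: Sequence[str],
                            background_annotations: Mapping[str, Sequence[str]],
                            universe: Sequence[str],
                            method: str = "hypergeometric") -> pd.DataFrame:
    """Term over-representation in ``gene_set`` against ``universe``.

    One-sided hypergeometric tail p per term (``method="ease"`` decrements
    the hit count by one, the conservative EASE score), Benjamini-Hochberg
    FDR across tested terms, and fold enrichment
    ``(hits/|set|) / (term_size/|universe|)``.  Results sorted by adjusted
    then raw p.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown method {method!r}")
    uni = set(universe)
    gset = set(gene_set) & uni
    if set(gene_set) - uni:
        raise ValueError("gene_set contains genes outside the universe")
    if not gset:
        logger.warning("empty gene set; no enrichment computed")
        return pd.DataFrame(columns=["term_id", "n_hits", "n_background",
                                     "fold_enrichment", "p_raw", "p_fdr"])
    M, N = len(uni), len(gset)
    rows = []
    for term, genes in background_annotations.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(gset & term_genes)
        k_eff = k if method == "hypergeometric" else max(k - 1, 0)
        p = float(stats.hypergeom.sf(k_eff - 1, M, K, N))
        fold = (k / N) / (K / M)
        rows.append({"term_id": term, "n_hits": k, "n_background": K,
                     "fold_enrichment": fold, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term_id", "n_hits", "n_background",
                                     "fold_enrichment", "p_raw"])
    if df.empty:
        df["p_fdr"] = []
        return df
    df["p_fdr"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df.sort_values(["p_fdr", "p_raw", "term_id"]).reset_index(drop=True)
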