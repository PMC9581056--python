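"""Quality filters turning raw repeat candidates into the reference catalog.

The chain keeps arrays with motif length 2-6 bp whose total length is at
least the per-period minimum (13/20/23/27/27 bp for periods 2-6) and at most
100 bp (so a short read can span the array), resolves clusters of nearby
arrays by keeping the greatest scores that are at least 20 bp apart, and
removes arrays overlapping transposon/telomere/centromere masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .repeat_finder import RepeatArray

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CatalogFilterConfig:
    min_period: int = 2
    max_period: int = 6
    max_total_length: int = 100
    min_length_by_period: dict[int, int] = field(
        default_factory=lambda: {2: 13, 3: 20, 4: 23, 5: 27, 6: 27})
    min_spacing: int = 20

    def __post_init__(self) -> None:
        keys = set(self.min_length_by_period)
        if keys != set(range(self.min_period, self.max_period + 1)):
            raise ValueError("min_length_by_period must cover every period "
                             f"in [{self.min_period}, {self.max_period}]")
        if any(v >= self.max_total_length
               for v in self.min_length_by_period.values()):
            raise ValueError("max_total_length must exceed all class minima")


@dataclass
class MaskSet:
    """Masked genomic intervals (0-based half-open), e.g. transposons,
    telomeres and centromeres whose low-fidelity sequence is excluded."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "mask") -> "MaskSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        ivs = []
        for _, row in df.iterrows():
            lab = str(row[3]) if df.shape[1] > 3 else label
            ivs.append((str(row[0]), int(row[1]), int(row[2]), lab))
        ivs.sort()
        return cls(ivs)

    def trees(self) -> dict[str, IntervalTree]:
        by_seq: dict[str, IntervalTree] = {}
        for seq, start, end, _ in self.intervals:
            if end > start:
                by_seq.setdefault(seq, IntervalTree()).addi(start, end)
        return by_seq


def apply_class_filters(candidates: Sequence[RepeatArray],
                        config: CatalogFilterConfig | None = None,
                        ) -> list[RepeatArray]:
    """Keep arrays with period in range, length within [class minimum, 100].

    Order preserved; arrays never modified.  Out-of-range periods are
    silently dropped (they are not errors, just not STRs of interest).
    """
    config = config or CatalogFilterConfig()
    kept = []
    for a in candidates:
        if not config.min_period <= a.period <= config.max_period:
            continue
        if a.length > config.max_total_length:
            continue
        if a.length < config.min_length_by_period[a.period]:
            continue
        kept.append(a)
    return kept


def resolve_overlaps(candidates: Sequence[RepeatArray],
                     min_spacing: int = 20) -> list[RepeatArray]:
    """Greedy selection of the greatest scores at least ``min_spacing`` apart.

    Candidates are visited in descending score order (ties: earlier start,
    then longer array) and kept iff the gap to every already kept interval on
    the same sequence is >= ``min_spacing`` bp.  Result sorted by
    (sequence_id, start); all pairwise gaps in the output are >= min_spacing.
    """
    order = sorted(candidates,
                   key=lambda a: (-a.score, a.start, -(a.end - a.start)))
    kept: list[RepeatArray] = []
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for a in order:
        ivs = by_seq.setdefault(a.sequence_id, [])
        if all(a.start - e >= min_spacing or s - a.end >= min_spacing
               for s, e in ivs):
            kept.append(a)
            ivs.append((a.start, a.end))
    kept.sort(key=lambda a: (a.sequence_id, a.start))
    return kept


def mask_exclusions(candidates: Sequence[RepeatArray],
                    masks: MaskSet) -> list[RepeatArray]:
    """Remove every array sharing >= 1 bp with any mask interval."""
    trees = masks.trees()
    cand_seqs = {a.sequence_id for a in candidates}
    for seq in set(trees) - cand_seqs:
        logger.warning("mask intervals on unknown sequence %r ignored", seq)
    return [a for a in candidates
            if not (seq_tree := trees.get(a.sequence_id))
            or not seq_tree.overlap(a.start, a.end)]


def filter_catalog(candidates: Sequence[RepeatArray],
                   config: CatalogFilterConfig | None = None,
                   masks: MaskSet | None = None,
                   ) -> tuple[list[RepeatArray], dict[str, int]]:
    """Full chain: class filters -> overlap resolution -> mask exclusion.

    Returns the kept arrays and an audit of per-rule drop counts satisfying
    ``input == kept + sum(dropped_*)``.
    """
    config = config or CatalogFilterConfig()
    audit = {"input": len(candidates)}

    after_class = apply_class_filters(candidates, config)
    audit["dropped_class"] = len(candidates) - len(after_class)

    after_overlap = resolve_overlaps(after_class, config.min_spacing)
    audit["dropped_overlap"] = len(after_class) - len(after_overlap)

    if masks is not None:
        kept = mask_exclusions(after_overlap, masks)
    else:
        kept = list(after_overlap)
    audit["dropped_masked"] = len(after_overlap) - len(kept)
    audit["kept"] = len(kept)
    logger.info("catalog filter audit: %s", audit)
    return kept, audit
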