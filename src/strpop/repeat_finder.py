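"""Detection and scoring of short tandem repeat arrays in DNA sequence.

A short tandem repeat (STR, microsatellite) is a run of a 2-6 bp motif
repeated in tandem.  This module scans raw sequence for such runs and scores
them under a per-copy convention: each whole motif copy aligned to the
consensus contributes ``match_weight`` points, while mismatched nucleotides
and indels inside copies are penalised per event.  Under the default weights
(MATCH=2, MISMATCH=7, DELTA=7) a perfect seven-copy dimer array scores 14,
the default reporting threshold.

Detection itself targets perfect tandem runs (partial trailing copies
allowed): a position seeds a candidate of period ``p`` when the sequence
equals itself shifted by ``p``, and runs are extended maximally.  Candidate
arrays containing mismatches or indels can still be scored and subjected to
the composition checks through :func:`score_array` and
:func:`check_composition`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment weights and reporting thresholds for the repeat scanner.

    Defaults follow the standard tandem-repeat parameterisation
    MATCH=2, MISMATCH=7, DELTA=7, PM=80, PI=10, MIN SCORE=14.
    """

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    match_probability_pct: int = 80
    indel_probability_pct: int = 10
    min_score: int = 14

    def __post_init__(self) -> None:
        for name in ("match_weight", "mismatch_penalty", "indel_penalty",
                     "min_score"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.match_probability_pct <= 100:
            raise ValueError("match_probability_pct must be in (0, 100]")
        if not 0 <= self.indel_probability_pct < 100:
            raise ValueError("indel_probability_pct must be in [0, 100)")


@dataclass
class RepeatArray:
    """One tandem repeat array on the forward strand.

    Coordinates are 0-based half-open.  ``motif`` is the canonical rotation
    (lexicographically smallest); ``consensus`` is the rotation as it occurs
    at ``start``.
    """

    sequence_id: str
    start: int
    end: int
    motif: str
    period: int
    copy_number: float
    consensus: str
    score: int
    n_mismatch: int = 0
    n_indel: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of a forward-strand motif.

    All rotations of a motif map to one canonical string, so e.g. "GC" and
    "CG" designate the same repeat class.  Reverse complements are *not*
    collapsed.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    """True iff ``motif`` is not a whole-number repetition of a shorter unit."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif[:d] * (p // d) == motif:
            return False
    return True


def score_array(array_sequence: str, consensus: str,
                config: ScoringConfig | None = None) -> tuple[int, int, int]:
    """Score a candidate array against its consensus motif.

    Aligns ``array_sequence`` to the cyclically repeated consensus with a
    small dynamic program (penalty = mismatch_penalty*mm + indel_penalty*ind,
    minimised; ties broken toward more completed copies).  Returns
    ``(score, n_mismatch, n_indel)`` where
    ``score = match_weight * whole_copies - mismatch_penalty * n_mismatch
    - indel_penalty * n_indel``.

    Raises ``ValueError`` if the array is shorter than one consensus copy.
    """
    config = config or ScoringConfig()
    s = array_sequence.upper()
    c = consensus.upper()
    p = len(c)
    if not 2 <= p <= 6:
        raise ValueError(f"consensus length must be 2-6, got {p}")
    if len(s) < p:
        raise ValueError(
            f"array ({len(s)} bp) shorter than one consensus copy ({p} bp)")

    L = len(s)
    INF = (1 << 30, 0, 0, 0)
    # state: (penalty, -wraps, mm, ind) at (chars consumed i, consensus pos j)
    cur = [INF] * p
    cur[0] = (0, 0, 0, 0)

    def relax(row, j, cand):
        if cand < row[j]:
            row[j] = cand

    # deletions within a row can chain; settle them with p passes
    def settle_deletions(row):
        for _ in range(p):
            for j in range(p):
                pen, nw, mm, ind = row[j]
                if pen >= INF[0]:
                    continue
                nj = (j + 1) % p
                wrap = 1 if j == p - 1 else 0
                relax(row, nj,
                      (pen + config.indel_penalty, nw - wrap, mm, ind + 1))

    settle_deletions(cur)
    for i in range(L):
        nxt = [INF] * p
        for j in range(p):
            pen, nw, mm, ind = cur[j]
            if pen >= INF[0]:
                continue
            nj = (j + 1) % p
            wrap = 1 if j == p - 1 else 0
            # consume s[i] against consensus[j]
            if s[i] == c[j]:
                relax(nxt, nj, (pen, nw - wrap, mm, ind))
            else:
                relax(nxt, nj,
                      (pen + config.mismatch_penalty, nw - wrap, mm + 1, ind))
            # insertion: extra character in the array
            relax(nxt, j, (pen + config.indel_penalty, nw, mm, ind + 1))
        settle_deletions(nxt)
        cur = nxt

    pen, neg_wraps, mm, ind = min(cur)
    wraps = -neg_wraps
    score = config.match_weight * wraps \
        - config.mismatch_penalty * mm - config.indel_penalty * ind
    return score, mm, ind


def check_composition(array: RepeatArray,
                      config: ScoringConfig | None = None) -> bool:
    """Composition predicate: enough matching nucleotides, few enough indels.

    With PM (match probability percent) and PI (indel probability percent):
    the number of matching nucleotides ``L - mm - ind`` must be at least
    ``ceil(PM/100 * L)`` and the number of indels at most
    ``floor(PI/100 * L)`` for total length ``L``.  E.g. a 20 nt dimer array
    must match in >= 16 of 20 positions, and a 30 nt trimer array may carry
    at most 3 indels.
    """
    config = config or ScoringConfig()
    L = array.length
    matches = L - array.n_mismatch - array.n_indel
    min_matches = -((-config.match_probability_pct * L) // 100)  # ceil
    max_indels = (config.indel_probability_pct * L) // 100       # floor
    return matches >= min_matches and array.n_indel <= max_indels


def find_candidate_arrays(sequence: str,
                          config: ScoringConfig | None = None,
                          period_range: tuple[int, int] = (2, 6),
                          sequence_id: str = "seq") -> list[RepeatArray]:
    """Scan a sequence for maximal perfect tandem runs of period 2-6.

    A position ``i`` seeds period ``p`` when ``seq[i] == seq[i+p]``; maximal
    runs of seeded positions delimit arrays.  An array is reported when its
    consensus (first ``p`` bases) is primitive, it spans at least two whole
    copies, and its score reaches ``config.min_score``.  Windows containing
    non-ACGT characters never yield arrays.  Deterministic; output sorted by
    (start, period).
    """
    config = config or ScoringConfig()
    lo, hi = period_range
    if not (2 <= lo <= hi <= 6):
        raise ValueError("period_range must lie within [2, 6]")
    seq = sequence.upper()
    n = len(seq)
    out: list[RepeatArray] = []
    if n == 0:
        return out

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) \
        | (arr == ord("T"))

    for p in range(lo, hi + 1):
        if n <= p:
            continue
        match = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        if not match.any():
            continue
        # maximal runs of True in `match`
        m = match.astype(np.int8)
        diffs = np.diff(np.concatenate(([0], m, [0])))
        starts = np.nonzero(diffs == 1)[0]
        ends = np.nonzero(diffs == -1)[0]  # exclusive, in `match` coords
        for a, b in zip(starts, ends):
            s, e = int(a), int(b) + p  # array interval [s, e)
            L = e - s
            if L < 2 * p:
                continue
            consensus = seq[s:s + p]
            if not is_primitive(consensus):
                continue
            whole = L // p
            score = config.match_weight * whole
            if score < config.min_score:
                continue
            out.append(RepeatArray(
                sequence_id=sequence_id, start=s, end=e,
                motif=canonical_motif(consensus), period=p,
                copy_number=L / p, consensus=consensus, score=score,
                n_mismatch=0, n_indel=0))

    out.sort(key=lambda r: (r.start, r.period))
    return out


def scan_fasta(path: str | Path,
               config: ScoringConfig | None = None,
               period_range: tuple[int, int] = (2, 6)) -> list[RepeatArray]:
    """Run the scanner over every record of a FASTA file (gzip allowed)."""
    import gzip
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    arrays: list[RepeatArray] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            arrays.extend(find_candidate_arrays(
                str(rec.seq), config, period_range, sequence_id=rec.id))
    return arrays


def arrays_to_frame(arrays: Iterable[RepeatArray]) -> pd.DataFrame:
    """Tabulate arrays as the catalog TSV schema."""
    rows = [{
        "sequence_id": a.sequence_id, "start": a.start, "end": a.end,
        "motif": a.motif, "period": a.period, "copy_number": a.copy_number,
        "score": a.score,
    } for a in arrays]
    return pd.DataFrame(
        rows, columns=["sequence_id", "start", "end", "motif", "period",
                       "copy_number", "score"])


def write_catalog_tsv(arrays: Sequence[RepeatArray], path: str | Path) -> None:
    arrays_to_frame(arrays).to_csv(path, sep="\t", index=False)


def write_bed(arrays: Sequence[RepeatArray], path: str | Path) -> None:
    """BED6: name = canonical motif, score capped at 1000 per the BED spec."""
    with open(path, "w") as fh:
        for a in arrays:
            fh.write(f"{a.sequence_id}\t{a.start}\t{a.end}\t{a.motif}\t"
                     f"{min(a.score, 1000)}\t+\n")
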