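"""Sequence identity, sequence-space clustering and composition profiles
for CDR loops.

Identity between two loops is the score of a global alignment with unit
match reward and no mismatch or gap penalties, normalised by the longer
length. With those scores the alignment optimum is exactly the longest
common subsequence (LCS), so the numerator is computed by LCS dynamic
programming; only the score is used, so ties among co-optimal alignments
are irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .clustering import greedy_cluster
from .geometry import DistanceMatrix
from .model import CANONICAL_AA, StructureError

logger = logging.getLogger(__name__)

ALPHABET = tuple(CANONICAL_AA)  # 20 canonical letters

#: residues counted as "small" (glycine-like flexibility enablers) by
#: default; always configurable and reported alongside any fraction.
DEFAULT_SMALL_SET = frozenset("GASCPT")


class SequenceError(StructureError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    record_id: str
    loop_kind: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.record_id}: empty sequence")
        bad = set(self.sequence.upper()) - set(CANONICAL_AA) - {"X"}
        if bad:
            raise SequenceError(f"{self.record_id}: non-canonical letters {bad}")


def _lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length by row-rolling dynamic programming."""
    if len(a) < len(b):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        append = cur.append
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                append(prev[j - 1] + 1)
            else:
                x, y = prev[j], cur[j - 1]
                append(x if x >= y else y)
        prev = cur
    return prev[-1]


def sequence_identity(a: str, b: str) -> float:
    """Gap-penalty-free global-alignment identity in [0, 1].

    Number of identically matched aligned pairs (= LCS length) divided by
    the length of the longer sequence.
    """
    if not a or not b:
        raise SequenceError("sequence identity needs two non-empty sequences")
    return _lcs_length(a, b) / max(len(a), len(b))


def sequence_distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Pairwise distance d = 1 - identity over a list of sequence records."""
    if len(records) < 2:
        raise SequenceError("need at least two records")
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - sequence_identity(records[i].sequence, records[j].sequence)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=[r.record_id for r in records], values=values)


def identity_threshold_scan(
    records: Sequence[SequenceRecord],
    thresholds: Iterable[float],
) -> dict[float, int]:
    """Greedy sequence-cluster counts across identity thresholds.

    At identity threshold ``s`` clustering runs on the 1-identity distance
    matrix with radius tau = 1 - s (strict, so members share > s identity
    with their representative).
    """
    thresholds = list(thresholds)
    for s in thresholds:
        if not 0.0 < s <= 1.0:
            raise SequenceError(f"identity threshold must be in (0, 1], got {s}")
    matrix = sequence_distance_matrix(records)
    counts: dict[float, int] = {}
    for s in thresholds:
        counts[s] = greedy_cluster(matrix, 1.0 - s).n_clusters
    return counts


@dataclass
class CompositionProfile:
    """Amino-acid composition of a set of loop sequences.

    Per-position outputs exist only for a single length class; overall
    composition pools every residue. Entropies are Shannon entropies in
    bits of the per-position distributions. ``small_residue_fraction`` is
    the total frequency mass on ``small_set`` (always reported with the
    set used).
    """

    overall_frequencies: pd.Series
    per_position_frequencies: Optional[pd.DataFrame]
    per_position_entropy: Optional[pd.Series]
    small_residue_fraction: float
    small_set: frozenset[str]
    n_sequences: int

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "small_set": sorted(self.small_set),
            "small_residue_fraction": self.small_residue_fraction,
            "overall_frequencies": self.overall_frequencies.to_dict(),
            "per_position_entropy": (
                None
                if self.per_position_entropy is None
                else self.per_position_entropy.tolist()
            ),
        }


def composition_profile(
    records: Sequence[SequenceRecord],
    small_set: Iterable[str] = DEFAULT_SMALL_SET,
    per_position: bool = True,
) -> CompositionProfile:
    """Empirical residue frequencies, positional entropy and small-residue
    mass for a set of loop sequences.

    The per-position frequency matrix (positions x 20 letters) is the
    position-frequency matrix a sequence-logo renderer consumes. Requesting
    per-position outputs for mixed-length input is an error; overall
    composition has no length restriction.
    """
    if not records:
        raise SequenceError("no records")
    small = frozenset(s.upper() for s in small_set)
    sequences = [r.sequence.upper() for r in records]
    lengths = {len(s) for s in sequences}
    if per_position and len(lengths) != 1:
        raise SequenceError(
            f"per-position profile needs one length class, got lengths {sorted(lengths)}"
        )

    counts = pd.Series(0.0, index=list(ALPHABET))
    for seq in sequences:
        for ch in seq:
            if ch in counts.index:
                counts[ch] += 1
    overall = counts / counts.sum()

    pos_freq = pos_entropy = None
    if per_position:
        length = lengths.pop()
        arr = np.zeros((length, len(ALPHABET)))
        index = {ch: k for k, ch in enumerate(ALPHABET)}
        for seq in sequences:
            for pos, ch in enumerate(seq):
                if ch in index:
                    arr[pos, index[ch]] += 1
        arr /= arr.sum(axis=1, keepdims=True)
        pos_freq = pd.DataFrame(arr, columns=list(ALPHABET))
        pos_freq.index.name = "position"
        pos_entropy = pd.Series(
            [_shannon_entropy(arr[p], base=2) for p in range(length)], name="entropy_bits"
        )

    fraction = float(overall[list(small & set(ALPHABET))].sum())
    return CompositionProfile(
        overall_frequencies=overall,
        per_position_frequencies=pos_freq,
        per_position_entropy=pos_entropy,
        small_residue_fraction=fraction,
        small_set=small,
        n_sequences=len(records),
    )
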