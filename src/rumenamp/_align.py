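"""Pairwise global alignment with free end gaps (shared kernel).

Scoring: match +1, mismatch -1, gap -2, terminal (end) gaps free.  The
optimal alignment is made canonical by two fixed tie-break rules so that
results are bit-reproducible and can be mirrored by an independent
implementation:

* per-cell pointer priority: diagonal, then up (gap in b), then left
  (gap in a);
* alignment endpoint: start from the corner cell; scan the last row from
  j=m-1 down to 0, then the last column from i=n-1 down to 0, replacing the
  endpoint only on a strictly greater score.

Distances and identities exclude end-gap columns, so length differences
(e.g. from primer trimming) do not count as divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = ["Alignment", "align", "pairwise_distance", "identity", "best_hits"]

_GAP_OPEN = -2
_MATCH = 1
_MISMATCH = -1


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment plus per-column bookkeeping."""

    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    internal_gaps: int        # gap columns between the end-gap regions
    end_gaps_a_5p: int        # leading columns where a has gaps
    end_gaps_a_3p: int
    end_gaps_b_5p: int
    end_gaps_b_3p: int

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def core_columns(self) -> int:
        """Columns excluding end gaps — the denominator for distance/identity."""
        return (
            self.columns
            - self.end_gaps_a_5p - self.end_gaps_a_3p
            - self.end_gaps_b_5p - self.end_gaps_b_3p
        )

    @property
    def distance(self) -> float:
        """(mismatches + internal gap columns) / core columns."""
        if self.core_columns == 0:
            return 1.0
        return (self.mismatches + self.internal_gaps) / self.core_columns

    @property
    def identity(self) -> float:
        """matches / core columns, in [0, 1]."""
        if self.core_columns == 0:
            return 0.0
        return self.matches / self.core_columns

    @property
    def query_identity(self) -> float:
        """matches / columns excluding only reference-side end gaps.

        Unlike :attr:`identity`, unaligned (clipped) query bases count
        against the denominator, so a short spurious matching core cannot
        score near 100% against an unrelated reference.  Equal to
        :attr:`identity` whenever the query is fully covered.
        """
        denom = self.columns - self.end_gaps_a_5p - self.end_gaps_a_3p
        if denom == 0:
            return 0.0
        return self.matches / denom


@njit(cache=True)
def _nw_fill(a: np.ndarray, b: np.ndarray):  # pragma: no cover - numba
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
            best = H[i - 1, j - 1] + s
            ptr = 0
            up = H[i - 1, j] + _GAP_OPEN
            if up > best:
                best = up
                ptr = 1
            left = H[i, j - 1] + _GAP_OPEN
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return H, P


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align(a: str, b: str) -> Alignment:
    """Canonical end-gap-free global alignment of two DNA strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ea, eb = _encode(a), _encode(b)
    H, P = _nw_fill(ea, eb)
    n, m = len(a), len(b)

    # canonical endpoint: corner, then last row (high j first), then last col
    bi, bj = n, m
    best = H[n, m]
    for j in range(m - 1, -1, -1):
        if H[n, j] > best:
            best = H[n, j]
            bi, bj = n, j
    for i in range(n - 1, -1, -1):
        if H[i, m] > best:
            best = H[i, m]
            bi, bj = i, m

    # trailing end gaps: suffixes beyond the endpoint
    tail_a = n - bi  # unaligned suffix of a -> end gaps in b at 3'
    tail_b = m - bj

    parts_a: list[str] = []
    parts_b: list[str] = []
    matches = mismatches = internal_gaps = 0
    i, j = bi, bj
    while i > 0 and j > 0:
        ptr = P[i, j]
        if ptr == 0:
            parts_a.append(a[i - 1])
            parts_b.append(b[j - 1])
            if a[i - 1] == b[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif ptr == 1:
            parts_a.append(a[i - 1])
            parts_b.append("-")
            internal_gaps += 1
            i -= 1
        else:
            parts_a.append("-")
            parts_b.append(b[j - 1])
            internal_gaps += 1
            j -= 1

    # leading end gaps: unaligned prefixes
    head_a = i  # unaligned prefix of a -> end gaps in b at 5'
    head_b = j

    core_a = "".join(reversed(parts_a))
    core_b = "".join(reversed(parts_b))
    aligned_a = a[:head_a] + "-" * head_b + core_a + "-" * tail_b + a[bi:]
    aligned_b = "-" * head_a + b[:head_b] + core_b + b[bj:] + "-" * tail_a

    return Alignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        matches=matches,
        mismatches=mismatches,
        internal_gaps=internal_gaps,
        end_gaps_a_5p=head_b,
        end_gaps_a_3p=tail_b,
        end_gaps_b_5p=head_a,
        end_gaps_b_3p=tail_a,
    )


def pairwise_distance(a: str, b: str) -> float:
    """Fraction of differing core columns between two sequences, in [0, 1]."""
    return min(align(a, b).distance, 1.0)


def identity(a: str, b: str) -> float:
    """Fraction of matching core columns between two sequences."""
    return align(a, b).identity


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_hits(
    query: str,
    refs: Sequence,
    prefilter: bool = True,
    prefilter_k: int = 12,
) -> list[tuple[object, Alignment]]:
    """Align ``query`` against references, best query-coverage identity first.

    Ties are broken by ``ref_id`` (lexicographic).  With ``prefilter`` on,
    references sharing no ``prefilter_k``-mer with the query are skipped as a
    speed-up; if the filter removes everything, all references are searched so
    the best hit is never lost.
    """
    if not refs:
        raise ValueError("reference set is empty")
    candidates = list(refs)
    if prefilter:
        qkmers = _kmer_set(query, prefilter_k)
        filtered = [r for r in candidates if qkmers & _kmer_set(r.seq, prefilter_k)]
        if filtered:
            candidates = filtered
    scored = [(ref, align(query, ref.seq)) for ref in candidates]
    scored.sort(key=lambda pair: (-pair[1].query_identity, pair[0].ref_id))
    return scored
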