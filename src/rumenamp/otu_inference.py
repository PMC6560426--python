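"""Greedy centroid OTU clustering at a fixed dissimilarity cutoff.

Reads are dereplicated into unique sequences with per-sample multiplicities,
processed in (multiplicity desc, length desc, lexicographic) order, and each
sequence joins the first existing centroid within the cutoff or founds a new
OTU.  The ordering and the alignment tie-breaks (see :mod:`rumenamp._align`)
make clustering fully deterministic.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._align import Alignment, align, identity, pairwise_distance

__all__ = [
    "Alignment",
    "align",
    "pairwise_distance",
    "identity",
    "Otu",
    "OtuTable",
    "cluster_greedy",
]


@dataclass
class Otu:
    otu_id: str
    centroid: str
    counts: dict[str, int] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)  # unique member sequences

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with centroid sequences."""

    sample_ids: tuple[str, ...]
    otus: list[Otu]

    def to_dataframe(self) -> pd.DataFrame:
        """OTUs (rows) x samples (columns) integer counts."""
        data = {
            otu.otu_id: [otu.counts.get(s, 0) for s in self.sample_ids]
            for otu in self.otus
        }
        return pd.DataFrame(data, index=list(self.sample_ids)).T.astype(int)

    def centroids(self) -> dict[str, str]:
        return {otu.otu_id: otu.centroid for otu in self.otus}

    def column_sums(self) -> dict[str, int]:
        return {
            s: sum(otu.counts.get(s, 0) for otu in self.otus)
            for s in self.sample_ids
        }


def cluster_greedy(
    reads: Mapping[str, Sequence[str]],
    cutoff: float = 0.05,
    otu_prefix: str = "OTU_",
    otu_pad: int = 5,
) -> OtuTable:
    """Cluster per-sample read sequences into OTUs at ``cutoff`` dissimilarity.

    Parameters
    ----------
    reads
        Mapping of sample id to that sample's (QC-passed, primer-trimmed)
        read sequences.
    cutoff
        Maximum member-to-centroid distance; centroids end up pairwise
        > cutoff apart.
    otu_prefix, otu_pad
        OTU ids are ``prefix`` + zero-padded founding ordinal.
    """
    sample_ids = tuple(reads.keys())

    # dereplicate: unique sequence -> per-sample multiplicities
    per_sample: dict[str, Counter] = defaultdict(Counter)
    totals: Counter = Counter()
    for sample, seqs in reads.items():
        for seq in seqs:
            if not seq:
                raise ValueError(f"empty read sequence in sample {sample!r}")
            per_sample[seq][sample] += 1
            totals[seq] += 1

    order = sorted(totals, key=lambda s: (-totals[s], -len(s), s))

    otus: list[Otu] = []
    for seq in order:
        placed = None
        for otu in otus:
            if pairwise_distance(seq, otu.centroid) <= cutoff:
                placed = otu
                break
        if placed is None:
            placed = Otu(otu_id="", centroid=seq)
            otus.append(placed)
        placed.members.append(seq)
        for sample, n in per_sample[seq].items():
            placed.counts[sample] = placed.counts.get(sample, 0) + n

    for ordinal, otu in enumerate(otus, start=1):
        otu.otu_id = f"{otu_prefix}{ordinal:0{otu_pad}d}"
    return OtuTable(sample_ids=sample_ids, otus=otus)
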