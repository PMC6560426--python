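"""Naive-Bayes k-mer taxonomy with bootstrap confidence, plus best-hit identity.

Training pools references by full lineage (domain..genus) and stores, per
genus, the number of references containing each k-mer word.  A query is
assigned by argmax of summed log word probabilities
``P(w|genus) = (n_w + 0.5) / (N_genus + 1)``; confidence per rank is the
fraction of 100 bootstrap subsamples (1/8 of the query's unique words, with
replacement) agreeing with the full-word-set assignment at that rank.  Ranks
below the confidence threshold are reported as ``unclassified <parent>``.

The closest-relative identity percentage is computed separately by exhaustive
alignment against the reference set; species-level naming always comes from
the best hit, never from the classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._align import best_hits
from .config_and_io import RANKS, ReferenceRecord

__all__ = [
    "KmerModel",
    "TaxonomyAssignment",
    "train_classifier",
    "classify",
    "best_hit_identity",
    "assign_taxonomy",
]


@dataclass(frozen=True)
class TaxonomyAssignment:
    otu_id: str
    lineage: tuple[str, ...]            # reported, with "unclassified" fills
    raw_lineage: tuple[str, ...]        # full-word-set argmax lineage
    bootstrap_conf: tuple[float, ...]   # per rank, domain..genus
    best_hit_id: str
    best_hit_identity: int              # integer percent

    def __post_init__(self) -> None:
        conf = self.bootstrap_conf
        if any(conf[i] < conf[i + 1] - 1e-12 for i in range(len(conf) - 1)):
            raise ValueError("bootstrap confidences must be non-increasing")
        if not (0 <= self.best_hit_identity <= 100):
            raise ValueError("identity must be in [0, 100]")


class KmerModel:
    """Per-genus k-mer word document frequencies."""

    def __init__(self, k: int, genera: list[tuple[str, ...]],
                 n_refs: list[int], word_counts: dict[str, list[int]]):
        self.k = k
        self.genera = genera
        self.n_refs = np.asarray(n_refs, dtype=float)
        self.word_counts = word_counts
        # log prior for a word unseen in a genus: log(0.5 / (N + 1))
        self._log_unseen = np.log(0.5 / (self.n_refs + 1.0))
        self._log_denom = np.log(self.n_refs + 1.0)

    def word_prob(self, word: str, genus: tuple[str, ...]) -> float:
        """P(word | genus) = (n_w + 0.5) / (N_genus + 1)."""
        gi = self.genera.index(genus)
        n_w = self.word_counts.get(word, [0] * len(self.genera))[gi]
        return (n_w + 0.5) / (self.n_refs[gi] + 1.0)

    def log_prob_matrix(self, words: Sequence[str]) -> np.ndarray:
        """(n_words x n_genera) matrix of log P(w|genus)."""
        out = np.tile(self._log_unseen, (len(words), 1))
        for i, w in enumerate(words):
            counts = self.word_counts.get(w)
            if counts is not None:
                out[i] = np.log(np.asarray(counts, dtype=float) + 0.5) - self._log_denom
        return out

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "genera": [list(g) for g in self.genera],
            "n_refs": [int(n) for n in self.n_refs],
            "word_counts": self.word_counts,
        })

    @classmethod
    def from_json(cls, payload: str) -> "KmerModel":
        data = json.loads(payload)
        return cls(
            k=data["k"],
            genera=[tuple(g) for g in data["genera"]],
            n_refs=data["n_refs"],
            word_counts={w: list(c) for w, c in data["word_counts"].items()},
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KmerModel)
            and self.k == other.k
            and self.genera == other.genera
            and list(self.n_refs) == list(other.n_refs)
            and self.word_counts == other.word_counts
        )


def _words(seq: str, k: int) -> list[str]:
    return sorted({seq[i : i + k] for i in range(len(seq) - k + 1)})


def train_classifier(refs: Sequence[ReferenceRecord], k: int = 8) -> KmerModel:
    """Build the per-genus word model from reference sequences."""
    if not (4 <= k <= 12):
        raise ValueError("k must be between 4 and 12")
    genera = sorted({r.lineage for r in refs})
    if len(genera) < 2:
        raise ValueError("training requires at least 2 distinct genera")
    index = {g: i for i, g in enumerate(genera)}
    n_refs = [0] * len(genera)
    word_counts: dict[str, list[int]] = {}
    for ref in refs:
        gi = index[ref.lineage]
        n_refs[gi] += 1
        for word in _words(ref.seq, k):
            if word not in word_counts:
                word_counts[word] = [0] * len(genera)
            word_counts[word][gi] += 1
    return KmerModel(k=k, genera=genera, n_refs=n_refs, word_counts=word_counts)


def classify(
    centroid: str,
    model: KmerModel,
    n_bootstrap: int = 100,
    conf_threshold: float = 0.8,
    seed: int = 0,
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[float, ...]]:
    """Classify one sequence; returns (reported_lineage, raw_lineage, conf).

    The reported lineage substitutes ``unclassified <parent>`` at every rank
    whose bootstrap confidence falls below ``conf_threshold``.
    """
    if len(centroid) < model.k:
        raise ValueError("sequence shorter than classifier word size")
    words = _words(centroid, model.k)
    logp = model.log_prob_matrix(words)            # (W, G)
    full_gi = int(np.argmax(logp.sum(axis=0)))
    raw_lineage = model.genera[full_gi]

    rng = np.random.default_rng(seed)
    n_words = len(words)
    n_sub = math.ceil(n_words / 8)
    idx = rng.integers(0, n_words, size=(n_bootstrap, n_sub))
    boot_scores = logp[idx].sum(axis=1)            # (B, G)
    winners = np.argmax(boot_scores, axis=1)

    n_ranks = len(raw_lineage)
    conf = []
    for r in range(n_ranks):
        prefix = raw_lineage[: r + 1]
        agree = sum(1 for w in winners if model.genera[w][: r + 1] == prefix)
        conf.append(agree / n_bootstrap)

    reported = list(raw_lineage)
    parent = None
    for r in range(n_ranks):
        if conf[r] >= conf_threshold:
            parent = raw_lineage[r]
        else:
            reported[r] = f"unclassified {parent}" if parent else "unclassified"
    return tuple(reported), raw_lineage, tuple(conf)


def best_hit_identity(
    centroid: str, refs: Sequence[ReferenceRecord], prefilter: bool = True
) -> tuple[str, int]:
    """Closest reference and its identity as an integer percent."""
    ref, aln = best_hits(centroid, refs, prefilter=prefilter)[0]
    return ref.ref_id, int(round(aln.query_identity * 100))


def assign_taxonomy(
    centroids: Mapping[str, str],
    refs: Sequence[ReferenceRecord],
    k: int = 8,
    n_bootstrap: int = 100,
    conf_threshold: float = 0.8,
    seed: int = 0,
    model: KmerModel | None = None,
) -> dict[str, TaxonomyAssignment]:
    """Classify every OTU centroid and attach its best-hit identity."""
    if model is None:
        model = train_classifier(refs, k=k)
    assignments = {}
    for otu_id in sorted(centroids):
        reported, raw, conf = classify(
            centroids[otu_id], model, n_bootstrap, conf_threshold, seed
        )
        hit_id, hit_pct = best_hit_identity(centroids[otu_id], refs)
        assignments[otu_id] = TaxonomyAssignment(
            otu_id=otu_id,
            lineage=reported,
            raw_lineage=raw,
            bootstrap_conf=conf,
            best_hit_id=hit_id,
            best_hit_identity=hit_pct,
        )
    return assignments
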