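"""Read retention screens: intact primers, length window, quality threshold.

A read is retained iff (1) the forward primer matches exactly (IUPAC-aware)
at the 5' end and the reverse complement of the reverse primer matches at the
3' end, (2) its full length (primers included) lies within the inclusive
window, and (3) at most ``max_lowq_frac`` of its bases fall below
``lowq_phred``.  Failures are attributed to the first failing rule in the
order primer -> length -> quality.  Primers are trimmed from retained reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .config_and_io import PipelineConfig, QualityRead

__all__ = [
    "FWD_PRIMER_27F",
    "REV_PRIMER_519R",
    "QcReport",
    "has_intact_primers",
    "passes_quality",
    "screen_reads",
]

FWD_PRIMER_27F = "AGAGTTTGATCMTGGCTCAG"
REV_PRIMER_519R = "GWATTACCGCGGCKGCTG"

_IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[base] for base in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in sequence: {exc}") from exc


def _iupac_match(pattern: str, window: str) -> bool:
    """Exact IUPAC match: every code matched by the base set it denotes."""
    if len(pattern) != len(window):
        return False
    for p, b in zip(pattern, window):
        allowed = _IUPAC.get(p)
        if allowed is None:
            raise ValueError(f"non-IUPAC character in primer: {p!r}")
        if b not in allowed:
            return False
    return True


def has_intact_primers(read: QualityRead, fwd: str, rev: str) -> bool:
    """True iff ``fwd`` matches at position 0 and revcomp(``rev``) at the 3' end.

    "Intact" means an exact IUPAC-aware match; no mismatches are tolerated.
    """
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    fwd = fwd.upper()
    rev_rc = reverse_complement(rev)
    seq = read.seq
    if len(seq) < len(fwd) + len(rev_rc):
        return False
    return _iupac_match(fwd, seq[: len(fwd)]) and _iupac_match(rev_rc, seq[-len(rev_rc):])


def passes_quality(
    read: QualityRead, lowq_phred: int = 15, max_lowq_frac: float = 0.01
) -> bool:
    """True iff the fraction of bases below ``lowq_phred`` is <= the cap.

    The cap is inclusive: exactly 1% low-quality bases still passes.
    """
    if len(read) == 0:
        raise ValueError("empty read")
    n_low = sum(1 for q in read.quals if q < lowq_phred)
    return n_low / len(read) <= max_lowq_frac


@dataclass
class QcReport:
    """Per-sample screening tally; retained + failures == input_reads."""

    input_reads: int = 0
    fail_primer: int = 0
    fail_length: int = 0
    fail_quality: int = 0
    retained: int = 0

    def check(self) -> None:
        total = self.retained + self.fail_primer + self.fail_length + self.fail_quality
        if total != self.input_reads:
            raise AssertionError("QcReport accounting identity violated")


def screen_reads(
    reads: Iterable[QualityRead],
    fwd: str = FWD_PRIMER_27F,
    rev: str = REV_PRIMER_519R,
    cfg: PipelineConfig | None = None,
) -> tuple[list[QualityRead], QcReport]:
    """Apply the three retention rules; trim primers from retained reads.

    The length window is applied to the read as received, primers included,
    with inclusive bounds.  Retained reads are emitted with both primer
    regions removed (sequence and qualities).
    """
    cfg = cfg or PipelineConfig()
    fwd = fwd.upper()
    n_fwd, n_rev = len(fwd), len(rev)
    report = QcReport()
    kept: list[QualityRead] = []
    for read in reads:
        report.input_reads += 1
        if not has_intact_primers(read, fwd, rev):
            report.fail_primer += 1
            continue
        if not (cfg.len_min <= len(read) <= cfg.len_max):
            report.fail_length += 1
            continue
        if not passes_quality(read, cfg.lowq_phred, cfg.max_lowq_frac):
            report.fail_quality += 1
            continue
        report.retained += 1
        kept.append(
            QualityRead(
                read_id=read.read_id,
                seq=read.seq[n_fwd : len(read) - n_rev],
                quals=read.quals[n_fwd : len(read) - n_rev],
            )
        )
    report.check()
    return kept, report
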