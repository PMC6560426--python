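"""Post-clustering OTU validity screens.

Three screens run in fixed order — chimera, end integrity, single-read —
and an OTU is removed (with its reads) on the first failure.  The chimera
screen is a reference-based split-alignment test: a centroid is flagged when
some breakpoint splits it into two segments that each match different
references at >= 98% identity while no single reference explains the whole
centroid at > 92% identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._align import align, best_hits
from .config_and_io import PipelineConfig, ReferenceRecord
from .otu_inference import Otu, OtuTable

__all__ = [
    "ScreenVerdict",
    "chimera_screen",
    "end_integrity_screen",
    "singleread_screen",
    "apply_screens",
]

PASS = "pass"
FAIL_CHIMERA = "fail_chimera"
FAIL_END_INTEGRITY = "fail_end_integrity"
FAIL_SINGLEREAD = "fail_singleread"


@dataclass
class ScreenVerdict:
    otu_id: str
    verdict: str
    evidence: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.verdict == PASS


def chimera_screen(
    centroid: str,
    refs: Sequence[ReferenceRecord],
    window: int = 40,
    segment_identity: float = 0.98,
    whole_identity_max: float = 0.92,
    prefilter: bool = True,
) -> ScreenVerdict:
    """Split-alignment chimera test against the reference set.

    Candidate breakpoints lie on a ``window``-step grid.  For grid point g
    the tested segments are ``centroid[:g]`` and ``centroid[g + window:]``;
    the one-window guard band between them absorbs the junction, so a true
    breakpoint anywhere inside [g, g + window] leaves both segments
    pure-parent.  Centroids shorter than two windows are not evaluable and
    pass with a warning.
    """
    if len(refs) < 2:
        raise ValueError("chimera screen needs at least 2 references")
    verdict = ScreenVerdict(otu_id="", verdict=PASS)
    if len(centroid) < 2 * window:
        verdict.warnings.append("centroid shorter than two windows; chimera screen skipped")
        return verdict

    whole = best_hits(centroid, refs, prefilter=prefilter)
    best_ref, best_aln = whole[0]
    verdict.evidence["best_hit_id"] = best_ref.ref_id
    verdict.evidence["best_hit_identity"] = best_aln.query_identity
    if best_aln.query_identity > whole_identity_max:
        return verdict  # whole-length match explains the sequence

    for breakpoint in range(window, len(centroid) - 2 * window + 1, window):
        prefix, suffix = centroid[:breakpoint], centroid[breakpoint + window:]
        pre = [(r, align(prefix, r.seq).query_identity) for r in refs]
        suf = [(r, align(suffix, r.seq).query_identity) for r in refs]
        pre_ok = {r.ref_id: ident for r, ident in pre if ident >= segment_identity}
        suf_ok = {r.ref_id: ident for r, ident in suf if ident >= segment_identity}
        pairs = [
            (p, q) for p in pre_ok for q in suf_ok if p != q
        ]
        if pairs:
            parent_a = max(pre_ok, key=lambda rid: (pre_ok[rid], rid))
            parent_b = max(
                (q for q in suf_ok if q != parent_a),
                key=lambda rid: (suf_ok[rid], rid),
                default=None,
            )
            if parent_b is None:  # best prefix parent is the only suffix parent
                parent_a = max(
                    (p for p in pre_ok if p != max(suf_ok, key=suf_ok.get)),
                    key=lambda rid: (pre_ok[rid], rid),
                )
                parent_b = max(suf_ok, key=lambda rid: (suf_ok[rid], rid))
            verdict.verdict = FAIL_CHIMERA
            verdict.evidence["parents"] = (parent_a, parent_b)
            verdict.evidence["breakpoint"] = breakpoint
            return verdict
    return verdict


def end_integrity_screen(
    centroid: str,
    refs: Sequence[ReferenceRecord],
    end_missing_max: int = 5,
    prefilter: bool = True,
) -> ScreenVerdict:
    """Fail centroids whose best equal-or-longer hit leaves > ``end_missing_max``
    unaligned centroid bases at the 5' or 3' end."""
    if not refs:
        raise ValueError("end-integrity screen needs references")
    verdict = ScreenVerdict(otu_id="", verdict=PASS)
    eligible = [r for r in refs if len(r.seq) >= len(centroid)]
    if not eligible:
        verdict.warnings.append(
            "no reference of equal or longer length; end-integrity screen skipped"
        )
        return verdict
    best_ref, aln = best_hits(centroid, eligible, prefilter=prefilter)[0]
    overhang_5p = aln.end_gaps_b_5p  # leading centroid bases unmatched by the ref
    overhang_3p = aln.end_gaps_b_3p
    verdict.evidence.update(
        best_hit_id=best_ref.ref_id,
        best_hit_identity=aln.query_identity,
        overhang_5p=overhang_5p,
        overhang_3p=overhang_3p,
    )
    if overhang_5p > end_missing_max or overhang_3p > end_missing_max:
        verdict.verdict = FAIL_END_INTEGRITY
    return verdict


def singleread_screen(
    otu: Otu,
    refs: Sequence[ReferenceRecord],
    max_dissim: float = 0.01,
    prefilter: bool = True,
) -> ScreenVerdict:
    """Extra screen for single-read OTUs: the best hit must span the whole
    centroid with at most ``max_dissim`` dissimilar positions (inclusive)."""
    verdict = ScreenVerdict(otu_id=otu.otu_id, verdict=PASS)
    if otu.total != 1:
        return verdict
    best_ref, aln = best_hits(otu.centroid, refs, prefilter=prefilter)[0]
    full_span = aln.end_gaps_b_5p == 0 and aln.end_gaps_b_3p == 0
    dissim = (aln.mismatches + aln.internal_gaps) / len(otu.centroid)
    verdict.evidence.update(
        best_hit_id=best_ref.ref_id,
        best_hit_identity=aln.query_identity,
        full_span=full_span,
        dissimilarity=dissim,
    )
    if not (full_span and dissim <= max_dissim):
        verdict.verdict = FAIL_SINGLEREAD
    return verdict


def apply_screens(
    table: OtuTable,
    refs: Sequence[ReferenceRecord],
    cfg: PipelineConfig | None = None,
    prefilter: bool = True,
) -> tuple[OtuTable, list[ScreenVerdict]]:
    """Run all screens in order over every OTU; drop failures with their reads."""
    cfg = cfg or PipelineConfig()
    verdicts: list[ScreenVerdict] = []
    kept: list[Otu] = []
    for otu in table.otus:
        verdict = chimera_screen(otu.centroid, refs, prefilter=prefilter)
        if verdict.passed:
            v2 = end_integrity_screen(
                otu.centroid, refs, cfg.end_missing_max, prefilter=prefilter
            )
            verdict.evidence.update(v2.evidence)
            verdict.warnings.extend(v2.warnings)
            verdict.verdict = v2.verdict
        if verdict.passed:
            v3 = singleread_screen(
                otu, refs, cfg.singleread_max_dissim, prefilter=prefilter
            )
            verdict.evidence.update(v3.evidence)
            verdict.verdict = v3.verdict
        verdict.otu_id = otu.otu_id
        verdicts.append(verdict)
        if verdict.passed:
            kept.append(otu)
    return OtuTable(sample_ids=table.sample_ids, otus=kept), verdicts
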