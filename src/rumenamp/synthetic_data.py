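"""Ground-truthed synthetic studies: reference DB, communities, reads, metadata.

The generator emulates a two-group amplicon study: log-normal community
abundances with planted treatment-enriched taxa, primer-flanked reads with
substitution errors tied to quality strings, and three artifact classes
(two-parent chimeras, end-damaged reads, short off-target reads) at
configurable fractions.  Reference sequences cover the region between the
primer binding sites only; primers are attached when reads are emitted.

All randomness flows from one counter-based Philox generator keyed by the
design seed, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._align import pairwise_distance
from .config_and_io import QualityRead, ReferenceRecord, write_fastq, write_reference_fasta
from .read_qc import FWD_PRIMER_27F, REV_PRIMER_519R, reverse_complement

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "ReferenceGenerationError",
    "simulate_reference_db",
    "simulate_study",
    "realized_primers",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_PHYLA = ["Bacteroidota", "Bacillota", "Pseudomonadota", "Actinomycetota"]


class ReferenceGenerationError(RuntimeError):
    """Raised when the divergence constraints cannot be satisfied."""


def realized_primers() -> tuple[str, str]:
    """One concrete (IUPAC-compatible) realization of the 27F/519R primers."""
    resolve = {"M": "A", "W": "A", "K": "G", "R": "A", "Y": "C", "S": "C"}
    fwd = "".join(resolve.get(b, b) for b in FWD_PRIMER_27F)
    rev = "".join(resolve.get(b, b) for b in REV_PRIMER_519R)
    return fwd, rev


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute ``n_subs`` distinct positions, always changing the base."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    positions = rng.choice(len(arr), size=n_subs, replace=False)
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def simulate_reference_db(
    n_taxa: int,
    seed: int = 0,
    species_per_genus: int = 2,
    seq_len_range: tuple[int, int] = (420, 560),
    between_genus_min: float = 0.10,
    within_genus_range: tuple[float, float] = (0.06, 0.09),
    max_tries: int = 20,
) -> list[ReferenceRecord]:
    """Generate ``n_taxa`` reference records satisfying divergence constraints.

    Sequences are the region between the primer sites (420-560 nt by
    default); pairwise dissimilarity is >= ``between_genus_min`` across
    genera and inside ``within_genus_range`` within a genus, verified with
    the pipeline's own aligner.  Lineages span at least two phyla.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    if species_per_genus < 1:
        raise ValueError("species_per_genus must be >= 1")
    rng = _rng(seed)
    lo, hi = seq_len_range
    if lo < 50:
        raise ValueError("sequences too short for amplicon simulation")
    # at least two genera so the DB always spans two phyla and contains a
    # >= 10%-divergent pair; taxa are distributed over genera as evenly as
    # the species_per_genus cap allows
    n_genera = max(2, math.ceil(n_taxa / species_per_genus))
    base_count, extra = divmod(n_taxa, n_genera)
    genus_sizes = [base_count + (g < extra) for g in range(n_genera)]
    target_within = sum(within_genus_range) / 2.0

    for _ in range(max_tries):
        refs: list[ReferenceRecord] = []
        seqs: list[tuple[int, str]] = []  # (genus index, seq)
        taxon = 0
        for g in range(n_genera):
            length = int(rng.integers(lo, hi + 1))
            base = _random_seq(rng, length)
            phylum = _PHYLA[g % min(len(_PHYLA), max(2, n_genera))]
            lineage = (
                "Bacteria", phylum, f"Class_{g % 2 + 1:02d}", f"Order_{g:02d}",
                f"Family_{g:02d}", f"Genus_{g:02d}",
            )
            for s in range(genus_sizes[g]):
                seq = base if s == 0 else _mutate(
                    rng, base, max(1, int(round(target_within * length)))
                )
                refs.append(ReferenceRecord(
                    ref_id=f"REF_{taxon:03d}", seq=seq, lineage=lineage,
                    species=f"Genus_{g:02d} species_{s}",
                ))
                seqs.append((g, seq))
                taxon += 1
        ok = True
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                d = pairwise_distance(refs[i].seq, refs[j].seq)
                if seqs[i][0] == seqs[j][0]:
                    if not (within_genus_range[0] <= d <= within_genus_range[1]):
                        ok = False
                elif d < between_genus_min:
                    ok = False
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return refs
    raise ReferenceGenerationError(
        f"could not satisfy divergence constraints for n_taxa={n_taxa} "
        f"at lengths {seq_len_range} in {max_tries} tries"
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic two-group study."""

    n_per_group: int = 10
    n_taxa: int = 12
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    enriched_taxa: tuple[tuple[str, str, float], ...] = ()  # (ref_id, group, fold)
    reads_per_sample: int | tuple[int, int] = 2000
    error_rate: float = 0.002
    chimera_frac: float = 0.0
    truncated_frac: float = 0.0
    offtarget_short_frac: float = 0.0
    lowq_prob_max: float = 0.02  # per-read low-quality base probability cap
    group_labels: tuple[str, str] = ("EO", "Control")
    metadata_means: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.chimera_frac, self.truncated_frac, self.offtarget_short_frac)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("artifact fractions must lie in [0, 1]")
        if sum(fracs) >= 1.0:
            raise ValueError("artifact fractions must sum to < 1")
        if any(fold <= 0 for _, _, fold in self.enriched_taxa):
            raise ValueError("fold changes must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")


#: group -> column -> (mean, sd) defaults for the metadata TSV.
_DEFAULT_METADATA_MEANS = {
    "EO": {
        "acetate_mM": (49.9, 9.5), "propionate_mM": (40.3, 9.6),
        "butyrate_mM": (6.1, 2.0), "isobutyrate_mM": (0.42, 0.12),
        "valerate_mM": (1.5, 0.5), "isovalerate_mM": (0.52, 0.15),
        "body_length": (117.0, 4.0), "heart_girth": (93.5, 3.0),
        "hip_width": (23.2, 1.0),
    },
    "Control": {
        "acetate_mM": (42.9, 9.8), "propionate_mM": (31.1, 9.9),
        "butyrate_mM": (5.6, 2.0), "isobutyrate_mM": (0.46, 0.12),
        "valerate_mM": (1.2, 0.5), "isovalerate_mM": (0.50, 0.15),
        "body_length": (115.0, 4.0), "heart_girth": (92.0, 3.0),
        "hip_width": (22.8, 1.0),
    },
}


@dataclass
class GroundTruth:
    """Per-sample truth emitted alongside the reads."""

    true_counts: pd.DataFrame            # taxa x samples, clean reads only
    read_labels: dict[str, list[tuple]]  # sample -> one tuple per read
    metadata_means: dict                 # covariate effects used
    warnings: list[str] = field(default_factory=list)

    def label_counts(self, sample: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.read_labels[sample]:
            out[label[0]] = out.get(label[0], 0) + 1
        return out

    def relative_abundance(self) -> pd.DataFrame:
        """Clean-read taxon fractions per sample (columns sum to 1)."""
        return self.true_counts.div(self.true_counts.sum(axis=0), axis=1)


def _quality_read(
    rng: np.random.Generator,
    read_id: str,
    seq: str,
    error_rate: float,
    lowq_prob_max: float,
) -> QualityRead:
    """Apply substitution errors and draw a quality string.

    Each read gets its own low-quality base probability, uniform on
    [0, lowq_prob_max], so realized sub-Q15 fractions bracket the 1% screen.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if error_rate > 0:
        hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
        for pos in hits:
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = choices[rng.integers(0, 3)]
    lowq_prob = rng.uniform(0.0, lowq_prob_max)
    low_mask = rng.random(arr.size) < lowq_prob
    quals = np.where(
        low_mask,
        rng.integers(2, 15, size=arr.size),
        rng.integers(30, 41, size=arr.size),
    )
    return QualityRead(
        read_id=read_id,
        seq=arr.tobytes().decode("ascii"),
        quals=tuple(int(q) for q in quals),
    )


def simulate_study(
    design: SimulationDesign,
    refs: Sequence[ReferenceRecord],
    outdir: str | None = None,
) -> tuple[dict[str, list[QualityRead]], pd.DataFrame, GroundTruth]:
    """Emit reads, metadata and ground truth for a two-group study.

    Returns in-memory structures; when ``outdir`` is given also writes one
    FASTQ per sample, the reference FASTA/taxonomy, ``metadata.tsv`` and a
    ``manifest.json`` recording the design and any warnings.
    """
    ref_ids = [r.ref_id for r in refs]
    by_id = {r.ref_id: r for r in refs}
    for taxon, group, _ in design.enriched_taxa:
        if taxon not in by_id:
            raise KeyError(f"enriched taxon {taxon!r} not in reference set")
        if group not in design.group_labels:
            raise KeyError(f"enriched group {group!r} not a design group")

    rng = _rng(design.seed)
    fwd, rev = realized_primers()
    rev_site = reverse_complement(rev)
    meta_means = design.metadata_means or _DEFAULT_METADATA_MEANS
    warnings: list[str] = []

    # base community: one log-normal abundance per taxon
    base_abund = rng.lognormal(design.lognormal_mu, design.lognormal_sigma,
                               size=len(ref_ids))

    genus_of = {r.ref_id: r.lineage for r in refs}
    samples = [
        f"{group}{i + 1:02d}"
        for group in design.group_labels
        for i in range(design.n_per_group)
    ]
    group_of = {
        s: (design.group_labels[0] if s.startswith(design.group_labels[0])
            else design.group_labels[1])
        for s in samples
    }

    reads: dict[str, list[QualityRead]] = {}
    labels: dict[str, list[tuple]] = {}
    counts = pd.DataFrame(0, index=ref_ids, columns=samples, dtype=int)
    clean_frac = 1.0 - design.chimera_frac - design.truncated_frac - design.offtarget_short_frac

    for sample in samples:
        group = group_of[sample]
        weights = base_abund.copy()
        for taxon, egroup, fold in design.enriched_taxa:
            if egroup == group:
                weights[ref_ids.index(taxon)] *= fold
        probs = weights / weights.sum()

        if isinstance(design.reads_per_sample, tuple):
            n_reads = int(rng.integers(design.reads_per_sample[0],
                                       design.reads_per_sample[1] + 1))
        else:
            n_reads = int(design.reads_per_sample)

        class_counts = rng.multinomial(
            n_reads,
            [design.chimera_frac, design.truncated_frac,
             design.offtarget_short_frac, clean_frac],
        )
        n_chim, n_trunc, n_off, n_clean = (int(x) for x in class_counts)

        sample_reads: list[QualityRead] = []
        sample_labels: list[tuple] = []
        ridx = 0

        taxon_counts = rng.multinomial(n_clean, probs)
        counts[sample] = taxon_counts
        for taxon_i, n_t in enumerate(taxon_counts):
            interior = by_id[ref_ids[taxon_i]].seq
            for _ in range(int(n_t)):
                read = _quality_read(
                    rng, f"{sample}_r{ridx:06d}", fwd + interior + rev_site,
                    design.error_rate, design.lowq_prob_max,
                )
                sample_reads.append(read)
                sample_labels.append(("clean", ref_ids[taxon_i]))
                ridx += 1

        for _ in range(n_chim):
            # prefer cross-genus parents so both are detectable
            for _try in range(20):
                pa, pb = rng.choice(len(ref_ids), size=2, replace=False, p=probs)
                if genus_of[ref_ids[pa]] != genus_of[ref_ids[pb]]:
                    break
            sa, sb = by_id[ref_ids[pa]].seq, by_id[ref_ids[pb]].seq
            m = min(len(sa), len(sb))
            breakpoint = int(rng.integers(int(0.25 * m), int(0.75 * m) + 1))
            mosaic = sa[:breakpoint] + sb[breakpoint:]
            read = _quality_read(
                rng, f"{sample}_r{ridx:06d}", fwd + mosaic + rev_site,
                design.error_rate, design.lowq_prob_max,
            )
            sample_reads.append(read)
            sample_labels.append(("chimera", ref_ids[pa], ref_ids[pb], breakpoint))
            ridx += 1

        for _ in range(n_trunc):
            taxon_i = int(rng.choice(len(ref_ids), p=probs))
            interior = by_id[ref_ids[taxon_i]].seq
            missing = int(rng.integers(6, 21))
            junk = _random_seq(rng, missing)
            if rng.random() < 0.5:  # 3' biology lost, novel bases lead
                damaged = junk + interior[: len(interior) - missing]
            else:                   # 5' biology lost, novel bases trail
                damaged = interior[missing:] + junk
            read = _quality_read(
                rng, f"{sample}_r{ridx:06d}", fwd + damaged + rev_site,
                design.error_rate, design.lowq_prob_max,
            )
            sample_reads.append(read)
            sample_labels.append(("truncated", ref_ids[taxon_i], missing))
            ridx += 1

        for _ in range(n_off):
            interior_len = int(rng.integers(80, 362 - len(fwd) - len(rev_site)))
            read = _quality_read(
                rng, f"{sample}_r{ridx:06d}",
                fwd + _random_seq(rng, interior_len) + rev_site,
                design.error_rate, design.lowq_prob_max,
            )
            sample_reads.append(read)
            sample_labels.append(("offtarget", None))
            ridx += 1

        reads[sample] = sample_reads
        labels[sample] = sample_labels
        if n_reads < 1800:
            warnings.append(
                f"sample {sample}: {n_reads} reads is below the default "
                "rarefaction depth of 1800"
            )

    # metadata
    rows = []
    for sample in samples:
        group = group_of[sample]
        row = {"sample_id": sample, "treatment": group}
        scfa_total = 0.0
        for col, (mean, sd) in meta_means[group].items():
            value = float(rng.normal(mean, sd))
            value = max(value, 0.01) if col.endswith("_mM") else value
            row[col] = round(value, 3)
            if col.endswith("_mM"):
                scfa_total += row[col]
        row["total_scfa_mM"] = round(scfa_total, 3)
        rows.append(row)
    metadata = pd.DataFrame(rows).set_index("sample_id")
    ordered = ["treatment"] + [c for c in (
        "acetate_mM", "propionate_mM", "butyrate_mM", "isobutyrate_mM",
        "valerate_mM", "isovalerate_mM", "total_scfa_mM",
        "body_length", "heart_girth", "hip_width",
    ) if c in metadata.columns]
    metadata = metadata[ordered]

    truth = GroundTruth(
        true_counts=counts, read_labels=labels,
        metadata_means=meta_means, warnings=warnings,
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for sample in samples:
            write_fastq(reads[sample], os.path.join(outdir, f"{sample}.fastq"))
        write_reference_fasta(
            refs,
            os.path.join(outdir, "refs.fasta"),
            os.path.join(outdir, "refs.tax"),
        )
        metadata.reset_index().to_csv(
            os.path.join(outdir, "metadata.tsv"), sep="\t", index=False
        )
        manifest = {
            "design": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(design).items()
                if k != "metadata_means"
            },
            "samples": samples,
            "warnings": warnings,
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return reads, metadata, truth
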