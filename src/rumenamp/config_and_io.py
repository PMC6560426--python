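"""Pipeline configuration and readers/writers for the standard formats.

Every numeric threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`; downstream modules take thresholds from a config
instance (or accept them as keyword arguments defaulting to the same values).

File formats handled here: FASTQ (Phred+33 only), FASTA with a companion
taxonomy TSV (``id<TAB>semicolon-separated lineage``), sample-metadata TSV,
and the OTU count / relative-abundance / taxonomy output tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PipelineConfig",
    "QualityRead",
    "ReferenceRecord",
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "read_reference_fasta",
    "write_reference_fasta",
    "read_metadata",
    "write_tables",
    "read_count_table",
]

#: Canonical rank names, coarse to fine, for reference lineages.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; message names the record index."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds, defaulting to the study's values."""

    cluster_cutoff: float = 0.05      # OTU dissimilarity cutoff
    len_min: int = 400                # read length window, inclusive, nt
    len_max: int = 580
    max_lowq_frac: float = 0.01       # max fraction of bases below lowq_phred
    lowq_phred: int = 15
    rarefy_depth: int = 1800
    main_otu_threshold: float = 0.01  # mean relative abundance, per group
    end_missing_max: int = 5          # max nt missing from either OTU end
    singleread_max_dissim: float = 0.01
    alpha: float = 0.05               # significance level
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_cutoff < 1.0):
            raise ValueError("cluster_cutoff must be in (0, 1)")
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if not (0.0 <= self.max_lowq_frac <= 1.0):
            raise ValueError("max_lowq_frac must be in [0, 1]")
        if self.rarefy_depth <= 0:
            raise ValueError("rarefy_depth must be positive")
        if self.end_missing_max < 0:
            raise ValueError("end_missing_max must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class QualityRead:
    """A single sequencing read with per-base Phred scores."""

    read_id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 60):
            raise ValueError(f"read {self.read_id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference 16S sequence with a rank-ordered lineage (coarse to fine)."""

    ref_id: str
    seq: str
    lineage: tuple[str, ...]
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError(f"reference {self.ref_id!r}: empty lineage")

    @property
    def genus(self) -> str:
        return self.lineage[-1]

    @property
    def phylum(self) -> str:
        return self.lineage[1] if len(self.lineage) > 1 else self.lineage[0]


def read_fastq(path: str | os.PathLike) -> Iterator[QualityRead]:
    """Stream :class:`QualityRead` records from a Phred+33 FASTQ file.

    Malformed records raise :class:`FastqParseError` naming the (0-based)
    record index.
    """
    parser = SeqIO.parse(str(path), "fastq")
    index = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
        yield QualityRead(
            read_id=record.id,
            seq=str(record.seq).upper(),
            quals=tuple(record.letter_annotations["phred_quality"]),
        )
        index += 1


def write_fastq(reads: Sequence[QualityRead], path: str | os.PathLike) -> None:
    """Write reads as 4-line-record Phred+33 FASTQ (deterministic bytes)."""
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")


def read_reference_fasta(
    path: str | os.PathLike, taxonomy_path: str | os.PathLike
) -> list[ReferenceRecord]:
    """Load a reference FASTA plus its taxonomy TSV (id<TAB>lineage).

    Lineages are semicolon-separated, ordered coarse to fine.  A seventh
    lineage field, when present, is taken as a species label.  Every FASTA id
    must appear in the taxonomy file; missing ids raise ``KeyError`` listing
    them all.
    """
    taxonomy: dict[str, tuple[tuple[str, ...], str | None]] = {}
    with open(taxonomy_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ref_id, lineage_str = line.split("\t", 1)
            parts = tuple(p.strip() for p in lineage_str.strip().rstrip(";").split(";"))
            species = parts[6] if len(parts) > 6 else None
            taxonomy[ref_id] = (parts[:6], species)

    records = []
    missing = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id not in taxonomy:
            missing.append(entry.id)
            continue
        lineage, species = taxonomy[entry.id]
        records.append(
            ReferenceRecord(
                ref_id=entry.id, seq=str(entry.seq).upper(),
                lineage=lineage, species=species,
            )
        )
    if missing:
        raise KeyError(
            "FASTA ids absent from taxonomy file: " + ", ".join(sorted(missing))
        )
    return records


def write_reference_fasta(
    refs: Sequence[ReferenceRecord],
    fasta_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
) -> None:
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.ref_id}\n{ref.seq}\n")
    with open(taxonomy_path, "w") as fh:
        for ref in refs:
            lineage = ";".join(ref.lineage)
            if ref.species:
                lineage += ";" + ref.species
            fh.write(f"{ref.ref_id}\t{lineage}\n")


#: Columns expected in the sample metadata TSV.
METADATA_COLUMNS = [
    "sample_id", "treatment", "acetate_mM", "propionate_mM", "butyrate_mM",
    "isobutyrate_mM", "valerate_mM", "isovalerate_mM", "total_scfa_mM",
    "body_length", "heart_girth", "hip_width",
]


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample-metadata TSV, indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    if "sample_id" not in df.columns or "treatment" not in df.columns:
        raise ValueError("metadata must have sample_id and treatment columns")
    return df.set_index("sample_id")


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent relative abundance per sample column (columns sum to 100)."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero reads: {empty}")
    return counts.div(totals, axis=1) * 100.0


def write_tables(
    counts: pd.DataFrame,
    assignments: Mapping[str, object],
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write OTU counts, percent relative abundances and taxonomy TSVs.

    ``counts`` is OTUs x samples (integer).  ``assignments`` maps every OTU id
    to an object with ``lineage``, ``best_hit_id`` and ``best_hit_identity``
    attributes (see :mod:`rumenamp.taxonomy`).  Counts round-trip losslessly;
    percentages are printed to 2 decimals and are derived, never re-read.
    """
    missing = [otu for otu in counts.index if otu not in assignments]
    if missing:
        raise KeyError("assignments missing for OTUs: " + ", ".join(missing))
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "otu_counts.tsv"),
        "relabund": os.path.join(outdir, "otu_relabund.tsv"),
        "taxonomy": os.path.join(outdir, "otu_taxonomy.tsv"),
    }
    counts.to_csv(paths["counts"], sep="\t", index_label="otu_id")
    rel = relative_abundance(counts)
    rel.round(2).to_csv(paths["relabund"], sep="\t", index_label="otu_id", float_format="%.2f")
    with open(paths["taxonomy"], "w") as fh:
        fh.write("otu_id\tlineage\tbest_hit_id\tbest_hit_identity\n")
        for otu in counts.index:
            a = assignments[otu]
            fh.write(f"{otu}\t{';'.join(a.lineage)}\t{a.best_hit_id}\t{a.best_hit_identity}\n")
    return paths


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back an OTU count TSV written by :func:`write_tables`."""
    return pd.read_csv(path, sep="\t", index_col="otu_id")
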