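"""Fragment containers and qualified-fragment loading.

A *fragment* is one sequenced cfDNA molecule represented as a 0-based
half-open genomic interval with mapping metadata and, optionally, its read
sequence.  Fragments are read either from a coordinate-sorted BAM (the
template span of a read pair, counted once) or from a simple fragment BED
dialect (chrom, start, end, name, mapq, strand) with an optional FASTA
sidecar keyed by fragment name.

Qualification follows standard cfDNA practice: mapping quality >= 30, no
supplementary alignment, not a PCR duplicate, and both ends mapped.  Each
dropped record is attributed to the FIRST failing criterion in the fixed
order mapq -> supplementary -> duplicate -> unpaired so that tallies are
deterministic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Fragment",
    "QcPolicy",
    "QcTally",
    "load_fragments",
    "read_fasta_sidecar",
    "write_fragments_bed",
    "write_fasta_sidecar",
]


@dataclass(slots=True)
class Fragment:
    """One cfDNA molecule as a genomic interval with mapping metadata."""

    chrom: str
    start: int
    end: int
    name: str = ""
    mapq: int = 60
    strand: str = "+"
    is_duplicate: bool = False
    is_supplementary: bool = False
    both_ends_mapped: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.mapq < 0:
            raise ValueError(f"fragment {self.name!r}: negative mapq")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QcPolicy:
    """Which qualification criteria to enforce when loading fragments."""

    min_mapq: int = 30
    require_both_ends: bool = True
    drop_duplicates: bool = True
    drop_supplementary: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def failure_reason(self, frag: Fragment) -> str | None:
        """First failing criterion, or None if the fragment qualifies."""
        if frag.mapq < self.min_mapq:
            return "mapq"
        if self.drop_supplementary and frag.is_supplementary:
            return "supplementary"
        if self.drop_duplicates and frag.is_duplicate:
            return "duplicate"
        if self.require_both_ends and not frag.both_ends_mapped:
            return "unpaired"
        return None


@dataclass
class QcTally:
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return self.kept + sum(self.dropped.values())

    def as_dict(self) -> dict:
        return {"kept": self.kept, "dropped": dict(sorted(self.dropped.items()))}


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta_sidecar(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA sidecar into a name -> sequence dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(Path(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def _iter_bed(path: Path, seqs: dict[str, str] | None) -> Iterator[Fragment]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else f"frag{lineno}"
            mapq = int(parts[4]) if len(parts) > 4 and parts[4] != "." else 60
            strand = parts[5] if len(parts) > 5 else "+"
            yield Fragment(
                chrom,
                start,
                end,
                name=name,
                mapq=mapq,
                strand=strand,
                sequence=seqs.get(name) if seqs else None,
            )


def _iter_bam(path: Path) -> Iterator[Fragment]:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        order = (bam.header.get("HD") or {}).get("SO")
        if order != "coordinate":
            raise ValueError(f"{path}: BAM/SAM must be coordinate-sorted (SO={order})")
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                # secondary alignments are never "uniquely mapped"
                continue
            both = (
                rec.is_paired
                and not rec.mate_is_unmapped
                and rec.template_length != 0
            )
            # emit one fragment per template: from the leftmost mate only
            if both and rec.template_length < 0:
                continue
            start = rec.reference_start
            end = start + abs(rec.template_length) if both else rec.reference_end
            if end is None or end <= start:
                end = start + 1
            yield Fragment(
                rec.reference_name,
                start,
                end,
                name=rec.query_name,
                mapq=rec.mapping_quality,
                strand="-" if rec.is_reverse else "+",
                is_duplicate=rec.is_duplicate,
                is_supplementary=rec.is_supplementary,
                both_ends_mapped=both,
                sequence=rec.query_sequence,
            )


def load_fragments(
    path: str | Path,
    policy: QcPolicy | None = None,
    *,
    sidecar: str | Path | None = None,
) -> tuple[list[Fragment], QcTally]:
    """Load fragments from BED/BAM/SAM and apply qualification filters.

    Returns the qualified fragments and a tally whose kept + dropped counts
    sum to the number of input records considered.
    """
    policy = policy or QcPolicy()
    path = Path(path)
    if path.suffix in {".bam", ".sam"} or str(path).endswith(".sam.gz"):
        source: Iterable[Fragment] = _iter_bam(path)
    else:
        seqs = read_fasta_sidecar(sidecar) if sidecar else None
        source = _iter_bed(path, seqs)
    tally = QcTally()
    kept: list[Fragment] = []
    for frag in source:
        reason = policy.failure_reason(frag)
        if reason is None:
            tally.kept += 1
            kept.append(frag)
        else:
            tally.drop(reason)
    return kept, tally


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as 6-column BED (gzipped when the path ends in .gz)."""
    path = Path(path)
    opener = (
        gzip.GzipFile(path, "wb", mtime=0)  # fixed mtime => byte-reproducible
        if str(path).endswith(".gz")
        else open(path, "wb")
    )
    with opener as fh:
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{f.mapq}\t{f.strand}\n".encode()
            )


def write_fasta_sidecar(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write the read sequences of fragments that carry one as FASTA."""
    path = Path(path)
    opener = (
        gzip.GzipFile(path, "wb", mtime=0)
        if str(path).endswith(".gz")
        else open(path, "wb")
    )
    with opener as fh:
        for f in fragments:
            if f.sequence:
                fh.write(f">{f.name}\n{f.sequence}\n".encode())
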