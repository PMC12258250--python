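"""Readers and writers for the genomic text formats the tool touches.

All internal coordinates are 0-based half-open; GFF/GTF input (1-based,
inclusive) is converted at this boundary and nowhere else.  BED and bedGraph
are already 0-based half-open.  Sequences are normalised to uppercase; by
default characters outside {A, C, G, T, N} are mapped to N, and a strict mode
rejects them instead.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO, motifs

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")
_IUPAC_STRICT = set("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigurationError(ValueError):
    """Inputs or options are inconsistent with what an operation needs."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    value: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript anchored by its TSS (0-based genomic position)."""

    transcript_id: str
    chrom: str
    tss: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class PfmRecord:
    """A position frequency matrix: 4 x L counts (rows A, C, G, T)."""

    tf_name: str
    counts: np.ndarray
    n_sequences: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class CoverageSegment:
    """One bedGraph segment with a non-negative signal value."""

    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("coverage value must be non-negative")


def _normalise_sequence(seq: str, name: str, ambiguous: str) -> str:
    seq = seq.upper()
    if ambiguous == "strict":
        bad = set(seq) - _IUPAC_STRICT
        if bad:
            raise FormatError(
                f"record {name!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )
        return seq
    # map everything outside ACGT to N
    return re.sub("[^ACGT]", "N", seq)


def read_fasta(path: str | Path, ambiguous: str = "map_n") -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence mapping.

    ``ambiguous`` is ``"map_n"`` (default: non-ACGT characters become N) or
    ``"strict"`` (characters outside ACGTN raise :class:`FormatError`).
    """
    if ambiguous not in ("map_n", "strict"):
        raise ConfigurationError(f"unknown ambiguity policy {ambiguous!r}")
    path = Path(path)
    with open(path) as handle:
        first = ""
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: expected FASTA header starting with '>'"
            )
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if len(record.seq) == 0:
            raise FormatError(f"{path}: record {record.id!r} is empty")
        out[record.id] = _normalise_sequence(str(record.seq), record.id, ambiguous)
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_jaspar_pfms(path: str | Path) -> list[PfmRecord]:
    """Parse a JASPAR-format PFM file into :class:`PfmRecord` objects.

    ``n_sequences`` is the (mean) column count sum; columns whose sums differ
    by more than 1 count raise a :class:`FormatError` since the matrix then
    cannot come from a single set of aligned sequences.
    """
    path = Path(path)
    try:
        with open(path) as handle:
            parsed = motifs.parse(handle, "jaspar")
            records = list(parsed)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: not a valid JASPAR matrix file: {exc}") from exc
    out: list[PfmRecord] = []
    for motif in records:
        counts = np.array(
            [motif.counts[nuc] for nuc in "ACGT"], dtype=float
        )
        if counts.shape[1] == 0:
            raise FormatError(f"{path}: motif {motif.name!r} has zero length")
        sums = counts.sum(axis=0)
        if sums.max() - sums.min() > 1.0 + 1e-6:
            raise FormatError(
                f"{path}: motif {motif.name!r} column sums differ "
                f"({sums.min()} vs {sums.max()}); not a count matrix"
            )
        out.append(
            PfmRecord(tf_name=motif.name, counts=counts, n_sequences=float(sums.mean()))
        )
    if not out:
        raise FormatError(f"{path}: no motifs found")
    return out


def write_jaspar_pfms(pfms: Iterable[PfmRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for i, pfm in enumerate(pfms):
            handle.write(f">MA{i:04d}.1 {pfm.tf_name}\n")
            for row, nuc in zip(pfm.counts, "ACGT"):
                cells = " ".join(f"{v:g}" for v in row)
                handle.write(f"{nuc}  [ {cells} ]\n")


def read_intervals(path: str | Path, kind: str = "generic") -> list[GenomicInterval]:
    """Read a BED-style file (0-based half-open) into sorted intervals.

    Columns: chrom, start, end[, name[, score[, strand]]].  The score column,
    when present, is parsed as a float and carried as the interval ``value``
    (CAGE peak counts, eQTL magnitudes, ChIP peak ranks, ...).
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval "
                    f"[{start}, {end}) for {kind} track"
                )
            value = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    value = float(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score column"
                    ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            out.append(GenomicInterval(fields[0], start, end, strand, value))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path, name_prefix: str = "elem"
) -> None:
    """Write intervals as 5-column BED; value round-trips via repr."""
    with open(path, "w") as handle:
        for i, iv in enumerate(intervals):
            score = repr(iv.value) if iv.value is not None else "."
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}\t{score}\t{iv.strand}\n"
            )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = dict(_GTF_ATTR.findall(text))
    if not attrs:
        attrs = dict(_GFF3_ATTR.findall(text))
    return attrs


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF or GFF3 annotation file.

    The TSS is the 1-based feature start (plus strand) or feature end (minus
    strand), converted to a 0-based position.  Records without a transcript
    identifier are skipped; the skip count is logged as a warning.
    """
    path = Path(path)
    out: list[TranscriptModel] = []
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns"
                )
            ftype = fields[2]
            if ftype not in ("transcript", "mRNA"):
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[6]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: line {lineno}: transcript strand must be + or -"
                )
            attrs = _parse_attributes(fields[8])
            tid = attrs.get("transcript_id") or attrs.get("ID")
            if not tid:
                skipped += 1
                continue
            gene = attrs.get("gene_id") or attrs.get("Parent") or tid
            tss = start1 - 1 if strand == "+" else end1 - 1
            out.append(TranscriptModel(tid, fields[0], tss, strand, gene))
    if skipped:
        logger.warning(
            "%s: skipped %d transcript record(s) without an identifier", path, skipped
        )
    return out


def write_transcripts_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    length: int = 1000,
    source: str = "promoterscan",
) -> None:
    """Write minimal GTF transcript records (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        for tx in transcripts:
            if tx.strand == "+":
                start1, end1 = tx.tss + 1, tx.tss + length
            else:
                start1, end1 = max(1, tx.tss + 2 - length), tx.tss + 1
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            handle.write(
                f"{tx.chrom}\t{source}\ttranscript\t{start1}\t{end1}\t.\t{tx.strand}\t.\t{attrs}\n"
            )


def read_bedgraph(path: str | Path) -> list[CoverageSegment]:
    """Read a 4-column bedGraph; drops zero-valued segments, rejects overlaps."""
    path = Path(path)
    raw: list[tuple[int, CoverageSegment]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 tab-separated columns"
                )
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad field types") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid segment [{start}, {end})"
                )
            if value < 0:
                raise FormatError(f"{path}: line {lineno}: negative coverage value")
            if value == 0:
                continue
            raw.append(
                (lineno, CoverageSegment(GenomicInterval(fields[0], start, end), value))
            )
    raw.sort(key=lambda item: (item[1].interval.chrom, item[1].interval.start))
    for (ln_a, a), (ln_b, b) in zip(raw, raw[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise FormatError(
                f"{path}: overlapping segments at lines {ln_a} and {ln_b}"
            )
    return [seg for _, seg in raw]


def write_bedgraph(segments: Iterable[CoverageSegment], path: str | Path) -> None:
    with open(path, "w") as handle:
        for seg in segments:
            iv = seg.interval
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.value:g}\n")


def read_eqtls(path: str | Path) -> list[GenomicInterval]:
    """Read a tab-delimited eQTL file: chrom, start, end, magnitude.

    Magnitudes may be signed effect sizes; downstream scoring uses |magnitude|.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected chrom, start, end, magnitude"
                )
            try:
                start, end, mag = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad field types") from exc
            if start >= end or start < 0:
                raise FormatError(f"{path}: line {lineno}: invalid interval")
            out.append(GenomicInterval(fields[0], start, end, ".", mag))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def write_eqtls(eqtls: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in eqtls:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{repr(iv.value)}\n")


def read_correlation_pairs(path: str | Path) -> list[tuple[str, str, float, float | None]]:
    """Read a TF-gene expression-correlation table.

    Tab-delimited columns: tf_name, gene_id, spearman_correlation[, p_value].
    """
    path = Path(path)
    out: list[tuple[str, str, float, float | None]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected tf, gene, correlation"
                )
            try:
                corr = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad correlation") from exc
            if not -1.0 <= corr <= 1.0:
                raise FormatError(
                    f"{path}: line {lineno}: correlation outside [-1, 1]"
                )
            pval = float(fields[3]) if len(fields) >= 4 and fields[3] != "." else None
            out.append((fields[0], fields[1], corr, pval))
    return out


def write_correlation_pairs(
    pairs: Iterable[tuple[str, str, float, float | None]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for tf, gene, corr, pval in pairs:
            ptxt = repr(pval) if pval is not None else "."
            handle.write(f"{tf}\t{gene}\t{repr(corr)}\t{ptxt}\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
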