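"""CAGE-like TSS peak calling from RNA-Seq coverage.

For species without true CAGE data, TSS-proximal peaks are derived from
coverage in three steps: (1) keep maximal runs of coverage with signal
strictly above ``min_signal``; (2) merge runs whose gap is at most
``merge_gap`` nucleotides; (3) keep merged peaks strictly wider than
``min_width``.  Merging runs before the width filter, so that sub-threshold-
width fragments can still join into one peak.  Peaks within ``max_distance``
of an annotated TSS are associated to that transcript; unassociated peaks are
dropped from the CAGE-like track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome_io import CoverageSegment, GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class CageLikePeak:
    """One CAGE-like peak; ``signal`` is the max coverage inside the peak."""

    interval: GenomicInterval
    signal: float
    transcript_id: str | None = None


def call_peaks(
    coverage: Sequence[CoverageSegment],
    min_width: int = 10,
    min_signal: float = 5.0,
    merge_gap: int = 10,
    merged_signal: str = "max",
) -> list[CageLikePeak]:
    """Call peaks from validated, non-overlapping coverage segments.

    Thresholds are strict (width > min_width, signal > min_signal); the merge
    gap is inclusive (gap <= merge_gap merges).  ``merged_signal`` is ``max``
    (default) or ``sum`` over merged members.
    """
    if merged_signal not in ("max", "sum"):
        raise ValueError(f"unknown merged_signal policy {merged_signal!r}")
    segs = sorted(
        (s for s in coverage if s.value > min_signal),
        key=lambda s: (s.interval.chrom, s.interval.start),
    )
    # step 1: contiguous above-threshold runs (gap 0 means same run)
    runs: list[list[CoverageSegment]] = []
    for seg in segs:
        if (
            runs
            and runs[-1][-1].interval.chrom == seg.interval.chrom
            and runs[-1][-1].interval.end == seg.interval.start
        ):
            runs[-1].append(seg)
        else:
            runs.append([seg])
    candidates = [
        (
            run[0].interval.chrom,
            run[0].interval.start,
            run[-1].interval.end,
            [s.value for s in run],
        )
        for run in runs
    ]
    # step 2: merge candidates whose gap is <= merge_gap
    merged: list[list] = []
    for chrom, start, end, values in candidates:
        if (
            merged
            and merged[-1][0] == chrom
            and start - merged[-1][2] <= merge_gap
        ):
            merged[-1][2] = end
            merged[-1][3].extend(values)
        else:
            merged.append([chrom, start, end, list(values)])
    # step 3: width filter (strict)
    peaks: list[CageLikePeak] = []
    for chrom, start, end, values in merged:
        if end - start <= min_width:
            continue
        signal = max(values) if merged_signal == "max" else sum(values)
        peaks.append(CageLikePeak(GenomicInterval(chrom, start, end), signal))
    return peaks


def associate_to_tss(
    peaks: Sequence[CageLikePeak],
    transcripts: Sequence[TranscriptModel],
    max_distance: int = 50,
) -> list[CageLikePeak]:
    """Assign peaks to every transcript whose TSS is within ``max_distance``.

    Distance is from the TSS position to the peak's nearest edge (0 when the
    TSS lies inside the peak); "within" is inclusive.  A peak near several
    TSSs yields one association per transcript; peaks near none are dropped.
    """
    out: list[CageLikePeak] = []
    for peak in peaks:
        iv = peak.interval
        for tx in transcripts:
            if tx.chrom != iv.chrom:
                continue
            if iv.start <= tx.tss < iv.end:
                d = 0
            elif tx.tss < iv.start:
                d = iv.start - tx.tss
            else:
                d = tx.tss - (iv.end - 1)
            if d <= max_distance:
                out.append(
                    CageLikePeak(peak.interval, peak.signal, tx.transcript_id)
                )
    return out


def peaks_to_coverage(peaks: Sequence[CageLikePeak]) -> list[CoverageSegment]:
    """Represent called peaks as coverage segments (for idempotence checks)."""
    return [CoverageSegment(p.interval, p.signal) for p in peaks]
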