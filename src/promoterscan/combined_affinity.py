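"""Combined affinity scoring of promoter windows.

For each putative binding site found by the PWM scan, the active feature
log-likelihood scores are summed into one combined affinity score:

    human mode:      PWM + CAGE + correlation + metaclusters + ATAC
                         + eQTL + CpG + conservation
    non-human mode:  PWM + CAGE + CpG + conservation

The combined score is calibrated against an empirical background built by
scoring a corpus of background promoters with the same feature set; the
empirical p-value of a score s against a background sample of size n is
(r + 1)/(n + 1) with r the count of background scores >= s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .empirical_likelihood import FEATURES, FeatureTracks
from .genome_io import (
    ConfigurationError,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
)
from .motif_scoring import (
    MotifHit,
    PositionWeightMatrix,
    ScoreDistribution,
    scan_sequence,
)

HUMAN_FEATURES = FEATURES
NON_HUMAN_FEATURES = ("pwm", "cage", "cpg", "conservation")


@dataclass(frozen=True)
class SpeciesMode:
    """The active feature set; PWM is always a member."""

    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ConfigurationError(f"unknown feature name(s): {sorted(unknown)}")
        if "pwm" not in self.features:
            raise ConfigurationError("the PWM feature is always included")

    @classmethod
    def human(cls) -> "SpeciesMode":
        return cls("human", HUMAN_FEATURES)

    @classmethod
    def non_human(cls) -> "SpeciesMode":
        return cls("non_human", NON_HUMAN_FEATURES)

    @classmethod
    def custom(cls, features: Sequence[str]) -> "SpeciesMode":
        return cls("custom", tuple(features))


@dataclass(frozen=True)
class CombinedAffinityResult:
    """One scored motif hit with its per-feature components."""

    hit: MotifHit
    genomic: GenomicInterval
    tss_relative_start: int
    tss_relative_end: int
    components: dict[str, float]
    combined_score: float
    combined_pvalue: float
    absent_features: frozenset[str] = frozenset()


def combine(components: Mapping[str, float], mode: SpeciesMode) -> float:
    """Exact sum of the mode's active feature components (absent -> 0)."""
    unknown = set(components) - set(FEATURES)
    if unknown:
        raise ConfigurationError(f"unknown feature name(s): {sorted(unknown)}")
    return float(sum(components.get(f, 0.0) for f in mode.features))


def empirical_pvalue(score: float, background: np.ndarray) -> float:
    """(r + 1)/(n + 1) with r = # background scores >= score.

    ``background`` must be sorted ascending.
    """
    background = np.asarray(background)
    n = background.size
    if n < 1:
        raise ConfigurationError("background sample must be non-empty")
    r = n - int(np.searchsorted(background, score, side="left"))
    return (r + 1) / (n + 1)


def promoter_window(
    transcript: TranscriptModel,
    before_tss: int = 900,
    after_tss: int = 100,
) -> GenomicInterval:
    """Genomic interval of the analysed window around the TSS.

    ``before_tss``/``after_tss`` follow the CLI semantics: negative values
    shift the window downstream/upstream respectively; after sign resolution
    the window must be non-empty.
    """
    if -before_tss >= after_tss:
        raise ConfigurationError(
            "promoter window is empty after sign resolution "
            f"(before={before_tss}, after={after_tss})"
        )
    if transcript.strand == "+":
        start = transcript.tss - before_tss
        end = transcript.tss + after_tss
    else:
        start = transcript.tss - after_tss + 1
        end = transcript.tss + before_tss + 1
    if start < 0:
        raise ValueError(
            f"promoter window extends past the chromosome start "
            f"(transcript {transcript.transcript_id})"
        )
    return GenomicInterval(transcript.chrom, start, end, transcript.strand)


def extract_promoter_sequence(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    before_tss: int = 900,
    after_tss: int = 100,
) -> tuple[str, GenomicInterval]:
    """Sense-strand promoter sequence and its genomic window."""
    window = promoter_window(transcript, before_tss, after_tss)
    chrom_seq = genome[transcript.chrom]
    if window.end > len(chrom_seq):
        raise ValueError(
            f"promoter window extends past the chromosome end "
            f"(transcript {transcript.transcript_id})"
        )
    seq = chrom_seq[window.start : window.end]
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq, window


def _hit_genomic_interval(
    hit: MotifHit, transcript: TranscriptModel, window: GenomicInterval
) -> GenomicInterval:
    """Map a promoter-relative hit back to plus-strand genomic coordinates."""
    if transcript.strand == "+":
        start = window.start + hit.start
    else:
        start = window.end - hit.end
    return GenomicInterval(transcript.chrom, start, start + (hit.end - hit.start))


def score_promoter_hits(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    tracks: FeatureTracks,
    pwms: Sequence[PositionWeightMatrix],
    mode: SpeciesMode,
    before_tss: int = 900,
    after_tss: int = 100,
    pval: float = 0.01,
    distributions: Mapping[str, ScoreDistribution] | None = None,
) -> list[CombinedAffinityResult]:
    """Scan a promoter and attach per-feature components and combined scores.

    Empirical p-values are not filled in here (combined_pvalue = 1.0
    placeholder); :func:`analyze_promoter` calibrates them against a
    background sample.
    """
    before = before_tss
    seq, window = extract_promoter_sequence(transcript, genome, before, after_tss)
    chrom_seq = genome[transcript.chrom]
    results: list[CombinedAffinityResult] = []
    for pwm in pwms:
        dist = distributions.get(pwm.tf_name) if distributions else None
        if dist is None:
            dist = ScoreDistribution(pwm)
        for hit in scan_sequence(pwm, seq, pvalue_threshold=pval, distribution=dist):
            genomic = _hit_genomic_interval(hit, transcript, window)
            components, absent = tracks.score_hit(
                genomic,
                gene_id=transcript.gene_id,
                tf_name=pwm.tf_name,
                sequence=chrom_seq,
                promoter_window=window,
            )
            components["pwm"] = hit.pwm_score
            score = combine(components, mode)
            rel_start = hit.start - before
            results.append(
                CombinedAffinityResult(
                    hit=hit,
                    genomic=genomic,
                    tss_relative_start=rel_start,
                    tss_relative_end=rel_start + (hit.end - hit.start),
                    components=components,
                    combined_score=score,
                    combined_pvalue=1.0,
                    absent_features=frozenset(absent),
                )
            )
    return results


def background_score_distribution(
    promoters: Sequence[tuple[TranscriptModel, Mapping[str, str]]],
    tracks: FeatureTracks,
    pwms: Sequence[PositionWeightMatrix],
    mode: SpeciesMode,
    before_tss: int = 900,
    after_tss: int = 100,
    pval: float = 0.01,
    distributions: Mapping[str, ScoreDistribution] | None = None,
) -> dict[str, np.ndarray]:
    """Per-TF sorted samples of combined scores over background promoters.

    Each background promoter is a (transcript, genome) pair; all hits across
    all background promoters contribute to the TF's sample.
    """
    if not promoters:
        raise ConfigurationError("background promoter set is empty")
    samples: dict[str, list[float]] = {pwm.tf_name: [] for pwm in pwms}
    for transcript, genome in promoters:
        for res in score_promoter_hits(
            transcript, genome, tracks, pwms, mode,
            before_tss, after_tss, pval, distributions,
        ):
            samples[res.hit.tf_name].append(res.combined_score)
    return {tf: np.sort(np.array(vals)) for tf, vals in samples.items()}


def analyze_promoter(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    tracks: FeatureTracks,
    pwms: Sequence[PositionWeightMatrix],
    background: Mapping[str, np.ndarray],
    mode: SpeciesMode | None = None,
    before_tss: int = 900,
    after_tss: int = 100,
    pval: float = 0.01,
    pvalc: float = 0.01,
    distributions: Mapping[str, ScoreDistribution] | None = None,
) -> list[CombinedAffinityResult]:
    """Full promoter analysis: scan, score, calibrate, filter, and rank.

    Hits are retained when their combined-score empirical p-value is <=
    ``pvalc`` and returned sorted by combined score, descending.  Promoter
    coordinates are TSS-relative with upstream negative.
    """
    if mode is None:
        mode = SpeciesMode.human()
    if not pwms:
        return []
    if not 0.0 < pvalc <= 1.0:
        raise ConfigurationError("pvalc must lie in (0, 1]")
    raw = score_promoter_hits(
        transcript, genome, tracks, pwms, mode,
        before_tss, after_tss, pval, distributions,
    )
    results: list[CombinedAffinityResult] = []
    for res in raw:
        sample = background.get(res.hit.tf_name)
        if sample is None or sample.size == 0:
            warnings.warn(
                f"no background sample for TF {res.hit.tf_name}; "
                "combined p-value set to 1.0",
                stacklevel=2,
            )
            p = 1.0
        else:
            p = empirical_pvalue(res.combined_score, sample)
        if p <= pvalc:
            results.append(
                CombinedAffinityResult(
                    hit=res.hit,
                    genomic=res.genomic,
                    tss_relative_start=res.tss_relative_start,
                    tss_relative_end=res.tss_relative_end,
                    components=res.components,
                    combined_score=res.combined_score,
                    combined_pvalue=p,
                    absent_features=res.absent_features,
                )
            )
    results.sort(
        key=lambda r: (
            -r.combined_score,
            r.hit.strand != "+",
            r.tss_relative_start,
        )
    )
    return results
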