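"""Benchmarking machinery: TP/TN construction, ROC analysis, and the
feature-combination search.

True positives are fixed-width regions centered on verified binding sites (50
bp) or on ChIP-Seq peak centers (200 bp).  For each verified-site TP, 50 true
negatives are sampled at random centers within a 2,000 bp window around the TP
center, at least 25 bp from it, inside the promoter, and not overlapping any
TP of the same TF.  Every region is scanned with p-value threshold 1 and the
top score per region represents it; regions with no scorable window carry a
-inf sentinel that ranks below all finite scores.  AUROC is the tie-aware
rank statistic (Mann-Whitney form).  All 128 feature subsets containing PWM
are evaluated by recombining cached per-hit component scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .empirical_likelihood import FEATURES, FeatureTracks
from .genome_io import ConfigurationError, GenomicInterval, TranscriptModel
from .motif_scoring import PositionWeightMatrix, ScoreDistribution, scan_sequence

TRUE_POSITIVE = "true_positive"
TRUE_NEGATIVE = "true_negative"

NO_SCORE = float("-inf")  # sentinel for regions with no scorable window


@dataclass
class BenchmarkSite:
    """A labeled benchmark region with cached per-model scores."""

    tf_name: str
    region: GenomicInterval
    label: str
    transcript_id: str | None = None
    gene_id: str | None = None
    best_scores: dict[str, float] = field(default_factory=dict)
    hit_components: np.ndarray | None = None  # (n_hits, len(FEATURES))


@dataclass(frozen=True)
class FeatureCombination:
    """An ordered feature subset; always contains the PWM."""

    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if "pwm" not in self.features:
            raise ConfigurationError("every combination must contain the PWM")
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ConfigurationError(f"unknown feature(s): {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "+".join(self.features)

    @property
    def mask(self) -> np.ndarray:
        return np.array([f in self.features for f in FEATURES])


@dataclass(frozen=True)
class RocRecord:
    tf_name: str
    model: str
    auroc: float
    n_tp: int
    n_tn: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("auroc must lie in [0, 1]")


def make_true_positive_regions(
    sites: Sequence[GenomicInterval],
    width: int = 50,
    tf_name: str = "",
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[BenchmarkSite]:
    """Fixed-width regions centered on each verified site.

    The site center is start + len//2 (odd site widths round down).  Regions
    falling outside chromosome bounds (when lengths are given) are skipped.
    """
    out: list[BenchmarkSite] = []
    for site in sites:
        center = site.start + (site.end - site.start) // 2
        start = center - width // 2
        end = start + width
        if start < 0 or (
            chrom_lengths is not None and end > chrom_lengths.get(site.chrom, end)
        ):
            continue
        out.append(
            BenchmarkSite(
                tf_name=tf_name,
                region=GenomicInterval(site.chrom, start, end),
                label=TRUE_POSITIVE,
            )
        )
    return out


def promoter_bounds(
    transcript: TranscriptModel,
    before: int = 2000,
    after: int = 2000,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Promoter interval around a TSS, clipped at chromosome edges."""
    start = max(transcript.tss - (before if transcript.strand == "+" else after), 0)
    end = transcript.tss + (after if transcript.strand == "+" else before) + 1
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(transcript.chrom, start, end, transcript.strand)


def feasible_tn_centers(
    tp: BenchmarkSite,
    promoter_bounds: GenomicInterval,
    window: int = 2000,
    min_dist: int = 25,
    tp_regions: Sequence[GenomicInterval] = (),
) -> np.ndarray:
    """All centers satisfying the TN constraints, enumerated exhaustively."""
    width = len(tp.region)
    tp_center = tp.region.start + width // 2
    half = window // 2
    centers = np.arange(tp_center - half, tp_center + half + 1)
    # region must fit inside the promoter of the same transcript
    starts = centers - width // 2
    ends = starts + width
    ok = (starts >= promoter_bounds.start) & (ends <= promoter_bounds.end)
    ok &= np.abs(centers - tp_center) >= min_dist
    for region in tp_regions:
        if region.chrom == tp.region.chrom:
            ok &= (ends <= region.start) | (starts >= region.end)
    return centers[ok]


def sample_true_negatives(
    tp: BenchmarkSite,
    promoter_bounds: GenomicInterval,
    n: int = 50,
    window: int = 2000,
    min_dist: int = 25,
    seed: int | np.random.Generator = 0,
    tp_regions: Sequence[GenomicInterval] = (),
) -> list[BenchmarkSite]:
    """Sample ``n`` TN regions for one TP, without replacement.

    Centers are uniform over the feasible positions: within the ``window``
    centered on the TP, at least ``min_dist`` from the TP center, inside the
    promoter, and not overlapping any TP region of the same TF.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    centers = feasible_tn_centers(tp, promoter_bounds, window, min_dist, tp_regions)
    if centers.size < n:
        raise ConfigurationError(
            f"only {centers.size} feasible true-negative centers "
            f"(need {n}) for TP at {tp.region.chrom}:{tp.region.start}"
        )
    width = len(tp.region)
    chosen = rng.choice(centers, size=n, replace=False)
    return [
        BenchmarkSite(
            tf_name=tp.tf_name,
            region=GenomicInterval(
                tp.region.chrom, int(c) - width // 2, int(c) - width // 2 + width
            ),
            label=TRUE_NEGATIVE,
            transcript_id=tp.transcript_id,
            gene_id=tp.gene_id,
        )
        for c in chosen
    ]


def best_score_per_region(scores: Sequence[float]) -> float:
    """Top score in the region, or the -inf sentinel when nothing scored."""
    finite = [s for s in scores if not math.isnan(s)]
    return max(finite) if finite else NO_SCORE


def roc_auc(tp_scores: Sequence[float], tn_scores: Sequence[float]) -> float:
    """Tie-aware rank-based AUROC (Mann-Whitney statistic form)."""
    tp_scores = np.asarray(tp_scores, dtype=float)
    tn_scores = np.asarray(tn_scores, dtype=float)
    if tp_scores.size == 0 or tn_scores.size == 0:
        raise ConfigurationError("both score lists must be non-empty")
    pooled = np.concatenate([tp_scores, tn_scores])
    ranks = stats.rankdata(pooled)
    r_tp = ranks[: tp_scores.size].sum()
    n1, n2 = tp_scores.size, tn_scores.size
    u = r_tp - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def enumerate_combinations() -> list[FeatureCombination]:
    """All feature subsets containing the PWM, in deterministic order."""
    others = tuple(f for f in FEATURES if f != "pwm")
    combos: list[FeatureCombination] = []
    for k in range(len(others) + 1):
        for subset in itertools.combinations(others, k):
            ordered = tuple(f for f in FEATURES if f == "pwm" or f in subset)
            combos.append(FeatureCombination(ordered))
    combos.sort(key=lambda c: (len(c.features), c.features))
    return combos


def score_sites(
    sites: Sequence[BenchmarkSite],
    genome: Mapping[str, str],
    tracks: FeatureTracks,
    pwms: Mapping[str, PositionWeightMatrix],
    distributions: Mapping[str, ScoreDistribution] | None = None,
) -> None:
    """Scan every site with its TF's PWM at threshold 1 and cache, per hit,
    the eight feature component scores (in FEATURES order) on the site."""
    dists = dict(distributions or {})
    for site in sites:
        pwm = pwms.get(site.tf_name)
        if pwm is None:
            raise ConfigurationError(f"no PWM for TF {site.tf_name!r}")
        if site.tf_name not in dists:
            dists[site.tf_name] = ScoreDistribution(pwm)
        seq = genome[site.region.chrom][site.region.start : site.region.end]
        rows: list[list[float]] = []
        for hit in scan_sequence(
            pwm, seq, pvalue_threshold=1.0, distribution=dists[site.tf_name]
        ):
            genomic = GenomicInterval(
                site.region.chrom,
                site.region.start + hit.start,
                site.region.start + hit.end,
            )
            components, _ = tracks.score_hit(
                genomic,
                gene_id=site.gene_id or "",
                tf_name=site.tf_name,
                sequence=genome[site.region.chrom],
                promoter_window=site.region,
            )
            components["pwm"] = hit.pwm_score
            rows.append([components[f] for f in FEATURES])
        site.hit_components = (
            np.array(rows) if rows else np.empty((0, len(FEATURES)))
        )


def _combination_best_scores(
    sites: Sequence[BenchmarkSite], combo: FeatureCombination
) -> np.ndarray:
    mask = combo.mask
    out = np.empty(len(sites))
    for i, site in enumerate(sites):
        if site.hit_components is None:
            raise ConfigurationError("sites must be scored first (score_sites)")
        if site.hit_components.shape[0] == 0:
            out[i] = NO_SCORE
        else:
            out[i] = site.hit_components[:, mask].sum(axis=1).max()
    return out


def evaluate_combinations(
    sites: Sequence[BenchmarkSite],
    combinations: Sequence[FeatureCombination] | None = None,
) -> tuple[pd.DataFrame, FeatureCombination, dict[str, FeatureCombination]]:
    """AUROC of every feature combination for every TF.

    Returns (table, best_overall, best_by_tf): the table has one row per
    (TF, combination); best_overall maximises the mean AUROC across TFs
    (ties broken by smaller feature set, then feature order); best_by_tf is
    the per-TF argmax with the same tie-break.
    """
    if combinations is None:
        combinations = enumerate_combinations()
    tf_names = sorted({s.tf_name for s in sites})
    by_tf = {
        tf: [s for s in sites if s.tf_name == tf] for tf in tf_names
    }
    records: list[dict] = []
    auroc_matrix: dict[str, dict[str, float]] = {tf: {} for tf in tf_names}
    for combo in combinations:
        for tf in tf_names:
            tf_sites = by_tf[tf]
            scores = _combination_best_scores(tf_sites, combo)
            labels = np.array([s.label == TRUE_POSITIVE for s in tf_sites])
            auc = roc_auc(scores[labels], scores[~labels])
            auroc_matrix[tf][combo.name] = auc
            records.append(
                {
                    "tf_name": tf,
                    "model": combo.name,
                    "auroc": auc,
                    "n_tp": int(labels.sum()),
                    "n_tn": int((~labels).sum()),
                }
            )
    table = pd.DataFrame.from_records(records)

    def _key(combo: FeatureCombination, mean_auc: float):
        return (-mean_auc, len(combo.features), combo.features)

    means = {
        combo: float(np.mean([auroc_matrix[tf][combo.name] for tf in tf_names]))
        for combo in combinations
    }
    best_overall = min(combinations, key=lambda c: _key(c, means[c]))
    best_by_tf = {
        tf: min(
            combinations, key=lambda c: _key(c, auroc_matrix[tf][c.name])
        )
        for tf in tf_names
    }
    return table, best_overall, best_by_tf


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def paired_t_test(
    aurocs_a: Sequence[float], aurocs_b: Sequence[float]
) -> PairedTResult:
    """Classical paired t-test on per-TF AUROC differences (two-sided).

    Zero-variance differences are degenerate: the statistic is 0 (all-zero
    differences) or signed infinity, and the p-value is reported as 1 with
    the degenerate flag set, so combination sweeps stay total.
    """
    a = np.asarray(aurocs_a, dtype=float)
    b = np.asarray(aurocs_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ConfigurationError("need two equal-length samples of size >= 2")
    d = a - b
    scale = max(1.0, float(np.max(np.abs(d))))
    if np.ptp(d) <= 1e-12 * scale:  # zero-variance differences
        if abs(d[0]) <= 1e-12:
            return PairedTResult(0.0, 1.0, degenerate=True)
        return PairedTResult(math.copysign(math.inf, d[0]), 1.0, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTResult(float(t), float(p), degenerate=False)


def build_chipseq_benchmark(
    peaks_by_tf: Mapping[str, Sequence[GenomicInterval]],
    transcripts: Sequence[TranscriptModel],
    top_k: int = 500,
    min_peaks: int = 100,
    width: int = 200,
    seed: int | np.random.Generator = 0,
) -> list[BenchmarkSite]:
    """ChIP-peak benchmark: 200 bp TPs at peak centers, TSS-offset-matched TNs.

    TFs with fewer than ``min_peaks`` peaks are excluded; each kept TF
    contributes up to its ``top_k`` highest-scoring peaks (ties by genomic
    order).  Each peak maps to its nearest transcript; the TN applies the
    same TSS-relative window to a random transcript with no peak for the TF.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    tx_by_id = {t.transcript_id: t for t in transcripts}
    sites: list[BenchmarkSite] = []
    for tf in sorted(peaks_by_tf):
        peaks = list(peaks_by_tf[tf])
        if len(peaks) < min_peaks:
            continue
        peaks.sort(
            key=lambda p: (-(p.value if p.value is not None else 0.0), p.chrom, p.start)
        )
        peaks = peaks[:top_k]
        matched_ids: set[str] = set()
        tp_info: list[tuple[GenomicInterval, TranscriptModel]] = []
        for peak in peaks:
            center = peak.start + (peak.end - peak.start) // 2
            same_chrom = [t for t in transcripts if t.chrom == peak.chrom]
            if not same_chrom:
                continue
            nearest = min(same_chrom, key=lambda t: abs(t.tss - center))
            start = center - width // 2
            if start < 0:
                continue
            region = GenomicInterval(peak.chrom, start, start + width)
            matched_ids.add(nearest.transcript_id)
            tp_info.append((region, nearest))
        eligible = [t for t in transcripts if t.transcript_id not in matched_ids]
        if not eligible:
            raise ConfigurationError(
                f"no transcript without a ChIP peak available as TN anchor for {tf}"
            )
        for region, anchor in tp_info:
            sites.append(
                BenchmarkSite(
                    tf_name=tf,
                    region=region,
                    label=TRUE_POSITIVE,
                    transcript_id=anchor.transcript_id,
                    gene_id=anchor.gene_id,
                )
            )
            # strand-aware TSS-relative offset of the TP window
            if anchor.strand == "+":
                rel_start = region.start - anchor.tss
            else:
                rel_start = anchor.tss - region.end + 1
            for _ in range(50):  # rejection-sample a TN that fits its contig
                tn_tx = eligible[int(rng.integers(len(eligible)))]
                if tn_tx.strand == "+":
                    tn_start = tn_tx.tss + rel_start
                else:
                    tn_start = tn_tx.tss - rel_start - width + 1
                if tn_start >= 0:
                    sites.append(
                        BenchmarkSite(
                            tf_name=tf,
                            region=GenomicInterval(
                                tn_tx.chrom, tn_start, tn_start + width
                            ),
                            label=TRUE_NEGATIVE,
                            transcript_id=tn_tx.transcript_id,
                            gene_id=tn_tx.gene_id,
                        )
                    )
                    break
            else:
                raise ConfigurationError(
                    f"could not place a TN window for TF {tf} at offset {rel_start}"
                )
    return sites
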