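"""Empirical score tables and the per-feature log-likelihood scores.

Each transcription-relevant feature contributes bits of evidence for a
putative binding site through an empirical tail probability taken from a
genome-wide distribution of its observable:

* distances (to the nearest CAGE peak, ATAC peak, or conserved element) use
  the lower tail P(x <= d) — being unusually close is informative;
* overlap counts (ChIP metaclusters), eQTL effect magnitudes, CpG
  observed/expected ratios, and expression-correlation magnitudes use the
  upper tail P(x >= v) — being unusually high is informative.

The log-likelihood score of an observed value v is LLS(v) = -log2 P(v),
which is >= 0 and kept finite by a per-table probability floor
eps = 1/(n + 1), n being the sample size behind the table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import ConfigurationError, GenomicInterval
from .motif_scoring import encode_sequence

LOWER_TAIL = "lower_tail"
UPPER_TAIL = "upper_tail"

DEFAULT_CORRELATION_CUTOFF = 0.3
DEFAULT_CPG_WINDOW = 200

#: canonical feature names, in reporting order
FEATURES = (
    "pwm",
    "cage",
    "correlation",
    "metaclusters",
    "atac",
    "eqtl",
    "cpg",
    "conservation",
)


class EmpiricalScoreTable:
    """Sorted support values with tail probabilities and a probability floor."""

    def __init__(
        self,
        feature: str,
        support: np.ndarray,
        probabilities: np.ndarray,
        direction: str,
        eps: float,
        provenance: dict | None = None,
    ):
        if direction not in (LOWER_TAIL, UPPER_TAIL):
            raise ConfigurationError(f"unknown tail direction {direction!r}")
        support = np.asarray(support, dtype=float)
        probabilities = np.asarray(probabilities, dtype=float)
        if support.ndim != 1 or support.shape != probabilities.shape:
            raise ValueError("support and probabilities must be matching 1-D arrays")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        diffs = np.diff(probabilities)
        if direction == LOWER_TAIL and np.any(diffs < -1e-12):
            raise ValueError("lower-tail probabilities must be non-decreasing")
        if direction == UPPER_TAIL and np.any(diffs > 1e-12):
            raise ValueError("upper-tail probabilities must be non-increasing")
        if np.any(probabilities < eps - 1e-12) or np.any(probabilities > 1 + 1e-12):
            raise ValueError("probabilities must lie in [eps, 1]")
        self.feature = feature
        self.support = support
        self.probabilities = probabilities
        self.direction = direction
        self.eps = float(eps)
        self.provenance = provenance or {}

    @classmethod
    def from_values(
        cls,
        values: Sequence[float] | np.ndarray,
        direction: str,
        feature: str = "",
        eps: float | None = None,
        provenance: dict | None = None,
    ) -> "EmpiricalScoreTable":
        """Build the empirical tail table from raw observations."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ConfigurationError(
                f"cannot build an empirical table for {feature or 'feature'}: "
                "no observations"
            )
        n = values.size
        if eps is None:
            eps = 1.0 / (n + 1)
        support, counts = np.unique(values, return_counts=True)
        cum = np.cumsum(counts)
        if direction == LOWER_TAIL:
            probs = cum / n  # P(x <= v)
        elif direction == UPPER_TAIL:
            probs = (n - (cum - counts)) / n  # P(x >= v)
        else:
            raise ConfigurationError(f"unknown tail direction {direction!r}")
        probs = np.clip(probs, eps, 1.0)
        prov = dict(provenance or {})
        prov.setdefault("n_observations", int(n))
        return cls(feature, support, probs, direction, eps, prov)

    def prob(self, value: float | np.ndarray) -> np.ndarray | float:
        """Tail probability of ``value`` (floored at eps, capped at 1)."""
        value = np.asarray(value, dtype=float)
        if self.direction == LOWER_TAIL:
            idx = np.searchsorted(self.support, value, side="right") - 1
            out = np.where(idx < 0, self.eps, self.probabilities[np.maximum(idx, 0)])
        else:
            idx = np.searchsorted(self.support, value, side="left")
            out = np.where(
                idx >= self.support.size,
                self.eps,
                self.probabilities[np.minimum(idx, self.support.size - 1)],
            )
        return out if out.ndim else float(out)

    def lls(self, value: float | np.ndarray) -> np.ndarray | float:
        """Log-likelihood score -log2 P(value), >= 0 and finite."""
        p = np.asarray(self.prob(value))
        out = -np.log2(p)
        # guard against -0.0 for p == 1
        out = np.abs(out)
        return out if out.ndim else float(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature": self.feature,
            "direction": self.direction,
            "eps": self.eps,
            "support": self.support.tolist(),
            "probabilities": self.probabilities.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EmpiricalScoreTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["feature"],
            np.array(payload["support"]),
            np.array(payload["probabilities"]),
            payload["direction"],
            payload["eps"],
            payload.get("provenance"),
        )


# ---------------------------------------------------------------------------
# interval geometry

def interval_distance(
    start: int, end: int, other_start: int, other_end: int
) -> int:
    """Nearest-edge distance between half-open intervals; 0 on overlap.

    Adjacent intervals ([0, 5) and [5, 9)) are at distance 1, matching the
    per-nucleotide convention where position p and position p+1 are 1 apart.
    """
    return max(other_start - end + 1, start - other_end + 1, 0)


def nearest_element_distance(
    hit: GenomicInterval, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Distance from ``hit`` to the nearest of the given elements."""
    if starts.size == 0:
        raise ConfigurationError("no elements to measure distance to")
    gaps = np.maximum(
        np.maximum(starts - hit.end + 1, hit.start - ends + 1), 0
    )
    return int(gaps.min())


def count_overlaps(hit: GenomicInterval, starts: np.ndarray, ends: np.ndarray) -> int:
    return int(np.count_nonzero((starts < hit.end) & (ends > hit.start)))


def genome_distance_vector(
    elements: Sequence[GenomicInterval], genome_lengths: Mapping[str, int]
) -> np.ndarray:
    """Per-nucleotide distance to the nearest element, pooled over chromosomes."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    pieces = []
    for chrom, length in genome_lengths.items():
        pos = np.arange(length)
        els = by_chrom.get(chrom)
        if not els:
            # no element on this chromosome: nearest element is off-chromosome;
            # use distance to the chromosome end as a conservative bound is not
            # meaningful, so treat the whole chromosome as maximally distant
            # from the nearest element on any chromosome is undefined -- follow
            # the per-chromosome convention and skip (tables pool positions
            # that have a defined distance).
            continue
        starts = np.array(sorted(e.start for e in els))
        ends = np.array(sorted(e.end for e in els))
        # distance to nearest start on the right
        idx = np.searchsorted(starts, pos, side="right")
        right = np.where(idx < starts.size, starts[np.minimum(idx, starts.size - 1)] - pos, np.iinfo(np.int64).max)
        # distance to nearest end on the left (last covered base is end-1)
        jdx = np.searchsorted(ends, pos, side="right") - 1
        left = np.where(jdx >= 0, pos - (ends[np.maximum(jdx, 0)] - 1), np.iinfo(np.int64).max)
        dist = np.minimum(np.maximum(right, 0), np.maximum(left, 0))
        # positions inside an element have distance 0
        cover = np.zeros(length + 1, dtype=np.int32)
        for e in els:
            cover[e.start] += 1
            cover[min(e.end, length)] -= 1
        inside = np.cumsum(cover[:-1]) > 0
        dist = np.where(inside, 0, dist)
        pieces.append(dist)
    if not pieces:
        raise ConfigurationError("no chromosome carries any element")
    return np.concatenate(pieces)


def build_distance_table(
    elements: Sequence[GenomicInterval],
    genome_lengths: Mapping[str, int],
    feature: str = "distance",
) -> EmpiricalScoreTable:
    """Genome-wide P(x <= d) table of distances to the nearest element."""
    if not elements:
        raise ConfigurationError(
            f"cannot build distance table for {feature!r}: empty element list"
        )
    if not genome_lengths:
        raise ConfigurationError("genome is empty")
    dist = genome_distance_vector(elements, genome_lengths)
    return EmpiricalScoreTable.from_values(
        dist, LOWER_TAIL, feature=feature,
        provenance={"n_elements": len(elements)},
    )


def genome_overlap_vector(
    elements: Sequence[GenomicInterval], genome_lengths: Mapping[str, int]
) -> np.ndarray:
    """Per-nucleotide count of overlapping elements, pooled over chromosomes."""
    pieces = []
    for chrom, length in genome_lengths.items():
        cover = np.zeros(length + 1, dtype=np.int64)
        for el in elements:
            if el.chrom != chrom or el.start >= length:
                continue
            cover[el.start] += 1
            cover[min(el.end, length)] -= 1
        pieces.append(np.cumsum(cover[:-1]))
    if not pieces:
        raise ConfigurationError("genome is empty")
    return np.concatenate(pieces)


def build_overlap_table(
    elements: Sequence[GenomicInterval],
    genome_lengths: Mapping[str, int],
    feature: str = "metaclusters",
) -> EmpiricalScoreTable:
    """Genome-wide P(x >= n) table of per-nucleotide element overlap counts."""
    counts = genome_overlap_vector(elements, genome_lengths)
    return EmpiricalScoreTable.from_values(
        counts, UPPER_TAIL, feature=feature,
        provenance={"n_elements": len(elements)},
    )


def build_tail_table(
    values: Sequence[float] | np.ndarray,
    direction: str,
    feature: str = "",
) -> EmpiricalScoreTable:
    """Empirical tail table over raw observations, floored at 1/(n+1)."""
    return EmpiricalScoreTable.from_values(values, direction, feature=feature)


# ---------------------------------------------------------------------------
# CAGE peaks

@dataclass
class CagePeakSet:
    """Per-gene CAGE (or CAGE-like) peaks with their tag counts."""

    peaks: dict[str, list[tuple[GenomicInterval, float]]] = field(default_factory=dict)

    def add(self, gene_id: str, interval: GenomicInterval, count: float) -> None:
        if count <= 0:
            raise ValueError("CAGE peak count must be positive")
        self.peaks.setdefault(gene_id, []).append((interval, count))

    def total(self, gene_id: str) -> float:
        return sum(c for _, c in self.peaks.get(gene_id, []))

    def genes(self) -> list[str]:
        return list(self.peaks)

    def all_intervals(self) -> list[GenomicInterval]:
        return [iv for entries in self.peaks.values() for iv, _ in entries]


def lls_cage(
    hit: GenomicInterval,
    peaks: CagePeakSet,
    gene_id: str,
    table: EmpiricalScoreTable,
    weighting: str = "literal",
) -> float:
    """TSS-proximity score: sum over the gene's peaks of the distance term.

    ``weighting="literal"`` places the peak's count share p_i/p_total inside
    the -log2 (a low-usage peak contributes more bits); ``"inverted"`` uses
    the share as an outer multiplier instead, down-weighting minor peaks.
    """
    entries = peaks.peaks.get(gene_id)
    if not entries:
        return 0.0
    p_total = sum(c for _, c in entries)
    total = 0.0
    for iv, count in entries:
        d = interval_distance(hit.start, hit.end, iv.start, iv.end) if iv.chrom == hit.chrom else nearest_far_distance(table)
        p = float(table.prob(d))
        share = count / p_total
        if weighting == "literal":
            total += -math.log2(p * share)
        elif weighting == "inverted":
            total += share * -math.log2(p)
        else:
            raise ConfigurationError(f"unknown cage weighting {weighting!r}")
    return total


def nearest_far_distance(table: EmpiricalScoreTable) -> float:
    """Off-chromosome sentinel: the largest distance the table has seen."""
    return float(table.support[-1])


def lls_metaclusters(
    hit: GenomicInterval,
    starts: np.ndarray,
    ends: np.ndarray,
    table: EmpiricalScoreTable,
) -> float:
    """ChIP metacluster co-location score: -log2 P(x >= n_overlap)."""
    n = count_overlaps(hit, starts, ends)
    if n == 0:
        return 0.0
    return float(table.lls(n))


def lls_atac(
    hit: GenomicInterval,
    peaks: Sequence[GenomicInterval],
    table: EmpiricalScoreTable,
) -> float:
    """Open-chromatin proximity: sum of -log2 P(x <= d_i) over in-window peaks."""
    total = 0.0
    for peak in peaks:
        if peak.chrom != hit.chrom:
            continue
        d = interval_distance(hit.start, hit.end, peak.start, peak.end)
        total += float(table.lls(d))
    return total


def lls_eqtl(
    hit: GenomicInterval,
    eqtls: Sequence[GenomicInterval],
    table: EmpiricalScoreTable,
) -> float:
    """Sum of -log2 P(x >= |m_i|) over eQTLs overlapping the hit."""
    total = 0.0
    for variant in eqtls:
        if variant.overlaps(hit):
            magnitude = abs(variant.value if variant.value is not None else 0.0)
            total += float(table.lls(magnitude))
    return total


def cpg_ratio(sequence: str, center: int, window: int = DEFAULT_CPG_WINDOW) -> float:
    """Observed/expected CpG ratio in a window centered on ``center``.

    ratio = count("CG") * window_length / (count(C) * count(G)); 0 when there
    is no C or no G.  The window is truncated at the sequence ends.
    """
    half = window // 2
    lo = max(0, center - half)
    hi = min(len(sequence), center + half)
    win = sequence[lo:hi].upper()
    if not win:
        return 0.0
    n_c = win.count("C")
    n_g = win.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    obs = win.count("CG")
    return obs * len(win) / (n_c * n_g)


def cpg_ratio_profile(sequence: str, window: int = DEFAULT_CPG_WINDOW) -> np.ndarray:
    """CpG observed/expected ratio at every position (vectorised)."""
    codes = encode_sequence(sequence.upper())
    n = codes.size
    is_c = (codes == 1).astype(np.int64)
    is_g = (codes == 2).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    half = window // 2
    pos = np.arange(n)
    lo = np.maximum(0, pos - half)
    hi = np.minimum(n, pos + half)
    length = hi - lo
    n_c = cum_c[hi] - cum_c[lo]
    n_g = cum_g[hi] - cum_g[lo]
    # a CG dinucleotide is counted when it starts inside the window
    hi_d = np.minimum(n, hi)  # window substring of length `length` starts at lo
    obs = cum_cg[np.maximum(hi_d - 1, lo)] - cum_cg[lo]
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, obs * length / np.maximum(denom, 1), 0.0)
    return ratio


def build_cpg_table(
    genome: Mapping[str, str], window: int = DEFAULT_CPG_WINDOW
) -> EmpiricalScoreTable:
    """Genome-wide upper-tail table of CpG observed/expected ratios."""
    ratios = np.concatenate(
        [cpg_ratio_profile(seq, window) for seq in genome.values()]
    )
    return EmpiricalScoreTable.from_values(
        ratios, UPPER_TAIL, feature="cpg",
        provenance={"window": window},
    )


def lls_cpg(ratio: float, table: EmpiricalScoreTable) -> float:
    """-log2 P(x >= ratio) against the genome-wide CpG ratio distribution."""
    return float(table.lls(ratio))


def lls_conservation(
    hit: GenomicInterval,
    starts: np.ndarray,
    ends: np.ndarray,
    table: EmpiricalScoreTable,
) -> float:
    """-log2 P(x <= d), d = distance to the nearest conserved element."""
    d = nearest_element_distance(hit, starts, ends)
    return float(table.lls(d))


# ---------------------------------------------------------------------------
# expression correlations

class CorrelationTable:
    """TF-gene Spearman correlations plus the global magnitude distribution.

    Pairs with |c| below ``cutoff`` are dropped at build time; when p-values
    are supplied, an optional Bonferroni filter keeps only pairs whose
    corrected p-value is <= alpha.
    """

    def __init__(
        self,
        pairs: Mapping[tuple[str, str], float],
        magnitude_table: EmpiricalScoreTable,
        cutoff: float = DEFAULT_CORRELATION_CUTOFF,
    ):
        for (tf, gene), c in pairs.items():
            if not -1.0 <= c <= 1.0:
                raise ValueError(f"correlation for ({tf}, {gene}) outside [-1, 1]")
            if abs(c) < cutoff:
                raise ValueError(
                    f"pair ({tf}, {gene}) has |c| < cutoff {cutoff}; "
                    "sub-cutoff pairs must be absent"
                )
        self.pairs = dict(pairs)
        self.magnitude_table = magnitude_table
        self.cutoff = cutoff

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float, float | None]],
        cutoff: float = DEFAULT_CORRELATION_CUTOFF,
        bonferroni_alpha: float | None = None,
    ) -> "CorrelationTable":
        records = list(records)
        if bonferroni_alpha is not None:
            m = len(records)
            records = [
                r for r in records
                if r[3] is None or r[3] * m <= bonferroni_alpha
            ]
        kept = {
            (tf, gene): corr
            for tf, gene, corr, _ in records
            if abs(corr) >= cutoff
        }
        if not kept:
            raise ConfigurationError("no correlation pairs survive the cutoff")
        mags = np.abs(np.array(list(kept.values())))
        table = EmpiricalScoreTable.from_values(
            mags, UPPER_TAIL, feature="correlation",
            provenance={"cutoff": cutoff, "n_pairs": len(kept)},
        )
        return cls(kept, table, cutoff)

    def get(self, tf_name: str, gene_id: str) -> float | None:
        return self.pairs.get((tf_name, gene_id))


def lls_correlation(
    tf_name: str, gene_id: str, table: CorrelationTable
) -> float:
    """-log2 P(|c_all| >= |c_current|); absent pairs (sub-cutoff) score 0."""
    c = table.get(tf_name, gene_id)
    if c is None:
        return 0.0
    return float(table.magnitude_table.lls(abs(c)))


# ---------------------------------------------------------------------------
# the per-species track bundle

class FeatureTracks:
    """All interval/value tracks and score tables a promoter is scored against.

    Any track may be None (species without that data type); its feature then
    scores 0 and is flagged as absent in results.
    """

    def __init__(
        self,
        cage: CagePeakSet | None = None,
        metaclusters: Sequence[GenomicInterval] | None = None,
        atac: Sequence[GenomicInterval] | None = None,
        eqtls: Sequence[GenomicInterval] | None = None,
        conservation: Sequence[GenomicInterval] | None = None,
        correlations: CorrelationTable | None = None,
        tables: Mapping[str, EmpiricalScoreTable] | None = None,
        cage_weighting: str = "literal",
    ):
        self.cage = cage
        self.metaclusters = list(metaclusters) if metaclusters is not None else None
        self.atac = list(atac) if atac is not None else None
        self.eqtls = list(eqtls) if eqtls is not None else None
        self.conservation = list(conservation) if conservation is not None else None
        self.correlations = correlations
        self.tables = dict(tables or {})
        self.cage_weighting = cage_weighting
        self._meta_idx = self._index(self.metaclusters)
        self._cons_idx = self._index(self.conservation)

    @staticmethod
    def _index(
        elements: Sequence[GenomicInterval] | None,
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if elements is None:
            return idx
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for el in elements:
            by_chrom.setdefault(el.chrom, []).append(el)
        for chrom, els in by_chrom.items():
            idx[chrom] = (
                np.array([e.start for e in els]),
                np.array([e.end for e in els]),
            )
        return idx

    def score_hit(
        self,
        hit: GenomicInterval,
        gene_id: str,
        tf_name: str,
        sequence: str,
        promoter_window: GenomicInterval,
        cpg_window: int = DEFAULT_CPG_WINDOW,
    ) -> tuple[dict[str, float], set[str]]:
        """Score one hit against every available feature track.

        ``sequence`` is the chromosome sequence the hit's coordinates refer
        to.  Returns (components, absent_features); components holds one
        entry per non-PWM feature, 0.0 where data is missing.
        """
        components: dict[str, float] = {}
        absent: set[str] = set()

        if self.cage is not None and "cage" in self.tables:
            if gene_id in self.cage.peaks:
                components["cage"] = lls_cage(
                    hit, self.cage, gene_id, self.tables["cage"], self.cage_weighting
                )
            else:
                components["cage"] = 0.0
                absent.add("cage")
        else:
            components["cage"] = 0.0
            absent.add("cage")

        if self.correlations is not None:
            components["correlation"] = lls_correlation(
                tf_name, gene_id, self.correlations
            )
        else:
            components["correlation"] = 0.0
            absent.add("correlation")

        if self._meta_idx and "metaclusters" in self.tables:
            starts, ends = self._meta_idx.get(
                hit.chrom, (np.array([]), np.array([]))
            )
            components["metaclusters"] = lls_metaclusters(
                hit, starts, ends, self.tables["metaclusters"]
            )
        else:
            components["metaclusters"] = 0.0
            absent.add("metaclusters")

        if self.atac is not None and "atac" in self.tables:
            in_window = [p for p in self.atac if p.overlaps(promoter_window)]
            if in_window:
                components["atac"] = lls_atac(hit, in_window, self.tables["atac"])
            else:
                components["atac"] = 0.0
                absent.add("atac")
        else:
            components["atac"] = 0.0
            absent.add("atac")

        if self.eqtls is not None and "eqtl" in self.tables:
            components["eqtl"] = lls_eqtl(hit, self.eqtls, self.tables["eqtl"])
        else:
            components["eqtl"] = 0.0
            absent.add("eqtl")

        if "cpg" in self.tables:
            center = (hit.start + hit.end) // 2
            ratio = cpg_ratio(sequence, center, cpg_window)
            components["cpg"] = lls_cpg(ratio, self.tables["cpg"])
        else:
            components["cpg"] = 0.0
            absent.add("cpg")

        if self._cons_idx and "conservation" in self.tables:
            starts, ends = self._cons_idx.get(hit.chrom, (np.array([]), np.array([])))
            if starts.size:
                components["conservation"] = lls_conservation(
                    hit, starts, ends, self.tables["conservation"]
                )
            else:
                components["conservation"] = 0.0
                absent.add("conservation")
        else:
            components["conservation"] = 0.0
            absent.add("conservation")

        return components, absent
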