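"""Position weight matrices, promoter scanning, and PWM score p-values.

A PFM (counts) becomes a PWM of log2 likelihood ratios against a background
nucleotide model:

    weight(nuc, i) = log2( ((a_i + b/4) / (S + b)) / p_bg(nuc) )

with pseudocount b (default 0.8).  The binding score of a window is the sum of
the addressed cells; the null distribution of that score under the background
model is computed exactly by per-position convolution on a fixed-width score
grid, giving an upper-tail p-value P(X >= score) for every scanned window.
Both strands are scanned; windows containing N are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import ConfigurationError, GenomicInterval, PfmRecord

NUCLEOTIDES = "ACGT"
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_SCORE_GRID = 1e-3  # bits; approximation knob for the p-value lattice

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and any other character (N) as 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class BackgroundModel:
    """Background nucleotide frequencies in A, C, G, T order."""

    freq: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (4,):
            raise ValueError("background must have exactly 4 frequencies")
        if np.any(freq <= 0) or np.any(freq >= 1):
            raise ValueError("background frequencies must lie in (0, 1)")
        if abs(freq.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1 within 1e-9")
        object.__setattr__(self, "freq", freq)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def human(cls) -> "BackgroundModel":
        """Human-genome nucleotide composition (A=T=0.295, C=G=0.205)."""
        return cls(np.array([0.295, 0.205, 0.205, 0.295]))

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[float],
        length: float | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "BackgroundModel":
        """Build from background-sequence nucleotide counts.

        Each raw frequency is (n_nuc + b) / (l_bg + b); the four values are
        then normalised so they sum to exactly 1.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (4,):
            raise ValueError("need counts for exactly A, C, G, T")
        l_bg = float(counts.sum()) if length is None else float(length)
        raw = (counts + pseudocount) / (l_bg + pseudocount)
        return cls(raw / raw.sum())

    @classmethod
    def from_sequences(cls, seqs: Sequence[str]) -> "BackgroundModel":
        counts = np.zeros(4)
        for seq in seqs:
            codes = encode_sequence(seq)
            counts += np.bincount(codes[codes < 4], minlength=4)
        return cls.from_counts(counts)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2 likelihood-ratio weights (bits), rows A, C, G, T."""

    tf_name: str
    weights: np.ndarray
    pseudocount: float
    background: BackgroundModel

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 4:
            raise ValueError("weights must be a 4 x L matrix")
        if not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", weights)

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def rc_weights(self) -> np.ndarray:
        """Weights for scoring the minus strand in plus-strand coordinates."""
        return self.weights[::-1, ::-1]


@dataclass(frozen=True)
class MotifHit:
    """One retained PWM hit, in coordinates of the scanned sequence."""

    tf_name: str
    start: int
    end: int
    strand: str
    sequence: str
    pwm_score: float
    pwm_pvalue: float

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("hit interval length must equal matched sequence length")
        if not (0.0 < self.pwm_pvalue <= 1.0):
            raise ValueError("pwm_pvalue must lie in (0, 1]")


def build_pwm(
    pfm: PfmRecord,
    background: BackgroundModel | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PositionWeightMatrix:
    """Turn a PFM into a PWM of log2 likelihood ratios against ``background``."""
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    if background is None:
        background = BackgroundModel.human()
    probs = (pfm.counts + pseudocount / 4.0) / (pfm.n_sequences + pseudocount)
    weights = np.log2(probs / background.freq[:, None])
    return PositionWeightMatrix(pfm.tf_name, weights, pseudocount, background)


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Score one window (must be exactly motif-length, ACGT only)."""
    codes = encode_sequence(window)
    if codes.shape[0] != pwm.length:
        raise ValueError(
            f"window length {codes.shape[0]} != motif length {pwm.length}"
        )
    if np.any(codes == 4):
        raise ValueError("window contains N; caller should skip it")
    return float(pwm.weights[codes, np.arange(pwm.length)].sum())


def _window_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every window of ``codes``; windows containing N come back NaN."""
    L = weights.shape[1]
    padded = np.vstack([weights, np.full((1, L), np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return padded[windows, np.arange(L)].sum(axis=1)


class ScoreDistribution:
    """Exact discretised null distribution of PWM window scores.

    Computed by convolving the four per-position cell values, weighted by the
    background frequencies, on a lattice of ``grid`` bits.  ``pvalue`` returns
    the upper tail P(X >= score) with scores snapped to the nearest lattice
    point.
    """

    def __init__(self, pwm: PositionWeightMatrix, grid: float = DEFAULT_SCORE_GRID):
        if grid <= 0:
            raise ConfigurationError("score grid width must be positive")
        self.grid = grid
        self.tf_name = pwm.tf_name
        bg = pwm.background.freq
        keys = np.rint(pwm.weights / grid).astype(np.int64)
        offset = 0
        probs = np.array([1.0])
        for j in range(pwm.length):
            col = keys[:, j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(probs.size + hi - lo)
            for nuc in range(4):
                shift = int(col[nuc]) - lo
                new[shift : shift + probs.size] += probs * bg[nuc]
            probs = new
            offset += lo
        self.offset = offset  # lattice index of the minimum score
        self.probs = probs
        # sf[i] = P(X >= offset + i grid); clipped so p-values stay in (0, 1]
        self.sf = np.minimum(np.cumsum(probs[::-1])[::-1], 1.0)
        total = probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"score distribution mass {total} != 1")

    @property
    def support(self) -> np.ndarray:
        return (self.offset + np.arange(self.probs.size)) * self.grid

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        """Upper-tail p-values P(X >= score); NaN scores give NaN."""
        scores = np.asarray(scores, dtype=float)
        nan_mask = np.isnan(scores)
        safe = np.where(nan_mask, 0.0, scores)
        idx = np.rint(safe / self.grid).astype(np.int64) - self.offset
        idx = np.clip(idx, 0, self.sf.size - 1)
        out = self.sf[idx]
        out = np.where(nan_mask, np.nan, out)
        return out

    def pvalue(self, score: float) -> float:
        return float(self.pvalues(np.array([score]))[0])


def pwm_score_distribution(
    pwm: PositionWeightMatrix,
    background: BackgroundModel | None = None,
    grid: float = DEFAULT_SCORE_GRID,
) -> ScoreDistribution:
    """Null score distribution of ``pwm`` under its (or an explicit) background."""
    if background is not None and background is not pwm.background:
        pwm = PositionWeightMatrix(
            pwm.tf_name, pwm.weights, pwm.pseudocount, background
        )
    return ScoreDistribution(pwm, grid=grid)


def pwm_pvalue(score: float, distribution: ScoreDistribution) -> float:
    """P(X >= score) under the PWM's null score distribution."""
    return distribution.pvalue(score)


def scan_sequence(
    pwm: PositionWeightMatrix,
    sequence: str,
    pvalue_threshold: float = 0.01,
    distribution: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan both strands of ``sequence``; keep hits with p-value <= threshold.

    Positions are 0-based relative to ``sequence``.  Minus-strand hits are
    reported at their plus-strand interval with the matched sequence given as
    the scanned (reverse-complemented) text.
    """
    if not 0.0 < pvalue_threshold <= 1.0:
        raise ConfigurationError("pvalue_threshold must lie in (0, 1]")
    L = pwm.length
    if len(sequence) < L:
        warnings.warn(
            f"sequence shorter than motif {pwm.tf_name} ({len(sequence)} < {L})",
            stacklevel=2,
        )
        return []
    if distribution is None:
        distribution = ScoreDistribution(pwm)
    codes = encode_sequence(sequence.upper())
    hits: list[MotifHit] = []
    from .genome_io import reverse_complement

    for strand, weights in (("+", pwm.weights), ("-", pwm.rc_weights)):
        scores = _window_scores(weights, codes)
        pvals = distribution.pvalues(scores)
        keep = np.flatnonzero(~np.isnan(pvals) & (pvals <= pvalue_threshold))
        for pos in keep:
            matched = sequence[pos : pos + L].upper()
            if strand == "-":
                matched = reverse_complement(matched)
            hits.append(
                MotifHit(
                    tf_name=pwm.tf_name,
                    start=int(pos),
                    end=int(pos) + L,
                    strand=strand,
                    sequence=matched,
                    pwm_score=float(scores[pos]),
                    pwm_pvalue=float(pvals[pos]),
                )
            )
    hits.sort(key=lambda h: (-h.pwm_score, h.strand != "+", h.start))
    return hits
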