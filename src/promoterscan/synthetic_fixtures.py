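"""Synthetic genomes, promoters, motif implants, and feature tracks.

The generator emulates the statistical structure the scoring model relies on:
a random genome of configurable GC content carrying transcripts with 1,000 bp
promoters; motif instances implanted at chosen promoter positions; and
feature tracks (CAGE peaks with tag counts, ChIP metaclusters, ATAC peaks,
eQTLs with effect magnitudes, conserved elements, TF-gene expression
correlations, RNA-Seq-like coverage) whose elements fall near implant sites
with a controlled enrichment probability and uniformly otherwise.  Every
output is reproducible bit-for-bit under a fixed seed, and file emission
writes exactly the text formats the readers consume plus a sidecar JSON
recording the generating parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import genome_io
from .empirical_likelihood import (
    CagePeakSet,
    CorrelationTable,
    EmpiricalScoreTable,
    FeatureTracks,
    build_cpg_table,
    build_distance_table,
    build_overlap_table,
    build_tail_table,
)
from .genome_io import (
    ConfigurationError,
    CoverageSegment,
    GenomicInterval,
    PfmRecord,
    TranscriptModel,
)

NUCLEOTIDES = np.array(list("ACGT"))

DEFAULT_ENRICHMENT = {
    "cage": 0.9,
    "metaclusters": 0.9,
    "atac": 0.9,
    "eqtl": 0.9,
    "conservation": 0.9,
}


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    genome_length: int = 100_000
    gc_fraction: float = 0.41
    n_transcripts: int = 20
    chrom: str = "chr1"
    promoter_before: int = 900
    promoter_after: int = 100
    motif_consensus: str = "TGACGTCA"
    motif_dominant_count: float = 85.0
    motif_other_count: float = 5.0
    enrichment: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENT)
    )
    enrichment_radius: int = 25
    n_cage_per_gene: int = 3
    n_metaclusters: int = 300
    n_atac: int = 150
    n_eqtls: int = 150
    n_conservation: int = 250
    n_background_correlations: int = 400
    correlation_cutoff: float = 0.3

    def __post_init__(self) -> None:
        for name, e in self.enrichment.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"enrichment for {name} outside [0, 1]: {e}")


def make_test_pfm(
    name: str, consensus: str, dominant: float = 85.0, other: float = 5.0
) -> PfmRecord:
    """An informative PFM whose columns put ``dominant`` counts on the
    consensus base and ``other`` on each alternative."""
    counts = np.full((4, len(consensus)), other)
    for i, base in enumerate(consensus.upper()):
        counts["ACGT".index(base), i] = dominant
    return PfmRecord(name, counts, float(counts[:, 0].sum()))


def sample_motif(pfm: PfmRecord, rng: np.random.Generator) -> str:
    """Draw one motif instance from the PFM's per-column frequencies."""
    probs = pfm.counts / pfm.counts.sum(axis=0)
    return "".join(
        str(rng.choice(NUCLEOTIDES, p=probs[:, j])) for j in range(pfm.length)
    )


def generate_genome(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """An i.i.d. genome at the stated GC fraction plus spaced transcripts."""
    if spec.genome_length < 1000:
        raise ConfigurationError("genome length must be at least 1 kb")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(NUCLEOTIDES, size=spec.genome_length, p=p))
    genome = {spec.chrom: seq}
    transcripts: list[TranscriptModel] = []
    if spec.n_transcripts:
        window = spec.promoter_before + spec.promoter_after
        margin = window + 100
        usable = spec.genome_length - 2 * margin
        if usable < (spec.n_transcripts - 1) * (window + 100) and spec.n_transcripts > 1:
            raise ConfigurationError(
                f"cannot place {spec.n_transcripts} transcripts with "
                f"{window} bp promoters in a {spec.genome_length} bp genome"
            )
        positions = (
            margin
            + np.arange(spec.n_transcripts)
            * (usable // max(spec.n_transcripts - 1, 1))
            if spec.n_transcripts > 1
            else np.array([spec.genome_length // 2])
        )
        for i, tss in enumerate(positions):
            strand = "+" if i % 2 == 0 else "-"
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"tx_{i}",
                    chrom=spec.chrom,
                    tss=int(tss),
                    strand=strand,
                    gene_id=f"gene_{i}",
                )
            )
    return genome, transcripts


def implant_motifs(
    genome: Mapping[str, str],
    motif: PfmRecord | str,
    positions: Sequence[tuple[str, int]],
    strand_policy: str = "forward",
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Write motif instances into the genome at the given positions.

    ``motif`` is a PFM (instances sampled per implant) or a consensus string
    (written verbatim).  ``strand_policy`` is ``forward``, ``reverse`` or
    ``random``.  Overlapping implants are an error.
    """
    if strand_policy not in ("forward", "reverse", "random"):
        raise ConfigurationError(f"unknown strand policy {strand_policy!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    length = motif.length if isinstance(motif, PfmRecord) else len(motif)
    ordered = sorted(positions)
    for (c1, p1), (c2, p2) in zip(ordered, ordered[1:]):
        if c1 == c2 and p2 < p1 + length:
            raise ConfigurationError(
                f"overlapping implants at {c1}:{p1} and {c2}:{p2}"
            )
    out = {chrom: list(seq) for chrom, seq in genome.items()}
    implanted: list[GenomicInterval] = []
    for chrom, pos in positions:
        if pos < 0 or pos + length > len(out[chrom]):
            raise ConfigurationError(f"implant at {chrom}:{pos} is out of bounds")
        instance = (
            sample_motif(motif, rng) if isinstance(motif, PfmRecord) else motif.upper()
        )
        strand = strand_policy
        if strand == "random":
            strand = "forward" if rng.random() < 0.5 else "reverse"
        if strand == "reverse":
            instance = genome_io.reverse_complement(instance)
        out[chrom][pos : pos + length] = instance
        implanted.append(
            GenomicInterval(chrom, pos, pos + length, "+" if strand == "forward" else "-")
        )
    return {chrom: "".join(chars) for chrom, chars in out.items()}, implanted


def _place_elements(
    n: int,
    width: int,
    enrichment: float,
    radius: int,
    implants: Sequence[GenomicInterval],
    chrom: str,
    genome_length: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Place ``n`` elements; a fraction ``enrichment`` near implant centers."""
    out: list[GenomicInterval] = []
    implant_centers = [
        (iv.start + iv.end) // 2 for iv in implants if iv.chrom == chrom
    ]
    for _ in range(n):
        if implant_centers and rng.random() < enrichment:
            center = implant_centers[int(rng.integers(len(implant_centers)))]
            offset = int(rng.integers(-radius, radius + 1))
            start = center + offset - width // 2
        else:
            start = int(rng.integers(0, genome_length - width))
        start = min(max(start, 0), genome_length - width)
        out.append(GenomicInterval(chrom, start, start + width))
    return sorted(out, key=lambda iv: iv.start)


@dataclass
class TrackBundle:
    """Raw generated track elements plus the assembled FeatureTracks."""

    tracks: FeatureTracks
    cage_records: list[tuple[str, GenomicInterval, float]]
    metaclusters: list[GenomicInterval]
    atac: list[GenomicInterval]
    eqtls: list[GenomicInterval]
    conservation: list[GenomicInterval]
    correlation_records: list[tuple[str, str, float, float | None]]
    coverage: list[CoverageSegment]


def generate_tracks(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    implants: Sequence[GenomicInterval],
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    tf_names: Sequence[str] = ("TF_A",),
) -> TrackBundle:
    """Feature tracks spatially enriched at implant sites, plus their tables.

    eQTL magnitudes are |Normal(0, 1)|; background correlations are
    Uniform(-1, 1) filtered at |c| >= cutoff; TF-gene pairs whose promoter
    carries an implant get a strong correlation (|c| in [0.5, 0.95]).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    chrom = spec.chrom
    length = len(genome[chrom])
    lengths = {c: len(s) for c, s in genome.items()}
    e = spec.enrichment

    # CAGE: peaks near each gene's TSS, with the enriched fraction pulled to
    # an implant inside that gene's promoter when one exists
    cage = CagePeakSet()
    cage_records: list[tuple[str, GenomicInterval, float]] = []
    for tx in transcripts:
        for _ in range(spec.n_cage_per_gene):
            promoter_implants = [
                iv
                for iv in implants
                if iv.chrom == tx.chrom and abs(((iv.start + iv.end) // 2) - tx.tss) <= 1000
            ]
            if promoter_implants and rng.random() < e.get("cage", 0.0):
                anchor = promoter_implants[int(rng.integers(len(promoter_implants)))]
                center = (anchor.start + anchor.end) // 2 + int(
                    rng.integers(-spec.enrichment_radius, spec.enrichment_radius + 1)
                )
            else:
                center = tx.tss + int(rng.integers(-150, 151))
            width = int(rng.integers(10, 30))
            start = min(max(center - width // 2, 0), length - width)
            iv = GenomicInterval(tx.chrom, start, start + width)
            count = float(rng.integers(1, 100))
            cage.add(tx.gene_id, iv, count)
            cage_records.append((tx.gene_id, iv, count))

    metaclusters = _place_elements(
        spec.n_metaclusters, 40, e.get("metaclusters", 0.0),
        spec.enrichment_radius, implants, chrom, length, rng,
    )
    atac = _place_elements(
        spec.n_atac, 60, e.get("atac", 0.0),
        spec.enrichment_radius, implants, chrom, length, rng,
    )
    conservation = _place_elements(
        spec.n_conservation, 30, e.get("conservation", 0.0),
        spec.enrichment_radius, implants, chrom, length, rng,
    )
    eqtl_pos = _place_elements(
        spec.n_eqtls, 1, e.get("eqtl", 0.0),
        spec.enrichment_radius, implants, chrom, length, rng,
    )
    magnitudes = np.abs(rng.normal(0.0, 1.0, size=len(eqtl_pos)))
    eqtls = [
        GenomicInterval(iv.chrom, iv.start, iv.end, ".", float(m))
        for iv, m in zip(eqtl_pos, magnitudes)
    ]

    # correlations: strong pairs for genes whose promoter carries an implant
    correlation_records: list[tuple[str, str, float, float | None]] = []
    implanted_genes = set()
    for tx in transcripts:
        for iv in implants:
            if iv.chrom == tx.chrom and abs(((iv.start + iv.end) // 2) - tx.tss) <= 1000:
                implanted_genes.add(tx.gene_id)
    for tf in tf_names:
        for gene in sorted(implanted_genes):
            c = float(rng.uniform(0.5, 0.95)) * (1 if rng.random() < 0.8 else -1)
            correlation_records.append((tf, gene, c, None))
    n_bg = 0
    while n_bg < spec.n_background_correlations:
        c = float(rng.uniform(-1.0, 1.0))
        if abs(c) < spec.correlation_cutoff:
            continue
        correlation_records.append((f"bgTF_{n_bg}", f"bg_gene_{n_bg}", c, None))
        n_bg += 1
    correlations = CorrelationTable.from_records(
        correlation_records, cutoff=spec.correlation_cutoff
    )

    # RNA-Seq-like coverage: rectangular bumps over each gene's TSS
    coverage: list[CoverageSegment] = []
    occupied: list[tuple[int, int]] = []
    for tx in transcripts:
        width = int(rng.integers(15, 40))
        start = max(tx.tss - width // 2, 0)
        end = min(start + width, length)
        if any(s < end and start < e_ for s, e_ in occupied):
            continue
        occupied.append((start, end))
        coverage.append(
            CoverageSegment(
                GenomicInterval(tx.chrom, start, end), float(rng.integers(6, 60))
            )
        )
    coverage.sort(key=lambda s: (s.interval.chrom, s.interval.start))

    tables = {
        "metaclusters": build_overlap_table(metaclusters, lengths),
        "atac": build_distance_table(atac, lengths, feature="atac"),
        "eqtl": build_tail_table(magnitudes, "upper_tail", feature="eqtl"),
        "cpg": build_cpg_table(genome),
        "conservation": build_distance_table(
            conservation, lengths, feature="conservation"
        ),
    }
    if cage.all_intervals():
        tables["cage"] = build_distance_table(
            cage.all_intervals(), lengths, feature="cage"
        )
    else:
        cage = None
    tracks = FeatureTracks(
        cage=cage,
        metaclusters=metaclusters,
        atac=atac,
        eqtls=eqtls,
        conservation=conservation,
        correlations=correlations,
        tables=tables,
    )
    return TrackBundle(
        tracks=tracks,
        cage_records=cage_records,
        metaclusters=metaclusters,
        atac=atac,
        eqtls=eqtls,
        conservation=conservation,
        correlation_records=correlation_records,
        coverage=coverage,
    )


@dataclass
class BenchmarkFixture:
    """Everything the verified-site and ChIP-peak protocols consume."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    pfm: PfmRecord
    verified_sites: dict[str, list[tuple[GenomicInterval, TranscriptModel]]]
    chip_peaks: dict[str, list[GenomicInterval]]
    tracks: FeatureTracks
    spec: FixtureSpec


def generate_benchmark_fixture(
    spec: FixtureSpec | None = None,
    n_tp: int = 20,
    tf_names: Sequence[str] = ("TF_A",),
    seed: int | None = None,
) -> BenchmarkFixture:
    """A genome whose true-positive promoters carry motif implants.

    One implant is placed inside each of ``n_tp`` transcript promoters per
    TF (instances sampled from the fixture PFM); feature tracks are enriched
    at the implants.  ChIP-mode peaks are centered on implants with scores
    that track the implanted instance's match to the consensus.
    """
    if spec is None:
        spec = FixtureSpec()
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    if n_tp > spec.n_transcripts:
        raise ConfigurationError("n_tp cannot exceed the number of transcripts")
    rng = np.random.default_rng(spec.seed)
    genome, transcripts = generate_genome(spec, rng)
    pfm = make_test_pfm(
        tf_names[0], spec.motif_consensus,
        spec.motif_dominant_count, spec.motif_other_count,
    )
    verified: dict[str, list[tuple[GenomicInterval, TranscriptModel]]] = {}
    chip: dict[str, list[GenomicInterval]] = {}
    all_implants: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for tf in tf_names:
        chosen = transcripts[:n_tp]
        positions: list[tuple[str, int]] = []
        for tx in chosen:
            for _ in range(100):  # avoid overlapping earlier implants
                offset = int(rng.integers(-700, 40))  # TSS-relative implant site
                pos = (
                    tx.tss + offset
                    if tx.strand == "+"
                    else tx.tss - offset - pfm.length
                )
                taken = occupied.setdefault(tx.chrom, [])
                if all(
                    pos + pfm.length <= s or pos >= e for s, e in taken
                ):
                    taken.append((pos, pos + pfm.length))
                    positions.append((tx.chrom, pos))
                    break
            else:
                raise ConfigurationError(
                    f"could not place a non-overlapping implant near {tx.transcript_id}"
                )
        genome, implants = implant_motifs(genome, pfm, positions, "forward", rng)
        all_implants.extend(implants)
        verified[tf] = list(zip(implants, chosen))
        peaks = []
        for rank, iv in enumerate(implants):
            jitter = int(rng.integers(-10, 11))
            half = int(rng.integers(30, 120))
            center = (iv.start + iv.end) // 2 + jitter
            peaks.append(
                GenomicInterval(
                    iv.chrom,
                    max(center - half, 0),
                    center + half,
                    ".",
                    float(len(implants) - rank),
                )
            )
        chip[tf] = peaks
    bundle = generate_tracks(genome, transcripts, all_implants, spec, rng, tf_names)
    return BenchmarkFixture(
        genome=genome,
        transcripts=transcripts,
        pfm=pfm,
        verified_sites=verified,
        chip_peaks=chip,
        tracks=bundle.tracks,
        spec=spec,
    )


@dataclass
class CalibrationCorpus:
    """Background promoters plus un-enriched tracks for p-value calibration."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    tracks: FeatureTracks
    pfm: PfmRecord
    spec: FixtureSpec


def generate_calibration_corpus(
    n_promoters: int = 200, seed: int = 0, spec: FixtureSpec | None = None
) -> CalibrationCorpus:
    """``n_promoters`` 1,000 bp background promoters with uniform tracks."""
    if spec is None:
        window = 1000
        spec = FixtureSpec(
            seed=seed,
            genome_length=max(100_000, n_promoters * (window + 200) + 4000),
            n_transcripts=n_promoters,
            enrichment={k: 0.0 for k in DEFAULT_ENRICHMENT},
        )
    rng = np.random.default_rng(spec.seed)
    genome, transcripts = generate_genome(spec, rng)
    pfm = make_test_pfm(
        "TF_A", spec.motif_consensus,
        spec.motif_dominant_count, spec.motif_other_count,
    )
    bundle = generate_tracks(genome, transcripts, [], spec, rng, ("TF_A",))
    return CalibrationCorpus(genome, transcripts, bundle.tracks, pfm, spec)


def write_fixture_files(
    outdir: str | Path,
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    bundle: TrackBundle,
    spec: FixtureSpec,
    pfm: PfmRecord | None = None,
) -> dict[str, Path]:
    """Emit every track as the text format its reader consumes.

    Returns the mapping of logical name to file path; a sidecar JSON records
    the generating parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "genome.fasta"
    genome_io.write_fasta(genome, paths["fasta"])
    paths["gtf"] = outdir / "transcripts.gtf"
    genome_io.write_transcripts_gtf(
        transcripts, paths["gtf"], length=spec.promoter_before + spec.promoter_after
    )
    paths["cage"] = outdir / "cage_peaks.bed"
    with open(paths["cage"], "w") as handle:
        for gene, iv, count in bundle.cage_records:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\t{repr(count)}\t.\n"
            )
    paths["metaclusters"] = outdir / "metaclusters.bed"
    genome_io.write_intervals(bundle.metaclusters, paths["metaclusters"], "meta")
    paths["atac"] = outdir / "atac_peaks.bed"
    genome_io.write_intervals(bundle.atac, paths["atac"], "atac")
    paths["conservation"] = outdir / "conserved_elements.bed"
    genome_io.write_intervals(bundle.conservation, paths["conservation"], "cons")
    paths["eqtls"] = outdir / "eqtls.tsv"
    genome_io.write_eqtls(bundle.eqtls, paths["eqtls"])
    paths["correlations"] = outdir / "correlations.tsv"
    genome_io.write_correlation_pairs(bundle.correlation_records, paths["correlations"])
    paths["coverage"] = outdir / "coverage.bedgraph"
    genome_io.write_bedgraph(bundle.coverage, paths["coverage"])
    if pfm is not None:
        paths["pfms"] = outdir / "motifs.jaspar"
        genome_io.write_jaspar_pfms([pfm], paths["pfms"])
    paths["spec"] = outdir / "fixture_spec.json"
    payload = dataclasses.asdict(spec)
    payload["files"] = {k: str(v.name) for k, v in paths.items() if k != "spec"}
    paths["spec"].write_text(json.dumps(payload, indent=2))
    return paths
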