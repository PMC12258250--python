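import numpy as np
import pytest

from promoterscan.benchmark import (
    evaluate_combinations,
    make_true_positive_regions,
    promoter_bounds,
    sample_true_negatives,
    score_sites,
)
from promoterscan.genome_io import PfmRecord
from promoterscan.motif_scoring import BackgroundModel, build_pwm
from promoterscan.synthetic_fixtures import (
    generate_benchmark_fixture,
    generate_calibration_corpus,
)

BENCH_SEED = 7
CALIBRATION_SEED = 3


@pytest.fixture(scope="session")
def toy_pfm() -> PfmRecord:
    """The single-column PFM from the worked scoring example (A=3, C=1)."""
    return PfmRecord("toy", np.array([[3.0], [1.0], [0.0], [0.0]]), 4.0)


@pytest.fixture(scope="session")
def uniform_background() -> BackgroundModel:
    return BackgroundModel.uniform()


@pytest.fixture(scope="session")
def bench_fixture():
    """Benchmark fixture: motif implants in TP promoters, enriched tracks."""
    return generate_benchmark_fixture(seed=BENCH_SEED)


def build_benchmark_sites(fixture, n_tn=50, width=50, seed=BENCH_SEED):
    """TP regions on the implants plus sampled TNs, for every TF."""
    lengths = {c: len(s) for c, s in fixture.genome.items()}
    rng = np.random.default_rng(seed)
    sites = []
    for tf, pairs in fixture.verified_sites.items():
        tps = []
        tp_regions = []
        for iv, tx in pairs:
            tp = make_true_positive_regions([iv], width, tf, lengths)[0]
            tp.transcript_id, tp.gene_id = tx.transcript_id, tx.gene_id
            tps.append((tp, tx))
            tp_regions.append(tp.region)
        for tp, tx in tps:
            bounds = promoter_bounds(tx, 2000, 2000, lengths[tx.chrom])
            sites.append(tp)
            sites.extend(
                sample_true_negatives(
                    tp, bounds, n=n_tn, seed=rng, tp_regions=tp_regions
                )
            )
    return sites


@pytest.fixture(scope="session")
def bench_sites(bench_fixture):
    sites = build_benchmark_sites(bench_fixture)
    pwms = {
        tf: build_pwm(bench_fixture.pfm) for tf in bench_fixture.verified_sites
    }
    score_sites(sites, bench_fixture.genome, bench_fixture.tracks, pwms)
    return sites


@pytest.fixture(scope="session")
def bench_evaluation(bench_sites):
    return evaluate_combinations(bench_sites)


@pytest.fixture(scope="session")
def calibration_corpus():
    return generate_calibration_corpus(n_promoters=200, seed=CALIBRATION_SEED)
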