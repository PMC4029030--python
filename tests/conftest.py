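import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from svrescore import pipeline
from svrescore.errors import estimate_error_profile, sample_concordant_pairs
from svrescore.simulate import SimConfig, make_benchmark


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """The default simulated benchmark, scored end-to-end once per session.

    200 kb genome, one 2 kb segmental duplication at 95% identity, three
    implanted deletions and three decoy candidates joining homologous
    duplication positions, 30x coverage, 100 bp reads, insert 300 +/- 30,
    seed 7.  The error profile is estimated from 2500 concordant pairs
    (5000 reads) sampled from the benchmark's own BAM.
    """
    outdir = tmp_path_factory.mktemp("benchmark")
    cfg = SimConfig(seed=7)
    paths, truth = make_benchmark(cfg, outdir)
    pairs = sample_concordant_pairs(paths.bam, n=2500, seed=7)
    profile = estimate_error_profile(pairs, _fasta(paths.fasta))
    results = pipeline.rescore(paths.bedpe, paths.bam, paths.fasta, profile, mode="full")
    return {
        "cfg": cfg,
        "paths": paths,
        "truth": truth,
        "profile": profile,
        "results": results,
    }


def _fasta(path):
    import pyfaidx

    return pyfaidx.Fasta(str(path))


@pytest.fixture
def flat_profile():
    """A flat 1% mismatch / 0.1% indel profile over 100 cycles."""
    import numpy as np

    from svrescore.errors import ErrorProfile

    return ErrorProfile(
        np.full(100, 0.01), np.full(100, 0.001), n_reads_sampled=10_000, floor=5e-5
    )
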