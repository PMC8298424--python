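import numpy as np
import pytest

import rloopmap as rl


@pytest.fixture(scope="session")
def truth():
    """Default stated-world annotation, seed 1."""
    return rl.generate_annotation(rl.TruthConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run (seed 1), shared by the acceptance
    and pipeline tests."""
    return rl.run_pipeline(rl.RunConfig(truth=rl.TruthConfig(seed=1)))


@pytest.fixture
def small_genome():
    return rl.GenomeModel(("chrI", "chrII"), (10_000, 5_000))


def random_intervals(rng, n, chrom_names=("chrI",), max_pos=10_000,
                     max_len=500, stranded=True):
    """Shared helper for property tests on small instances."""
    out = []
    for _ in range(n):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        strand = ["+", "-", "."][rng.integers(3)] if stranded else "."
        out.append(rl.Interval(chrom, start, start + length, strand))
    return out
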