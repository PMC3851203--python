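from __future__ import annotations

import numpy as np
import pytest

from epienrich import (
    ClassSpec,
    GenomicInterval,
    RegionSet,
    SyntheticStudySpec,
    TrackSpec,
    generate_study,
)


def random_region_set(
    rng: np.random.Generator,
    n: int,
    label: str = "set",
    role: str = "query",
    n_chroms: int = 2,
    genome_len: int = 1000,
    max_len: int = 60,
) -> RegionSet:
    """Small random interval set for oracle comparisons."""
    ivs = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, genome_len - 1))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, min(start + length, genome_len), f"{label}_{i}"))
    return RegionSet(label, ivs, role=role)


@pytest.fixture(scope="session")
def small_study():
    """A compact 4-class x 5-track study with planted effects, shared
    across tests that only need a realistic fitted object."""
    spec = SyntheticStudySpec(
        genome=(("chr1", 4_000_000), ("chr2", 2_000_000)),
        classes=(
            ClassSpec("alpha", 600, 30, 100, 300),
            ClassSpec("beta", 500, 30, 100, 300),
            ClassSpec("gamma", 800, 30, 100, 300),
            ClassSpec("delta", 400, 30, 100, 300),
        ),
        tracks=(
            TrackSpec("t1", 150, 0.20),
            TrackSpec("t2", 120, 0.15),
            TrackSpec("t3", 100, 0.10),
            TrackSpec("t4", 90, 0.25),
            TrackSpec("t5", 80, 0.05),
        ),
        effects={("alpha", "t1"): 2.5, ("beta", "t2"): 0.3, ("gamma", "t3"): 3.0},
        seed=2024,
    )
    return generate_study(spec)


@pytest.fixture(scope="session")
def small_results(small_study):
    from epienrich import RegionEnrichment

    model = RegionEnrichment.from_study(small_study)
    return model.fit(n_samplings=300, seed=7)
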