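import numpy as np
import pytest

from screg.intervals import GenomicInterval, PeakSet


def brute_force_pair_count(a: PeakSet, b: PeakSet) -> int:
    """O(n*m) nested-loop oracle for pair-overlap counting."""
    return sum(1 for x in a for y in b if x.overlaps(y))


def random_peakset(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_pos: int = 100_000,
    max_width: int = 500,
) -> PeakSet:
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return PeakSet(out)


@pytest.fixture(scope="session")
def toy_world():
    """One shared small planted world; tests must not mutate it."""
    from screg.simulate import make_toy_world

    return make_toy_world(
        n_cell_types=3, cells_per_type=50, peaks_per_dataset=300, seed=11
    )


@pytest.fixture(scope="session")
def toy_activity(toy_world):
    from screg.enrichment import score_activity

    return score_activity(toy_world.cells, toy_world.index, knn=10, seed=11)
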