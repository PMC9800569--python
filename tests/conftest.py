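from __future__ import annotations

import numpy as np
import pytest

from hrdscar.genome import Chromosome, GenomeAssembly
from hrdscar.segments import Segment, SegmentProfile


@pytest.fixture(scope="session")
def sim_assembly() -> GenomeAssembly:
    """Small 3-chromosome genome matching the simulator's default."""
    from hrdscar.simulate import default_assembly

    return default_assembly()


@pytest.fixture(scope="session")
def toy_assembly() -> GenomeAssembly:
    """Single 100 Mb chromosome with a centromere at 45-55 Mb."""
    return GenomeAssembly(
        build_label="toy",
        chromosomes=(Chromosome("1", 100_000_000, 45_000_000, 55_000_000),),
    )


def build_profile(rows, sample_id="S1", purity=None) -> SegmentProfile:
    """Profile from (chrom, start, end, major, minor) tuples."""
    return SegmentProfile(
        sample_id=sample_id,
        segments=tuple(Segment(str(c), int(s), int(e), int(a), int(b))
                       for c, s, e, a, b in rows),
        purity=purity,
    )


@pytest.fixture
def make_profile():
    return build_profile


def random_profile(rng: np.random.Generator, assembly: GenomeAssembly,
                   max_segments_per_chromosome: int = 15,
                   sample_id: str = "R") -> SegmentProfile:
    """Random valid profile: per chromosome, up to ``max_segments`` tiled
    segments with mixed bp-to-Mb scales, random gaps and random states."""
    rows = []
    for spec in assembly.chromosomes:
        n = int(rng.integers(0, max_segments_per_chromosome + 1))
        pos = int(rng.integers(1, 5_000_000))
        for _ in range(n):
            scale = rng.random()
            if scale < 0.15:
                length = int(rng.integers(10, 200))  # sub-smoothing fragments
            elif scale < 0.5:
                length = int(rng.integers(200, 5_000_000))
            else:
                length = int(rng.integers(5_000_000, 60_000_000))
            end = pos + length - 1
            if end > spec.length_bp:
                break
            major = int(rng.integers(0, 4))
            minor = int(rng.integers(0, major + 1))
            rows.append((spec.name, pos, end, major, minor))
            gap = 0 if rng.random() < 0.5 else int(rng.integers(1, 2_000_000))
            pos = end + 1 + gap
    return SegmentProfile(
        sample_id=sample_id,
        segments=tuple(Segment(*r) for r in rows),
    )


@pytest.fixture
def random_profile_factory(sim_assembly):
    def factory(seed: int, **kwargs) -> SegmentProfile:
        return random_profile(np.random.default_rng(seed), sim_assembly, **kwargs)

    return factory
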