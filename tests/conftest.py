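from pathlib import Path

import pytest

from hrdscar.genome import GenomeModel, ChromosomeSpec
from hrdscar.segments import Segment, SegmentProfile

DATA = Path(__file__).parent / "data"

MB = 1_000_000


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def one_chrom_genome() -> GenomeModel:
    """Single 200 Mb chromosome with centromere at 90–95 Mb."""
    return GenomeModel.from_specs([ChromosomeSpec("chr1", 200 * MB, 90 * MB, 95 * MB)])


def make_profile(states, chrom="chr1", sample_id="S1"):
    """Build a profile from (start_mb, end_mb, total_cn, minor_cn) tuples."""
    segs = [
        Segment(chrom, int(s * MB), int(e * MB), t, m) for s, e, t, m in states
    ]
    return SegmentProfile(sample_id, tuple(segs))
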