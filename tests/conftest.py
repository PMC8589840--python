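import numpy as np
import pandas as pd
import pytest

from rtgloh import GenomeLayout, GenotypeTrack, MarkerMap


@pytest.fixture
def toy_layout():
    """One 10 kb chromosome, centromere mid, no masks."""
    return GenomeLayout(
        lengths={"chrT": 10_000},
        centromeres={"chrT": (5_000, 5_100)},
    )


@pytest.fixture
def toy_map():
    """Nine markers on chrT, four per arm plus none inside the centromere."""
    pos = [100, 1_000, 2_000, 4_000, 6_000, 7_000, 8_000, 9_000, 9_900]
    return MarkerMap(
        pd.DataFrame(
            {
                "chrom": "chrT",
                "pos": pos,
                "allele1": "A",
                "allele2": "C",
            }
        )
    )


def make_track(codes, clone="clone"):
    return GenotypeTrack(clone, np.asarray(codes, dtype=np.int8))


@pytest.fixture
def make_map():
    def _make(positions, chrom="chrT"):
        return MarkerMap(
            pd.DataFrame(
                {"chrom": chrom, "pos": positions, "allele1": "A", "allele2": "C"}
            )
        )

    return _make
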