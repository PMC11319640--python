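import numpy as np
import pytest

from mosaicstr import PCR_FREE, StutterParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def low_error_theta():
    return StutterParams(u=0.01, d=0.01, rho=0.9)


@pytest.fixture
def pcr_free_theta():
    return PCR_FREE


@pytest.fixture
def str_reference(tmp_path):
    """Synthetic reference FASTA: 600 bp flanks around a 10x ACG tract.

    Returns (path, chrom, tract_start, tract_end, motif) with 1-based
    inclusive tract coordinates.
    """
    rng = np.random.default_rng(777)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, size=600))
    right = "".join(rng.choice(bases, size=600))
    motif = "ACG"
    tract = motif * 10
    # avoid accidental motif runs at the junctions
    left = left[:-3] + "TTT"
    right = "TTT" + right[3:]
    seq = left + tract + right
    path = tmp_path / "ref.fa"
    path.write_text(f">chrT\n{seq}\n")
    return path, "chrT", 601, 600 + len(tract), motif
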