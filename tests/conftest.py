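import numpy as np
import pytest

from cnvbeast import CutoffParams, ProbeTrack


def make_track(y, spacing=50, chrom="chr1"):
    y = np.asarray(y, dtype=float)
    return ProbeTrack(chrom, spacing * np.arange(1, y.size + 1), y)


@pytest.fixture
def params_s1():
    """Default cutoff structure with a low score threshold for small fixtures."""
    return CutoffParams(score_min=1.0)


@pytest.fixture
def noiseless_cnv_track():
    """30 probes, a +0.6 CNV on probes 11-20, zero elsewhere."""
    y = np.zeros(30)
    y[10:20] = 0.6
    return make_track(y)
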