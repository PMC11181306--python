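from __future__ import annotations

import numpy as np
import pytest

from panplastome.structure import PlastomeSequence, revcomp
from panplastome.variants import AlignmentMatrix

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def aln(*rows: tuple[str, str], ref_index: int = 0) -> AlignmentMatrix:
    return AlignmentMatrix.from_sequences(list(rows), ref_index=ref_index)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240603)


@pytest.fixture
def toy_quadripartite(rng):
    """Planted 500 (LSC) + 120 (IRb) + 90 (SSC) + revcomp(IRb) toy genome."""
    lsc = random_seq(rng, 500)
    ir = random_seq(rng, 120)
    ssc = random_seq(rng, 90)
    genome = lsc + ir + ssc + revcomp(ir)
    return PlastomeSequence("toy", genome), (lsc, ir, ssc)


@pytest.fixture
def small_simulation():
    from panplastome.synthetic_data import SimulationConfig, simulate_population

    cfg = SimulationConfig(
        seed=11,
        n_clusters=3,
        samples_per_cluster=(4, 4, 4),
        within_cluster_extra_snvs=(2, 0, 1),
    )
    return simulate_population(cfg)
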