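import numpy as np
import pytest

import rescue


def make_toy_model(extra: float = 0.0) -> rescue.PottsModel:
    """L=3 two-state model ('A','B') with J[0,1](A,A)=1.0, J[0,2](A,A)=0.5
    plus symmetric partners; ``extra`` adds J[0,2](A,B)=extra (and partner),
    which lets a one-letter change raise the coupling strength."""
    L, q = 3, 2
    J = np.zeros((L, L, q, q))
    J[0, 1, 0, 0] = J[1, 0, 0, 0] = 1.0
    J[0, 2, 0, 0] = J[2, 0, 0, 0] = 0.5
    if extra:
        J[0, 2, 0, 1] = J[2, 0, 1, 0] = extra
    return rescue.PottsModel(np.zeros((L, q)), J, "AB", provenance="synthetic")


@pytest.fixture
def toy_model() -> rescue.PottsModel:
    return make_toy_model()


@pytest.fixture(scope="session")
def recovery_benchmark():
    """The default inference-recovery benchmark: L=30, q=8, 20 coupled
    pairs, M=5000 sequences, fixed seed (shared across tests: expensive)."""
    bench = rescue.make_benchmark(30, 8, 20, M=5000, seed=11)
    aln = rescue.compute_weights(bench.alignment)
    model = rescue.infer_potts(aln)
    return bench, model


PSSM_TEXT = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down

            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -3  -4  -2  -1  -3  -3  -2   1   2  -2   8   0  -3  -2  -1  -2  -1   1
    2 K    -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1  -1  -1  -4  -2  -3
    3 V     0  -3  -3  -4  -1  -3  -3  -4  -4   3   1  -3   1  -1  -3  -2   0  -3  -1   4
    4 S     1  -1   1   0  -1   0   0   0  -1  -3  -3   0  -2  -3  -1   4   1  -3  -2  -2
    5 W    -3  -3  -4  -5  -3  -2  -3  -3  -3  -3  -2  -3  -2   1  -4  -3  -3  11   2  -3
"""


@pytest.fixture
def pssm_file(tmp_path):
    p = tmp_path / "query.pssm"
    p.write_text(PSSM_TEXT)
    return p
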