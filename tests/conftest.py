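import numpy as np
import pytest

from alnbench.align_io import AA20, Alignment
from alnbench.conservation import SubstitutionModel, default_model
from alnbench.synthetic import BlockSpec, FamilySpec, generate


@pytest.fixture(scope="session")
def model() -> SubstitutionModel:
    return default_model()


def random_alignment(
    rng: np.random.Generator, n_seqs: int, n_cols: int, gap_frac: float = 0.2
) -> Alignment:
    """A random gapped alignment (every sequence keeps >= 1 residue and
    every column is non-empty where possible)."""
    seqs = []
    for r in range(n_seqs):
        chars = [
            "-" if rng.random() < gap_frac else AA20[rng.integers(20)]
            for _ in range(n_cols)
        ]
        if all(c == "-" for c in chars):
            chars[rng.integers(n_cols)] = AA20[rng.integers(20)]
        seqs.append("".join(chars))
    return Alignment(
        tuple(f"s{r}" for r in range(n_seqs)), tuple(seqs)
    )


@pytest.fixture(scope="session")
def small_truth():
    """A clean one-subfamily family with three conserved blocks."""
    spec = FamilySpec(
        subfamily_sizes=(8,),
        blocks=(
            BlockSpec(20, (0,), 0.9),
            BlockSpec(24, (0,), 0.9),
            BlockSpec(16, (0,), 0.85),
        ),
        seed=42,
        linker_length=12,
        linker_jitter=2,
    )
    return generate(spec)
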