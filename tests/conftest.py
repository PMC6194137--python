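import numpy as np
import pytest

from haplopop.simulate import SimConfig, simulate_matrix
from haplopop.types import GenotypeMatrix, SampleRecord, VariantRecord


def make_matrix(
    calls,
    positions=None,
    scaffold="s1",
    populations=None,
    behaviors=None,
    n_outgroup=0,
    quals=None,
    refs=None,
    alts=None,
):
    """Build a small GenotypeMatrix from plain arrays for hand-constructed tests."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    quals = quals if quals is not None else [100.0] * m
    refs = refs if refs is not None else ["A"] * m
    alts = alts if alts is not None else [("T",)] * m
    variants = [
        VariantRecord(
            scaffold=scaffold if isinstance(scaffold, str) else scaffold[j],
            pos=int(positions[j]),
            ref_allele=refs[j],
            alt_alleles=tuple(alts[j]),
            qual=float(quals[j]),
        )
        for j in range(m)
    ]
    n_in = n - n_outgroup
    populations = populations if populations is not None else ["p1"] * n_in
    behaviors = behaviors if behaviors is not None else ["social"] * n_in
    samples = [
        SampleRecord(f"ind{i}", populations[i], behaviors[i], False) for i in range(n_in)
    ] + [
        SampleRecord(f"out{i}", "outgroup", "unknown", True) for i in range(n_outgroup)
    ]
    return GenotypeMatrix(calls, variants, samples)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation shared across tests (seed fixed)."""
    cfg = SimConfig(seed=11)
    gm, truth = simulate_matrix(cfg)
    return cfg, gm, truth
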