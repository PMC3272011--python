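import numpy as np
import pandas as pd
import pytest

from frceval import (
    ANALYSIS_COLUMNS,
    Assembly,
    Contig,
    CountingConfig,
    FeatureCountTable,
)


def random_toy_assembly(rng, max_contigs=20, max_count=5):
    """A small assembly plus a random per-contig count table, for oracles."""
    n = int(rng.integers(1, max_contigs + 1))
    contigs = [
        Contig(f"c{i:02d}", int(rng.integers(10, 1000))) for i in range(n)
    ]
    cfg = CountingConfig()
    counts = pd.DataFrame(
        rng.integers(0, max_count + 1, size=(n, len(ANALYSIS_COLUMNS))),
        index=pd.Index([c.id for c in contigs], name="contig_id"),
        columns=list(ANALYSIS_COLUMNS),
    )
    asm = Assembly(label="toy", contigs=contigs)
    return asm, FeatureCountTable(counts=counts, config=cfg)


def frc_prefix_oracle(assembly, per_contig_counts, phi, genome_size):
    """Exhaustive prefix enumeration: longest size-sorted prefix whose
    cumulative count is <= phi."""
    order = sorted(assembly.contigs, key=lambda c: (-c.length, c.id))
    best_len = 0
    acc_count = 0
    acc_len = 0
    for c in order:
        acc_count += per_contig_counts[c.id]
        acc_len += c.length
        if acc_count <= phi:
            best_len = acc_len
        else:
            break
    return best_len / genome_size


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
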