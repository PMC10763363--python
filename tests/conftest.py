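import numpy as np
import pandas as pd
import pytest

from dvburst.containers import CountTable
from dvburst.genome import GeneModel, GenomicInterval, TadDomain, Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """3 genes x 6 samples, 3 conditions x 2 replicates."""
    samples = [f"{c}_rep{r}" for c in ("A", "B", "C") for r in (1, 2)]
    counts = pd.DataFrame(
        [[10, 12, 20, 22, 30, 33], [5, 6, 5, 6, 5, 6], [100, 90, 10, 12, 11, 10]],
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    condition_of = {s: s.split("_")[0] for s in samples}
    replicate_of = {s: int(s[-1]) for s in samples}
    return CountTable(counts, condition_of, replicate_of)


@pytest.fixture
def plus_gene():
    cds = GenomicInterval("chr2L", 1200, 4200, "+", "tA_cds0")
    return GeneModel("geneA", "chr2L", 1000, "+", (Transcript("tA", (cds,)),))


@pytest.fixture
def minus_gene():
    cds = GenomicInterval("chr2L", 3000, 5800, "-", "tB_cds0")
    return GeneModel("geneB", "chr2L", 6000, "-", (Transcript("tB", (cds,)),))


@pytest.fixture
def toy_tads():
    return [
        TadDomain(GenomicInterval("chr2L", 0, 10_000, ".", "tad_0"), "tad_0"),
        TadDomain(GenomicInterval("chr2L", 10_000, 20_000, ".", "tad_1"), "tad_1"),
    ]
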