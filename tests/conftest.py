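import numpy as np
import pytest

from ctxatac.intervals import GenomicInterval
from ctxatac.simulate import SimulationConfig, simulate_study


def random_intervals(rng, n, chrom_len=100_000, max_width=500, chroms=("chr1",)):
    """Uniform random intervals on a toy chromosome set."""
    out = []
    for i in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - max_width))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(c, start, start + width, f"iv{i}"))
    return out


@pytest.fixture(scope="session")
def small_study():
    """One shared small synthetic study (expensive stages reuse it)."""
    cfg = SimulationConfig(
        seed=11, n_peaks=300, n_genes=120, n_hic_pairs=40,
        n_panel_blocks=40, n_gwas_leads=12, n_ai_variants=100,
        qc_reads_per_library=1000,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
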