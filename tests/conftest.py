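import numpy as np
import pytest

from xdrive.pooled_popgen import PoolInfo, SyncSiteTable

TABLE1_FREQS = (0.86526, 0.13455, 0.00004, 0.00015)  # ST, SR, BM, T gametes


def make_sync_table(freq1, freq2, depth=50, sizes=(8, 8), seed=0, outgroup=None):
    """Sync table from explicit per-site allele-1 frequencies for two pools.

    freq1/freq2 are the allele 'A' sample frequencies per site; reads are
    binomial at the given depth, the alternative allele is 'G'.
    """
    rng = np.random.default_rng(seed)
    n = len(freq1)
    counts = np.zeros((n, 2, 6), dtype=np.int64)
    for i, (f1, f2) in enumerate(zip(freq1, freq2)):
        for j, f in enumerate((f1, f2)):
            a = rng.binomial(depth, f)
            counts[i, j, 0] = a          # A
            counts[i, j, 3] = depth - a  # G
    return SyncSiteTable(
        chrom=np.array(["chr1"] * n),
        pos=np.arange(1, n + 1, dtype=np.int64),
        ref=np.array(["A"] * n),
        counts=counts,
        pools=[PoolInfo("p1", sizes[0]), PoolInfo("p2", sizes[1])],
        outgroup=None if outgroup is None else np.array(outgroup),
    )


def make_exact_sync_table(counts_per_site, sizes=(8, 8), outgroup=None):
    """Sync table with literal (n_sites, n_pools, 6) counts."""
    counts = np.array(counts_per_site, dtype=np.int64)
    n = counts.shape[0]
    return SyncSiteTable(
        chrom=np.array(["chr1"] * n),
        pos=np.arange(1, n + 1, dtype=np.int64),
        ref=np.array(["A"] * n),
        counts=counts,
        pools=[PoolInfo("p1", sizes[0]), PoolInfo("p2", sizes[1])],
        outgroup=None if outgroup is None else np.array(outgroup),
    )


@pytest.fixture(scope="session")
def table1_freqs():
    return TABLE1_FREQS
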