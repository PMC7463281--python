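"""Synthetic-data generators for every pipeline stage.

Each generator is deterministic given (seed, parameters) and returns the
data object a pipeline stage consumes together with a truth record, so
estimator accuracy can be measured against known ground truth without any
external sequencing data. Pooled count tables are driven by the internal
coalescent, so the data generator and the neutrality test share one
stochastic model; progeny and survey generators are simple multinomial
draws at the experimental designs' sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import DemographyScenario, _simulate_tree
from .ld import HaplotypePanel
from .mapstats import ProgenyTable
from .pooled_popgen import ALLELES, PoolInfo, SyncSiteTable

__all__ = [
    "sim_pooled_counts",
    "sim_haplotype_panel",
    "sim_testcross_progeny",
    "sim_segregation_counts",
    "sim_survey_sample",
]


def _haplotypes_from_tree(rng, scenario, positions_per_mutation=True):
    """Simulate one non-recombining locus; return (hap matrix, positions, groups).

    Rows are sampled chromosomes (outgroup, then ST, then SR); columns are
    segregating sites with 0 = ancestral, 1 = derived. Sites are assigned
    distinct positions uniformly along the locus.
    """
    gen, leaves = _simulate_tree(rng, scenario)
    n_nodes = len(gen.time)
    n_leaves = scenario.n_outgroup + scenario.n_st + scenario.n_sr
    # leaves under each node
    below = [set() for _ in range(n_nodes)]
    for li in range(n_leaves):
        below[li].add(li)
    for node in np.argsort(gen.time):
        p = gen.parent[node]
        if p is not None:
            below[p] |= below[node]
    theta = scenario.mutation_rate * scenario.locus_length
    cols, carriers = [], []
    for node in range(n_nodes):
        p = gen.parent[node]
        if p is None:
            continue
        muts = rng.poisson(theta * (gen.time[p] - gen.time[node]))
        for _ in range(muts):
            carriers.append(below[node])
    hap = np.zeros((n_leaves, len(carriers)), dtype=np.int8)
    for j, who in enumerate(carriers):
        hap[list(who), j] = 1
    pos = np.sort(rng.choice(scenario.locus_length, size=len(carriers), replace=False)) + 1 \
        if len(carriers) <= scenario.locus_length else None
    if pos is None:
        raise ValueError("more mutations than sites; increase locus length or lower mutation rate")
    return hap, pos, leaves


def sim_pooled_counts(
    scenario: DemographyScenario | None = None,
    depth: int = 50,
    n_windows: int = 1,
    chrom: str = "XR_sim",
    include_invariant: bool = True,
    outgroup_as_pool: bool = False,
    seed: int | None = None,
) -> tuple[SyncSiteTable, dict]:
    """Pooled sync counts for an SR pool, an ST pool, and an outgroup allele.

    Each window is an independent non-recombining locus simulated under
    the demographic scenario; the pooled chromosomes are the simulated ST
    and SR samples, and read counts are binomial draws at the configured
    depth from each pool's true sample frequency. The outgroup allele is
    the single sampled outgroup chromosome's base; with
    ``outgroup_as_pool`` the outgroup sample is additionally emitted as a
    third read pool, so focal and calibration comparisons share the same
    windows. The truth record holds the per-site sample frequencies, each
    site's classification, and the per-window true sample heterozygosity.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if scenario is None:
        scenario = DemographyScenario()
    rng = np.random.default_rng(seed)
    L = scenario.locus_length
    pools = [PoolInfo("ST", scenario.n_st, "ST"), PoolInfo("SR", scenario.n_sr, "SR")]
    if outgroup_as_pool:
        pools.append(PoolInfo("OG", scenario.n_outgroup, "OG"))

    rows_chrom, rows_pos, rows_ref, rows_counts, og_alleles = [], [], [], [], []
    truth_sites = []
    truth_windows = []
    for w in range(n_windows):
        hap, pos, leaves = _haplotypes_from_tree(rng, scenario)
        st_idx = np.array(leaves["st"])
        sr_idx = np.array(leaves["sr"])
        og_idx = np.array(leaves["outgroup"])
        offset = w * L
        # ancestral/derived bases per segregating site
        anc = rng.choice(len(ALLELES), size=hap.shape[1])
        der = (anc + rng.integers(1, 4, size=hap.shape[1])) % 4
        seg_at = {int(p): j for j, p in enumerate(pos)}
        group_idx = {"ST": st_idx, "SR": sr_idx}
        if outgroup_as_pool:
            group_idx["OG"] = og_idx
        freq = {name: hap[idx].mean(axis=0) for name, idx in group_idx.items()}
        og_state = hap[og_idx[0]]

        positions = range(1, L + 1) if include_invariant else sorted(seg_at)
        het_sum = {"ST": 0.0, "SR": 0.0}
        for p in positions:
            j = seg_at.get(p)
            site_counts = np.zeros((len(pools), 6), dtype=np.int64)
            if j is None:
                base = rng.integers(0, 4)
                site_counts[:, base] = depth
                og_alleles.append(ALLELES[base])
                ref = ALLELES[base]
            else:
                a_i, d_i = int(anc[j]), int(der[j])
                for gi, name in enumerate(group_idx):
                    f = freq[name][j]
                    nd = rng.binomial(depth, f)
                    site_counts[gi, d_i] = nd
                    site_counts[gi, a_i] = depth - nd
                og_alleles.append(ALLELES[d_i] if og_state[j] else ALLELES[a_i])
                ref = ALLELES[a_i]
                n_st, n_sr = scenario.n_st, scenario.n_sr
                f_st, f_sr = freq["ST"][j], freq["SR"][j]
                het_sum["ST"] += 2 * f_st * (1 - f_st) * n_st / (n_st - 1)
                het_sum["SR"] += 2 * f_sr * (1 - f_sr) * n_sr / (n_sr - 1)
                truth_sites.append(
                    {"chrom": chrom, "pos": offset + p, "window": w,
                     "freq_ST": f_st, "freq_SR": f_sr,
                     "ancestral": ALLELES[a_i], "derived": ALLELES[d_i],
                     "outgroup_derived": bool(og_state[j])}
                )
            rows_chrom.append(chrom)
            rows_pos.append(offset + p)
            rows_ref.append(ref)
            rows_counts.append(site_counts)
        truth_windows.append(
            {"window": w, "start": offset + 1, "end": offset + L,
             "pi_ST": het_sum["ST"] / L, "pi_SR": het_sum["SR"] / L}
        )

    table = SyncSiteTable(
        chrom=np.array(rows_chrom),
        pos=np.array(rows_pos, dtype=np.int64),
        ref=np.array(rows_ref),
        counts=np.array(rows_counts),
        pools=pools,
        outgroup=np.array(og_alleles),
    )
    truth = {
        "sites": pd.DataFrame(truth_sites),
        "windows": pd.DataFrame(truth_windows),
        "scenario": scenario,
    }
    return table, truth


def sim_haplotype_panel(
    n_per_arrangement: int = 8,
    regions: int = 2,
    length: int = 400,
    n_fixed: int = 5,
    n_shared: int = 5,
    n_singleton: int = 3,
    n_indel: int = 2,
    seed: int | None = None,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Aligned haplotype panel with known column classes per region.

    Columns are drawn without overlap: arrangement-fixed (all SR strains
    carry one base, all ST the other), shared polymorphisms (a random
    subset of strains in both arrangements carries the variant), singleton
    columns, and indel columns (one strain gets a gap). The truth sidecar
    lists each placed column's class and coordinate.
    """
    rng = np.random.default_rng(seed)
    panel = HaplotypePanel()
    bases = np.array(list("ACGT"))
    n = 2 * n_per_arrangement
    names = [f"ST{i+1}" for i in range(n_per_arrangement)] + \
            [f"SR{i+1}" for i in range(n_per_arrangement)]
    arrs = ["ST"] * n_per_arrangement + ["SR"] * n_per_arrangement
    truth_rows = []
    for r in range(regions):
        region = f"R{r+1}"
        ref = bases[rng.integers(0, 4, size=length)]
        seqs = np.tile(ref, (n, 1))
        n_special = n_fixed + n_shared + n_singleton + n_indel
        cols = rng.choice(length, size=n_special, replace=False)
        it = iter(cols)
        for _ in range(n_fixed):
            j = next(it)
            alt = bases[(np.flatnonzero(bases == ref[j])[0] + rng.integers(1, 4)) % 4]
            seqs[n_per_arrangement:, j] = alt
            truth_rows.append({"region": region, "column": int(j), "class": "fixed"})
        for _ in range(n_shared):
            j = next(it)
            alt = bases[(np.flatnonzero(bases == ref[j])[0] + rng.integers(1, 4)) % 4]
            # at least two carriers spread over both arrangements
            carriers = np.concatenate([
                rng.choice(n_per_arrangement, size=rng.integers(1, n_per_arrangement), replace=False),
                n_per_arrangement + rng.choice(n_per_arrangement, size=rng.integers(1, n_per_arrangement), replace=False),
            ])
            seqs[carriers, j] = alt
            truth_rows.append({"region": region, "column": int(j), "class": "shared"})
        for _ in range(n_singleton):
            j = next(it)
            alt = bases[(np.flatnonzero(bases == ref[j])[0] + rng.integers(1, 4)) % 4]
            seqs[rng.integers(0, n), j] = alt
            truth_rows.append({"region": region, "column": int(j), "class": "singleton"})
        for _ in range(n_indel):
            j = next(it)
            seqs[rng.integers(0, n), j] = "-"
            truth_rows.append({"region": region, "column": int(j), "class": "indel"})
        panel.add_region(region, names, arrs, ["".join(s) for s in seqs],
                         chrom="XR_sim", start=1 + r * length)
    return panel, pd.DataFrame(truth_rows)


TESTCROSS_CLASSES = ("parental_SR", "parental_ST", "recombinant_T", "recombinant_BM")


def sim_testcross_progeny(
    n: int,
    c: float,
    viability: tuple[float, float] = (1.0, 1.0),
    seed: int | None = None,
) -> tuple[ProgenyTable, dict]:
    """Multinomial testcross progeny with recombination fraction c.

    Parental classes occur at (1-c)/2 each and the two reciprocal
    recombinant classes at c/2 each, optionally reweighted by relative
    recombinant viabilities (e.g. an asymmetry factor of 0 reproduces a
    one-sided recombinant deficit). Truth records the generating c.
    """
    if n < 1:
        raise ValueError("progeny count must be >= 1")
    if not 0 <= c <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    probs = np.array([(1 - c) / 2, (1 - c) / 2, c / 2 * viability[0], c / 2 * viability[1]])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    table = ProgenyTable("testcross", TESTCROSS_CLASSES, tuple(int(x) for x in counts))
    return table, {"c": c, "viability": viability, "probs": probs}


def sim_segregation_counts(
    n: int, k: float, seed: int | None = None
) -> tuple[ProgenyTable, dict]:
    """Binomial(n, k) daughters from a segregation assay of one male genotype."""
    if n < 1:
        raise ValueError("progeny count must be >= 1")
    if not 0 <= k <= 1:
        raise ValueError("k must be in [0, 1]")
    rng = np.random.default_rng(seed)
    females = int(rng.binomial(n, k))
    table = ProgenyTable("segregation", ("female", "male"), (females, n - females))
    return table, {"k": k}


def sim_survey_sample(
    n: int, freqs, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Multinomial survey of n chromosomes over the four haplotype classes.

    ``freqs`` is (SR, BM, T, ST); returns a one-row survey table with
    observed frequencies alongside the generating truth.
    """
    if n < 1:
        raise ValueError("survey size must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1) > 5e-5:
        raise ValueError("frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, freqs / freqs.sum())
    obs = counts / n
    df = pd.DataFrame(
        [{"study": "synthetic", "n": n, "freq_SR": obs[0], "freq_BM": obs[1],
          "freq_T": obs[2], "freq_ST": obs[3]}]
    )
    return df, {"freqs": freqs, "counts": counts}
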