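"""Three-lineage neutral coalescent for an inversion polymorphism.

Simulates the genealogy of samples from an outgroup species, the standard
(ST) arrangement, and the inverted (SR) arrangement of an X chromosome,
treating the inversion as a non-recombining locus. Backward in time SR and
ST are separate populations until the inversion's origin, when every
surviving SR lineage is forced to coalesce into the single founder
chromosome sampled from the parental population; the merged lineage then
coalesces in the parental population until the species split with the
outgroup. Infinite-sites mutation on the resulting tree yields per-group
diversity statistics, and the distribution of the ST/SR diversity ratio
under neutrality gives an empirical test for whether an observed reduction
in SR diversity is compatible with drift alone.

All effective sizes are multiplied by 3/4 exactly once, at scenario
construction, to account for X hemizygosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DemographyScenario",
    "ReplicateSummary",
    "simulate_neutral_replicates",
    "simulate_single_population",
    "neutrality_test",
    "tajimas_d_from_counts",
]


@dataclass(frozen=True)
class DemographyScenario:
    """Demographic parameters of the three-lineage neutral model.

    Sizes are haploid-equivalent effective sizes *before* the X correction;
    times are in generations before present. The ST size is the total
    species size minus the SR share, so the species total is conserved
    across the SR-fraction scenarios.
    """

    total_ne: float = 1.8e6
    sr_fraction: float = 0.135
    outgroup_ne: float = 3.6e5
    origin_time: float = 2e6
    split_time: float = 4e6
    x_correction: float = 0.75
    mutation_rate: float = 3.5e-9
    locus_length: int = 10_000
    n_outgroup: int = 1
    n_st: int = 8
    n_sr: int = 8
    founder_event: bool = True

    def __post_init__(self):
        if not 0 < self.sr_fraction < 1:
            raise ValueError("SR fraction must be in (0, 1)")
        if self.origin_time >= self.split_time:
            raise ValueError("inversion origin must predate the species split (backward)")
        if self.locus_length <= 0:
            raise ValueError("locus length must be positive")
        if min(self.n_outgroup, self.n_st, self.n_sr) < 1:
            raise ValueError("sample sizes must be >= 1")

    @property
    def ne_sr(self) -> float:
        return self.total_ne * self.sr_fraction * self.x_correction

    @property
    def ne_st(self) -> float:
        return self.total_ne * (1 - self.sr_fraction) * self.x_correction

    @property
    def ne_parental(self) -> float:
        return self.total_ne * self.x_correction

    @property
    def ne_outgroup(self) -> float:
        return self.outgroup_ne * self.x_correction


@dataclass
class ReplicateSummary:
    """Diversity summaries of one simulated locus."""

    pi_st: float
    pi_sr: float
    pi_joint: float
    s_st: int
    s_sr: int
    tajimas_d_st: float
    tajimas_d_sr: float

    @property
    def ratio(self) -> float:
        """pi_ST / pi_SR; NaN when SR is devoid of variation."""
        return self.pi_st / self.pi_sr if self.pi_sr > 0 else float("nan")


class _Genealogy:
    """Parent-pointer tree over leaves 0..n-1 with node times."""

    def __init__(self, n_leaves: int):
        self.parent: list[int | None] = [None] * n_leaves
        self.time: list[float] = [0.0] * n_leaves

    def add_node(self, t: float, children: list[int]) -> int:
        node = len(self.time)
        self.time.append(t)
        self.parent.append(None)
        for ch in children:
            self.parent[ch] = node
        return node


def _coalesce_within(rng, lineages: list[int], gen: _Genealogy, t: float, ne: float,
                     t_stop: float) -> float:
    """Coalesce a list of lineages at rate C(k,2)/Ne until t_stop; returns time."""
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2 / ne
        t_next = t + rng.exponential(1 / rate)
        if t_next >= t_stop:
            return t_stop
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        node = gen.add_node(t_next, [a, b])
        lineages[:] = [x for x in lineages if x not in (a, b)] + [node]
        t = t_next
    return t_stop


def _simulate_tree(rng, sc: DemographyScenario) -> tuple[_Genealogy, dict[str, list[int]]]:
    n_total = sc.n_outgroup + sc.n_st + sc.n_sr
    gen = _Genealogy(n_total)
    leaves = {
        "outgroup": list(range(sc.n_outgroup)),
        "st": list(range(sc.n_outgroup, sc.n_outgroup + sc.n_st)),
        "sr": list(range(sc.n_outgroup + sc.n_st, n_total)),
    }
    st = list(leaves["st"])
    sr = list(leaves["sr"])
    og = list(leaves["outgroup"])

    # present -> inversion origin: SR and ST are isolated demes
    _interleave_coalescence(rng, gen, [(st, sc.ne_st), (sr, sc.ne_sr), (og, sc.ne_outgroup)],
                            0.0, sc.origin_time)
    # single-founder origin: all surviving SR lineages join in one node;
    # with founder_event off this is an ordinary population split instead
    if sc.founder_event and len(sr) > 1:
        node = gen.add_node(sc.origin_time, list(sr))
        sr = [node]
    st.extend(sr)
    # origin -> species split: merged lineage coalesces in the parental population
    _interleave_coalescence(rng, gen, [(st, sc.ne_parental), (og, sc.ne_outgroup)],
                            sc.origin_time, sc.split_time)
    # beyond the split: everything in the ancestral (parental-size) population
    anc = st + og
    _coalesce_within(rng, anc, gen, sc.split_time, sc.ne_parental, math.inf)
    return gen, leaves


def _interleave_coalescence(rng, gen, demes, t_start, t_stop):
    """Run independent within-deme coalescence over a fixed interval.

    Each deme's waiting times are exponential with its own rate; because
    the demes are independent, each is advanced separately over the window.
    """
    for lineages, ne in demes:
        t = t_start
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2 / ne
            t_next = t + rng.exponential(1 / rate)
            if t_next >= t_stop:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = lineages[i], lineages[j]
            node = gen.add_node(t_next, [a, b])
            lineages.remove(a)
            lineages.remove(b)
            lineages.append(node)
            t = t_next


def tajimas_d_from_counts(pi_sum: float, s: int, n: int) -> float:
    """Classical Tajima's D from summed pairwise diversity and S at sample size n."""
    if s == 0 or n < 2:
        return float("nan")
    a1 = sum(1 / k for k in range(1, n))
    a2 = sum(1 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi_sum - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def _replicate_summary(rng, sc: DemographyScenario) -> ReplicateSummary:
    gen, leaves = _simulate_tree(rng, sc)
    n_nodes = len(gen.time)
    # leaf-descendant counts per group for every branch (node -> parent edge)
    desc = np.zeros((n_nodes, 2), dtype=np.int64)  # columns: st, sr
    for li in leaves["st"]:
        desc[li, 0] = 1
    for li in leaves["sr"]:
        desc[li, 1] = 1
    # accumulate child counts upward; parents are strictly later in time
    for node in np.argsort(gen.time):
        p = gen.parent[node]
        if p is not None:
            desc[p] += desc[node]

    theta = sc.mutation_rate * sc.locus_length
    pi = {"st": 0.0, "sr": 0.0, "joint": 0.0}
    seg = {"st": 0, "sr": 0}
    n_st, n_sr = sc.n_st, sc.n_sr
    n_joint = n_st + n_sr
    for node in range(n_nodes):
        p = gen.parent[node]
        if p is None:
            continue
        blen = gen.time[p] - gen.time[node]
        muts = rng.poisson(theta * blen)
        if muts == 0:
            continue
        d_st, d_sr = desc[node]
        d_joint = d_st + d_sr
        pi["st"] += muts * d_st * (n_st - d_st)
        pi["sr"] += muts * d_sr * (n_sr - d_sr)
        pi["joint"] += muts * d_joint * (n_joint - d_joint)
        if 0 < d_st < n_st:
            seg["st"] += muts
        if 0 < d_sr < n_sr:
            seg["sr"] += muts

    pair_st = n_st * (n_st - 1) / 2
    pair_sr = n_sr * (n_sr - 1) / 2
    pair_joint = n_joint * (n_joint - 1) / 2
    pi_sum_st = pi["st"] / pair_st if pair_st else 0.0
    pi_sum_sr = pi["sr"] / pair_sr if pair_sr else 0.0
    return ReplicateSummary(
        pi_st=pi_sum_st / sc.locus_length,
        pi_sr=pi_sum_sr / sc.locus_length,
        pi_joint=(pi["joint"] / pair_joint) / sc.locus_length,
        s_st=seg["st"],
        s_sr=seg["sr"],
        tajimas_d_st=tajimas_d_from_counts(pi_sum_st, seg["st"], n_st),
        tajimas_d_sr=tajimas_d_from_counts(pi_sum_sr, seg["sr"], n_sr),
    )


def simulate_neutral_replicates(
    scenario: DemographyScenario, n_reps: int = 100_000, seed: int | None = None
):
    """Yield ReplicateSummary objects for independent neutral loci."""
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        yield _replicate_summary(rng, scenario)


def simulate_single_population(
    n_samples: int, ne: float, mutation_rate: float, locus_length: int,
    n_reps: int, seed: int | None = None
) -> pd.DataFrame:
    """Panmictic control: per-replicate pairwise TMRCA, pi, and S.

    Used for closed-form checks: E[pairwise coalescence time] = Ne and
    E[S] = theta * sum 1/k for a constant-size haploid population.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        gen = _Genealogy(n_samples)
        lineages = list(range(n_samples))
        _coalesce_within(rng, lineages, gen, 0.0, ne, math.inf)
        root = lineages[0]
        times = gen.time
        # pairwise coalescence time for samples 0,1: their MRCA's time
        a, b = 0, 1
        anc_a = set()
        x = a
        while x is not None:
            anc_a.add(x)
            x = gen.parent[x]
        x = b
        while x not in anc_a:
            x = gen.parent[x]
        t2 = times[x]
        theta = mutation_rate * locus_length
        s = 0
        pi_sum = 0.0
        desc = np.zeros(len(times), dtype=np.int64)
        desc[:n_samples] = 1
        for node in np.argsort(times):
            p = gen.parent[node]
            if p is not None:
                desc[p] += desc[node]
        for node in range(len(times)):
            p = gen.parent[node]
            if p is None:
                continue
            muts = rng.poisson(theta * (times[p] - times[node]))
            d = desc[node]
            if 0 < d < n_samples:
                s += muts
            pi_sum += muts * d * (n_samples - d)
        pi_sum /= n_samples * (n_samples - 1) / 2
        rows.append({"t2": t2, "tmrca": times[root], "S": s, "pi_sum": pi_sum})
    return pd.DataFrame(rows)


def neutrality_test(
    observed_ratio: float,
    scenario: DemographyScenario,
    n_reps: int = 2_000,
    seed: int | None = None,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> dict[str, object]:
    """Empirical test of an observed pi_ST/pi_SR reduction against neutrality.

    One-sided by default: p is the proportion of neutral replicates whose
    ST/SR diversity ratio is at most the observed ratio, i.e. whether the
    observed reduction in SR diversity is too *small* to be explained by
    the inversion's recent single-founder origin and low frequency alone.
    Replicates with undefined ratio (pi_SR = 0) are excluded.
    """
    ratios = np.array(
        [r.ratio for r in simulate_neutral_replicates(scenario, n_reps, seed)]
    )
    valid = ratios[~np.isnan(ratios)]
    if len(valid) == 0:
        raise ValueError("all replicate ratios undefined (pi_SR = 0 everywhere)")
    n_le = int((valid <= observed_ratio).sum())
    p = n_le / len(valid)
    if two_sided:
        p = min(1.0, 2 * min(p, 1 - p))
    out = {
        "p_value": p,
        "p_report": f"< {1 / len(valid):.2e}" if n_le == 0 else f"{p:.4g}",
        "n_valid": len(valid),
        "mean_ratio": float(valid.mean()),
        "median_ratio": float(np.median(valid)),
        "reject_at_alpha": p < alpha,
        "alpha": alpha,
    }
    return out
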