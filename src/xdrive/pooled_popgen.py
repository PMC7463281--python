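"""Pool-seq site filtering and window statistics.

Works on sync-format allele-count tables: one row per genomic position,
one ``A:T:C:G:N:del`` count column per pool. Each pool is a set of
haploid X chromosomes sequenced together, so every statistic corrects for
the two layers of sampling in pooled data — chromosomes into the pool and
reads off the chromosomes. Provides the methods-of-moments F_ST for a pool
pair, pooled nucleotide diversity and Tajima's D in physical windows,
absolute divergence d_XY via probabilistic consensus sequences, and
per-site classification into fixed/shared/private categories after
polarization against an outgroup allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PoolInfo",
    "SyncSiteTable",
    "WindowStat",
    "load_sync_table",
    "write_sync_table",
    "read_gff_intervals",
    "read_bed_positions",
    "filter_sites",
    "fst_windows",
    "diversity_windows",
    "dxy",
    "classify_sites",
    "CATEGORIES",
]

ALLELES = ("A", "T", "C", "G")  # sync column order, then N and del
_IDX = {a: i for i, a in enumerate(ALLELES)}


@dataclass(frozen=True)
class PoolInfo:
    """Metadata for one sequenced pool: name, haploid size, arrangement label."""

    name: str
    size: int
    arrangement: str = ""

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("pool size must be >= 1")


@dataclass
class WindowStat:
    """A windowed statistic with an optional bootstrap CI."""

    chrom: str
    start: int
    end: int
    n_sites: int
    stat: str
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    partial: bool = False
    frac_uncallable: float = 0.0
    flags: str = ""


@dataclass
class SyncSiteTable:
    """Per-site nucleotide counts for named pools, plus optional outgroup.

    counts has shape (n_sites, n_pools, 6) in sync order A,T,C,G,N,del.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    pools: list[PoolInfo]
    outgroup: np.ndarray | None = None  # allele per site, "" when absent
    callable_mask: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.pos)
        if self.counts.shape[:2] != (n, len(self.pools)):
            raise ValueError("counts shape does not match sites x pools")
        if n and self.counts.min() < 0:
            raise ValueError("negative allele count")
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        if df.duplicated().any():
            dup = df[df.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup.chrom}:{dup.pos}")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.counts = self.counts[order]
            if self.outgroup is not None:
                self.outgroup = self.outgroup[order]
            if self.callable_mask is not None:
                self.callable_mask = self.callable_mask[order]
        if self.callable_mask is None:
            self.callable_mask = np.ones(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.pos)

    def pool_index(self, name: str) -> int:
        for i, p in enumerate(self.pools):
            if p.name == name:
                return i
        raise KeyError(f"no pool named {name!r}")

    @property
    def acgt(self) -> np.ndarray:
        """Nucleotide counts only, shape (n_sites, n_pools, 4)."""
        return self.counts[:, :, :4]

    @property
    def coverage(self) -> np.ndarray:
        """Nucleotide read depth per site and pool."""
        return self.acgt.sum(axis=2)

    def observed_alleles(self) -> np.ndarray:
        """Boolean (n_sites, 4): allele seen in any pool."""
        return self.acgt.sum(axis=1) > 0

    def n_alleles(self) -> np.ndarray:
        return self.observed_alleles().sum(axis=1)

    def is_variant(self) -> np.ndarray:
        return self.n_alleles() >= 2

    def biallelic_freqs(self, pool_idx) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Frequencies of the (lexicographically first) minor-track allele.

        Returns (freq per site per pool, coverage, allele-pair index array).
        Only meaningful at biallelic sites; other sites yield NaN.
        """
        obs = self.observed_alleles()
        n_all = obs.sum(axis=1)
        first = np.argmax(obs, axis=1)
        counts = self.acgt[:, pool_idx, :]
        cov = counts.sum(axis=-1).astype(float)
        f1 = np.take_along_axis(
            counts, first[:, None, None] if counts.ndim == 3 else first[:, None], axis=-1
        ).squeeze(-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = f1 / cov
        freq = np.where(n_all[:, None] == 2 if freq.ndim == 2 else n_all == 2, freq, np.nan)
        return freq, cov, first


def _parse_count_field(field_str: str, path: str, lineno: int) -> list[int]:
    parts = field_str.split(":")
    if len(parts) != 6:
        raise ValueError(f"{path}:{lineno}: expected 6 ':'-separated counts, got {field_str!r}")
    try:
        return [int(p) for p in parts]
    except ValueError as e:
        raise ValueError(f"{path}:{lineno}: non-numeric count in {field_str!r}") from e


def load_sync_table(
    path, pools: list[PoolInfo], outgroup_pool: str | None = None
) -> SyncSiteTable:
    """Read a sync-format file (chrom, pos, ref, per-pool A:T:C:G:N:del).

    When ``outgroup_pool`` names one of the pools, that column (expected
    haploid size 1) is consumed as the per-site outgroup allele (its
    majority nucleotide) instead of an analysis pool.
    """
    chroms, poss, refs, rows = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(pools):
                raise ValueError(
                    f"{path}:{lineno}: expected {3 + len(pools)} columns, got {len(fields)}"
                )
            chroms.append(fields[0])
            try:
                poss.append(int(fields[1]))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer position {fields[1]!r}") from e
            refs.append(fields[2])
            rows.append([_parse_count_field(f, str(path), lineno) for f in fields[3:]])
    counts = np.array(rows, dtype=np.int64).reshape(len(poss), len(pools), 6)
    table = SyncSiteTable(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        counts=counts,
        pools=list(pools),
    )
    if outgroup_pool is not None:
        gi = table.pool_index(outgroup_pool)
        og_counts = table.acgt[:, gi, :]
        has = og_counts.sum(axis=1) > 0
        alleles = np.array(ALLELES)[np.argmax(og_counts, axis=1)]
        table.outgroup = np.where(has, alleles, "")
        keep = [i for i in range(len(table.pools)) if i != gi]
        table.counts = table.counts[:, keep, :]
        table.pools = [p for i, p in enumerate(table.pools) if i != gi]
    return table


def write_sync_table(table: SyncSiteTable, path) -> None:
    """Write a table back to sync format (outgroup column not included)."""
    with open(path, "w") as fh:
        for i in range(len(table)):
            fields = [str(table.chrom[i]), str(table.pos[i]), str(table.ref[i])]
            for j in range(len(table.pools)):
                fields.append(":".join(str(c) for c in table.counts[i, j]))
            fh.write("\t".join(fields) + "\n")


def read_gff_intervals(path, feature_types=("gene",)) -> pd.DataFrame:
    """Gene-feature intervals (chrom, start, end; 1-based closed) from a GFF."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attr"],
    )
    df = df[df["type"].isin(feature_types)]
    return df[["chrom", "start", "end"]].reset_index(drop=True)


def read_bed_positions(path) -> pd.DataFrame:
    """Positions from a BED file, converted to 1-based (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"])
    rows = []
    for _, r in df.iterrows():
        for p in range(int(r.start) + 1, int(r.end) + 1):
            rows.append((r.chrom, p))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def filter_sites(
    table: SyncSiteTable,
    indel_positions: pd.DataFrame | None = None,
    indel_margin: int = 5,
    coverage_sd: float = 3.0,
    coverage_stats: dict | None = None,
) -> SyncSiteTable:
    """Apply the coverage, indel-proximity, and biallelic callability rules.

    A site is uncallable in the table when, in any pool, nucleotide
    coverage is below that pool's haploid size or above the scaffold mean
    plus ``coverage_sd`` standard deviations (mean/SD per chromosome per
    pool, computed from the table unless supplied). Sites within
    ``indel_margin`` bp of an indel position are masked. Sites showing more
    than two alleles across pools are removed outright.
    """
    if len(table) == 0:
        return table
    cov = table.coverage.astype(float)
    callable_mask = table.callable_mask.copy()

    for ci, chrom in enumerate(pd.unique(table.chrom)):
        on = table.chrom == chrom
        for pi, pool in enumerate(table.pools):
            if coverage_stats and (chrom, pool.name) in coverage_stats:
                mean, sd = coverage_stats[(chrom, pool.name)]
            else:
                mean, sd = cov[on, pi].mean(), cov[on, pi].std()
            bad = (cov[:, pi] < pool.size) | (cov[:, pi] > mean + coverage_sd * sd)
            callable_mask &= ~(on & bad)

    if indel_positions is not None and len(indel_positions):
        for chrom, grp in indel_positions.groupby("chrom"):
            on = table.chrom == chrom
            pos = table.pos
            for p in grp["pos"]:
                callable_mask &= ~(on & (np.abs(pos - p) <= indel_margin))

    keep = table.n_alleles() <= 2
    return SyncSiteTable(
        chrom=table.chrom[keep],
        pos=table.pos[keep],
        ref=table.ref[keep],
        counts=table.counts[keep],
        pools=table.pools,
        outgroup=None if table.outgroup is None else table.outgroup[keep],
        callable_mask=callable_mask[keep],
    )


# ---------------------------------------------------------------------------
# F_ST


def _fst_components(freq: np.ndarray, cov: np.ndarray, sizes: np.ndarray):
    """Per-site ANOVA variance components (a, b) for pooled reads.

    freq, cov: (n_sites, n_pools) read frequency of one allele and depth;
    sizes: haploid pool sizes. Moment equations account for binomial read
    sampling off ``n`` chromosomes: E[p̂(1-p̂)] = b (C-1)(n-1)/(Cn) and
    Var(p̂) = a + b (C+n-1)/(Cn), with a, b the between/within components
    whose ratio-of-sums gives the multilocus F_ST = Σa / Σ(a+b).
    """
    n = sizes[None, :].astype(float)
    C = cov
    Ctot = C.sum(axis=1)
    ssi = (C * freq * (1 - freq)).sum(axis=1)
    b = ssi / ((C - 1) * (n - 1) / n).sum(axis=1)
    pbar = (C * freq).sum(axis=1) / Ctot
    ssp = (C * (freq - pbar[:, None]) ** 2).sum(axis=1)
    beta = (C + n - 1) / (C * n)
    nc = Ctot - (C**2).sum(axis=1) / Ctot
    m = (C * beta).sum(axis=1) - (C**2 * beta).sum(axis=1) / Ctot
    a = (ssp - b * m) / nc
    return a, b


def _site_arrays_for_pair(table: SyncSiteTable, pool_pair) -> tuple[np.ndarray, ...]:
    idx = [table.pool_index(p) if isinstance(p, str) else p for p in pool_pair]
    acgt = table.acgt[:, idx, :]
    cov = acgt.sum(axis=2).astype(float)
    obs = table.observed_alleles()
    first = np.argmax(obs, axis=1)
    cnt1 = np.take_along_axis(acgt, first[:, None, None], axis=2).squeeze(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = cnt1 / cov
    biallelic = table.n_alleles() == 2
    usable = (
        table.callable_mask
        & biallelic
        & (cov > 1).all(axis=1)
    )
    sizes = np.array([table.pools[i].size for i in idx])
    return freq, cov, sizes, usable


def fst_windows(
    table: SyncSiteTable,
    pool_pair,
    window_snps: int = 100,
    n_boot: int = 0,
    seed: int | None = None,
    ci: float = 0.95,
) -> list[WindowStat]:
    """Multilocus pool-seq F_ST in nonoverlapping windows of SNPs.

    The window estimate is the ratio of summed between-pool to total
    variance components (ratio of sums, not mean of ratios). The CI
    resamples SNPs within the window with replacement. Windows whose SNPs
    are all effectively monomorphic get an NA estimate. A trailing window
    with fewer than ``window_snps`` SNPs is reported with partial=True.
    Negative estimates are reported as computed and flagged.
    """
    freq, cov, sizes, usable = _site_arrays_for_pair(table, pool_pair)
    poly = usable & (np.nanmax(freq, axis=1) > 0) & (np.nanmin(freq, axis=1) < 1)
    rng = np.random.default_rng(seed)
    out: list[WindowStat] = []
    for chrom in pd.unique(table.chrom):
        snp_idx = np.flatnonzero(poly & (table.chrom == chrom))
        for w0 in range(0, len(snp_idx), window_snps):
            widx = snp_idx[w0 : w0 + window_snps]
            a, b = _fst_components(freq[widx], cov[widx], sizes)
            denom = (a + b).sum()
            est = a.sum() / denom if denom != 0 else float("nan")
            ws = WindowStat(
                chrom=str(chrom),
                start=int(table.pos[widx[0]]),
                end=int(table.pos[widx[-1]]),
                n_sites=len(widx),
                stat="fst",
                estimate=float(est),
                partial=len(widx) < window_snps,
            )
            if np.isnan(est):
                ws.flags = "na"
            elif est < 0:
                ws.flags = "negative"
            if n_boot and not np.isnan(est):
                reps = np.empty(n_boot)
                for r in range(n_boot):
                    take = rng.integers(0, len(widx), len(widx))
                    ar, br = a[take], b[take]
                    d = (ar + br).sum()
                    reps[r] = ar.sum() / d if d != 0 else np.nan
                lo, hi = np.nanquantile(reps, [(1 - ci) / 2, 1 - (1 - ci) / 2])
                ws.ci_low, ws.ci_high, ws.n_boot = float(lo), float(hi), n_boot
            out.append(ws)
    return out


# ---------------------------------------------------------------------------
# diversity


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1 / k for k in range(1, n))
    a2 = sum(1 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def _intergenic_mask(table: SyncSiteTable, gene_intervals: pd.DataFrame | None) -> np.ndarray:
    if gene_intervals is None or not len(gene_intervals):
        return np.ones(len(table), dtype=bool)
    mask = np.ones(len(table), dtype=bool)
    for _, r in gene_intervals.iterrows():
        mask &= ~((table.chrom == r.chrom) & (table.pos >= r.start) & (table.pos <= r.end))
    return mask


def diversity_windows(
    table: SyncSiteTable,
    pool,
    statistic: str = "pi",
    window_bp: int = 10_000,
    gene_intervals: pd.DataFrame | None = None,
    min_count: int = 2,
    max_uncallable: float = 0.4,
) -> list[WindowStat]:
    """Pooled nucleotide diversity or Tajima's D in physical windows.

    Windows tile each chromosome in ``window_bp`` steps from position 1.
    Only callable sites outside annotated gene features enter the
    calculation; a window is skipped when more than ``max_uncallable`` of
    its in-mask sites are uncallable. Per site, heterozygosity is estimated
    from read frequencies with the read-depth correction C/(C-1) and the
    pool-size correction n/(n-1); alleles whose summed read count across
    the pool is below ``min_count`` are ignored, so a sub-threshold variant
    contributes zero diversity. Tajima's D contrasts the window's summed
    heterozygosity with the segregating-site count using the classical
    constants at the haploid pool size.
    """
    if statistic not in ("pi", "tajimas_d"):
        raise ValueError("statistic must be 'pi' or 'tajimas_d'")
    pi_idx = table.pool_index(pool) if isinstance(pool, str) else pool
    n = table.pools[pi_idx].size
    counts = table.acgt[:, pi_idx, :].astype(float)
    counts = np.where(counts >= min_count, counts, 0.0)
    cov = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / cov[:, None]
        het = 1 - (freqs**2).sum(axis=1)
        het = het * cov / (cov - 1) * n / (n - 1)
    het = np.where(cov > 1, het, 0.0)
    seg = (counts > 0).sum(axis=1) >= 2
    in_mask = _intergenic_mask(table, gene_intervals)
    usable = table.callable_mask & (cov > 1)
    consts = _tajima_constants(n)

    out: list[WindowStat] = []
    for chrom in pd.unique(table.chrom):
        on = table.chrom == chrom
        last = table.pos[on].max()
        for start in range(1, int(last) + 1, window_bp):
            end = start + window_bp - 1
            inw = on & in_mask & (table.pos >= start) & (table.pos <= end)
            n_inw = int(inw.sum())
            if n_inw == 0:
                continue
            ok = inw & usable
            frac_unc = 1 - ok.sum() / n_inw
            if frac_unc > max_uncallable:
                out.append(
                    WindowStat(str(chrom), start, end, 0, statistic, float("nan"),
                               frac_uncallable=float(frac_unc), flags="skipped_uncallable")
                )
                continue
            L = int(ok.sum())
            pi_sum = het[ok].sum()
            if statistic == "pi":
                est = pi_sum / L
                ws = WindowStat(str(chrom), start, end, L, "pi", float(est),
                                frac_uncallable=float(frac_unc))
            else:
                S = int((seg & ok).sum())
                if S == 0:
                    ws = WindowStat(str(chrom), start, end, L, "tajimas_d", float("nan"),
                                    frac_uncallable=float(frac_unc), flags="na")
                else:
                    theta_w = S / consts["a1"]
                    var = consts["e1"] * S + consts["e2"] * S * (S - 1)
                    d = (pi_sum - theta_w) / np.sqrt(var)
                    ws = WindowStat(str(chrom), start, end, L, "tajimas_d", float(d),
                                    frac_uncallable=float(frac_unc))
            out.append(ws)
    return out


# ---------------------------------------------------------------------------
# d_XY


def dxy(
    table: SyncSiteTable,
    pair,
    region: tuple[str, int, int] | None = None,
    n_boot: int = 10_000,
    n_draws: int = 1,
    seed: int | None = None,
    ci: float = 0.95,
) -> dict[str, object]:
    """Absolute divergence between two pools (or a pool and the outgroup).

    Per callable site, each group's consensus base is drawn with
    probability equal to its read frequency (the outgroup contributes its
    single allele); d_XY is the proportion of differing sites. Reported in
    two forms: the seeded draw-based estimate (mean over ``n_draws``
    consensus draws) and the exact expectation over draws,
    sum_s (1 - sum_a p_a q_a) / L. The CI bootstraps sites on the exact
    form.
    """
    rng = np.random.default_rng(seed)
    mask = table.callable_mask.copy()
    if region is not None:
        chrom, start, end = region
        mask &= (table.chrom == chrom) & (table.pos >= start) & (table.pos <= end)

    def group_freqs(g):
        if g == "outgroup":
            if table.outgroup is None:
                raise ValueError("table has no outgroup alleles")
            has = table.outgroup != ""
            f = np.zeros((len(table), 4))
            for a, i in _IDX.items():
                f[table.outgroup == a, i] = 1.0
            return f, has
        gi = table.pool_index(g) if isinstance(g, str) else g
        cnt = table.acgt[:, gi, :].astype(float)
        cov = cnt.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = cnt / cov[:, None]
        return f, cov > 0

    p, ok_p = group_freqs(pair[0])
    q, ok_q = group_freqs(pair[1])
    use = mask & ok_p & ok_q
    L = int(use.sum())
    if L == 0:
        raise ValueError("no callable sites in region")
    per_site = 1 - (p[use] * q[use]).sum(axis=1)
    exact = per_site.mean()

    draws = np.empty(n_draws)
    cp = p[use].cumsum(axis=1)
    cq = q[use].cumsum(axis=1)
    for d in range(n_draws):
        ap = (rng.random(L)[:, None] < cp).argmax(axis=1)
        aq = (rng.random(L)[:, None] < cq).argmax(axis=1)
        draws[d] = (ap != aq).mean()

    boot = rng.choice(per_site, size=(n_boot, L), replace=True).mean(axis=1) if n_boot else None
    lo, hi = (np.quantile(boot, [(1 - ci) / 2, 1 - (1 - ci) / 2]) if n_boot else (np.nan, np.nan))
    return {
        "dxy_expectation": float(exact),
        "dxy_draw": float(draws.mean()),
        "n_sites": L,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# site classification

CATEGORIES = (
    "fixed_derived_pool1",
    "fixed_derived_pool2",
    "shared_polymorphism",
    "private_polymorphism_pool1",
    "private_polymorphism_pool2",
    "monomorphic",
    "unpolarizable",
    "uncallable",
)


def classify_sites(
    table: SyncSiteTable,
    pool_pair,
    window_bp: int = 10_000,
) -> tuple[pd.DataFrame, dict]:
    """Assign each site to a fixed/shared/private category.

    Polarization uses the table's outgroup allele: a between-pool fixed
    difference is 'fixed derived' in the pool whose allele differs from
    the outgroup (the other pool must carry the outgroup allele); when no
    outgroup allele is available, or it matches neither allele, such sites
    are unpolarizable. Polymorphism categories do not require polarization.
    Returns the per-site table and a summary with category counts, the
    fixed-derived:shared ratio per pool, and per-window proportions of
    pool-1 fixed-derived sites.
    """
    i1, i2 = (table.pool_index(p) if isinstance(p, str) else p for p in pool_pair)
    c1 = table.acgt[:, i1, :]
    c2 = table.acgt[:, i2, :]
    cov1, cov2 = c1.sum(axis=1), c2.sum(axis=1)
    og = table.outgroup if table.outgroup is not None else np.array([""] * len(table))

    cats = np.empty(len(table), dtype=object)
    anc = np.empty(len(table), dtype=object)
    for s in range(len(table)):
        anc[s] = og[s] if og[s] else ""
        if not table.callable_mask[s] or cov1[s] == 0 or cov2[s] == 0:
            cats[s] = "uncallable"
            continue
        a1 = {ALLELES[i] for i in np.flatnonzero(c1[s])}
        a2 = {ALLELES[i] for i in np.flatnonzero(c2[s])}
        poly1, poly2 = len(a1) > 1, len(a2) > 1
        if poly1 and poly2:
            cats[s] = "shared_polymorphism"
        elif poly1:
            cats[s] = "private_polymorphism_pool1"
        elif poly2:
            cats[s] = "private_polymorphism_pool2"
        else:
            b1, b2 = next(iter(a1)), next(iter(a2))
            if b1 == b2:
                cats[s] = "monomorphic"
            elif og[s] == b2:
                cats[s] = "fixed_derived_pool1"
            elif og[s] == b1:
                cats[s] = "fixed_derived_pool2"
            else:
                cats[s] = "unpolarizable"

    df = pd.DataFrame(
        {"chrom": table.chrom, "pos": table.pos, "category": cats, "ancestral": anc}
    )
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    shared = counts["shared_polymorphism"]
    summary = {
        "counts": counts,
        "fixed_shared_ratio_pool1": counts["fixed_derived_pool1"] / shared if shared else float("inf"),
        "fixed_shared_ratio_pool2": counts["fixed_derived_pool2"] / shared if shared else float("inf"),
    }
    windows = []
    for chrom in pd.unique(table.chrom):
        on = table.chrom == chrom
        last = int(table.pos[on].max())
        for start in range(1, last + 1, window_bp):
            inw = on & (table.pos >= start) & (table.pos < start + window_bp)
            call = inw & (cats != "uncallable")
            if not call.any():
                continue
            prop = (cats[call] == "fixed_derived_pool1").mean()
            windows.append(
                {"chrom": str(chrom), "start": start, "end": start + window_bp - 1,
                 "n_callable": int(call.sum()), "prop_fixed_derived_pool1": float(prop)}
            )
    summary["windows"] = pd.DataFrame(windows)
    return df, summary
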