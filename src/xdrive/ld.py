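"""LD and arrangement association on haplotype panels of sequenced amplicons.

Input is a set of aligned Sanger-style haplotypes per intergenic region,
each strain labelled with its chromosome arrangement (SR or ST). Columns
with indels or singleton variants are removed, the remaining segregating
sites of all regions are concatenated, and pairwise LD is computed with
the correlation-based r^2 for haploid data (the squared Pearson
correlation of 0/1 allele indicators, identical to D^2/(p(1-p)q(1-q))
from the 2x2 haplotype table). Site-by-arrangement association uses
Fisher's exact test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HaplotypePanel",
    "SegregatingMatrix",
    "read_fasta_panel",
    "build_segregating_matrix",
    "ld_matrix",
    "arrangement_fet",
]

GAP_CHARS = set("-.*Nn")


@dataclass
class HaplotypePanel:
    """Aligned haplotypes for one or more regions, labelled by arrangement.

    regions maps region id -> (strain names, arrangement labels, sequence
    matrix of single characters, genomic start coordinate).
    """

    regions: dict[str, dict] = field(default_factory=dict)

    def add_region(self, region_id: str, names, arrangements, seqs, chrom="", start=1):
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"{region_id}: sequences have unequal lengths {lengths}")
        self.regions[region_id] = {
            "names": list(names),
            "arrangements": list(arrangements),
            "seqs": np.array([list(s.upper()) for s in seqs]),
            "chrom": chrom,
            "start": int(start),
        }

    @property
    def strain_names(self) -> list[str]:
        first = next(iter(self.regions.values()))
        return first["names"]

    @property
    def arrangements(self) -> list[str]:
        first = next(iter(self.regions.values()))
        return first["arrangements"]


def read_fasta_panel(paths_by_region: dict[str, str], manifest: pd.DataFrame | None = None) -> HaplotypePanel:
    """Read one multi-FASTA per region; headers encode arrangement as 'strain|SR'.

    The optional manifest (region, chrom, start, end) supplies genomic
    coordinates per region.
    """
    panel = HaplotypePanel()
    for region, path in paths_by_region.items():
        names, arrs, seqs = [], [], []
        with open(path) as fh:
            name, buf = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        seqs.append("".join(buf))
                    header = line[1:]
                    strain, _, arr = header.partition("|")
                    names.append(strain)
                    arrs.append(arr or "NA")
                    name, buf = header, []
                elif line:
                    buf.append(line)
            if name is not None:
                seqs.append("".join(buf))
        chrom, start = "", 1
        if manifest is not None:
            row = manifest[manifest["region"] == region]
            if len(row):
                chrom, start = row.iloc[0]["chrom"], int(row.iloc[0]["start"])
        panel.add_region(region, names, arrs, seqs, chrom=chrom, start=start)
    return panel


@dataclass
class SegregatingMatrix:
    """0/1 site-by-strain matrix of concatenated qualifying columns.

    Coding: 1 marks the derived allele when an outgroup base is available
    for the column, otherwise the minor allele (ties broken toward the
    lexicographically larger base). Column provenance (region, genomic
    coordinate) is kept alongside.
    """

    matrix: np.ndarray  # (n_sites, n_strains)
    strains: list[str]
    arrangements: list[str]
    provenance: pd.DataFrame  # region, column, chrom, position


def build_segregating_matrix(
    panel: HaplotypePanel,
    outgroup: dict[str, str] | None = None,
    min_minor_count: int = 2,
) -> SegregatingMatrix:
    """Concatenate qualifying columns from every region into a 0/1 matrix.

    Columns containing gap characters are removed, as are monomorphic
    columns, columns with more than two alleles, and columns whose minor
    allele count is below ``min_minor_count`` (singletons by default).
    """
    cols, prov = [], []
    strains = panel.strain_names
    arrangements = panel.arrangements
    for region, data in panel.regions.items():
        if data["names"] != strains:
            raise ValueError(f"region {region}: strain order differs from panel")
        seqs = data["seqs"]
        og = outgroup.get(region) if outgroup else None
        for j in range(seqs.shape[1]):
            col = seqs[:, j]
            if any(ch in GAP_CHARS for ch in col):
                continue
            alleles, counts = np.unique(col, return_counts=True)
            if len(alleles) != 2 or counts.min() < min_minor_count:
                continue
            if og is not None and j < len(og) and og[j].upper() in alleles:
                one = [a for a in alleles if a != og[j].upper()][0]
            else:
                order = np.argsort(counts)  # minor first
                if counts[order[0]] == counts[order[1]]:
                    one = max(alleles)
                else:
                    one = alleles[order[0]]
            cols.append((col == one).astype(np.int8))
            prov.append(
                {"region": region, "column": j, "chrom": data["chrom"],
                 "position": data["start"] + j}
            )
    if not cols:
        raise ValueError("no segregating sites after filtering")
    return SegregatingMatrix(
        matrix=np.array(cols), strains=strains, arrangements=arrangements,
        provenance=pd.DataFrame(prov),
    )


def _r2_from_columns(x: np.ndarray, y: np.ndarray) -> float:
    """Haploid r^2: squared Pearson correlation of the 0/1 indicators."""
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise ValueError("zero-variance column; filter before computing LD")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_matrix(
    seg: SegregatingMatrix,
    significance: str = "chi-square",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise r^2 values with significance and BH-adjusted q-values.

    With 'chi-square' significance, n*r^2 is referred to chi-square(1);
    with 'permutation', one column of each pair is permuted ``n_perm``
    times (seeded) and the p-value is the fraction of permutations with
    r^2 at least as large (add-one correction).
    """
    if significance not in ("chi-square", "permutation"):
        raise ValueError("significance must be 'chi-square' or 'permutation'")
    m, n = seg.matrix.shape
    if m < 2:
        raise ValueError("need at least two polymorphic columns")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            x, y = seg.matrix[i], seg.matrix[j]
            r2 = _r2_from_columns(x, y)
            if significance == "chi-square":
                p = float(stats.chi2.sf(n * r2, df=1))
            else:
                null = np.empty(n_perm)
                for t in range(n_perm):
                    null[t] = _r2_from_columns(x, rng.permutation(y))
                p = (1 + (null >= r2 - 1e-15).sum()) / (n_perm + 1)
            rows.append({"site_i": i, "site_j": j, "r2": r2, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def arrangement_fet(seg: SegregatingMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-site Fisher's exact test of allele-by-arrangement association.

    Two-sided exact p per column from the 2x2 table of allele (0/1) by
    arrangement (SR/ST), BH q-values across columns, and a per-site note
    of the smallest p attainable given the table margins (whether the
    test has any power to reach alpha at these counts).
    """
    arrs = np.array(seg.arrangements)
    labels = sorted(set(arrs))
    if len(labels) < 2:
        raise ValueError("both arrangement labels must be present")
    rows = []
    for i, col in enumerate(seg.matrix):
        a = int(col[arrs == labels[0]].sum())
        b = int((arrs == labels[0]).sum()) - a
        c = int(col[arrs == labels[1]].sum())
        d = int((arrs == labels[1]).sum()) - c
        if (a + c == 0) or (b + d == 0):
            raise ValueError(f"column {i} is monomorphic; filter before testing")
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        # smallest achievable p given margins: most extreme allocation
        n1, n2, k = a + b, c + d, a + c
        lo = max(0, k - n2)
        hi = min(k, n1)
        p_min = min(
            float(stats.fisher_exact([[x, n1 - x], [k - x, n2 - (k - x)]])[1])
            for x in (lo, hi)
        )
        rows.append(
            {"site": i, "p": p, "p_min_attainable": p_min, "powered": p_min < alpha}
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
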