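"""Classical genetics statistics for testcross, segregation, and survey data.

Covers the statistics used around a two-point testcross of a driving X
chromosome: exact binomial (Clopper-Pearson) intervals for recombination
fractions and segregation proportions, the Kosambi map function, the
reciprocal-class chi-square against a 1:1 Mendelian expectation, and
two-locus linkage disequilibrium from survey haplotype-frequency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProgenyTable",
    "BinomialEstimate",
    "recomb_fraction",
    "kosambi_cm",
    "chi2_reciprocal",
    "survey_ld",
    "segregation_k",
    "load_survey_table",
    "clopper_pearson",
]


@dataclass
class ProgenyTable:
    """Progeny counts per class (marker classes or sexes) from one cross."""

    cross_id: str
    classes: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.classes) != len(self.counts):
            raise ValueError("classes and counts differ in length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if sum(self.counts) < 1:
            raise ValueError("need at least one scored individual")

    def count(self, label: str) -> int:
        return self.counts[self.classes.index(label)]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class BinomialEstimate:
    """Point estimate and exact two-sided CI for a binomial proportion."""

    successes: int
    total: int
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float

    @property
    def excludes_half(self) -> bool:
        return self.ci_low > 0.5 or self.ci_high < 0.5


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Beta-quantile inversion of the binomial tails; the boundary cases x=0 and
    x=n use the one-sided closed forms 1-(alpha/2)^(1/n).
    """
    if n < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("successes must lie in [0, total]")
    alpha = 1.0 - confidence
    low = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    high = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return float(low), float(high)


def recomb_fraction(
    recombinants: int, total: int, confidence: float = 0.95
) -> BinomialEstimate:
    """Recombination fraction with an exact binomial CI.

    Pooled recombinant counts over all replicates are the binomial successes;
    `total` is the number of scored progeny.
    """
    low, high = clopper_pearson(recombinants, total, confidence)
    return BinomialEstimate(
        recombinants, total, recombinants / total, low, high, confidence
    )


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in centimorgans, d = 25*ln((1+2r)/(1-2r)).

    Corrects the observed recombination fraction for multiple crossovers
    under moderate interference. Defined for 0 <= r < 0.5.
    """
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5:
        raise ValueError("r >= 0.5 is beyond two-point map resolution")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def chi2_reciprocal(
    class1: int, class2: int, continuity: bool = False
) -> dict[str, float]:
    """Chi-square test of reciprocal recombinant classes against 1:1.

    Expected counts are (n1+n2)/2 in each class. Returns the chi-square
    statistic (1 df), its p-value, and the exact two-sided binomial p-value
    for the same comparison. No continuity correction by default.
    """
    n = class1 + class2
    if n < 1:
        raise ValueError("need at least one observation")
    exp = n / 2.0
    if continuity:
        chi2 = sum((abs(o - exp) - 0.5) ** 2 / exp for o in (class1, class2))
    else:
        chi2 = (class1 - exp) ** 2 / exp + (class2 - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    p_exact = float(stats.binomtest(class1, n, 0.5).pvalue)
    return {"chi2": float(chi2), "p": p, "p_exact_binomial": p_exact}


def survey_ld(freqs) -> dict[str, float]:
    """Two-locus LD from four haplotype frequencies.

    `freqs` holds the frequencies of (AB, Ab, aB, ab): the full driving
    chromosome carries both inversion units (AB), the two single-unit
    recombinant classes carry one each, and the standard arrangement neither.
    Returns the allele frequencies p_A, q_B, the coupling disequilibrium
    D = P(AB) - p_A*q_B, and r^2 = D^2 / (p_A(1-p_A) q_B(1-q_B)).
    """
    pAB, pAb, paB, pab = (float(x) for x in freqs)
    total = pAB + pAb + paB + pab
    if not math.isclose(total, 1.0, abs_tol=5e-5):
        raise ValueError(f"haplotype frequencies sum to {total}, not 1")
    pA = pAB + pAb
    qB = pAB + paB
    D = pAB - pA * qB
    denom = pA * (1 - pA) * qB * (1 - qB)
    if denom <= 0:
        return {"p_A": pA, "q_B": qB, "D": 0.0, "r2": float("nan")}
    return {"p_A": pA, "q_B": qB, "D": D, "r2": D * D / denom}


def segregation_k(
    females: int, males: int, confidence: float = 0.95
) -> dict[str, object]:
    """Segregation proportion k (fraction of female progeny) with exact CI.

    k = 0.5 is Mendelian; a driving X gives k near 1. The cross is flagged
    as distorting when the exact CI excludes 0.5.
    """
    est = recomb_fraction(females, females + males, confidence)
    return {
        "k": est.estimate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n": est.total,
        "distorting": est.excludes_half,
    }


def load_survey_table() -> pd.DataFrame:
    """Load the packaged table of natural-population survey haplotype frequencies.

    Columns: study, n, freq_SR, freq_BM, freq_T, freq_ST. The final row pools
    all non-duplicated surveys.
    """
    with resources.files("xdrive.data").joinpath("survey_frequencies.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def pooled_survey_frequencies() -> np.ndarray:
    """Pooled (SR, BM, T, ST) haplotype frequencies from the packaged surveys."""
    df = load_survey_table()
    row = df[df["study"] == "pooled"].iloc[0]
    return np.array([row.freq_SR, row.freq_BM, row.freq_T, row.freq_ST])
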