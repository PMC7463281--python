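"""F_ST-based divergence dating with per-window outgroup calibration.

Differentiation between chromosome arrangements is converted to a
divergence-time scale with the log transform T = -ln(1 - F_ST), which is
linear in time for small divergence under a drift model. Each window's
focal transform is scaled by the same window's transform for a
calibration pair with a known split time (by default 2 Myr for the
standard arrangement against the outgroup species), so locally varying
mutation/drift rates cancel window by window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pooled_popgen import WindowStat

__all__ = ["CalibratedAge", "budowle_transform", "window_scaled_ages"]

DEFAULT_CALIBRATION_AGE = 2_000_000.0


@dataclass
class CalibratedAge:
    """Per-window divergence-time estimate."""

    chrom: str
    start: int
    end: int
    t_focal: float
    t_calibration: float
    age: float
    clipped: bool = False


def budowle_transform(fst: float) -> tuple[float, bool]:
    """T = -ln(1 - F_ST); negative inputs clip to zero with a flag.

    F_ST >= 1 has no finite transform and is rejected.
    """
    if fst >= 1:
        raise ValueError("F_ST >= 1: divergence transform is infinite")
    if fst < 0:
        return 0.0, True
    return -math.log(1.0 - fst), False


def window_scaled_ages(
    focal: list[WindowStat],
    calibration: list[WindowStat],
    calibration_age: float = DEFAULT_CALIBRATION_AGE,
    n_boot: int = 1000,
    seed: int | None = None,
    weight_by_snps: bool = False,
    ci: float = 0.95,
) -> tuple[list[CalibratedAge], dict]:
    """Window ages and the region-level mean age with a bootstrap CI.

    Focal and calibration windows must share coordinates. Windows where
    the calibration transform is zero (or either estimate is NA) are
    excluded. The region summary is the unweighted mean of window ages
    (SNP-count weighting optional); its CI resamples windows.
    """
    if len(focal) != len(calibration):
        raise ValueError("focal and calibration window lists differ in length")
    ages: list[CalibratedAge] = []
    weights = []
    n_excluded = 0
    for fw, cw in zip(focal, calibration):
        if (fw.chrom, fw.start, fw.end) != (cw.chrom, cw.start, cw.end):
            raise ValueError(
                f"window mismatch: {fw.chrom}:{fw.start}-{fw.end} vs "
                f"{cw.chrom}:{cw.start}-{cw.end}"
            )
        if math.isnan(fw.estimate) or math.isnan(cw.estimate):
            n_excluded += 1
            continue
        tf, clip_f = budowle_transform(fw.estimate)
        tc, _ = budowle_transform(cw.estimate)
        if tc == 0:
            n_excluded += 1
            continue
        ages.append(
            CalibratedAge(
                chrom=fw.chrom, start=fw.start, end=fw.end,
                t_focal=tf, t_calibration=tc,
                age=calibration_age * tf / tc, clipped=clip_f,
            )
        )
        weights.append(fw.n_sites)
    if not ages:
        raise ValueError("no usable windows (all excluded)")
    vals = np.array([a.age for a in ages])
    w = np.array(weights, dtype=float)
    mean_age = float(np.average(vals, weights=w) if weight_by_snps else vals.mean())
    rng = np.random.default_rng(seed)
    if n_boot and len(vals) > 1:
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        if weight_by_snps:
            reps = (vals[idx] * w[idx]).sum(axis=1) / w[idx].sum(axis=1)
        else:
            reps = vals[idx].mean(axis=1)
        lo, hi = np.quantile(reps, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    else:
        lo = hi = mean_age
    summary = {
        "mean_age": mean_age,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_windows": len(vals),
        "n_excluded": n_excluded,
        "n_boot": n_boot,
    }
    return ages, summary
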