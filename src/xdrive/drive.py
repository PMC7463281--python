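"""Deterministic dynamics of an X-linked driving chromosome with two inversion blocks.

The driving X carries two linked inversion units: A, the basal+medial
inversion block, and B, the terminal inversion. Four gamete (chromosome)
types circulate:

====== ======= =========================================
index  name    composition
====== ======= =========================================
0      ST      ab — standard arrangement
1      SR      AB — full driving chromosome
2      BM      Ab — basal+medial-only recombinant
3      T       aB — terminal-only recombinant
====== ======= =========================================

Two model layers are provided.

*Gametic (haploid) layer* — the textbook decay of gametic-phase
disequilibrium ``D_t = (1-c)^t D_0``, plus a gamete-pool recursion with
per-type haploid selection coefficients and recombinant production from
SR/ST pairings, used to fit the selection intensities that reconcile the
laboratory recombination rate with the rarity of recombinants in nature.

*Diploid layer* — a sex-structured recursion with X linkage: females carry
two X's and recombine between the A and B blocks at rate ``c``; males are
hemizygous and a male of type g sires a fraction ``k_g`` daughters (his X)
and ``1 - k_g`` sons, with brood size independent of genotype. Viability
costs are recessive: by default a cost is expressed in homozygous females
and in hemizygous males (a single dose is the full exposed dose in a
hemizygous male), with a female-only mode available. On top of the
recursion sit equilibrium solvers: the homozygous cost that balances drive
at an observed population frequency, and the minimum recombinant cost that
prevents a recombinant from displacing the full driving chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAMETE_TYPES",
    "DriveParams",
    "DiploidState",
    "gametic_decay",
    "half_life",
    "meiosis_tensor",
    "diploid_step",
    "iterate_to_equilibrium",
    "ld_half_life",
    "find_balance_cost",
    "min_cost_to_exclude",
    "haploid_step",
    "haploid_selection_equilibrium",
    "fit_haploid_s",
    "gamete_ld",
]

GAMETE_TYPES = ("ST", "SR", "BM", "T")
_ST, _SR, _BM, _T = 0, 1, 2, 3

# Measured proportions of female progeny per fathered type. ST's measured
# 0.439 has a CI spanning 0.5 and is treated as Mendelian by default.
K_MEASURED = {"ST": 0.439, "SR": 0.969, "BM": 0.622, "T": 0.426}
K_DEFAULT = (0.5, 0.969, 0.622, 0.426)


# ---------------------------------------------------------------------------
# gametic-phase decay


def gametic_decay(D0: float, c: float, t: float) -> float:
    """LD after t generations of recombination at rate c: (1-c)^t * D0."""
    if not 0 <= c <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    if t < 0:
        raise ValueError("generations must be >= 0")
    return (1 - c) ** t * D0


def half_life(c: float) -> tuple[float, int]:
    """Generations for gametic-phase LD to halve: ln(1/2)/ln(1-c).

    Returns the real-valued solution and its nearest integer.
    """
    if not 0 < c <= 0.5:
        raise ValueError("recombination fraction must be in (0, 0.5]")
    t = math.log(0.5) / math.log(1 - c)
    return t, round(t)


def gamete_ld(x) -> dict[str, float]:
    """D and r^2 of the A/B association in a gamete-type frequency vector."""
    x = np.asarray(x, dtype=float)
    x = x / x.sum()
    pA = x[_SR] + x[_BM]
    qB = x[_SR] + x[_T]
    D = x[_SR] - pA * qB
    denom = pA * (1 - pA) * qB * (1 - qB)
    r2 = D * D / denom if denom > 0 else float("nan")
    return {"D": float(D), "r2": float(r2), "p_A": float(pA), "q_B": float(qB)}


# ---------------------------------------------------------------------------
# diploid layer


@dataclass(frozen=True)
class DriveParams:
    """Parameters of the diploid X-linked drive recursion.

    k
        Per-type proportion of female progeny sired by a carrier male.
    cost
        Per-type recessive viability cost (homozygous females; also
        hemizygous males when ``cost_in_males``).
    c
        Female recombination fraction between the A and B blocks.
    cost_in_males
        Express each cost in hemizygous males as well as homozygous
        females (default). With False, costs are strictly female-limited;
        male drive is then unopposed in males and no cost can balance
        strong drive at the observed population frequency.
    """

    k: tuple[float, float, float, float] = K_DEFAULT
    cost: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    c: float = 0.0012
    cost_in_males: bool = True

    def __post_init__(self):
        for v in self.k:
            if not 0 <= v <= 1:
                raise ValueError("k values must be in [0, 1]")
        for v in self.cost:
            if not 0 <= v <= 1:
                raise ValueError("costs must be in [0, 1]")
        if not 0 <= self.c <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")


def meiosis_tensor(c: float) -> np.ndarray:
    """T[i, j, g]: P(gamete g | female genotype i/j) with recombination c.

    Recombination separates the A block from the B block only in double
    heterozygotes: SR/ST produces BM and T at c/2 each, BM/T produces SR
    and ST at c/2 each. All other genotypes segregate 1/2 : 1/2.
    """
    T = np.zeros((4, 4, 4))
    for i in range(4):
        for j in range(4):
            if {i, j} == {_SR, _ST}:
                T[i, j, _SR] = T[i, j, _ST] = (1 - c) / 2
                T[i, j, _BM] = T[i, j, _T] = c / 2
            elif {i, j} == {_BM, _T}:
                T[i, j, _BM] = T[i, j, _T] = (1 - c) / 2
                T[i, j, _SR] = T[i, j, _ST] = c / 2
            else:
                T[i, j, i] += 0.5
                T[i, j, j] += 0.5
    return T


@dataclass
class DiploidState:
    """Sex-structured population state at the zygote census.

    F
        4x4 symmetric matrix of female genotype frequencies over ordered
        gamete-type pairs (sums to 1).
    M
        Male hemizygote type frequencies (sums to 1).
    phi
        Fraction of the population that is female.
    """

    F: np.ndarray
    M: np.ndarray
    phi: float = 0.5

    @classmethod
    def from_gamete_freqs(cls, x, phi: float = 0.5) -> "DiploidState":
        """State under random union of a single gamete pool."""
        x = np.asarray(x, dtype=float)
        if x.min() < 0 or abs(x.sum() - 1) > 1e-9:
            raise ValueError("gamete frequencies must be a distribution")
        return cls(F=np.outer(x, x), M=x.copy(), phi=phi)

    def validate(self) -> None:
        if self.F.min() < -1e-15 or self.M.min() < -1e-15:
            raise ValueError("negative frequency in state")
        if abs(self.F.sum() - 1) > 1e-9 or abs(self.M.sum() - 1) > 1e-9:
            raise ValueError("frequencies do not sum to 1")

    @property
    def female_type_freqs(self) -> np.ndarray:
        """Gamete-type frequencies among female-carried X chromosomes."""
        return self.F.sum(axis=1)

    @property
    def pooled_x_freqs(self) -> np.ndarray:
        """Type frequencies over all X copies (two per female, one per male)."""
        fem = self.female_type_freqs
        return (2 * self.phi * fem + (1 - self.phi) * self.M) / (1 + self.phi)

    def ld(self, pool: str = "pooled") -> dict[str, float]:
        x = {
            "pooled": self.pooled_x_freqs,
            "female": self.female_type_freqs,
            "male": self.M,
        }[pool]
        return gamete_ld(x)

    def allele_freqs(self) -> dict[str, float]:
        out = {}
        for sex, x in (("female", self.female_type_freqs), ("male", self.M)):
            out[f"pA_{sex}"] = float(x[_SR] + x[_BM])
            out[f"qB_{sex}"] = float(x[_SR] + x[_T])
        return out


def _viability(params: DriveParams):
    Wf = np.ones((4, 4))
    for g in range(4):
        Wf[g, g] = 1 - params.cost[g]
    Wm = np.array([1 - cg for cg in params.cost]) if params.cost_in_males else np.ones(4)
    return Wf, Wm


def diploid_step(
    state: DiploidState, params: DriveParams, tensor: np.ndarray | None = None
) -> DiploidState:
    """Advance one generation.

    Order of events: recessive viability selection on the zygote census;
    female meiosis with recombination; male meiosis with drive (a type-g
    father sires k_g daughters, who receive his X, per unit brood); random
    mating with equal male mating success; zygote formation. Daughters are
    maternal gamete x paternal X, sons carry a maternal gamete.
    """
    if tensor is None:
        tensor = meiosis_tensor(params.c)
    Wf, Wm = _viability(params)
    F = state.F * Wf
    tot = F.sum()
    if tot <= 0:
        raise ValueError("all females inviable under these costs")
    F = F / tot
    M = state.M * Wm
    M = M / M.sum()

    fgam = np.einsum("ij,ijg->g", F, tensor)
    sired = M * np.asarray(params.k)
    phi = float(sired.sum())
    if phi <= 0:
        raise ValueError("no daughters sired; k vector all zero")
    pat = sired / phi

    Fn = np.outer(fgam, pat)
    Fn = (Fn + Fn.T) / 2
    new = DiploidState(F=Fn, M=fgam.copy(), phi=phi)
    new.validate()
    return new


def iterate_to_equilibrium(
    state: DiploidState,
    params: DriveParams,
    tol: float = 1e-12,
    t_max: int = 1_000_000,
    record_ld: bool = False,
    ld_pool: str = "pooled",
) -> tuple[DiploidState, dict]:
    """Iterate the recursion until the pooled X frequencies stop moving.

    Returns the final state and a summary with the generation count, the
    convergence flag, and (optionally) the trajectory of D in the chosen
    X pool together with its first-passage half-life.
    """
    tensor = meiosis_tensor(params.c)
    D_traj = []
    prev = state.pooled_x_freqs
    if record_ld:
        D_traj.append(state.ld(ld_pool)["D"])
    converged = False
    t = 0
    for t in range(1, t_max + 1):
        state = diploid_step(state, params, tensor)
        cur = state.pooled_x_freqs
        if record_ld:
            D_traj.append(state.ld(ld_pool)["D"])
        if np.max(np.abs(cur - prev)) < tol:
            converged = True
            break
        prev = cur
    info: dict = {"generations": t, "converged": converged}
    if record_ld:
        D0 = D_traj[0]
        hl = next(
            (i for i, D in enumerate(D_traj) if abs(D) <= abs(D0) / 2), None
        )
        info["D_trajectory"] = np.array(D_traj)
        info["D_half_life"] = hl
    if not converged and not record_ld:
        raise RuntimeError(
            f"no equilibrium within {t_max} generations (last state {state.pooled_x_freqs})"
        )
    return state, info


def ld_half_life(
    params: DriveParams,
    x0=None,
    pool: str = "pooled",
    t_max: int = 100_000,
) -> dict:
    """First generation at which |D| falls to half its initial value.

    The population starts at random union of the supplied gamete-type
    frequencies (default: the pooled natural-survey frequencies with the
    full driving chromosome at 0.13455 and both recombinants rare, giving
    D0 = 0.116).
    """
    if x0 is None:
        x0 = np.array([0.86526, 0.13455, 0.00004, 0.00015])
    state = DiploidState.from_gamete_freqs(x0)
    tensor = meiosis_tensor(params.c)
    D0 = state.ld(pool)["D"]
    for t in range(1, t_max + 1):
        state = diploid_step(state, params, tensor)
        D = state.ld(pool)["D"]
        if abs(D) <= abs(D0) / 2:
            return {"half_life": t, "D0": D0, "D_final": D}
    return {"half_life": None, "D0": D0, "D_final": D}


def _two_type_equilibrium_freq(
    cost_sr: float,
    k_sr: float,
    params_template: DriveParams,
    tol: float = 1e-12,
    t_max: int = 200_000,
) -> float:
    """Pooled SR frequency at equilibrium of the recombinant-free system."""
    k = list(params_template.k)
    k[_SR] = k_sr
    cost = [0.0, cost_sr, 0.0, 0.0]
    params = replace(params_template, k=tuple(k), cost=tuple(cost), c=0.0)
    state = DiploidState.from_gamete_freqs([0.865, 0.135, 0.0, 0.0])
    tensor = meiosis_tensor(0.0)
    prev = None
    for _ in range(t_max):
        state = diploid_step(state, params, tensor)
        p = state.pooled_x_freqs[_SR]
        if prev is not None and abs(p - prev) < tol:
            return float(p)
        prev = p
    return float(p)


def find_balance_cost(
    k_full: float = 0.969,
    target: float = 0.135,
    tol: float = 1e-6,
    params_template: DriveParams | None = None,
) -> float:
    """Recessive cost on the driving homozygote that balances drive.

    Bisects the SR cost in the two-type (ST, SR) system until the long-run
    pooled SR X frequency equals the target. Requires k_full > 0.5; a
    Mendelian chromosome has no interior drive-selection balance.
    """
    if k_full <= 0.5:
        raise ValueError("no drive (k <= 0.5): no interior equilibrium to balance")
    if params_template is None:
        params_template = DriveParams()
    lo, hi = 0.0, 1.0
    f_lo = _two_type_equilibrium_freq(lo, k_full, params_template)
    f_hi = _two_type_equilibrium_freq(hi, k_full, params_template)
    if not (f_hi <= target <= f_lo):
        raise ValueError(
            f"target {target} outside attainable range [{f_hi:.4f}, {f_lo:.4f}]"
        )
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if _two_type_equilibrium_freq(mid, k_full, params_template) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def min_cost_to_exclude(
    recombinant: str,
    k_full: float = 0.969,
    target: float = 0.135,
    c: float = 0.0012,
    horizon: int = 100_000,
    tol: float = 1e-3,
    loss_threshold: float = 1e-6,
    params_template: DriveParams | None = None,
) -> dict:
    """Minimum recessive cost on a recombinant that protects the full driver.

    The four-gamete system starts at the two-type drive-selection balance
    (SR balanced at ``target`` by its fitted cost); recombination at rate c
    in SR/ST females then regenerates the recombinant every generation.
    Below the returned threshold the full SR chromosome is asymptotically
    lost to the recombinant; above it SR persists at a positive long-run
    frequency. The non-focal recombinant class is given a lethal homozygous
    cost so each threshold is measured in isolation.

    Returns the threshold (0.0 when SR persists even with a cost-free
    recombinant) plus the bracketing evidence.
    """
    if recombinant not in ("BM", "T"):
        raise ValueError("recombinant must be 'BM' or 'T'")
    rec = _BM if recombinant == "BM" else _T
    other = _T if rec == _BM else _BM
    if params_template is None:
        params_template = DriveParams()
    bal = find_balance_cost(k_full, target, params_template=params_template)

    k = list(params_template.k)
    k[_SR] = k_full

    def sr_persists(rec_cost: float) -> bool:
        cost = [0.0, bal, 0.0, 0.0]
        cost[rec] = rec_cost
        cost[other] = 1.0
        params = replace(params_template, k=tuple(k), cost=tuple(cost), c=c)
        # settle at the recombinant-free two-type balance first
        state = DiploidState.from_gamete_freqs([1 - target, target, 0.0, 0.0])
        params0 = replace(params, c=0.0)
        tensor0 = meiosis_tensor(0.0)
        prev = None
        for _ in range(50_000):
            state = diploid_step(state, params0, tensor0)
            p = state.pooled_x_freqs[_SR]
            if prev is not None and abs(p - prev) < 1e-12:
                break
            prev = p
        tensor = meiosis_tensor(c)
        for _ in range(horizon):
            state = diploid_step(state, params, tensor)
        return state.pooled_x_freqs[_SR] > loss_threshold

    lo, hi = 0.0, 1.0
    if sr_persists(lo):
        return {
            "recombinant": recombinant,
            "threshold": 0.0,
            "balance_cost": bal,
            "note": "full SR persists even with a cost-free recombinant",
        }
    if not sr_persists(hi):
        raise RuntimeError(
            "outcome undecided at both brackets; increase the horizon"
        )
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if sr_persists(mid):
            hi = mid
        else:
            lo = mid
    return {
        "recombinant": recombinant,
        "threshold": (lo + hi) / 2,
        "balance_cost": bal,
        "bracket": (lo, hi),
    }


# ---------------------------------------------------------------------------
# haploid (gametic) selection layer


def haploid_step(
    x: np.ndarray,
    s,
    c: float,
    hold_major: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of the gamete-pool model with production and selection.

    Recombinant production at meiosis converts SR/ST pairings into each
    single-unit recombinant at rate c/2 per pairing (pairing probability is
    the product of the two frequencies), and BM/T pairings back into SR and
    ST at the same rate. Selection then weights type g by 1 - s_g. With
    ``hold_major`` the SR and ST frequencies are pinned to the supplied
    values after each step, so only the recombinant classes equilibrate —
    the fitting configuration.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    flux_fwd = (c / 2) * x[_SR] * x[_ST]
    flux_rev = (c / 2) * x[_BM] * x[_T]
    z = x.copy()
    z[_BM] += flux_fwd - flux_rev
    z[_T] += flux_fwd - flux_rev
    z[_SR] += flux_rev - flux_fwd
    z[_ST] += flux_rev - flux_fwd
    out = z * (1 - s)
    if hold_major is not None:
        out[_SR] = hold_major[_SR]
        out[_ST] = hold_major[_ST]
        return out
    return out / out.sum()


def haploid_selection_equilibrium(
    x0,
    s,
    c: float,
    hold_major: bool = False,
    tol: float = 1e-12,
    t_max: int = 1_000_000,
) -> np.ndarray:
    """Iterate the gamete-pool recursion to its fixed point."""
    x = np.asarray(x0, dtype=float)
    hold = x.copy() if hold_major else None
    for _ in range(t_max):
        nxt = haploid_step(x, s, c, hold_major=hold)
        if np.max(np.abs(nxt - x)) < tol:
            return nxt
        x = nxt
    raise RuntimeError(f"no equilibrium within {t_max} generations (state {x})")


def fit_haploid_s(
    observed,
    c: float = 0.0012,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Haploid selection coefficients that hold recombinants at observed rarity.

    ``observed`` is the (ST, SR, BM, T) gamete-frequency vector from the
    natural surveys. For each recombinant class the selection coefficient s
    is bisected until the equilibrium frequency under recurrent production
    from SR/ST pairings (with SR and ST held at their observed frequencies)
    equals the observed recombinant frequency.
    """
    obs = np.asarray(observed, dtype=float)
    if obs[_BM] <= 0 or obs[_T] <= 0:
        raise ValueError("observed recombinant frequencies must be > 0")
    out = {}
    for rec, name in ((_BM, "BM"), (_T, "T")):

        def eq_freq(s_val: float) -> float:
            s = np.zeros(4)
            s[rec] = s_val
            s[_BM if rec == _T else _T] = 1.0  # silence the other class
            start = obs.copy()
            start[_BM if rec == _T else _T] = 0.0
            x = haploid_selection_equilibrium(
                start, s, c, hold_major=True, tol=1e-14
            )
            return x[rec]

        lo, hi = 0.0, 1.0
        # equilibrium frequency diverges as s -> 0+ and vanishes at s = 1,
        # so a root always exists in (0, 1]; check only the upper end
        if eq_freq(hi) > obs[rec]:
            raise ValueError(
                f"{name}: no selection coefficient in [0, 1] reaches the observed frequency"
            )
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if eq_freq(mid) > obs[rec]:
                lo = mid
            else:
                hi = mid
        out[name] = (lo + hi) / 2
    return out
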