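"""Per-population and pooled molecular diversity and demographic statistics.

Implements the single-locus haploid estimators used in mtDNA
phylogeography: haplotype diversity (Hd) and nucleotide diversity (pi)
with Nei (1987) sampling standard deviations, rarefied allelic richness,
Tajima's D and Fu's Fs with coalescent-simulated null distributions, and
mismatch-distribution fitting under the Rogers-Harpending sudden-expansion
model (SSD and raggedness goodness-of-fit with parametric-bootstrap
p-values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import DegenerateDataError, ParameterError
from .seqio import Alignment, HaplotypeTable, MISSING, PopulationMap, SiteMask

__all__ = [
    "haplotype_diversity",
    "nucleotide_diversity",
    "allelic_richness",
    "tajimas_d",
    "fu_fs",
    "ewens_log_pmf",
    "neutrality_null",
    "NeutralityResult",
    "mismatch_observed",
    "mismatch_expected",
    "mismatch_fit",
    "MismatchResult",
    "raggedness",
    "pairwise_difference_matrix",
    "diversity_table",
    "simulate_coalescent_summary",
]


# ---------------------------------------------------------------------------
# pairwise distances

def pairwise_difference_matrix(
    aln: Alignment, mask: SiteMask
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (differences, compared-site counts) over included columns.

    Under complete deletion every pair compares the same columns; under
    pairwise deletion columns where either sequence is missing are skipped
    for that pair only.
    """
    M = aln.matrix()[:, list(mask.included_sites)]
    n = M.shape[0]
    missing = np.isin(M, list(MISSING))
    # integer codes for vectorised comparison
    codes = np.zeros(M.shape, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        codes[M == b] = i
    codes[missing] = -1
    diffs = np.zeros((n, n), dtype=float)
    compared = np.zeros((n, n), dtype=float)
    for i in range(n):
        ok = (codes[i] >= 0) & (codes[i + 1:] >= 0)
        d = ((codes[i] != codes[i + 1:]) & ok).sum(axis=1)
        c = ok.sum(axis=1)
        diffs[i, i + 1:] = d
        diffs[i + 1:, i] = d
        compared[i, i + 1:] = c
        compared[i + 1:, i] = c
    return diffs, compared


def _pair_stats(diffs: np.ndarray, compared: np.ndarray) -> tuple[float, float]:
    """(mean absolute pairwise difference, mean per-site pairwise difference)."""
    n = diffs.shape[0]
    iu = np.triu_indices(n, 1)
    d, c = diffs[iu], compared[iu]
    if np.any(c == 0):
        raise DegenerateDataError("a sequence pair shares no comparable sites")
    return float(d.mean()), float((d / c).mean())


# ---------------------------------------------------------------------------
# diversity

def haplotype_diversity(counts: np.ndarray) -> tuple[float, float]:
    """Nei's gene (haplotype) diversity with its sampling sd.

    Hd = n/(n-1) * (1 - sum p_i^2); variance per Nei (1987, eq. 8.12).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise DegenerateDataError("haplotype diversity needs n >= 2")
    p = counts / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    hd = n / (n - 1.0) * (1.0 - s2)
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    )
    return float(hd), math.sqrt(max(var, 0.0))


def nucleotide_diversity(
    aln: Alignment,
    mask: SiteMask,
    sample_ids: list[str] | None = None,
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi with Nei (1987, eq. 10.7) total sd."""
    sub = aln if sample_ids is None else aln.subset(sample_ids)
    n = sub.n
    if n < 2:
        raise DegenerateDataError("nucleotide diversity needs n >= 2")
    diffs, compared = pairwise_difference_matrix(sub, mask)
    _, pi = _pair_stats(diffs, compared)
    L = len(mask.included_sites)
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return float(pi), math.sqrt(max(var, 0.0))


def allelic_richness(
    counts: np.ndarray, g: int, convention: str = "raw"
) -> float:
    """Rarefied allelic richness: expected haplotype count in a sample of g.

    raw: Ar(g) = sum_i [1 - C(n - n_i, g)/C(n, g)]; ``minus_one`` subtracts 1
    (the number-of-alleles-beyond-the-first convention used by CONTRIB).
    """
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if not 1 <= g <= n:
        raise ParameterError(f"rarefaction size g={g} outside [1, n={n}]")
    denom = math.comb(n, g)
    ar = sum(1.0 - math.comb(n - ni, g) / denom if n - ni >= g else 1.0
             for ni in counts)
    if convention == "raw":
        return float(ar)
    if convention == "minus_one":
        return float(ar - 1.0)
    raise ParameterError(f"unknown allelic-richness convention {convention!r}")


# ---------------------------------------------------------------------------
# neutrality statistics

def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S: int, mean_pairwise_diff: float, n: int) -> float:
    """Tajima's (1989) D from S, the mean absolute pairwise difference and n.

    Returns NaN when S = 0 (the statistic is undefined).
    """
    if n < 4:
        raise ParameterError("Tajima's D needs n >= 4")
    if S == 0:
        return float("nan")
    c = _tajima_constants(n)
    num = mean_pairwise_diff - S / c["a1"]
    den = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1.0))
    return float(num / den)


@lru_cache(maxsize=8)
def _log_stirling_triangle(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via the signless-Stirling recursion.

    Computed in log-space (|s(n,k)| overflows fixed-width integers well
    below the sample sizes seen in pooled mtDNA datasets, e.g. n = 273).
    """
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        cur[1: m + 1] = np.logaddexp(
            prev[0:m], math.log(m - 1) + prev[1: m + 1] if m > 1 else -np.inf
        )
        prev = cur
    return prev


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 1..n under the Ewens sampling formula.

    Pr(K=k) = |s(n,k)| theta^k / theta^(n) (rising factorial).
    """
    if theta <= 0:
        raise ParameterError("Ewens distribution needs theta > 0")
    logs = _log_stirling_triangle(n)[1:]  # k = 1..n
    k = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    return logs + k * math.log(theta) - log_rising


def fu_fs(k_obs: int, n: int, theta: float) -> float:
    """Fu's (1997) Fs: ln(S'/(1-S')) with S' = Pr(K >= k_obs | theta, n).

    theta is conventionally the mean pairwise difference (theta-pi).
    Returns +inf when k_obs = 1 (S' = 1, statistic undefined/degenerate).
    """
    if not 1 <= k_obs <= n:
        raise ParameterError("k_obs must lie in [1, n]")
    if theta <= 0:
        raise ParameterError("Fu's Fs needs theta > 0")
    logp = ewens_log_pmf(n, theta)
    log_tail = special.logsumexp(logp[k_obs - 1:])
    if log_tail >= 0.0:  # S' = 1 within rounding
        return float("inf")
    # log(1 - S') computed stably
    log_head = special.logsumexp(logp[: k_obs - 1]) if k_obs > 1 else -np.inf
    if not np.isfinite(log_head):
        return float("inf")
    return float(log_tail - log_head)


# ---------------------------------------------------------------------------
# coalescent null simulation

def simulate_coalescent_summary(
    n: int, theta: float, rng: np.random.Generator
) -> tuple[int, float, int, float]:
    """One standard-coalescent sample; returns (S, mean pairwise diff, K, n).

    Simulates a Kingman genealogy (no recombination), drops
    Poisson(theta/2 * branch length) infinite-sites mutations on it, and
    summarises: segregating sites S, mean absolute pairwise difference and
    the haplotype count K.
    """
    # genealogy: branch list of (descendant-tip-count, length, parent index)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    ntips = np.zeros(n_nodes, dtype=int)
    time = np.zeros(n_nodes)
    ntips[:n] = 1
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(nxt)
        ntips[nxt] = ntips[a] + ntips[b]
        nxt += 1
    root = n_nodes - 1
    lengths = np.array(
        [time[parent[v]] - time[v] if parent[v] >= 0 else 0.0 for v in range(n_nodes)]
    )
    total = lengths.sum()
    S = int(rng.poisson(theta / 2.0 * total))
    if S == 0:
        return 0, 0.0, 1, float(n)
    branches = rng.choice(n_nodes, size=S, p=lengths / total)
    muts = np.bincount(branches, minlength=n_nodes)
    # mean pairwise difference: each mutation on a branch with m descendant
    # tips contributes m*(n-m) discordant pairs
    m = ntips[branches]
    kbar = float((m * (n - m)).sum() / (n * (n - 1) / 2.0))
    # haplotype count: tips sharing the same set of mutated ancestral branches
    mutated = muts > 0
    sig = {}
    for tip in range(n):
        key = []
        v = tip
        while v != root:
            if mutated[v]:
                key.append(v)
            v = parent[v]
        sig.setdefault(tuple(key), 0)
    K = len(sig)
    return S, kbar, K, float(n)


@dataclass(frozen=True)
class NeutralityResult:
    D: float
    D_p: float
    Fs: float
    Fs_p: float
    n_sim: int
    seed: int


def neutrality_null(
    S: int,
    mean_pairwise_diff: float,
    k_obs: int,
    n: int,
    n_sim: int = 1000,
    seed: int = 0,
) -> NeutralityResult:
    """Tajima's D and Fu's Fs with coalescent-simulated p-values.

    Null samples are standard constant-size coalescent genealogies without
    recombination. Following the definitions of each statistic, the D null
    is simulated at theta-hat = S/a1 (Watterson) and the Fs null at
    theta-hat-pi (mean pairwise difference). Significance convention:
    p = Pr(stat_sim <= stat_obs); for Fs the conventional significance
    level is 0.02 (an Fs test at nominal alpha = 0.05).
    """
    if n_sim < 100:
        raise ParameterError("n_sim must be >= 100")
    c = _tajima_constants(n)
    D_obs = tajimas_d(S, mean_pairwise_diff, n)
    Fs_obs = (
        fu_fs(k_obs, n, mean_pairwise_diff)
        if mean_pairwise_diff > 0
        else float("inf")
    )
    rng = np.random.Generator(np.random.PCG64(seed))
    theta_w = S / c["a1"] if S > 0 else 0.0
    theta_pi = mean_pairwise_diff
    D_hits = D_tot = 0
    Fs_hits = Fs_tot = 0
    for _ in range(n_sim):
        if theta_w > 0:
            S_sim, kbar_sim, _, _ = simulate_coalescent_summary(n, theta_w, rng)
            D_sim = tajimas_d(S_sim, kbar_sim, n) if S_sim > 0 else float("nan")
            if not math.isnan(D_sim) and not math.isnan(D_obs):
                D_tot += 1
                if D_sim <= D_obs:
                    D_hits += 1
        if theta_pi > 0:
            _, kbar_sim, K_sim, _ = simulate_coalescent_summary(n, theta_pi, rng)
            Fs_sim = (
                fu_fs(K_sim, n, kbar_sim) if kbar_sim > 0 else float("inf")
            )
            if math.isfinite(Fs_obs):
                Fs_tot += 1
                if Fs_sim <= Fs_obs:
                    Fs_hits += 1
    D_p = D_hits / D_tot if D_tot else float("nan")
    Fs_p = Fs_hits / Fs_tot if Fs_tot else float("nan")
    return NeutralityResult(D_obs, D_p, Fs_obs, Fs_p, n_sim, seed)


# ---------------------------------------------------------------------------
# mismatch distribution

def mismatch_observed(
    aln: Alignment, mask: SiteMask, sample_ids: list[str] | None = None
) -> np.ndarray:
    """Histogram of absolute pairwise differences over all C(n,2) pairs."""
    sub = aln if sample_ids is None else aln.subset(sample_ids)
    if sub.n < 3:
        raise DegenerateDataError("mismatch distribution needs n >= 3")
    diffs, _ = pairwise_difference_matrix(sub, mask)
    iu = np.triu_indices(sub.n, 1)
    d = diffs[iu].astype(int)
    return np.bincount(d)


def mismatch_expected(
    tau: float, theta0: float, theta1: float, d_max: int
) -> np.ndarray:
    """Expected pairwise-difference frequencies under sudden expansion.

    Rogers-Harpending (1992) model: a population at mutation-scaled size
    theta0 grew instantaneously to theta1 at mutation time tau before the
    present. The equilibrium case is the geometric law
    F_j(theta) = theta^j / (theta+1)^(j+1). Probability mass beyond d_max
    is folded into the last class so the vector sums to 1.
    """
    j = np.arange(d_max + 1)
    log_eq1 = j * np.log(theta1) - (j + 1) * np.log1p(theta1) if theta1 > 0 else \
        np.where(j == 0, 0.0, -np.inf)
    eq1 = np.exp(log_eq1)
    if theta0 > 0:
        eq0 = np.exp(j * np.log(theta0) - (j + 1) * np.log1p(theta0))
    else:
        eq0 = np.where(j == 0, 1.0, 0.0)
    if tau <= 0:
        F = eq1.copy()
    else:
        if theta1 > 0:
            rate = (1.0 + theta1) / theta1
            recent = eq1 * special.gammainc(j + 1, rate * tau)
            # convolution of the pre-expansion geometric with Poisson(tau)
            log_pois = j * math.log(tau) - special.gammaln(j + 1)
            pois = np.exp(log_pois)
            conv = np.convolve(pois, eq0)[: d_max + 1]
            old = math.exp(-rate * tau) * conv
            F = recent + old
        else:  # theta1 = 0: every pair coalesces immediately, zero differences
            F = eq1.copy()
    F = np.clip(F, 0.0, None)
    tail = max(0.0, 1.0 - F.sum())
    F[-1] += tail
    return F


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness index with a trailing zero class.

    r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2 over relative frequencies
    x_0..x_d with x_{d+1} = 0 appended (boundary convention fixed here;
    other published conventions omit the trailing term).
    """
    x = np.append(np.asarray(freqs, dtype=float), 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass(frozen=True)
class MismatchResult:
    observed: np.ndarray
    tau: float
    theta0: float
    theta1: float
    SSD: float
    raggedness: float
    SSD_p: float
    raggedness_p: float
    converged: bool
    n_boot: int
    seed: int


def _fit_ssd(obs_freq: np.ndarray, coarse: bool = True,
             x0: tuple[float, float, float] | None = None) -> tuple[np.ndarray, float, bool]:
    """Minimise SSD over (tau, theta0, theta1 >= theta0)."""
    d_max = len(obs_freq) - 1
    mean_d = float(np.sum(np.arange(d_max + 1) * obs_freq))

    def ssd(params: np.ndarray) -> float:
        tau, th0, dth = params
        if tau < 0 or th0 < 0 or dth < 0:
            return np.inf
        exp_f = mismatch_expected(tau, th0, th0 + dth, d_max)
        return float(np.sum((obs_freq - exp_f) ** 2))

    best, best_val = None, np.inf
    if coarse:
        taus = np.linspace(0.0, max(2.0 * mean_d, 1.0), 9)
        th0s = np.array([0.0, 0.1, 0.5, 1.0, max(mean_d, 1.0)])
        dths = np.array([0.0, 1.0, 5.0, 20.0, 100.0, 1000.0])
        for t in taus:
            for a in th0s:
                for b in dths:
                    v = ssd(np.array([t, a, b]))
                    if v < best_val:
                        best, best_val = np.array([t, a, b]), v
    if x0 is not None:
        v = ssd(np.asarray(x0, dtype=float))
        if v < best_val:
            best, best_val = np.asarray(x0, dtype=float), v
    res = optimize.minimize(
        ssd, best, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    params = np.clip(res.x, 0.0, None)
    final = ssd(params)
    if final > best_val:  # keep the grid point if refinement wandered off
        params, final = best, best_val
    return params, float(final), bool(res.success or final <= best_val)


def mismatch_fit(
    observed: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
) -> MismatchResult:
    """Fit the sudden-expansion model by least squares on frequencies.

    Parameters are estimated by coarse grid search plus Nelder-Mead
    refinement of SSD = sum_j (obs_freq_j - exp_freq_j)^2. p-values come
    from a parametric bootstrap: C(n,2) pairwise differences are redrawn
    i.i.d. from the fitted law, the model is refit, and the observed SSD
    and raggedness are compared to the simulated distributions.
    """
    observed = np.asarray(observed, dtype=float)
    n_pairs = observed.sum()
    if n_pairs < 3:
        raise DegenerateDataError("mismatch fit needs >= 3 pairs")
    obs_freq = observed / n_pairs
    params, ssd_obs, converged = _fit_ssd(obs_freq)
    tau, th0, dth = params
    rag_obs = raggedness(obs_freq)
    d_max = len(obs_freq) - 1
    fitted = mismatch_expected(tau, th0, th0 + dth, d_max)
    rng = np.random.Generator(np.random.PCG64(seed))
    ssd_ge = rag_ge = 0
    for _ in range(n_boot):
        sim = rng.multinomial(int(n_pairs), fitted) / n_pairs
        _, ssd_sim, _ = _fit_ssd(sim, coarse=False, x0=(tau, th0, dth))
        if ssd_sim >= ssd_obs:
            ssd_ge += 1
        if raggedness(sim) >= rag_obs:
            rag_ge += 1
    return MismatchResult(
        observed=observed,
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th0 + dth),
        SSD=float(ssd_obs),
        raggedness=float(rag_obs),
        SSD_p=ssd_ge / n_boot,
        raggedness_p=rag_ge / n_boot,
        converged=converged,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-population summary table

def diversity_table(
    aln: Alignment,
    mask: SiteMask,
    popmap: PopulationMap,
    table: HaplotypeTable,
    min_n: int = 5,
    rarefaction_g: int | None = None,
    ar_convention: str = "raw",
    neutrality_sims: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population and pooled diversity statistics.

    Populations with fewer than ``min_n`` samples are listed with their
    sample size but excluded from per-population statistics; they are
    always included in the pooled TOTAL row. ``rarefaction_g`` defaults to
    the smallest sample size among included populations.
    """
    from .seqio import count_site_classes

    pops = list(table.population_ids)
    sizes = {p: int(table.population_counts(p).sum()) for p in pops}
    included = [p for p in pops if sizes[p] >= min_n]
    if rarefaction_g is None:
        rarefaction_g = min((sizes[p] for p in included), default=1)
    rows = []
    units = [(p, popmap.samples_of(p)) for p in pops] + [
        ("TOTAL", list(aln.sample_ids))
    ]
    for label, sids in units:
        n = len(sids)
        row: dict[str, object] = {"population_id": label, "n": n}
        if label != "TOTAL" and sizes[label] < min_n:
            rows.append(row)
            continue
        counts = table.population_counts(None if label == "TOTAL" else label)
        sub = aln.subset(sids)
        hd, hd_sd = haplotype_diversity(counts)
        pi, pi_sd = nucleotide_diversity(aln, mask, sids)
        S, _, _ = count_site_classes(sub, mask)
        diffs, _ = pairwise_difference_matrix(sub, mask)
        kbar = float(diffs[np.triu_indices(n, 1)].mean())
        nh = int((counts > 0).sum())
        row.update(
            Nh=nh,
            Hd=hd,
            Hd_sd=hd_sd,
            pi=pi,
            pi_sd=pi_sd,
            S=S,
            singletons=int((counts == 1).sum()),
            Ar=allelic_richness(counts, min(rarefaction_g, n), ar_convention),
        )
        if n >= 4 and S >= 1 and kbar > 0:
            res = neutrality_null(
                S, kbar, nh, n, n_sim=neutrality_sims, seed=seed
            )
            row.update(D=res.D, D_p=res.D_p, Fs=res.Fs, Fs_p=res.Fs_p)
        rows.append(row)
    return pd.DataFrame(rows)
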