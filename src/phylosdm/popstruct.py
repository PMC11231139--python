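"""Pairwise Phi-ST and hierarchical AMOVA with permutation significance.

Distance-based analysis of molecular variance in the Excoffier,
Smouse & Quattro (1992) framework: the total sum of squared inter-haplotype
distances is partitioned among groups, among populations within groups and
within populations; Phi-statistics are ratios of the resulting variance
components and their significance is assessed by permutation of the
appropriate exchangeable units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, MetadataError, ParameterError
from .popgen import pairwise_difference_matrix
from .seqio import Alignment, SiteMask

__all__ = [
    "distance_matrix",
    "pairwise_phist",
    "PairwiseFstMatrix",
    "amova",
    "AmovaResult",
    "grouping_presets",
]


def distance_matrix(
    aln: Alignment, mask: SiteMask, gamma_a: float | None = None
) -> np.ndarray:
    """Pairwise distance matrix in (optionally gamma-corrected) differences.

    Default is the raw count of differing sites, appropriate for shallow
    intraspecific divergence. ``gamma_a`` applies a Jukes-Cantor + gamma
    rate-heterogeneity correction to the per-site distance before rescaling
    back to site counts.
    """
    diffs, compared = pairwise_difference_matrix(aln, mask)
    if gamma_a is None:
        return diffs
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(compared > 0, diffs / compared, 0.0)
        d = 0.75 * gamma_a * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / gamma_a) - 1.0)
    np.fill_diagonal(d, 0.0)
    return d * compared


def _ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared distances within a set, divided by its size."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _variance_components(
    d2: np.ndarray, pop_of: np.ndarray, group_of_pop: dict[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AMOVA sums of squares, dfs and variance components (sigma_a,b,c)."""
    N = len(pop_of)
    pops = np.unique(pop_of)
    groups = np.unique([group_of_pop[p] for p in pops])
    P, G = len(pops), len(groups)
    ss_total = _ss(d2, np.arange(N))
    pop_idx = {p: np.nonzero(pop_of == p)[0] for p in pops}
    ss_wp = sum(_ss(d2, pop_idx[p]) for p in pops)
    ss_group = 0.0
    group_sizes = {}
    for g in groups:
        gi = np.concatenate([pop_idx[p] for p in pops if group_of_pop[p] == g])
        group_sizes[g] = len(gi)
        ss_group += _ss(d2, gi)
    ss_ag = ss_total - ss_group
    ss_apwg = ss_group - ss_wp
    df = np.array([G - 1, P - G, N - P], dtype=float)
    # Excoffier et al. (1992) expected-mean-square coefficients
    sizes = {p: len(pop_idx[p]) for p in pops}
    sum_np2_over_Ng = sum(
        sum(sizes[p] ** 2 for p in pops if group_of_pop[p] == g) / group_sizes[g]
        for g in groups
    )
    sum_np2_over_N = sum(sizes[p] ** 2 for p in pops) / N
    sum_Ng2_over_N = sum(s**2 for s in group_sizes.values()) / N
    n1 = (N - sum_np2_over_Ng) / (P - G) if P > G else 0.0
    n2 = (sum_np2_over_Ng - sum_np2_over_N) / (G - 1) if G > 1 else 0.0
    n3 = (N - sum_Ng2_over_N) / (G - 1) if G > 1 else 0.0
    ms_wp = ss_wp / df[2] if df[2] > 0 else 0.0
    sigma_c = ms_wp
    sigma_b = ((ss_apwg / df[1]) - sigma_c) / n1 if df[1] > 0 and n1 > 0 else 0.0
    sigma_a = (
        ((ss_ag / df[0]) - sigma_c - n2 * sigma_b) / n3
        if df[0] > 0 and n3 > 0
        else 0.0
    )
    return (
        np.array([ss_ag, ss_apwg, ss_wp]),
        df,
        np.array([sigma_a, sigma_b, sigma_c]),
    )


@dataclass(frozen=True)
class AmovaResult:
    grouping_name: str
    df: np.ndarray
    sigma: np.ndarray  # (sigma_a, sigma_b, sigma_c)
    percent_variation: np.ndarray
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float
    p_sc: float
    p_st: float
    n_perm: int
    seed: int
    degenerate_levels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [
                    "among_groups",
                    "among_populations_within_groups",
                    "within_populations",
                ],
                "df": self.df.astype(int),
                "percent_variation": self.percent_variation,
                "phi": [self.phi_ct, self.phi_sc, self.phi_st],
                "p": [self.p_ct, self.p_sc, self.p_st],
            }
        )


def _phis(sigma: np.ndarray) -> tuple[float, float, float]:
    a, b, c = sigma
    total = a + b + c
    phi_ct = a / total if total != 0 else float("nan")
    phi_sc = b / (b + c) if (b + c) != 0 else float("nan")
    phi_st = (a + b) / total if total != 0 else float("nan")
    return phi_ct, phi_sc, phi_st


def amova(
    dist: np.ndarray,
    sample_pops: list[str],
    grouping: dict[str, str],
    grouping_name: str = "grouping",
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA with per-level permutation tests.

    ``dist`` is the square matrix of inter-individual distances ordered as
    ``sample_pops``; ``grouping`` maps population id -> group id.
    Permutation schemes: individuals among all populations (Phi-st),
    individuals among populations within their group (Phi-sc), and whole
    populations among groups (Phi-ct). Negative variance components (and
    hence negative Phi estimates) are retained.
    """
    dist = np.asarray(dist, dtype=float)
    missing = sorted({p for p in sample_pops} - set(grouping))
    if missing:
        raise MetadataError(f"populations missing from grouping: {missing}")
    pop_names = list(dict.fromkeys(sample_pops))
    pop_code = {p: i for i, p in enumerate(pop_names)}
    grp_names = list(dict.fromkeys(grouping[p] for p in pop_names))
    grp_code = {g: i for i, g in enumerate(grp_names)}
    pop_of = np.array([pop_code[p] for p in sample_pops])
    group_of_pop = {pop_code[p]: grp_code[grouping[p]] for p in pop_names}
    d2 = dist**2
    _, df, sigma = _variance_components(d2, pop_of, group_of_pop)
    phi_ct, phi_sc, phi_st = _phis(sigma)
    total = sigma.sum()
    pct = 100.0 * sigma / total if total != 0 else np.full(3, np.nan)
    degenerate = []
    if len(grp_names) < 2:
        degenerate.append("among_groups")
    pops_per_group: dict[int, list[int]] = {}
    for p, g in group_of_pop.items():
        pops_per_group.setdefault(g, []).append(p)
    if all(len(v) < 2 for v in pops_per_group.values()):
        degenerate.append("among_populations_within_groups")

    rng = np.random.Generator(np.random.PCG64(seed))
    ge_st = ge_sc = ge_ct = 0
    n_st = n_sc = n_ct = 0
    group_of_ind = np.array([group_of_pop[p] for p in pop_of])
    for _ in range(n_perm):
        # Phi-st: shuffle individuals among all populations
        perm = rng.permutation(len(pop_of))
        _, _, s = _variance_components(d2, pop_of[perm], group_of_pop)
        st = _phis(s)[2]
        if not np.isnan(st) and not np.isnan(phi_st):
            n_st += 1
            if st >= phi_st:
                ge_st += 1
        # Phi-sc: shuffle individuals among populations within each group
        if "among_populations_within_groups" not in degenerate:
            perm2 = np.arange(len(pop_of))
            for g in np.unique(group_of_ind):
                idx = np.nonzero(group_of_ind == g)[0]
                perm2[idx] = idx[rng.permutation(len(idx))]
            _, _, s = _variance_components(d2, pop_of[perm2], group_of_pop)
            sc = _phis(s)[1]
            if not np.isnan(sc) and not np.isnan(phi_sc):
                n_sc += 1
                if sc >= phi_sc:
                    ge_sc += 1
        # Phi-ct: shuffle whole populations among groups
        if "among_groups" not in degenerate:
            pop_list = sorted(group_of_pop)
            shuffled = rng.permutation([group_of_pop[p] for p in pop_list])
            g_perm = {p: int(shuffled[i]) for i, p in enumerate(pop_list)}
            _, _, s = _variance_components(d2, pop_of, g_perm)
            ct = _phis(s)[0]
            if not np.isnan(ct) and not np.isnan(phi_ct):
                n_ct += 1
                if ct >= phi_ct:
                    ge_ct += 1
    p_st = ge_st / n_st if n_st else float("nan")
    p_sc = ge_sc / n_sc if n_sc else float("nan")
    p_ct = ge_ct / n_ct if n_ct else float("nan")
    return AmovaResult(
        grouping_name=grouping_name,
        df=df,
        sigma=sigma,
        percent_variation=pct,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_ct=p_ct,
        p_sc=p_sc,
        p_st=p_st,
        n_perm=n_perm,
        seed=seed,
        degenerate_levels=tuple(degenerate),
    )


@dataclass(frozen=True)
class PairwiseFstMatrix:
    population_ids: tuple[str, ...]
    phist: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int
    skipped: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.phist,
            index=list(self.population_ids),
            columns=list(self.population_ids),
        )


def _two_pop_phist(d2: np.ndarray, labels: np.ndarray) -> float:
    """Phi-st of a two-population AMOVA from squared distances."""
    N = len(labels)
    pops = np.unique(labels)
    ss_total = _ss(d2, np.arange(N))
    ss_wp = sum(_ss(d2, np.nonzero(labels == p)[0]) for p in pops)
    df_ap, df_wp = len(pops) - 1, N - len(pops)
    if df_wp <= 0:
        return float("nan")
    sizes = np.array([(labels == p).sum() for p in pops], dtype=float)
    n_c = (N - (sizes**2).sum() / N) / df_ap
    sigma_w = ss_wp / df_wp
    sigma_a = ((ss_total - ss_wp) / df_ap - sigma_w) / n_c
    tot = sigma_a + sigma_w
    return float(sigma_a / tot) if tot != 0 else float("nan")


def pairwise_phist(
    dist: np.ndarray,
    sample_pops: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    min_n: int = 2,
) -> PairwiseFstMatrix:
    """Pairwise Phi-ST between all population pairs with permutation p-values.

    Negative estimates are retained (not clamped at zero). p = fraction of
    permutations (individuals shuffled between the two populations) with
    Phi >= the observed value. Populations smaller than ``min_n`` are
    skipped and reported in ``skipped``.
    """
    dist = np.asarray(dist, dtype=float)
    d2 = dist**2
    pops = list(dict.fromkeys(sample_pops))
    labels = np.asarray(sample_pops)
    sizes = {p: int((labels == p).sum()) for p in pops}
    kept = [p for p in pops if sizes[p] >= min_n]
    skipped = tuple(p for p in pops if sizes[p] < min_n)
    k = len(kept)
    if k < 2:
        raise DegenerateDataError("pairwise Phi-ST needs >= 2 usable populations")
    phist = np.zeros((k, k))
    pvals = np.ones((k, k))
    rng = np.random.Generator(np.random.PCG64(seed))
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.nonzero(np.isin(labels, [kept[i], kept[j]]))[0]
            sub = d2[np.ix_(idx, idx)]
            sub_labels = labels[idx]
            obs = _two_pop_phist(sub, sub_labels)
            ge = tot = 0
            for _ in range(n_perm):
                perm = _two_pop_phist(sub, sub_labels[rng.permutation(len(idx))])
                if not np.isnan(perm):
                    tot += 1
                    if perm >= obs:
                        ge += 1
            phist[i, j] = phist[j, i] = obs
            pvals[i, j] = pvals[j, i] = ge / tot if tot else float("nan")
    return PairwiseFstMatrix(tuple(kept), phist, pvals, n_perm, seed, skipped)


#: Regional AMOVA grouping schemes, keyed by population ids.
_PRESETS: dict[str, dict[str, str]] = {
    "cerraticus_geo2": {
        # Khangai Mountains vs others
        "CER1621": "khangai", "CER1808": "khangai", "CER2208": "khangai",
        "CER1402": "others", "CER1502": "others", "CER1626": "others",
        "CER1822": "others", "CER2213": "others", "CER2218": "others",
        "CER2222": "others",
    },
    "cerraticus_geo3": {
        "CER1402": "north", "CER2218": "north",
        "CER1502": "central", "CER1621": "central", "CER1626": "central",
        "CER2208": "central", "CER2213": "central", "CER2222": "central",
        "CER1808": "west", "CER1822": "west",
    },
    "ceumenes_geo2": {
        "CEU1608": "southern", "CEU1609": "southern", "CEU22A4": "southern",
        "CEU22A6": "southern", "CEU22A7": "southern", "CEU22A8": "southern",
        "CEU1415": "southeastern", "CEU1713": "southeastern",
    },
    "gmopsus_climate": {
        "GM1403": "steppe", "GM1628": "steppe", "GM1630": "steppe",
        "GM2217": "steppe",
        "GM1417": "desert", "GM1510": "desert", "GM1604": "desert",
        "GM1605": "desert", "GM1611": "desert", "GM162b": "desert",
    },
    "gmopsus_geo3": {
        "GM1403": "north", "GM2217": "north",
        "GM1628": "central", "GM1630": "central",
        "GM1417": "south", "GM1510": "south", "GM1604": "south",
        "GM1605": "south", "GM1611": "south", "GM162b": "south",
    },
    "gmopsus_roads4": {
        "GM1403": "northcentral", "GM1630": "northcentral",
        "GM1628": "northwest", "GM2217": "northwest",
        "GM1510": "south", "GM1604": "south", "GM1605": "south",
        "GM1611": "south",
        "GM1417": "southeast", "GM162b": "southeast",
    },
}


def grouping_presets(name: str | None = None) -> dict:
    """Preset grouping schemes (population id -> group id).

    With no argument, returns the full preset dictionary.
    """
    if name is None:
        return {k: dict(v) for k, v in _PRESETS.items()}
    try:
        return dict(_PRESETS[name])
    except KeyError:
        raise ParameterError(
            f"unknown grouping preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
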