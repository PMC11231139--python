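"""Seeded synthetic-data generators with known ground truth.

Emulates every input class the pipeline consumes: coalescent mtDNA
alignments under constant-size or sudden-expansion demographies with
island-model population structure; smooth, correlated bioclim-like raster
layers; occurrences sampled from a known suitability surface; and future
layers as perturbed copies of the present. A single top-level seed fans
out to per-stage seeds through ``numpy.random.SeedSequence`` spawning, so
each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .sdm.evaluate import OccurrenceSet
from .sdm.raster import GridGeometry, RasterStack
from .seqio import Alignment, PopulationMap

__all__ = [
    "SimConfig",
    "simulate_alignment",
    "simulate_genealogy",
    "simulate_rasters",
    "true_suitability",
    "sample_occurrences",
    "make_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults mirror a regional single-locus survey: a handful of
    populations of 15-35 samples each at a few-hundred-bp mitochondrial
    locus, weak-to-moderate island-model structure, a 60x60 bioclim-like
    grid over a temperate-arid window, and a few dozen occurrence records.
    """

    seed: int = 0
    n_populations: int = 3
    samples_per_population: int = 20
    locus_length_bp: int = 600
    theta: float = 5.0
    demography: str = "constant"  # "constant" | "sudden_expansion"
    growth_factor: float = 100.0
    expansion_time: float = 0.125  # coalescent units before present
    migration_rate: float = 1.0  # per-lineage emigration rate
    grid_rows: int = 60
    grid_cols: int = 60
    n_layers: int = 7
    layer_correlation: float = 0.5
    lon_min: float = 90.0
    lat_min: float = 42.0
    cellsize: float = 0.2
    suitability_coef: tuple[float, ...] = (30.0, 24.0, -75.0, -60.0)
    n_presences: int = 40
    future_deltas: tuple[float, ...] = ()
    future_noise_sd: float = 0.05

    def __post_init__(self):
        if min(self.n_populations, self.samples_per_population,
               self.locus_length_bp, self.grid_rows, self.grid_cols,
               self.n_layers, self.n_presences) <= 0:
            raise ParameterError("all sizes must be positive")
        if self.demography not in ("constant", "sudden_expansion"):
            raise ParameterError(f"unknown demography {self.demography!r}")

    def stage_seeds(self) -> dict[str, np.random.SeedSequence]:
        names = ["alignment", "rasters", "occurrences", "background", "cv"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return dict(zip(names, children))


# ---------------------------------------------------------------------------
# coalescent sequence simulation

def simulate_genealogy(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structured-coalescent genealogy under the configured demography.

    Returns (parent, time, deme_of_tip). Island model: each lineage
    emigrates at ``migration_rate`` to a uniformly chosen other deme;
    within-deme pairs coalesce at rate 1 per pair in units of the present
    population size, multiplied by ``growth_factor`` past the expansion
    time (the ancestral population being that much smaller).
    """
    d = cfg.n_populations
    k = cfg.samples_per_population
    n = d * k
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    deme_of_tip = np.repeat(np.arange(d), k)
    lineage_deme = {i: int(deme_of_tip[i]) for i in range(n)}
    active = list(range(n))
    t = 0.0
    nxt = n
    expanding = cfg.demography == "sudden_expansion"
    while len(active) > 1:
        by_deme: dict[int, list[int]] = {}
        for lin in active:
            by_deme.setdefault(lineage_deme[lin], []).append(lin)
        size_factor = (
            cfg.growth_factor if expanding and t >= cfg.expansion_time else 1.0
        )
        coal_rates = {
            dm: len(v) * (len(v) - 1) / 2.0 * size_factor
            for dm, v in by_deme.items()
        }
        mig_rate = len(active) * cfg.migration_rate if d > 1 else 0.0
        total = sum(coal_rates.values()) + mig_rate
        if total == 0.0:
            # isolated singleton lineages with no migration cannot meet
            raise ParameterError("genealogy cannot coalesce: no migration")
        dt = rng.exponential(1.0 / total)
        if expanding and t < cfg.expansion_time and t + dt > cfg.expansion_time:
            t = cfg.expansion_time  # rates change; redraw waiting time
            continue
        t += dt
        u = rng.uniform(0.0, total)
        acc = 0.0
        event = None
        for dm, r in coal_rates.items():
            acc += r
            if u < acc:
                event = ("coal", dm)
                break
        if event is None:
            event = ("mig", None)
        if event[0] == "mig":
            lin = active[rng.integers(len(active))]
            others = [x for x in range(d) if x != lineage_deme[lin]]
            lineage_deme[lin] = int(others[rng.integers(len(others))])
        else:
            dm = event[1]
            pool = by_deme[dm]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[i], pool[j]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            active.remove(a)
            active.remove(b)
            del lineage_deme[a], lineage_deme[b]
            lineage_deme[nxt] = dm
            active.append(nxt)
            nxt += 1
    return parent, time, deme_of_tip


def simulate_alignment(
    cfg: SimConfig, seed: int | None = None
) -> tuple[Alignment, PopulationMap, dict]:
    """Coalescent alignment with finite-sites mutation plus metadata.

    Mutations fall as a Poisson process of rate theta/2 per unit branch
    length; each hit picks a uniform site and substitutes a uniformly
    chosen different base, so recurrent and back mutation are possible
    (finite-sites, matching real mtDNA data where S, haplotype collapsing
    and the mismatch distribution all feel multiple hits).
    """
    ss = (
        np.random.SeedSequence(seed)
        if seed is not None
        else cfg.stage_seeds()["alignment"]
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    parent, time, deme_of_tip = simulate_genealogy(cfg, rng)
    n = cfg.n_populations * cfg.samples_per_population
    n_nodes = 2 * n - 1
    L = cfg.locus_length_bp
    root = n_nodes - 1
    bases = np.array(list("ACGT"))
    seqs = {root: rng.integers(0, 4, size=L)}
    # children lists for top-down traversal
    children: dict[int, list[int]] = {}
    for v in range(n_nodes - 1):
        children.setdefault(parent[v], []).append(v)
    stack = [root]
    while stack:
        v = stack.pop()
        for c in children.get(v, []):
            seq = seqs[v].copy()
            bl = time[v] - time[c]
            n_mut = rng.poisson(cfg.theta / 2.0 * bl)
            for _ in range(n_mut):
                site = rng.integers(L)
                seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
            seqs[c] = seq
            stack.append(c)
    sample_ids = tuple(
        f"P{deme_of_tip[i] + 1}_{i % cfg.samples_per_population + 1:03d}"
        for i in range(n)
    )
    sequences = tuple("".join(bases[seqs[i]]) for i in range(n))
    # place populations at spread-out coordinates inside the raster window
    lon_span = cfg.grid_cols * cfg.cellsize
    lat_span = cfg.grid_rows * cfg.cellsize
    pop_coords = {
        f"P{dm + 1}": (
            cfg.lon_min + lon_span * (dm + 0.5) / cfg.n_populations,
            cfg.lat_min + lat_span * (0.3 + 0.4 * (dm % 2)),
        )
        for dm in range(cfg.n_populations)
    }
    popmap = PopulationMap(
        population={
            sid: f"P{deme_of_tip[i] + 1}" for i, sid in enumerate(sample_ids)
        },
        lon={
            sid: pop_coords[f"P{deme_of_tip[i] + 1}"][0]
            for i, sid in enumerate(sample_ids)
        },
        lat={
            sid: pop_coords[f"P{deme_of_tip[i] + 1}"][1]
            for i, sid in enumerate(sample_ids)
        },
    )
    truth = {
        "theta": cfg.theta,
        "demography": cfg.demography,
        "growth_factor": cfg.growth_factor if cfg.demography != "constant" else 1.0,
        "expansion_time": cfg.expansion_time,
        "migration_rate": cfg.migration_rate,
    }
    return Alignment(sample_ids, sequences), popmap, truth


# ---------------------------------------------------------------------------
# rasters, suitability and occurrences

def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  sigma: float = 6.0) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_rasters(
    cfg: SimConfig, seed: int | None = None
) -> tuple[RasterStack, dict[str, RasterStack]]:
    """Current stack plus one perturbed future stack per scenario.

    Layers are smooth Gaussian-blurred fields sharing a common component
    to reach the configured pairwise correlation; future layers add the
    per-layer deltas of ``future_deltas`` (grouped in blocks of
    ``n_layers``; scenario s uses block s) plus small smooth noise.
    """
    ss = (
        np.random.SeedSequence(seed)
        if seed is not None
        else cfg.stage_seeds()["rasters"]
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    shape = (cfg.grid_rows, cfg.grid_cols)
    shared = _smooth_field(shape, rng)
    rho = math.sqrt(max(0.0, min(1.0, cfg.layer_correlation)))
    layers: dict[str, np.ndarray] = {}
    for i in range(cfg.n_layers):
        indep = _smooth_field(shape, rng)
        layers[f"bio{i + 1}"] = rho * shared + math.sqrt(1 - rho**2) * indep
    geom = GridGeometry(cfg.grid_rows, cfg.grid_cols, cfg.lon_min,
                        cfg.lat_min, cfg.cellsize)
    current = RasterStack(geom, {k: v.copy() for k, v in layers.items()})
    futures: dict[str, RasterStack] = {}
    if cfg.future_deltas:
        if len(cfg.future_deltas) % cfg.n_layers:
            raise ParameterError(
                "future_deltas length must be a multiple of n_layers"
            )
        n_scen = len(cfg.future_deltas) // cfg.n_layers
        for s in range(n_scen):
            block = cfg.future_deltas[s * cfg.n_layers:(s + 1) * cfg.n_layers]
            fut = {}
            for i, name in enumerate(layers):
                noise = (
                    cfg.future_noise_sd * _smooth_field(shape, rng)
                    if cfg.future_noise_sd > 0
                    else 0.0
                )
                fut[name] = layers[name] + block[i] + noise
            futures[f"scenario{s + 1}"] = RasterStack(geom, fut)
    return current, futures


def true_suitability(cfg: SimConfig, stack: RasterStack) -> np.ndarray:
    """Known linear-quadratic suitability surface on the first two layers.

    eta = c1*z1 + c2*z2 + c3*(z1 - 0.5)^2 + c4*(z2 - 0.5)^2 with z the
    min-max-normalised layers; suitability = exp(eta) normalised to sum to
    1 over valid cells.
    """
    c1, c2, c3, c4 = cfg.suitability_coef
    names = stack.layer_names[:2]
    z = []
    for nm in names:
        a = stack.layers[nm]
        lo, hi = np.nanmin(a), np.nanmax(a)
        z.append((a - lo) / (hi - lo) if hi > lo else np.zeros_like(a))
    eta = c1 * z[0] + c2 * z[1] + c3 * (z[0] - 0.5) ** 2 + c4 * (z[1] - 0.5) ** 2
    s = np.exp(eta)
    s[~stack.mask] = np.nan
    s /= np.nansum(s)
    return s


def sample_occurrences(
    suitability: np.ndarray,
    stack: RasterStack,
    n: int,
    seed: int = 0,
    species: str = "synthetic",
) -> OccurrenceSet:
    """Occurrence points drawn cell-wise proportional to true suitability.

    Cells are drawn with replacement proportional to suitability and the
    point is jittered uniformly within its cell.
    """
    cells = stack.valid_cells()
    if n > len(cells):
        raise ParameterError("more occurrences requested than valid cells")
    rng = np.random.Generator(np.random.PCG64(seed))
    w = suitability[cells[:, 0], cells[:, 1]]
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    idx = rng.choice(len(cells), size=n, replace=True, p=w)
    g = stack.geometry
    pts = []
    for i in idx:
        r, c = cells[i]
        lon, lat = g.cell_center(r, c)
        pts.append(
            (
                lon + (rng.uniform() - 0.5) * g.cellsize * 0.98,
                lat + (rng.uniform() - 0.5) * g.cellsize * 0.98,
            )
        )
    return OccurrenceSet(np.array(pts), species)


# ---------------------------------------------------------------------------
# micro-fixtures for unit tests

def make_fixture(name: str) -> dict:
    """Deterministic micro-datasets used across the test-suite.

    Available fixtures:

    * ``"cer1502-like"`` — one population of 5 sequences carrying 3
      haplotypes with counts (3, 1, 1), so Hd = 0.7000.
    * ``"extirpation-toy"`` — 3 populations, 5 haplotypes, 2 of them
      private to population C.
    * ``"two-cluster"`` — two populations fixed for haplotypes 5 sites
      apart (complete between-population divergence).
    """
    base = "ACGTACGTAC"
    if name == "cer1502-like":
        seqs = {
            "s1": base, "s2": base, "s3": base,
            "s4": "ACGTACGTAT",
            "s5": "ACGTACGAAC",
        }
        aln = Alignment(tuple(seqs), tuple(seqs.values()))
        popmap = PopulationMap(
            {s: "A" for s in seqs},
            {s: 100.0 for s in seqs},
            {s: 45.0 for s in seqs},
        )
        return {"alignment": aln, "popmap": popmap}
    if name == "extirpation-toy":
        hap = {
            "h1": "AAAAAAAAAA",
            "h2": "AAAAAAAAAT",
            "h3": "AAAAAAAATT",
            "h4": "TTTTTAAAAA",
            "h5": "TTTTTAAAAT",
        }
        assign = [
            ("a1", "A", "h1"), ("a2", "A", "h1"), ("a3", "A", "h2"),
            ("b1", "B", "h1"), ("b2", "B", "h3"), ("b3", "B", "h3"),
            ("c1", "C", "h4"), ("c2", "C", "h5"), ("c3", "C", "h4"),
        ]
        aln = Alignment(
            tuple(s for s, _, _ in assign),
            tuple(hap[h] for _, _, h in assign),
        )
        coords = {"A": (95.0, 44.0), "B": (100.0, 47.0), "C": (105.0, 50.0)}
        popmap = PopulationMap(
            {s: p for s, p, _ in assign},
            {s: coords[p][0] for s, p, _ in assign},
            {s: coords[p][1] for s, p, _ in assign},
        )
        return {"alignment": aln, "popmap": popmap, "private_to_C": 2}
    if name == "two-cluster":
        a = "AAAAAAAAAA"
        b = "TTTTTAAAAA"  # 5 fixed differences
        ids = [f"x{i}" for i in range(6)]
        seqs = [a, a, a, b, b, b]
        pops = ["X", "X", "X", "Y", "Y", "Y"]
        aln = Alignment(tuple(ids), tuple(seqs))
        popmap = PopulationMap(
            dict(zip(ids, pops)),
            {i: 100.0 for i in ids},
            {i: 45.0 for i in ids},
        )
        return {"alignment": aln, "popmap": popmap, "fixed_differences": 5}
    raise ParameterError(f"unknown fixture {name!r}")
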