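"""Coupling projected range change to genetic diversity.

Binary presence/absence maps give range-size change per climate scenario;
sampled populations persist when the projected suitability of their cell
clears the current model's 10% training threshold; haplotype number,
haplotype diversity and nucleotide diversity are then recomputed over the
individuals of persisting populations only. Populations are point-sampled
at their cell with no dispersal buffer, the conservative
restricted-dispersal assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, MetadataError
from .haplonet import HaplotypeNetwork
from .popgen import haplotype_diversity, nucleotide_diversity
from .sdm.raster import RasterStack
from .seqio import Alignment, HaplotypeTable, PopulationMap, SiteMask

__all__ = [
    "range_change",
    "persisting_populations",
    "retained_diversity",
    "annotate_loss",
    "ScenarioForecast",
    "forecast_table",
]


@dataclass(frozen=True)
class ScenarioForecast:
    scenario: str
    area_current_km2: float
    area_future_km2: float
    cells_current: int
    cells_future: int
    change_pct: float
    persisting_populations: tuple[str, ...]
    haplotypes_retained_pct: float
    Hd_retained: float
    pi_retained: float
    lost_haplotype_ids: tuple[str, ...]


def range_change(
    binary_current: np.ndarray,
    binary_future: np.ndarray,
    stack: RasterStack,
) -> tuple[float, float, int, int, float]:
    """Cosine-latitude-weighted areas and the percent change in range size.

    Returns (area_current_km2, area_future_km2, cells_current,
    cells_future, change_pct). Change is undefined (NaN) when the current
    range is empty.
    """
    if binary_current.shape != binary_future.shape:
        raise MetadataError("binary maps must share one grid geometry")
    areas = stack.cell_areas_km2()
    cur = binary_current == 1
    fut = binary_future == 1
    a_c = float(areas[cur].sum())
    a_f = float(areas[fut].sum())
    change = 100.0 * (a_f - a_c) / a_c if a_c > 0 else float("nan")
    return a_c, a_f, int(cur.sum()), int(fut.sum()), change


def persisting_populations(
    future_suitability: np.ndarray,
    threshold: float,
    popmap: PopulationMap,
    stack: RasterStack,
    strict: bool = False,
) -> tuple[set[str], set[str]]:
    """Populations whose cell clears the current threshold in the future map.

    Persistence uses suitability >= threshold by default (consistent with
    map binarisation; ``strict`` switches to a strict inequality, which
    differs only on exact ties). Coordinates on a nodata cell fall back to
    the nearest valid cell within a 1-cell radius; populations with no
    evaluable cell are reported separately.

    Returns (persisting, non_evaluable).
    """
    mask = stack.mask
    persisting: set[str] = set()
    non_evaluable: set[str] = set()
    for pop, (lon, lat) in popmap.population_coords().items():
        r, c = stack.geometry.cell_of(lon, lat)
        if not mask[r, c]:
            candidates = [
                (rr, cc)
                for rr in range(max(0, r - 1), min(mask.shape[0], r + 2))
                for cc in range(max(0, c - 1), min(mask.shape[1], c + 2))
                if mask[rr, cc]
            ]
            if not candidates:
                non_evaluable.add(pop)
                continue
            r, c = candidates[0]
        s = future_suitability[r, c]
        if np.isnan(s):
            non_evaluable.add(pop)
            continue
        if (s > threshold) if strict else (s >= threshold):
            persisting.add(pop)
    return persisting, non_evaluable


def retained_diversity(
    table: HaplotypeTable,
    aln: Alignment,
    mask: SiteMask,
    popmap: PopulationMap,
    persisting: set[str],
) -> tuple[float, float, float, tuple[str, ...]]:
    """Genetic diversity recomputed over persisting populations only.

    All individuals of persisting populations are pooled, including those
    from small sites excluded from per-population reporting, because the
    retained totals are species-level. Returns (haplotypes_retained_pct,
    Hd, pi, lost haplotype ids); an empty persisting set yields all-zero
    retained statistics by definition.
    """
    unknown = persisting - set(table.population_ids)
    if unknown:
        raise MetadataError(f"unknown populations: {sorted(unknown)}")
    nh_total = table.n_haplotypes
    if not persisting:
        return 0.0, 0.0, 0.0, tuple(table.haplotype_ids)
    cols = [table.population_ids.index(p) for p in sorted(persisting)]
    kept_counts = table.counts[:, cols].sum(axis=1)
    retained_ids = [
        h for h, c in zip(table.haplotype_ids, kept_counts) if c > 0
    ]
    lost = tuple(
        h for h, c in zip(table.haplotype_ids, kept_counts) if c == 0
    )
    retained_pct = 100.0 * len(retained_ids) / nh_total
    sids = [
        s for s in aln.sample_ids if popmap.population[s] in persisting
    ]
    if len(sids) < 2:
        return retained_pct, 0.0, 0.0, lost
    hd, _ = haplotype_diversity(kept_counts)
    pi, _ = nucleotide_diversity(aln, mask, sids)
    return retained_pct, float(hd), float(pi), lost


def annotate_loss(
    net: HaplotypeNetwork, lost_by_scenario: dict[str, tuple[str, ...]]
) -> tuple[dict[str, dict[str, str]], dict[str, bool]]:
    """Per-scenario retained/lost node annotation and a scattered-loss flag.

    Losses are 'scattered' when lost nodes are not predominantly adjacent
    to other lost nodes in the tree (no majority of edges incident to lost
    nodes join two lost nodes), echoing the observation that missing
    haplotypes spread across the genealogy rather than pruning a clade.
    """
    status: dict[str, dict[str, str]] = {}
    scattered: dict[str, bool] = {}
    all_ids = set(net.table.haplotype_ids)
    for scen, lost in lost_by_scenario.items():
        unknown = set(lost) - all_ids
        if unknown:
            raise MetadataError(f"unknown haplotype ids: {sorted(unknown)}")
        lost_set = set(lost)
        status[scen] = {
            h: ("lost" if h in lost_set else "retained")
            for h in net.table.haplotype_ids
        }
        incident = [
            (a, b)
            for a, b in net.graph.edges()
            if a in lost_set or b in lost_set
        ]
        both = sum(1 for a, b in incident if a in lost_set and b in lost_set)
        scattered[scen] = not incident or both <= len(incident) / 2.0
    return status, scattered


def forecast_table(forecasts: list[ScenarioForecast]) -> pd.DataFrame:
    """Render scenario forecasts with the standard report columns."""
    return pd.DataFrame(
        [
            {
                "scenario": f.scenario,
                "haplotypes_retained_pct": f.haplotypes_retained_pct,
                "Hd": f.Hd_retained,
                "pi": f.pi_retained,
                "area_change_pct": f.change_pct,
            }
            for f in forecasts
        ],
        columns=[
            "scenario",
            "haplotypes_retained_pct",
            "Hd",
            "pi",
            "area_change_pct",
        ],
    )
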