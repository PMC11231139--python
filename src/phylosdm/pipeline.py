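"""End-to-end orchestration: one config in, the full report bundle out.

Runs the complete analysis — diversity table, AMOVA, haplotype network,
SDM grid evaluation and selection, current/future suitability maps and the
scenario forecast of retained genetic diversity — from either file inputs
or the synthetic generators, and renders the standard table shapes.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import forecast as fc, haplonet, popgen, popstruct, sdm, seqio
from .errors import InputError
from .synthetic import (
    SimConfig,
    sample_occurrences,
    simulate_alignment,
    simulate_rasters,
    true_suitability,
)

__all__ = ["RunConfig", "run_all", "report"]


@dataclass
class RunConfig:
    """All knobs of one analysis run.

    Either ``sim`` is set (synthetic run) or the input paths are; every
    under-determined analysis choice (site-mask policy, rarefaction size,
    permutation/simulation counts, the RM grid, feature classes, folds,
    background size, the correlation cutoff, output transform, threshold
    rule and the persistence inequality) surfaces here with its default.
    """

    species: str = "synthetic"
    sim: SimConfig | None = None
    alignment_path: str | None = None
    metadata_path: str | None = None
    occurrence_path: str | None = None
    raster_paths: dict[str, dict[str, str]] = field(default_factory=dict)
    # popgen
    mask_policy: str = "complete_deletion"
    min_population_n: int = 5
    rarefaction_g: int | None = None
    ar_convention: str = "raw"
    n_perm: int = 1000
    n_sim: int = 1000
    mismatch_boot: int = 100
    grouping: dict[str, str] | None = None
    # sdm
    thin_km: float = 5.0
    r_max: float = 0.8
    keep_list: tuple[str, ...] = ()
    rm_grid: tuple[float, ...] = sdm.DEFAULT_RM_GRID
    feature_classes: tuple[str, ...] = sdm.DEFAULT_FEATURE_CLASSES
    k_folds: int = 10
    background_size: int = 10_000
    n_knots: int = 20
    transform: str = "logistic"
    # forecast
    strict_persistence: bool = False
    seed: int = 0


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        cfg = config.sim
        aln, popmap, truth = simulate_alignment(cfg)
        current, futures = simulate_rasters(cfg)
        suit = true_suitability(cfg, current)
        occ = sample_occurrences(
            suit, current, cfg.n_presences,
            seed=int(cfg.stage_seeds()["occurrences"].generate_state(1)[0] % 2**31),
        )
        popmap = _place_populations_on_range(popmap, current, suit)
        return aln, popmap, occ, current, futures, truth
    if not (config.alignment_path and config.metadata_path):
        raise InputError("either sim or alignment/metadata paths must be set")
    aln = seqio.read_alignment(config.alignment_path)
    popmap = seqio.read_population_map(config.metadata_path)
    occ = (
        sdm.OccurrenceSet.read_csv(config.occurrence_path, config.species)
        if config.occurrence_path
        else None
    )
    current = futures = None
    if config.raster_paths:
        paths = dict(config.raster_paths)
        if "current" not in paths:
            raise InputError("raster_paths must include a 'current' stack")
        current = sdm.read_raster_stack(paths.pop("current"))
        futures = {k: sdm.read_raster_stack(v) for k, v in paths.items()}
    return aln, popmap, occ, current, futures or {}, None


def _place_populations_on_range(popmap, stack, suitability):
    """Relocate synthetic populations onto occupied habitat.

    Sampled populations sit where the species occurs, so each synthetic
    population is assigned the centre of a distinct cell drawn from
    spread-out ranks of the upper suitability range (from near-optimal to
    marginal), mirroring surveys that sample occupied sites of varying
    habitat quality.
    """
    cells = stack.valid_cells()
    s = suitability[cells[:, 0], cells[:, 1]]
    order = np.argsort(-s, kind="stable")
    pops = popmap.populations()
    # ranks spread over the top ~30% of cells: best site first, then
    # progressively more marginal ones
    span = max(1, int(0.3 * len(order)))
    picks = [order[int(i * span / max(1, len(pops)))] for i in range(len(pops))]
    lon = dict(popmap.lon)
    lat = dict(popmap.lat)
    for pop, pick in zip(pops, picks):
        r, c = cells[pick]
        plon, plat = stack.geometry.cell_center(int(r), int(c))
        for sid in popmap.samples_of(pop):
            lon[sid] = plon
            lat[sid] = plat
    return seqio.PopulationMap(dict(popmap.population), lon, lat,
                               dict(popmap.groups))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the report bundle.

    The bundle maps stage names to data frames / objects and includes a
    manifest with versions, seeds and the effective settings, sufficient
    to reproduce every table.
    """
    aln, popmap, occ, current, futures, truth = _load_inputs(config)
    bundle: dict = {"notices": []}

    # --- sequence handling and diversity ---------------------------------
    mask = seqio.build_site_mask(aln, config.mask_policy)
    table = seqio.collapse_haplotypes(aln, mask, popmap)
    S, pi_sites, singleton_sites = seqio.count_site_classes(aln, mask)
    bundle["site_classes"] = {
        "S": S,
        "parsimony_informative": pi_sites,
        "singleton_sites": singleton_sites,
    }
    bundle["diversity"] = popgen.diversity_table(
        aln, mask, popmap, table,
        min_n=config.min_population_n,
        rarefaction_g=config.rarefaction_g,
        ar_convention=config.ar_convention,
        neutrality_sims=config.n_sim,
        seed=config.seed,
    )
    observed = popgen.mismatch_observed(aln, mask)
    bundle["mismatch"] = popgen.mismatch_fit(
        observed, n_boot=config.mismatch_boot, seed=config.seed
    )

    # --- structure --------------------------------------------------------
    dist = popstruct.distance_matrix(aln, mask)
    sample_pops = [popmap.population[s] for s in aln.sample_ids]
    sizes = pd.Series(sample_pops).value_counts()
    usable = sizes[sizes >= config.min_population_n]
    if len(usable) >= 2:
        keep = [
            i for i, p in enumerate(sample_pops) if p in set(usable.index)
        ]
        bundle["pairwise_phist"] = popstruct.pairwise_phist(
            dist[np.ix_(keep, keep)],
            [sample_pops[i] for i in keep],
            n_perm=config.n_perm,
            seed=config.seed,
            min_n=config.min_population_n,
        )
    grouping = config.grouping
    if grouping is None and popmap.groups:
        grouping = next(iter(popmap.groups.values()))
    if grouping is None:
        # default split: first half of populations vs second half
        pops = popmap.populations()
        grouping = {
            p: ("G1" if i < len(pops) / 2 else "G2") for i, p in enumerate(pops)
        }
    bundle["amova"] = popstruct.amova(
        dist, sample_pops, grouping,
        n_perm=config.n_perm, seed=config.seed,
    )

    # --- haplotype network ------------------------------------------------
    net = haplonet.build_network(table)
    bundle["network"] = net
    bundle["network_summary"] = haplonet.network_summary(net)

    # --- SDM --------------------------------------------------------------
    forecasts: list[fc.ScenarioForecast] = []
    lost_by_scenario: dict[str, tuple[str, ...]] = {}
    if occ is not None and current is not None:
        occ_thin = sdm.thin_occurrences(occ, config.thin_km)
        layer_names = sdm.correlation_filter(
            current, keep_list=list(config.keep_list), r_max=config.r_max
        )
        pres_cells = occ_thin.snap_to_cells(current)
        bg_cells = sdm.sample_background(
            current, config.background_size, seed=config.seed
        )
        X_pres = current.values_at(pres_cells, layer_names)
        X_bg = current.values_at(bg_cells, layer_names)
        X_grid = current.values_at(current.valid_cells(), layer_names)
        report_df = sdm.evaluate_cv(
            X_pres, X_bg,
            rm_grid=config.rm_grid,
            feature_classes=config.feature_classes,
            k_folds=config.k_folds,
            seed=config.seed,
            n_knots=config.n_knots,
            X_grid=X_grid,
            transform=config.transform,
        )
        bundle["sdm_report"] = report_df
        rm, fcls = sdm.select_model(report_df)
        bundle["sdm_selected"] = {"rm": rm, "fc": fcls}
        model = sdm.MaxEntSDM(
            feature_classes=fcls, rm=rm, n_knots=config.n_knots,
            transform=config.transform,
        ).fit(
            np.vstack([X_pres, X_bg]),
            np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_bg))]),
        )
        bundle["sdm_model"] = model
        bundle["sdm_layers"] = layer_names
        thr = sdm.threshold_10pct(model.predict(X_pres))
        bundle["threshold"] = thr
        cur_map = sdm.predict_map(model, current, layer_names)
        cur_bin = sdm.binarize(cur_map, thr.value)
        bundle["current_map"] = cur_map
        bundle["current_binary"] = cur_bin

        # --- forecast ----------------------------------------------------
        if not futures:
            bundle["notices"].append(
                "no future rasters configured; forecast stage skipped"
            )
        for scen, stack in (futures or {}).items():
            fut_map = sdm.predict_map(model, stack, layer_names)
            fut_bin = sdm.binarize(fut_map, thr.value)
            a_c, a_f, c_c, c_f, change = fc.range_change(
                cur_bin, fut_bin, current
            )
            persisting, non_eval = fc.persisting_populations(
                fut_map, thr.value, popmap, stack,
                strict=config.strict_persistence,
            )
            if non_eval:
                bundle["notices"].append(
                    f"{scen}: populations not evaluable: {sorted(non_eval)}"
                )
            retained_pct, hd, pi, lost = fc.retained_diversity(
                table, aln, mask, popmap, persisting
            )
            lost_by_scenario[scen] = lost
            forecasts.append(
                fc.ScenarioForecast(
                    scenario=scen,
                    area_current_km2=a_c,
                    area_future_km2=a_f,
                    cells_current=c_c,
                    cells_future=c_f,
                    change_pct=change,
                    persisting_populations=tuple(sorted(persisting)),
                    haplotypes_retained_pct=retained_pct,
                    Hd_retained=hd,
                    pi_retained=pi,
                    lost_haplotype_ids=lost,
                )
            )
        if lost_by_scenario:
            bundle["loss_annotation"] = fc.annotate_loss(net, lost_by_scenario)
    else:
        bundle["notices"].append(
            "no occurrences/rasters configured; SDM and forecast skipped"
        )
    bundle["forecasts"] = forecasts
    bundle["haplotype_table"] = table
    from . import __version__ as pkg_version

    bundle["manifest"] = {
        "package_version": pkg_version,
        "python": platform.python_version(),
        "species": config.species,
        "seed": config.seed,
        "settings": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("sim",)
        }
        | ({"sim": asdict(config.sim)} if config.sim is not None else {}),
        "truth": truth,
    }
    return bundle


def report(bundle: dict, out_dir: str | Path, fmt: str = "tsv") -> dict[str, Path]:
    """Render the bundle as tab-separated tables plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str, index=False):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        written[name] = p

    _write(bundle["diversity"], "diversity_table")
    if "amova" in bundle:
        _write(bundle["amova"].to_frame(), "amova_table")
    if "pairwise_phist" in bundle:
        _write(bundle["pairwise_phist"].to_frame(), "pairwise_phist", index=True)
    net = bundle.get("network")
    if net is not None:
        _write(net.edge_list(), "network_edges")
        _write(net.node_table(), "network_nodes", index=True)
    if "sdm_report" in bundle:
        _write(bundle["sdm_report"], "sdm_evaluation")
    _write(fc.forecast_table(bundle["forecasts"]), "forecast_table")
    manifest = dict(bundle["manifest"])
    manifest["notices"] = bundle["notices"]
    if "sdm_selected" in bundle:
        manifest["sdm_selected"] = bundle["sdm_selected"]
    if "threshold" in bundle:
        manifest["threshold"] = float(bundle["threshold"].value)
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = mp
    if fmt == "json":
        jp = out / "tables.json"
        jp.write_text(
            json.dumps(
                {
                    "diversity": bundle["diversity"].to_dict(orient="records"),
                    "forecast": fc.forecast_table(
                        bundle["forecasts"]
                    ).to_dict(orient="records"),
                },
                indent=2,
                default=str,
            )
        )
        written["tables_json"] = jp
    return written
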