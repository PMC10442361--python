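"""End-to-end pipeline: simulate -> covariates -> fit -> evaluate -> risk.

One master seed drives every stage; rerunning with the same seed and
parameters produces byte-identical output files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import evaluation as ev
from . import models as md
from . import risk as rk
from . import simulate as sim
from .raster import RasterGrid

__all__ = ["run_pipeline", "sites_to_frame", "units_to_geojson", "simulate_dataset"]

N_SITES_DEFAULT = 248
N_UNITS_DEFAULT = 159


def sites_to_frame(sites) -> pd.DataFrame:
    """Long-format site table (site_id, x, y, year, count)."""
    rows = []
    for s in sites:
        for year, count in sorted(s.counts_by_year.items()):
            rows.append({"site_id": s.site_id, "x": s.x, "y": s.y, "year": year, "count": count})
    return pd.DataFrame(rows)


def units_to_geojson(units, extra: pd.DataFrame | None = None) -> dict:
    """GeoJSON FeatureCollection of admin units with their properties."""
    import shapely

    features = []
    extra_by_id = (
        {int(r["unit_id"]): r for _, r in extra.iterrows()} if extra is not None else {}
    )
    for u in units:
        props = {
            "unit_id": u.unit_id,
            "population": u.population,
            "colonies": u.colonies,
            "report_count": u.report_count,
            "apiary_rate": round(u.apiary_rate, 6),
        }
        row = extra_by_id.get(u.unit_id)
        if row is not None:
            for k, v in row.items():
                if k in props or k == "unit_id":
                    continue
                props[k] = None if pd.isna(v) else (round(float(v), 8) if isinstance(v, float) else v)
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(u.polygon)),
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def simulate_dataset(
    seed: int,
    config: sim.LandscapeConfig | None = None,
    process: sim.AbundanceProcess | None = None,
    n_sites: int = N_SITES_DEFAULT,
    n_units: int = N_UNITS_DEFAULT,
):
    """Generate one full synthetic study: environment, abundance surface,
    trap sites, covariate table and administrative units.

    Returns a dict with every intermediate product (rasters, site table
    with covariates and categories, admin units).
    """
    if config is None:
        config = sim.LandscapeConfig(seed=seed)
    else:
        config = sim.replace(config, seed=seed)
    if process is None:
        process = sim.AbundanceProcess()

    climate, landcover = sim.generate_environment(config)
    ref = next(iter(climate.values()))
    comp = cov.align_to_coarse(
        landcover,
        ref,
        radius=process.buffer_radius_km,
        n_classes=config.n_land_classes,
        class_names=config.land_class_names(),
    )
    surface = sim.generate_abundance_surface(climate, comp, process, config)
    sites = sim.sample_sites(surface, n_sites, process, seed=seed)
    site_tab = cov.site_mean_abundance(sites)
    table = cov.build_covariate_table(site_tab, climate, comp)
    table["mean_count"] = site_tab["mean_count"]
    table["category"] = md.categorize(table["mean_count"].to_numpy())
    units = sim.generate_admin_data(config.extent, n_units, surface, seed=seed)
    covariate_names = list(climate.keys()) + list(comp.keys())
    return {
        "config": config,
        "process": process,
        "climate": climate,
        "landcover": landcover,
        "composition": comp,
        "surface": surface,
        "sites": sites,
        "table": table,
        "units": units,
        "covariate_names": covariate_names,
    }


def _grid_covariate_frame(climate, comp) -> pd.DataFrame:
    layers = {**climate, **comp}
    return pd.DataFrame({k: g.values.ravel().astype(float) for k, g in layers.items()})


def run_pipeline(
    seed: int,
    out_dir: str | Path | None = None,
    config: sim.LandscapeConfig | None = None,
    process: sim.AbundanceProcess | None = None,
    n_sites: int = N_SITES_DEFAULT,
    n_units: int = N_UNITS_DEFAULT,
    n_rep: int = 100,
    cor_threshold: float = 0.8,
    priority: list[str] | None = None,
    write_rasters: bool = False,
) -> dict:
    """Run the full analysis on one synthetic study and optionally write
    all output tables (CSV/GeoJSON/ASCII-grid) under ``out_dir``.

    Stages: landscape + survey simulation; buffer-composition covariates
    and the Pearson collinearity filter; replicated stratified evaluation
    of the four abundance and two occurrence variants with rank-sum /
    AUC selection; final full-data fits with importance, partial
    dependence and the Kruskal-Wallis + Dunn category-discrimination test;
    admin aggregation, validation correlations and the two hazard x
    sensitivity risk indices.
    """
    data = simulate_dataset(seed, config=config, process=process, n_sites=n_sites, n_units=n_units)
    table = data["table"]
    covariate_names = data["covariate_names"]

    retained = cov.collinearity_filter(
        table[covariate_names], threshold=cor_threshold, priority=priority
    )

    rows, summary = ev.replicate_evaluation(
        table, retained, n_rep=n_rep, base_seed=seed
    )
    sam_best = summary.loc[
        summary["selected"] & summary["variant"].isin(ev.SAM_VARIANTS), "variant"
    ].iloc[0]
    sdm_best = summary.loc[
        summary["selected"] & summary["variant"].isin(ev.SDM_VARIANTS), "variant"
    ].iloc[0]

    # final full-data models
    _, alg, transform = ev._variant_spec(sam_best)
    final_sam = md.fit_sam(table, retained, algorithm=alg, transform=transform, seed=seed)
    _, alg_sdm, _ = ev._variant_spec(sdm_best)
    final_sdm = md.fit_sdm(table, retained, algorithm=alg_sdm, seed=seed)

    sam_site_pred = final_sam.predict(table[retained])
    sdm_site_prob = final_sdm.predict_proba_presence(table[retained])
    cats = table["category"].to_numpy()
    dunn_sam = ev.kruskal_dunn(sam_site_pred, cats)
    dunn_sdm = ev.kruskal_dunn(sdm_site_prob, cats)

    importance = md.variable_importance(final_sam)
    pdp = {
        v: md.partial_dependence(final_sam, table[retained], v)
        for v in importance["variable"].head(4)
    }

    grid_X = _grid_covariate_frame(data["climate"], data["composition"])[retained]
    surface_shape = data["surface"].values.shape
    pred_raster = data["surface"].copy_with(
        final_sam.predict(grid_X).reshape(surface_shape)
    )
    prob_raster = data["surface"].copy_with(
        final_sdm.predict_proba_presence(grid_X).reshape(surface_shape)
    )
    suitable_fraction = float(np.mean(prob_raster.values > 0.5))

    unit_table = rk.build_unit_risk_table(data["units"], pred_raster)
    validation = rk.validate_abundance(unit_table)

    results = {
        **data,
        "retained": retained,
        "replicates": rows,
        "summary": summary,
        "sam_best": sam_best,
        "sdm_best": sdm_best,
        "final_sam": final_sam,
        "final_sdm": final_sdm,
        "dunn_sam": dunn_sam,
        "dunn_sdm": dunn_sdm,
        "importance": importance,
        "pdp": pdp,
        "prediction_raster": pred_raster,
        "probability_raster": prob_raster,
        "suitable_fraction": suitable_fraction,
        "unit_table": unit_table,
        "validation": validation,
    }
    if out_dir is not None:
        _write_outputs(results, Path(out_dir), write_rasters=write_rasters)
    return results


def _write_outputs(results: dict, out_dir: Path, write_rasters: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    sites_to_frame(results["sites"]).to_csv(
        out_dir / "sites.csv", index=False, float_format=float_fmt
    )
    results["table"].to_csv(out_dir / "covariates.csv", index=False, float_format=float_fmt)
    results["replicates"].to_csv(
        out_dir / "evaluation_replicates.csv", index=False, float_format=float_fmt
    )
    results["summary"].to_csv(
        out_dir / "evaluation_summary.csv", index=False, float_format=float_fmt
    )
    results["importance"].to_csv(
        out_dir / "importance.csv", index=False, float_format=float_fmt
    )
    pdp_long = pd.concat(
        [df.assign(variable=v) for v, df in results["pdp"].items()], ignore_index=True
    )
    pdp_long.to_csv(out_dir / "partial_dependence.csv", index=False, float_format=float_fmt)
    results["unit_table"].to_csv(
        out_dir / "units_risk.csv", index=False, float_format=float_fmt
    )
    validation_rows = [
        {"signal": k, "r": v.r, "t": v.t, "df": v.df, "p": v.p}
        for k, v in results["validation"].items()
    ]
    pd.DataFrame(validation_rows).to_csv(
        out_dir / "validation.csv", index=False, float_format=float_fmt
    )
    letters = {
        "sam": results["dunn_sam"]["letters"],
        "sdm": results["dunn_sdm"]["letters"],
        "sam_H": results["dunn_sam"]["H"],
        "sdm_H": results["dunn_sdm"]["H"],
        "sam_best": results["sam_best"],
        "sdm_best": results["sdm_best"],
        "retained": results["retained"],
        "suitable_fraction": results["suitable_fraction"],
    }
    (out_dir / "selection.json").write_text(json.dumps(letters, indent=2, sort_keys=True))
    geo = units_to_geojson(results["units"], extra=results["unit_table"])
    (out_dir / "admin_units.geojson").write_text(json.dumps(geo, sort_keys=True))
    if write_rasters:
        results["prediction_raster"].write_ascii(out_dir / "predicted_abundance.asc")
        results["probability_raster"].write_ascii(out_dir / "establishment_probability.asc")
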