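"""End-to-end orchestration: simulate -> extract -> agromet -> select -> model.

The feature table produced here is the package's central container: one row
per plot-date with namespaced columns ``vi.*`` (vegetation indices),
``tex.band*.*`` (GLCM texture), ``cc`` (canopy cover), ``gdd`` (growing
degree days), ``gpr`` (growth process ratio), design covariates and the
``true_agb`` target.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import agromet, feature_selection, image_features, model_eval
from .synthetic_scene import SceneConfig, iterate_scene, simulate_weather

__all__ = [
    "build_feature_table",
    "extract_from_directory",
    "run_pipeline",
    "config_hash",
]


def config_hash(config: SceneConfig, seed: int) -> str:
    """Short provenance hash of the run configuration."""
    def _default(o):
        if isinstance(o, dt.date):
            return o.isoformat()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    payload = json.dumps({"config": config, "seed": seed}, default=_default,
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _agromet_columns(
    df: pd.DataFrame,
    weather: pd.DataFrame,
    cultivars,
) -> pd.DataFrame:
    """Append ``gdd`` and ``gpr`` columns keyed on cultivar and flight date."""
    gdd_vals, gpr_vals = [], []
    cache: dict[tuple[str, str], tuple[float, float]] = {}
    for cv_id, date_iso in zip(df["cultivar"], df["flight_date"]):
        key = (cv_id, date_iso)
        if key not in cache:
            cv = cultivars[cv_id]
            date = dt.date.fromisoformat(date_iso)
            g = agromet.accumulate_gdd(
                weather, cv.base_temp, cv.emergence_date, date
            )
            r = agromet.gpr_at(
                cv_id, cv.total_period_days, cv.emergence_date, date
            ).gpr
            cache[key] = (g, r)
        g, r = cache[key]
        gdd_vals.append(g)
        gpr_vals.append(r)
    out = df.copy()
    out["gdd"] = gdd_vals
    out["gpr"] = gpr_vals
    return out


def build_feature_table(
    config: SceneConfig | None = None,
    seed: int = 0,
    *,
    include_texture: bool = True,
) -> pd.DataFrame:
    """Simulate the study in memory and extract the full feature table."""
    if config is None:
        config = SceneConfig()
    h, w = config.image_size
    polygon = box(0, 0, w, h)
    weather = simulate_weather(config.weather_start, config.weather_end, seed=seed)
    rows = []
    for plot, truth, stack in iterate_scene(config, seed):
        row = {
            "experiment": plot.experiment_id,
            "plot_id": plot.plot_id,
            "flight_date": truth.flight_date.isoformat(),
            "stage": truth.stage,
            "cultivar": plot.cultivar_id,
            "density": plot.density,
            "n_rate": plot.n_rate,
            "k_rate": plot.k_rate,
            "true_agb": truth.true_agb,
            "true_cc": truth.true_cc,
        }
        row.update(
            image_features.extract_features(
                stack, polygon, include_texture=include_texture
            )
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return _agromet_columns(df, weather, config.cultivars)


def extract_from_directory(
    scene_dir,
    *,
    include_texture: bool = True,
) -> pd.DataFrame:
    """Extract the feature table from a written scene directory.

    Expects the layout of :func:`agbfusion.synthetic_scene.generate_dataset`:
    ``rasters/*.tif`` (six reflectance bands then RGB), ``plots.geojson``,
    ``weather.csv``, ``cultivars.csv`` and ``ground_truth.csv``.
    """
    import tifffile
    import shapely.geometry

    from .synthetic_scene import BandStack, CultivarInfo

    scene = Path(scene_dir)
    truth = pd.read_csv(scene / "ground_truth.csv")
    weather = pd.read_csv(scene / "weather.csv")
    catalog = pd.read_csv(scene / "cultivars.csv")
    cultivars = {
        r.cultivar_id: CultivarInfo(
            r.cultivar_id,
            int(r.total_period_days),
            dt.date.fromisoformat(r.emergence_date),
            float(r.base_temp),
        )
        for r in catalog.itertuples()
    }
    with open(scene / "plots.geojson") as fh:
        features = json.load(fh)["features"]
    polygons = {
        f["properties"]["plot_id"]: shapely.geometry.shape(f["geometry"])
        for f in features
    }

    rows = []
    for rec in truth.itertuples():
        with tifffile.TiffFile(scene / rec.raster) as tif:
            planes = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        ms = np.moveaxis(planes[:6], 0, -1).astype(float)
        rgb = np.moveaxis(planes[6:9], 0, -1).astype(float) * 255.0
        stack = BandStack(
            ms=ms,
            rgb=rgb,
            band_roles=meta["band_roles"],
            plot_id=rec.plot_id,
            flight_date=dt.date.fromisoformat(rec.flight_date),
        )
        row = rec._asdict()
        row.pop("Index", None)
        row.update(
            image_features.extract_features(
                stack, polygons[rec.plot_id], include_texture=include_texture
            )
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return _agromet_columns(df, weather, cultivars)


def run_pipeline(
    config: SceneConfig | None = None,
    seed: int = 0,
    *,
    selection: str = "both",
    models: tuple[str, ...] = model_eval.MODEL_KINDS,
    outdir=None,
    table: pd.DataFrame | None = None,
    boruta_max_iter: int = 50,
) -> dict:
    """Run the full comparison and return (optionally write) the report bundle.

    ``selection`` is ``"boruta"``, ``"pearson"`` or ``"both"``.  Returns a
    dict with the feature table, per-route selection results, result grids
    and best-per-model summaries.
    """
    if config is None:
        config = SceneConfig()
    if table is None:
        table = build_feature_table(config, seed)
    routes = ("boruta", "pearson") if selection == "both" else (selection,)
    chash = config_hash(config, seed)
    bundle: dict = {"table": table, "config_hash": chash, "routes": {}}
    for route in routes:
        if route == "pearson":
            sel = feature_selection.pearson_rank(table)
        elif route == "boruta":
            sel = feature_selection.boruta_select(
                table, max_iter=boruta_max_iter, seed=seed
            )
            vif = feature_selection.vif_screen(
                table.dropna(subset=sel.confirmed) if sel.confirmed else table,
                sel.confirmed,
            ) if len(sel.confirmed) > 1 else []
            kept = {r.feature for r in vif if r.retained} if vif else set(sel.confirmed)
            sel.confirmed = [c for c in sel.confirmed if c in kept]
        else:
            raise ValueError(f"unknown selection route {route!r}")
        results, best = model_eval.run_comparison(
            table, selection=sel, models=models, seed=seed
        )
        bundle["routes"][route] = {
            "selection": sel,
            "results": results,
            "best": best,
        }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash: {chash}\n"
        with open(out / "feature_table.csv", "w") as fh:
            fh.write(header)
            table.to_csv(fh, index=False)
        for route, payload in bundle["routes"].items():
            with open(out / f"selection_{route}.json", "w") as fh:
                json.dump(
                    {"config_hash": chash, **payload["selection"].to_dict()},
                    fh, indent=2,
                )
            with open(out / f"results_{route}.csv", "w") as fh:
                fh.write(header)
                payload["results"].to_csv(fh, index=False)
        _write_report(out / "report.txt", bundle)
    return bundle


def _write_report(path, bundle: dict) -> None:
    lines = [f"config_hash: {bundle['config_hash']}", ""]
    for route, payload in bundle["routes"].items():
        sel = payload["selection"]
        lines.append(f"== selection route: {route} ==")
        lines.append(f"confirmed features ({len(sel.confirmed)}): "
                     + ", ".join(sel.confirmed))
        lines.append("")
        lines.append("best fusion per model (test partition):")
        for r in payload["best"].itertuples():
            lines.append(
                f"  {r.model:6s} {r.combo:45s} "
                f"R2={r.test_r2:.2f} rRMSE={r.test_rrmse:.2f} MAE={r.test_mae:.2f}"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines))
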