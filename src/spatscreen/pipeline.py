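"""End-to-end district workflow: weights -> global Moran per variable ->
LISA cluster map -> OLS + spatial diagnostics -> SEM/SLM -> model ranking.

The stages mirror the standard three-step spatial-econometric procedure:
first an aspatial OLS baseline, then score tests for spatial dependence in
its residuals, then maximum-likelihood spatial models where the diagnostics
call for them.  Every stage's output is a pure function of (inputs, config,
seed), so reruns are byte-identical; the bundle is written as CSV/GeoJSON
artifacts plus one machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autocorrelation import lisa_conditional_permutation, moran_permutation_test
from .geo_io import AreaTable, read_areas, write_cluster_geojson, write_geojson
from .spatial_models import (
    RegressionDesign,
    compare_models,
    fit_ols,
    fit_spatial_error,
    fit_spatial_lag,
    lm_diagnostics,
)
from .weights import build_queen_weights, write_gal

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    geometry_path: str
    attribute_path: str
    id_field: str
    outcome: str
    covariates: list[str]
    weight_style: str = "row"  # "row" | "binary"
    snap_distance: float = 1e-7
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    models: tuple[str, ...] = ("ols", "sem", "slm")
    output_dir: str = "spatscreen_output"

    def __post_init__(self) -> None:
        if self.outcome in self.covariates:
            raise ValueError("outcome cannot appear among covariates")
        if self.weight_style not in ("row", "binary"):
            raise ValueError(f"unknown weight_style {self.weight_style!r}")
        bad = set(self.models) - {"ols", "sem", "slm"}
        if bad:
            raise ValueError(f"unknown models: {sorted(bad)}")


def load_config(path) -> PipelineConfig:
    """Flat key=value config file, one key per line; '#' comments."""
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, val = line.split("=", 1)
        kv[key.strip()] = val.strip()
    return config_from_mapping(kv)


def config_from_mapping(kv: dict) -> PipelineConfig:
    required = ["geometry_path", "attribute_path", "id_field", "outcome", "covariates"]
    missing = [k for k in required if k not in kv or kv[k] in (None, "")]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    cov = kv["covariates"]
    if isinstance(cov, str):
        cov = [c.strip() for c in cov.split(",") if c.strip()]
    models = kv.get("models", ("ols", "sem", "slm"))
    if isinstance(models, str):
        models = tuple(m.strip() for m in models.split(",") if m.strip())
    return PipelineConfig(
        geometry_path=str(kv["geometry_path"]),
        attribute_path=str(kv["attribute_path"]),
        id_field=str(kv["id_field"]),
        outcome=str(kv["outcome"]),
        covariates=list(cov),
        weight_style=str(kv.get("weight_style", "row")),
        snap_distance=float(kv.get("snap_distance", 1e-7)),
        n_perm=int(kv.get("n_perm", 999)),
        alpha=float(kv.get("alpha", 0.05)),
        seed=int(kv.get("seed", 0)),
        models=tuple(models),
        output_dir=str(kv.get("output_dir", "spatscreen_output")),
    )


def summarize_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable n, mean, median, and sample SD (n-1 denominator)."""
    if table.shape[1] == 0 or len(table) == 0:
        raise ValueError("empty attribute table")
    rows = []
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        if len(v) == 0:
            raise ValueError(f"empty column {col!r}")
        rows.append(
            {
                "variable": col,
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Outputs under ``config.output_dir``: summary_statistics.csv,
    global_moran.csv, lisa_clusters.{csv,geojson}, weights.gal, residual
    GeoJSONs per fitted model, and report.json with everything (including
    the seed and a software stamp).  Returns the report dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _stage(name):
    logger.info("stage: %s", name)


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    _stage("read inputs")
    area = read_areas(config.geometry_path, config.attribute_path, config.id_field)
    names = [config.outcome, *config.covariates]
    missing = [v for v in names if v not in area.attributes.columns]
    if missing:
        raise ValueError(f"variables missing from attribute table: {missing}")

    _stage("summary statistics")
    summary = summarize_variables(area.attributes[names])
    p_sum = out / "summary_statistics.csv"
    summary.to_csv(p_sum, float_format="%.12g")
    written.append(p_sum)

    _stage("queen weights")
    w_bin = build_queen_weights(area.geometries, area.ids, config.snap_distance)
    w = w_bin.row_standardized() if config.weight_style == "row" else w_bin
    p_gal = out / "weights.gal"
    write_gal(w, p_gal)
    written.append(p_gal)

    _stage("global Moran per variable")
    moran_rows = {}
    for var in names:
        mr = moran_permutation_test(
            area.attributes[var].to_numpy(float), w, config.n_perm, seed=config.seed
        )
        moran_rows[var] = mr.to_dict()
    moran_tbl = pd.DataFrame(
        {
            "moran_i": {v: moran_rows[v]["I"] for v in names},
            "p_sim": {v: moran_rows[v]["p_sim"] for v in names},
            "z_score": {v: moran_rows[v]["z_score"] for v in names},
        }
    )
    p_moran = out / "global_moran.csv"
    moran_tbl.to_csv(p_moran, float_format="%.12g")
    written.append(p_moran)

    _stage("LISA clusters for outcome")
    y = area.attributes[config.outcome].to_numpy(float)
    lisa = lisa_conditional_permutation(
        y, w, n_perm=config.n_perm, alpha=config.alpha, seed=config.seed
    )
    lisa_tbl = pd.DataFrame(
        {
            "unit_id": area.ids,
            "local_i": lisa.local_i,
            "p_sim": lisa.p_sim,
            "quadrant": lisa.quadrant,
            "label": lisa.label,
        }
    ).set_index("unit_id")
    p_lcsv = out / "lisa_clusters.csv"
    lisa_tbl.to_csv(p_lcsv, float_format="%.12g")
    written.append(p_lcsv)
    p_lgeo = out / "lisa_clusters.geojson"
    write_cluster_geojson(area, lisa.label, lisa.local_i, lisa.p_sim, p_lgeo)
    written.append(p_lgeo)

    report: dict = {
        "software": {"package": "spatscreen", "version": __version__},
        "config": {
            "outcome": config.outcome,
            "covariates": list(config.covariates),
            "weight_style": config.weight_style,
            "snap_distance": config.snap_distance,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "seed": config.seed,
            "models": list(config.models),
        },
        "n_units": area.n,
        "weights": {
            "style": w.style,
            "s0": w.s0,
            "islands": [w.ids[i] for i in w.islands],
            "mean_neighbors": float(w.cardinalities.mean()),
        },
        "summary_statistics": json.loads(summary.to_json(orient="index")),
        "global_moran": moran_rows,
        "lisa": {
            "alpha": config.alpha,
            "n_significant": int((lisa.p_sim < config.alpha).sum()),
            "label_counts": {
                lab: int((lisa.label == lab).sum())
                for lab in ("HH", "LL", "HL", "LH", "NS")
            },
        },
        "models": {},
    }

    if config.models:
        _stage("regression models")
        w_fit = w if config.weight_style == "row" else w_bin.row_standardized()
        design = RegressionDesign.from_frame(
            area.attributes, config.outcome, list(config.covariates)
        )
        fitted = {}
        ols = fit_ols(design)
        rm = moran_permutation_test(ols.residuals, w, config.n_perm, seed=config.seed)
        od = ols.to_dict()
        od["residual_moran"] = rm.to_dict()
        if "ols" in config.models:
            report["models"]["ols"] = od
            fitted["ols"] = ols
            _write_residual_map(area, ols.residuals, out / "residuals_ols.geojson", written)
        if not w_fit.islands:
            diag = lm_diagnostics(ols, design, w_fit)
            report["lm_diagnostics"] = diag.to_dict()
        else:
            report["lm_diagnostics"] = None

        for kind, fitter in (("sem", fit_spatial_error), ("slm", fit_spatial_lag)):
            if kind not in config.models:
                continue
            res = fitter(design, w_fit)
            rd = res.to_dict()
            if len(res.residuals) == area.n:  # no islands dropped
                rm = moran_permutation_test(res.residuals, w_fit, config.n_perm, seed=config.seed)
                rd["residual_moran"] = rm.to_dict()
                _write_residual_map(area, res.residuals, out / f"residuals_{kind}.geojson", written)
            report["models"][kind] = rd
            fitted[kind] = res

        if len(fitted) >= 2 and len({len(r.residuals) for r in fitted.values()}) == 1:
            report["model_comparison"] = compare_models(*fitted.values())

    p_rep = out / "report.json"
    with open(p_rep, "w") as fh:
        json.dump(_round_floats(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(p_rep)
    return report


def _write_residual_map(area: AreaTable, residuals, path, written) -> None:
    props = pd.DataFrame({"residual": np.asarray(residuals, float)}, index=area.ids)
    write_geojson(area, path, properties=props)
    written.append(Path(path))


def _round_floats(obj):
    """12-significant-digit canonical floats so reports are byte-stable."""
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
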