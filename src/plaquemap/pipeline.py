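"""Run-level orchestration: config, stage sequencing, manifest, metrics.

A run executes the stages io -> preprocess -> segment -> annotate ->
enrich/correlate -> render on one dataset (one subject), writing every
artifact plus a manifest with checksums and wall times into the output
directory. All randomness is drawn from the single ``seed`` in the config,
so a rerun with the same config is checksum-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import msi_io, preprocessing, reference, segmentation, synthetic_data
from . import plaque_stats
from .lipid_library import MassLibrary, match_peaks

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "annotate_features", "run",
           "run_in_memory", "simulate_to_dir"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": None,         # path to an imzML file; or use `simulate`
    "simulate": None,      # kwargs for synthetic_data.generate
    "preprocessing": {
        "snr_threshold": 5.0,
        "min_fwhm_points": 3,
        "resample_spacing": None,
        "write_feature_matrix": False,
    },
    "annotation": {"tol_ppm": 2.0, "library": "reference"},
    "segmentation": {
        "k": 8,
        "n_restarts": 10,
        "scaling": "zscore",
        "rule": "marker",
        "marker_species": ["GM1(d18:1/18:0)", "GM1(d18:1/20:0)"],
        "marker_z_threshold": 1.0,
        "min_area": 5,
        "max_area": 200,
    },
    "controls": {"inner_margin_px": 2, "outer_margin_px": 6},
    "stats": {"mode": "control", "spsc_scope": "plaque_union"},
    "render": {
        "enabled": True,
        "clip_quantile": 0.99,
        "species": ["GM1(d18:1/18:0)", "GM1(d18:1/20:0)", "CerP(d18:1/18:0)",
                    "ST(d18:1/24:0)"],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve a run config: defaults <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def annotate_features(bins, library: MassLibrary, tol_ppm: float = 2.0) -> pd.DataFrame:
    """Annotate every bin center against the library; unmatched bins stay "unknown"."""
    records = []
    for center in bins.centers:
        hits = match_peaks([float(center)], library, tol_ppm)
        if hits:
            best = hits[0]
            records.append({
                "bin": float(np.round(center, 6)), "species": best.species,
                "adduct": best.adduct, "theoretical_mz": best.theoretical_mz,
                "ppm_error": best.ppm_error,
            })
        else:
            records.append({
                "bin": float(np.round(center, 6)), "species": "unknown",
                "adduct": "", "theoretical_mz": np.nan, "ppm_error": np.nan,
            })
    return pd.DataFrame.from_records(records)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_to_dir(config: dict, outdir) -> dict:
    """Generate a synthetic dataset; write imzML, truth masks and params YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.get("simulate") or {})
    sim_kwargs.setdefault("seed", config["seed"])
    ds, truth = synthetic_data.generate(**sim_kwargs)
    imzml_path = outdir / "simulated.imzML"
    msi_io.write_imzml(ds, imzml_path)
    np.savetxt(outdir / "truth_plaque_labels.csv", truth.plaque_labels,
               fmt="%d", delimiter=",")
    truth.panel.to_csv(outdir / "truth_panel.csv", index=False, float_format="%.9g")
    with open(outdir / "generator_params.yml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth.params, fh)
    return {"imzml": str(imzml_path), "n_plaques": truth.n_plaques}


def run_in_memory(config: dict, dataset=None, truth=None) -> dict:
    """Execute the analysis stages and return every intermediate product.

    ``dataset``/``truth`` may be passed directly (e.g. from
    :func:`plaquemap.synthetic_data.generate`); otherwise they come from the
    config's ``simulate`` block or ``input`` path. Returns a dict with keys
    ``dataset, truth, normalized, mean, bins, features, annotations,
    species_map, seg, rois, table, spsc, metrics, counts``.
    """
    counts: dict = {}
    if dataset is None:
        if config.get("simulate") is not None:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", config["seed"])
            dataset, truth = synthetic_data.generate(**sim_kwargs)
        elif config.get("input"):
            dataset = msi_io.read_imzml(config["input"])
        else:
            raise ValueError("config must provide either 'input' or 'simulate'")
    counts["input_pixels"] = dataset.n_pixels

    pp = config["preprocessing"]
    normalized = preprocessing.tic_normalize(dataset)
    counts["used_pixels"] = normalized.n_pixels
    counts["dropped_pixels"] = counts["input_pixels"] - normalized.n_pixels
    mz, mean = preprocessing.mean_spectrum(
        normalized, resample_spacing=pp["resample_spacing"])
    bins = preprocessing.detect_peaks(
        mz, mean, pp["snr_threshold"], pp["min_fwhm_points"])
    features = preprocessing.integrate_bins(normalized, bins)

    library = MassLibrary.from_names(reference.library_names())
    annotations = annotate_features(bins, library, config["annotation"]["tol_ppm"])
    species_map = {
        row["bin"]: row["species"]
        for _, row in annotations.iterrows() if row["species"] != "unknown"
    }

    seg_cfg = config["segmentation"]
    shape = dataset.grid_shape
    seg = segmentation.bisecting_kmeans(
        features, seg_cfg["k"], seed=config["seed"],
        n_restarts=seg_cfg["n_restarts"], scaling=seg_cfg["scaling"])
    marker_bins = [b for b, s in species_map.items()
                   if s in seg_cfg["marker_species"]]
    rule = seg_cfg["rule"]
    if rule == "marker" and not marker_bins:
        logger.warning("no marker species annotated; falling back to punctate rule")
        rule = "punctate"
    selected = segmentation.select_plaque_clusters(
        seg, features, rule=rule, marker_bins=marker_bins or None,
        area_bounds=(seg_cfg["min_area"], seg_cfg["max_area"]),
        marker_z_threshold=seg_cfg["marker_z_threshold"], shape=shape)
    counts["selected_clusters"] = sorted(int(c) for c in selected)
    rois = segmentation.derive_rois(
        seg, selected, seg_cfg["min_area"], seg_cfg["max_area"], shape)
    rois = segmentation.control_rois(
        rois, config["controls"]["inner_margin_px"],
        config["controls"]["outer_margin_px"], seed=config["seed"])
    counts["n_rois"] = len(rois.roi_ids)

    table = plaque_stats.enrichment(
        features, rois, species_map=species_map,
        subject=f"seed{config['seed']}", mode=config["stats"]["mode"])
    spsc_matrix = None
    if len(rois.roi_ids) and rois.plaque_mask().sum() >= 3:
        annotated_cols = [b for b in features.df.columns
                          if float(np.round(b, 6)) in species_map]
        spsc_matrix = plaque_stats.spsc(
            features, rois, columns=annotated_cols, species_map=species_map,
            mask_scope=config["stats"]["spsc_scope"])

    metrics = None
    if truth is not None:
        metrics = synthetic_data.score_recovery(
            truth, rois=rois, enrichment_table=table,
            detected_centers=bins.centers, spsc_matrix=spsc_matrix)

    return {
        "dataset": dataset, "truth": truth, "normalized": normalized,
        "mean_spectrum": (mz, mean), "bins": bins, "features": features,
        "annotations": annotations, "species_map": species_map, "seg": seg,
        "rois": rois, "table": table, "spsc": spsc_matrix, "metrics": metrics,
        "counts": counts,
    }


def run(config: dict, outdir) -> dict:
    """Execute the full pipeline, write all artifacts, return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "outputs": {}, "config": config}
    with open(outdir / "config_effective.yml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh)

    t0 = time.perf_counter()
    res = run_in_memory(config)
    manifest["stages"].append(
        {"stage": "analysis", "wall_s": round(time.perf_counter() - t0, 3),
         "ok": True})

    t0 = time.perf_counter()
    msi_io.write_bin_borders(res["bins"], outdir / "bin_borders.tsv")
    if config["preprocessing"]["write_feature_matrix"]:
        res["features"].to_csv(outdir / "feature_matrix.csv")
    res["annotations"].to_csv(outdir / "bin_annotations.csv", index=False,
                              float_format="%.9g")
    res["rois"].to_csv(outdir / "rois.csv")
    res["table"].to_csv(outdir / "enrichment.csv", index=False,
                        float_format="%.9g")
    if res["spsc"] is not None:
        res["spsc"].to_csv(outdir / "spsc.csv")
    rois, normalized = res["rois"], res["normalized"]
    if rois.roi_ids:
        roi_table = msi_io.ROISpectrumTable({
            f"plaque_{rid}": preprocessing.mean_spectrum(
                normalized,
                np.flatnonzero(rois.plaque_mask(rid)[
                    normalized.coords[:, 1], normalized.coords[:, 0]]))
            for rid in rois.roi_ids
        })
        msi_io.export_roi_csv(roi_table, outdir / "roi_spectra.csv")
    if res["metrics"] is not None:
        serializable = {k: v for k, v in res["metrics"].items()
                        if isinstance(v, (int, float, str))}
        with open(outdir / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(serializable, fh, indent=2, sort_keys=True)
    manifest["stages"].append(
        {"stage": "export", "wall_s": round(time.perf_counter() - t0, 3),
         "ok": True})

    if config["render"]["enabled"]:
        t0 = time.perf_counter()
        features, species_map = res["features"], res["species_map"]
        wanted = set(config["render"]["species"])
        cols = [b for b, s in species_map.items() if s in wanted]
        sub = preprocessing.FeatureMatrix(
            features.df[cols] if cols else features.df.iloc[:, :1],
            features.bins, features.normalization)
        plaque_stats.render_outputs(
            outdir, sub, rois=rois, seg=res["seg"], enrichment_table=res["table"],
            spsc_matrix=res["spsc"], species_map=species_map,
            clip_quantile=config["render"]["clip_quantile"],
            shape=res["dataset"].grid_shape)
        manifest["stages"].append(
            {"stage": "render", "wall_s": round(time.perf_counter() - t0, 3),
             "ok": True})

    manifest["counts"] = res["counts"]
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
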