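"""Stage orchestration: simulate -> segment -> measure -> train -> classify ->
analyze -> report, over a run directory of CSV/TIFF artifacts.

Each stage reads the previous stage's declared outputs from the run directory
and is deterministic given the run seed; every CSV carries a provenance
header (version, seed, config hash) as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from morphoscreen import __version__
from morphoscreen.boosting import (
    TrainingSet,
    evaluate,
    export_rules,
    import_rules,
    score,
    train_gentle_boost,
)
from morphoscreen.features import measure_objects
from morphoscreen.fixtures import (
    delamination_training_from_well,
    labeled_feature_frame,
)
from morphoscreen.phantoms import (
    SceneConfig,
    ScreenScenario,
    generate_screen,
    rng_for,
    scenario_from_dict,
    scene_from_dict,
)
from morphoscreen.screen import (
    class_area_stats,
    classify_effect,
    compute_yields,
    condition_yield_summary,
    dunnett_by_dose,
    morphotoxicity_summary,
)
from morphoscreen.segmentation import (
    LabeledObjects,
    SegmentationParams,
    SegmentedObject,
    assign_microwells,
    segment_montage,
)

log = logging.getLogger("morphoscreen")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage output is missing from the run directory."""


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"missing upstream artifact: {path}")
    return path


class RunConfig:
    """Per-stage configuration with a stable content hash for provenance."""

    def __init__(self, data: dict | None = None):
        self.data = data or {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    @property
    def scene(self) -> SceneConfig:
        return scene_from_dict(self.data.get("scene", {}))

    @property
    def scenario(self) -> ScreenScenario:
        if "scenario" not in self.data:
            raise KeyError("config has no 'scenario' section")
        return scenario_from_dict(self.data["scenario"])

    @property
    def segmentation(self) -> SegmentationParams:
        return SegmentationParams(**self.data.get("segmentation", {}))

    def classifier_opt(self, key: str, default):
        return self.data.get("classifier", {}).get(key, default)

    def analysis_opt(self, key: str, default):
        return self.data.get("analysis", {}).get(key, default)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = (f"# morphoscreen {__version__} seed={cfg.seed} "
              f"config={cfg.digest()}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(_require(path), comment="#")


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, *exc):
            log.info("stage %s finished in %.1fs", name, time.time() - self.t0)
    return _T()


# ------------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    with _timed("simulate"):
        manifest = generate_screen(cfg.scenario, cfg.scene, out_dir, seed=cfg.seed)
        log.info("simulated %d wells", len(manifest))
    return manifest


def stage_segment(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    scene = cfg.scene
    params = cfg.segmentation
    manifest = read_csv(out_dir / "manifest.csv")
    rows = []
    with _timed("segment"):
        for _, w in manifest.iterrows():
            img = tifffile.imread(_require(out_dir / str(w["image"])))
            seg = assign_microwells(
                segment_montage(img, params, pixel_size=scene.pixel_size), scene)
            tifffile.imwrite(out_dir / f"{w['well_id']}_labels.tif",
                             seg.label_image.astype(np.uint16))
            for o in seg.objects:
                rows.append(dict(
                    well_id=w["well_id"], object_id=o.object_id,
                    centroid_row=o.centroid[0], centroid_col=o.centroid[1],
                    bbox_r0=o.bbox[0], bbox_c0=o.bbox[1],
                    bbox_r1=o.bbox[2], bbox_c1=o.bbox[3],
                    pixel_count=o.pixel_count,
                    microwell_index=o.microwell_index, duplicate=o.duplicate))
            log.info("well %s: %d objects", w["well_id"], len(seg.objects))
    df = pd.DataFrame(rows)
    write_csv(df, out_dir / "objects.csv", cfg)
    return df


def _labeled_from_artifacts(out_dir: Path, well_id: str,
                            objects: pd.DataFrame) -> LabeledObjects:
    labels = tifffile.imread(_require(out_dir / f"{well_id}_labels.tif")).astype(np.int32)
    objs = [
        SegmentedObject(
            object_id=int(r.object_id),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            bbox=(int(r.bbox_r0), int(r.bbox_c0), int(r.bbox_r1), int(r.bbox_c1)),
            pixel_count=int(r.pixel_count),
            microwell_index=int(r.microwell_index),
            duplicate=bool(r.duplicate),
        )
        for r in objects.itertuples()
    ]
    return LabeledObjects(labels, objs)


def stage_measure(cfg: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    scene = cfg.scene
    manifest = read_csv(out_dir / "manifest.csv")
    objects = read_csv(out_dir / "objects.csv")
    feats_all, comps_all = [], []
    with _timed("measure"):
        for _, w in manifest.iterrows():
            wid = w["well_id"]
            img = tifffile.imread(_require(out_dir / str(w["image"])))
            labeled = _labeled_from_artifacts(
                out_dir, wid, objects[objects["well_id"] == wid])
            feats, comps = measure_objects(labeled, img, scene.pixel_size)
            feats.insert(0, "well_id", wid)
            if len(comps):
                comps.insert(0, "well_id", wid)
            feats_all.append(feats)
            comps_all.append(comps)
    features = pd.concat(feats_all, ignore_index=True)
    compartments = pd.concat([c for c in comps_all if len(c)], ignore_index=True) \
        if any(len(c) for c in comps_all) else pd.DataFrame()
    write_csv(features, out_dir / "features.csv", cfg)
    write_csv(compartments, out_dir / "compartments.csv", cfg)
    return features, compartments


def stage_train(cfg: RunConfig, out_dir: Path) -> None:
    """Train the five-class phenotype model and the binary delamination model
    on freshly rendered labeled exemplars (same measurement path as the
    screen) and write their rules files."""
    scene = cfg.scene
    n_per_class = int(cfg.classifier_opt("train_per_class", 30))
    n_rounds = int(cfg.classifier_opt("n_rounds", 50))
    with _timed("train"):
        train5 = labeled_feature_frame(n_per_class, scene,
                                       rng_for(cfg.seed, "train/phenotype"))
        model5 = train_gentle_boost(TrainingSet.from_dataframe(train5), n_rounds)
        (out_dir / "phenotype.rules").write_text(export_rules(model5))
        train2 = delamination_training_from_well(
            scene, rng_for(cfg.seed, "train/delamination"),
            n_per_class=n_per_class)
        model2 = train_gentle_boost(TrainingSet.from_dataframe(train2), n_rounds)
        (out_dir / "delamination.rules").write_text(export_rules(model2))
        rep = evaluate(model5, train5.drop(columns="label"), train5["label"])
        log.info("phenotype model: training accuracy %.3f", rep.accuracy)


def stage_classify(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    features = read_csv(out_dir / "features.csv")
    model5 = import_rules(_require(out_dir / "phenotype.rules").read_text())
    model2 = import_rules(_require(out_dir / "delamination.rules").read_text())
    with _timed("classify"):
        _, pred5 = score(model5, features)
        _, pred2 = score(model2, features)
    out = features[["well_id", "object_id"]].copy()
    out["pred_class"] = pred5
    out["delaminated"] = pred2 == "delaminated"
    write_csv(out, out_dir / "predictions.csv", cfg)
    return out


def stage_analyze(cfg: RunConfig, out_dir: Path) -> dict[str, pd.DataFrame]:
    manifest = read_csv(out_dir / "manifest.csv")
    predictions = read_csv(out_dir / "predictions.csv")
    features = read_csv(out_dir / "features.csv")
    control = cfg.analysis_opt("control", "control")
    n_mc = int(cfg.analysis_opt("n_mc", 200_000))

    meta = manifest[["well_id", "condition", "dose", "replicate"]]
    preds = predictions.merge(meta, on="well_id")
    with _timed("analyze"):
        wells = compute_yields(preds)
        summary = condition_yield_summary(wells)
        outputs = {"well_results": wells, "condition_summary": summary}

        tests = []
        if (wells["condition"] != control).any():
            for c in [f"yield_XEnEpiC", "delaminated_yield"]:
                if c in wells.columns:
                    tests.append(dunnett_by_dose(
                        wells, c, control, n_mc=n_mc, seed=cfg.seed))
        if tests:
            outputs["dunnett"] = pd.concat(tests, ignore_index=True)

        area_summary, _ = class_area_stats(features, preds)
        outputs["area_summary"] = area_summary

        comp_path = out_dir / "compartments.csv"
        if comp_path.exists():
            comps = read_csv(comp_path)
            if len(comps):
                comps = comps.merge(meta, on="well_id")
                outputs["morphotoxicity"] = morphotoxicity_summary(
                    wells, comps, control_condition=control,
                    n_mc=n_mc, seed=cfg.seed)

        categories = _effect_categories(outputs, control)
        if categories is not None:
            outputs["effect_categories"] = categories
    for name, df in outputs.items():
        write_csv(df, out_dir / f"{name}.csv", cfg)
    return outputs


def _effect_categories(outputs: dict, control: str) -> pd.DataFrame | None:
    """Best-effort effect categorization per non-control compound."""
    wells = outputs["well_results"]
    if "dunnett" not in outputs:
        return None
    dn = outputs["dunnett"]
    rows = []
    ctrl_yield = wells.loc[wells["condition"] == control, "yield_XEnEpiC"].mean()
    for cond in sorted(set(wells["condition"]) - {control}):
        sub = wells[wells["condition"] == cond]
        per_dose = sub.groupby("dose")["yield_XEnEpiC"].mean().reset_index()
        per_dose.columns = ["dose", "xen_epic_yield"]
        yp = dn[(dn["condition"] == cond) & (dn["endpoint"] == "yield_XEnEpiC")]
        per_dose = per_dose.merge(
            yp[["dose", "p_adj"]].rename(columns={"p_adj": "xen_epic_p"}),
            on="dose", how="left")
        dp = dn[(dn["condition"] == cond) & (dn["endpoint"] == "delaminated_yield")]
        if len(dp):
            per_dose = per_dose.merge(
                dp[["dose", "p_adj", "mean_diff"]].rename(
                    columns={"p_adj": "delam_p"}), on="dose", how="left")
            per_dose["delam_increase"] = per_dose["mean_diff"] > 0
        per_dose["control_yield"] = ctrl_yield
        call = classify_effect(per_dose)
        rows.append(dict(condition=cond, category=call.category,
                         **{f"diag_{k}": v for k, v in call.diagnostics.items()}))
    return pd.DataFrame(rows)


def stage_report(cfg: RunConfig, out_dir: Path) -> list[Path]:
    from morphoscreen import plots

    summary = read_csv(out_dir / "condition_summary.csv")
    wells = read_csv(out_dir / "well_results.csv")
    out = []
    with _timed("report"):
        p = out_dir / "yield_stacked.png"
        plots.yield_stacked_bars(summary, p)
        out.append(p)
        features = read_csv(out_dir / "features.csv")
        predictions = read_csv(out_dir / "predictions.csv")
        manifest = read_csv(out_dir / "manifest.csv")
        merged = predictions.merge(
            manifest[["well_id", "condition", "dose"]], on="well_id").merge(
            features, on=["well_id", "object_id"])
        p = out_dir / "area_strip.png"
        plots.area_strip(merged, p)
        out.append(p)
        p = out_dir / "dose_response.png"
        plots.dose_response(wells, p)
        out.append(p)
    return out


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "measure": stage_measure,
    "train": stage_train,
    "classify": stage_classify,
    "analyze": stage_analyze,
    "report": stage_report,
}
STAGE_ORDER = ["simulate", "segment", "measure", "train", "classify",
               "analyze", "report"]


def run_stage(name: str, cfg: RunConfig, out_dir: str | Path):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "all":
        results = None
        for s in STAGE_ORDER:
            results = STAGES[s](cfg, out)
        return results
    if name not in STAGES:
        raise KeyError(f"unknown stage {name!r}")
    return STAGES[name](cfg, out)
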