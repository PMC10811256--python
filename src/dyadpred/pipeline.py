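"""End-to-end pipeline: simulate/read → preprocess → derive → search → report.

Driven by a nested config dict (YAML on disk).  Artifacts per run:
``targets.csv``, ``predictors.csv``, per-outcome ``report_<outcome>.txt`` /
``.json``, ``search_ledger_<outcome>.csv``, effect-grid CSVs and a
``manifest.json`` with seeds, versions, stage status and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import mixed_model_engine as engine
from . import model_search, reporting, study_data, synthetic_study
from . import target_derivation as targets_mod

logger = logging.getLogger(__name__)

OUTCOMES = targets_mod.TARGET_COLUMNS

DEFAULT_SEARCH = {
    "outcomes": list(OUTCOMES),
    "max_terms": 9,
    "drop_threshold": 0.10,
    "drop_mode": "absolute",
    "cv_pool_size": 50,
    "budget": 2_000_000,
    "beam_width": 100,
    "heredity_interactions": True,
    "heredity_quadratics": False,
    "rescale_per_fold": True,
}


def _is_binary(series: pd.Series) -> bool:
    vals = set(series.dropna().unique().tolist())
    if series.dtype == object:
        return True
    return vals <= {-0.5, 0.5} and len(vals) >= 1


def preprocess_predictors(dataset: study_data.DyadDataset,
                          knn_k: int = 5) -> tuple[pd.DataFrame, dict]:
    """Merged client-level predictor frame, coded, Z-scored and imputed.

    Binary predictors (string-labelled or already ±0.5) are coded −0.5/+0.5
    with the lexically first level mapped to −0.5; continuous predictors are
    Z-scored on available values; remaining missing cells are filled by
    k-nearest-neighbour imputation over the standardized matrix.
    """
    frame = study_data.predictor_frame(dataset)
    pred_cols = list(study_data.CLIENT_PREDICTORS
                     + study_data.THERAPIST_PREDICTORS)
    meta: dict = {"binary": {}, "scaling": {}, "knn": {"k": knn_k, "log": []}}
    predictors = []
    for col in pred_cols:
        s = frame[col]
        if _is_binary(s):
            levels = sorted(map(str, s.dropna().unique()))
            if len(levels) > 2:
                raise study_data.VocabularyError(
                    f"binary predictor {col!r} has levels {levels}")
            if s.dtype == object:
                coding = {lev: (-0.5 if i == 0 else 0.5)
                          for i, lev in enumerate(levels)}
                frame[col] = s.map(lambda v: coding[str(v)]
                                   if pd.notna(v) else np.nan)
                meta["binary"][col] = coding
            else:
                meta["binary"][col] = "already coded ±0.5"
            level = "therapist" if col in study_data.THERAPIST_PREDICTORS else "client"
            predictors.append(model_search.Predictor(col, "binary", level))
        else:
            x = pd.to_numeric(s, errors="coerce")
            m = float(x.mean())
            sd = float(x.std(ddof=1))
            if not np.isfinite(sd) or sd <= 0:
                raise study_data.DegenerateVariableError(
                    f"predictor {col!r} has zero variance")
            frame[col] = (x - m) / sd
            meta["scaling"][col] = {"mean": m, "sd": sd}
            level = "therapist" if col in study_data.THERAPIST_PREDICTORS else "client"
            predictors.append(model_search.Predictor(col, "continuous", level))

    matrix = frame[pred_cols].astype(float)
    if matrix.isna().any().any():
        n_complete = int((~matrix.isna().any(axis=1)).sum())
        k = min(knn_k, max(n_complete - 1, 1))
        imputed, log = study_data.knn_impute(matrix, k=k)
        frame[pred_cols] = imputed
        meta["knn"]["k"] = k
        meta["knn"]["log"] = [{"row": str(e["row"]),
                               "variable": str(e["variable"]),
                               "donors": [str(d) for d in e["donors"]],
                               "value": e["value"]} for e in log]
    meta["predictors"] = [{"name": p.name, "kind": p.kind, "level": p.level}
                          for p in predictors]
    return frame, meta


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    On a stage failure the exception propagates after the manifest (with
    the failure point) has been written; partial artifacts are preserved.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))

    manifest: dict = {"version": __version__, "seed": seed,
                      "config": json.loads(json.dumps(config, default=str)),
                      "stages": {}, "files": {}}

    def checkpoint(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    try:
        # -- stage 1: data ------------------------------------------------
        if "inputs" in config:
            paths = config["inputs"]
            dataset = study_data.read_study_tables(
                paths["therapists"], paths["clients"], paths["sessions"])
        else:
            sim_cfg = synthetic_study.config_from_yaml(
                yaml.safe_dump(config.get("simulate", {}) or {}))
            sim_cfg.seed = seed
            dataset, truth = synthetic_study.generate_study(sim_cfg)
            study_data.write_study_tables(dataset, out / "data")
            (out / "data" / "ground_truth.json").write_text(
                json.dumps(truth.to_jsonable(), indent=2, sort_keys=True))
        logger.info("data: %d therapists, %d clients, %d session rows",
                    len(dataset.therapists), len(dataset.clients),
                    len(dataset.sessions))
        checkpoint("data", "ok")

        # -- stage 2: preprocess ------------------------------------------
        pp_cfg = config.get("preprocess", {}) or {}
        frame, pp_meta = preprocess_predictors(dataset,
                                               knn_k=pp_cfg.get("knn_k", 5))
        frame.to_csv(out / "predictors.csv", index=False)
        (out / "preprocess_log.json").write_text(
            json.dumps(pp_meta, indent=2, sort_keys=True))
        checkpoint("preprocess", "ok")

        # -- stage 3: derive targets --------------------------------------
        dv_cfg = config.get("derive", {}) or {}
        targets, derive_log = targets_mod.derive_targets(
            dataset,
            standardize=dv_cfg.get("standardize", True),
            week_coding=dv_cfg.get("week_coding", False),
            prepost_only=dv_cfg.get("prepost_only", False))
        targets.reset_index().to_csv(out / "targets.csv", index=False)
        (out / "derivation_log.json").write_text(
            json.dumps(derive_log, indent=2, sort_keys=True, default=str))
        checkpoint("derive", "ok")

        # -- stage 4+5: search and report per outcome ---------------------
        search_cfg = {**DEFAULT_SEARCH, **(config.get("search", {}) or {})}
        predictors = [model_search.Predictor(p["name"], p["kind"], p["level"])
                      for p in pp_meta["predictors"]]
        universe = model_search.build_universe(predictors)
        merged = frame.merge(targets.reset_index(), on="client_id",
                             validate="1:1")
        merged = merged[merged["included"]]
        rescale = ([p.name for p in predictors if p.kind == "continuous"]
                   if search_cfg["rescale_per_fold"] else None)
        binary_names = [p.name for p in predictors if p.kind == "binary"]
        grids_dir = out / "effect_grids"

        for outcome in search_cfg["outcomes"]:
            if outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r}; "
                                 f"expected one of {OUTCOMES}")
            logger.info("searching models for %s", outcome)
            result = model_search.select_model(
                merged, universe, outcome,
                max_terms=search_cfg["max_terms"],
                drop_threshold=search_cfg["drop_threshold"],
                drop_mode=search_cfg["drop_mode"],
                cv_pool_size=search_cfg["cv_pool_size"],
                budget=search_cfg["budget"],
                beam_width=search_cfg["beam_width"],
                heredity_interactions=search_cfg["heredity_interactions"],
                heredity_quadratics=search_cfg["heredity_quadratics"],
                rescale_columns=rescale,
                seed=seed)
            fit = result.selected_fit
            design = engine.build_design(merged, result.selected)
            diagnostics = engine.residual_diagnostics(fit, design)
            score = result.selected_score()
            bundle = reporting.render_model_report(
                outcome, fit, r2_train=score.r2_train, r2_cv=score.r2_cv,
                diagnostics=diagnostics,
                search_meta={"mode": result.search_mode, "seed": seed,
                             "drop_threshold": result.drop_threshold,
                             "drop_mode": result.drop_mode,
                             "note": result.selection_note,
                             "n_candidates": len(result.scores)},
                binary_predictors=binary_names)
            (out / f"report_{outcome}.txt").write_text(bundle.to_text())
            (out / f"report_{outcome}.json").write_text(bundle.to_json() + "\n")
            result.ledger.to_csv(out / f"search_ledger_{outcome}.csv",
                                 index=False)
            for tname, grid in bundle.effect_grids.items():
                gdir = grids_dir / outcome
                gdir.mkdir(parents=True, exist_ok=True)
                safe = tname.replace(":", "_x_").replace("^", "")
                grid.to_csv(gdir / f"{safe}.csv", index=False)
            checkpoint(f"search:{outcome}", "ok")

        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["files"][str(p.relative_to(out))] = _sha256(p)
        checkpoint("done", "ok")
        return manifest
    except Exception as err:  # noqa: BLE001 - manifest must record failure
        failed = [s for s in manifest["stages"]]
        checkpoint("failed", f"{type(err).__name__}: {err}")
        logger.error("pipeline failed after stages %s: %s", failed, err)
        raise
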