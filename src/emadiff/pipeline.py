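"""End-to-end orchestration: preprocess -> fit/score -> multilevel analyses.

`run_pipeline` chains the stages over one or two item sets and writes a
report bundle: the scored-occasion CSV, one JSON report per requested
analysis, and a run manifest with the seed and the occasion accounting at
every filter step (scheduled = missed + filtered + retained).  All
randomness flows from the single run seed through named substreams, so
toggling one analysis never perturbs another's results.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_model, diffirt, growth, multilevel, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_STAGES = ("load", "preprocess", "fit", "score", "analyze", "write")


class PipelineError(RuntimeError):
    """Stage failure with a stage name and machine-readable code."""

    def __init__(self, stage: str, code: int, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    seed: int
    input_path: str | None = None          # long-format CSV; exclusive with preset
    synthetic_preset: str | None = None    # "paper-shape" or "small"
    n_persons: int | None = None           # overrides the preset size
    rt_cap: float = 30.0
    min_items: int = 2
    n_quad: int = 15
    kappa: float = 0.9
    max_fit_rows: int | None = None        # subsample rows for item estimation
    analyses: tuple = ("icc", "regression", "correspondence", "mediation", "growth")
    outdir: str | None = None
    affect_items: data_model.ItemSet = field(
        default_factory=lambda: synthetic.affect_item_set()
    )
    event_items: data_model.ItemSet | None = field(
        default_factory=lambda: synthetic.event_item_set()
    )


def _substream(seed: int, name: str) -> np.random.Generator:
    # stable across processes (no salted hashing)
    key = zlib.crc32(name.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _fit_and_score(occasions, item_set, cfg, rng):
    rows = occasions
    if cfg.max_fit_rows is not None and len(occasions) > cfg.max_fit_rows:
        idx = rng.choice(len(occasions), cfg.max_fit_rows, replace=False)
        rows = [occasions[i] for i in sorted(idx)]
    fit = diffirt.fit_item_parameters(
        rows, item_ids=list(item_set.items), n_quad=cfg.n_quad,
        kappa=cfg.kappa, min_items=cfg.min_items,
    )
    scores = diffirt.score_occasions(occasions, fit, min_items=cfg.min_items)
    return fit, diffirt.scores_to_frame(scores)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return (and optionally write) the bundle."""
    cfg = config
    bundle: dict = {"config": _config_dict(cfg), "seed": cfg.seed}
    manifest: dict = {"seed": cfg.seed, "stages": []}

    # ---- load ----------------------------------------------------------
    try:
        if cfg.input_path is not None:
            all_items = data_model.ItemSet(
                "all",
                tuple(cfg.affect_items.items)
                + tuple(cfg.event_items.items if cfg.event_items else ()),
                "vas",
            )
            records = data_model.read_long_table(cfg.input_path, all_items)
            scheduled = None
        elif cfg.synthetic_preset is not None:
            n = cfg.n_persons
            if cfg.synthetic_preset == "paper-shape":
                scfg = synthetic.SyntheticConfig(seed=cfg.seed, n_persons=n or 954)
            elif cfg.synthetic_preset == "small":
                scfg = synthetic.SyntheticConfig(seed=cfg.seed, n_persons=n or 60)
            else:
                raise ValueError(f"unknown synthetic preset {cfg.synthetic_preset!r}")
            records, truth = synthetic.generate_dataset(scfg)
            scheduled = scfg.scheduled_total
            cfg.affect_items = synthetic.affect_item_set(scfg)
            cfg.event_items = synthetic.event_item_set(scfg)
        else:
            raise ValueError("either input_path or synthetic_preset is required")
    except (OSError, ValueError, data_model.SchemaError) as exc:
        raise PipelineError("load", 2, str(exc)) from exc
    manifest["stages"].append({"stage": "load", "n_records": len(records)})
    if scheduled is not None:
        completed = len({(r.person_id, r.occasion_id) for r in records})
        manifest["occasions_scheduled"] = scheduled
        manifest["occasions_completed"] = completed
        manifest["occasions_missed"] = scheduled - completed

    # ---- preprocess ----------------------------------------------------
    sets = [cfg.affect_items] + ([cfg.event_items] if cfg.event_items else [])
    occ_by_set = {}
    try:
        for iset in sets:
            occ, acct = data_model.preprocess(
                records, iset, rt_cap=cfg.rt_cap, min_items=cfg.min_items
            )
            occ_by_set[iset.name] = occ
            acct["stage"] = "preprocess"
            if "occasions_completed" in manifest:
                filtered = manifest["occasions_completed"] - acct["occasions_retained"]
                acct["occasions_filtered"] = filtered
                acct["accounting_identity"] = (
                    acct["occasions_retained"]
                    == manifest["occasions_scheduled"]
                    - manifest["occasions_missed"]
                    - filtered
                )
            manifest["stages"].append(acct)
    except ValueError as exc:
        raise PipelineError("preprocess", 2, str(exc)) from exc

    bundle["manifest"] = manifest
    if not cfg.analyses:
        bundle["occasions"] = {
            name: data_model.occasions_to_frame(occ, iset)
            for (name, occ), iset in zip(occ_by_set.items(), sets)
        }
        _write_bundle(bundle, cfg)
        return bundle

    # ---- fit & score ---------------------------------------------------
    fit_rng = _substream(cfg.seed, "estimation")
    fits, score_frames = {}, {}
    try:
        for iset in sets:
            fit, sdf = _fit_and_score(occ_by_set[iset.name], iset, cfg, fit_rng)
            fits[iset.name] = fit
            score_frames[iset.name] = sdf
    except (diffirt.FitError, ValueError) as exc:
        raise PipelineError("fit", 3, str(exc)) from exc
    bundle["fits"] = {name: f.to_dict() for name, f in fits.items()}

    main = sets[0].name
    sdf = score_frames[main].copy()
    occ_meta = pd.DataFrame(
        [
            {
                "person_id": o.person_id,
                "occasion_id": o.occasion_id,
                "work": o.work,
                "recovery": o.recovery,
            }
            for o in occ_by_set[main]
        ]
    )
    sdf = sdf.merge(occ_meta, on=["person_id", "occasion_id"], how="left")
    covs = data_model.person_covariates(records)
    sdf = sdf.merge(covs, on="person_id", how="left")
    bundle["scores"] = sdf

    # ---- analyses ------------------------------------------------------
    reports: dict = {}
    score_vars = ("mean_log_rt", "log_abs_drift", "log_gamma")
    try:
        if "icc" in cfg.analyses:
            reports["icc"] = {
                var: multilevel.fit_null_model(sdf[var], sdf["person_id"]).to_dict()
                for var in score_vars
            }
        if "regression" in cfg.analyses:
            reports["regression"] = multilevel.fit_latent_regression(
                sdf["mean_log_rt"], sdf["log_abs_drift"], sdf["log_gamma"],
                sdf["person_id"],
            ).to_dict()
        if "correspondence" in cfg.analyses and cfg.event_items is not None:
            other = score_frames[cfg.event_items.name][
                ["person_id", "occasion_id", "log_abs_drift", "log_gamma"]
            ].rename(columns={"log_abs_drift": "drift_b", "log_gamma": "boundary_b"})
            joined = sdf.merge(other, on=["person_id", "occasion_id"], how="inner")
            joined = joined.rename(
                columns={"log_abs_drift": "drift_a", "log_gamma": "boundary_a"}
            )
            cvars = ["drift_a", "boundary_a", "drift_b", "boundary_b"]
            pair = multilevel.multilevel_correlations(joined, cvars, "person_id")
            tests = {}
            boot_seed = int(_substream(cfg.seed, "bootstrap").integers(2**31))
            for level in ("within", "between"):
                tests[level] = dataclasses.asdict(
                    multilevel.compare_dependent_correlations(
                        joined, "person_id",
                        pair_a=("drift_a", "drift_b"),
                        pair_b=("drift_a", "boundary_a"),
                        level=level, seed=boot_seed,
                    )
                )
            reports["correspondence"] = {
                "within": pair.within.to_dict(),
                "between": pair.between.to_dict(),
                "dependent_tests": tests,
            }
        if "mediation" in cfg.analyses:
            med_seed = int(_substream(cfg.seed, "mediation").integers(2**31))
            med = {}
            for pred, level in (
                ("work", "within"),
                ("recovery", "within"),
                ("neuroticism", "between"),
                ("depression", "between"),
            ):
                if pred not in sdf or sdf[pred].isna().all():
                    continue
                med[pred] = multilevel.fit_mediation(
                    sdf, pred, ("log_abs_drift", "log_gamma"), "mean_log_rt",
                    "person_id", predictor_level=level, seed=med_seed,
                ).to_dict()
            reports["mediation"] = med
        if "growth" in cfg.analyses:
            gres = {}
            gfits = {}
            for var in score_vars:
                gfits[var] = growth.fit_negative_exponential(
                    sdf["person_id"], sdf["occasion_id"] - 1, sdf[var]
                )
                gres[var] = gfits[var].to_dict()
            zfits = {}
            for var in ("log_abs_drift", "log_gamma"):
                vals = sdf[var].to_numpy(float)
                z = (vals - np.nanmean(vals)) / np.nanstd(vals)
                zfits[var] = growth.fit_negative_exponential(
                    sdf["person_id"], sdf["occasion_id"] - 1, z
                )
            comp = growth.compare_gains(zfits["log_abs_drift"], zfits["log_gamma"])
            gres["gain_comparison"] = dataclasses.asdict(comp)
            gres["observed_vs_fitted"] = {
                var: gfits[var].observed_vs_fitted().to_dict(orient="list")
                for var in score_vars
            }
            reports["growth"] = gres
    except (ValueError, RuntimeError) as exc:
        raise PipelineError("analyze", 3, str(exc)) from exc

    bundle["reports"] = reports
    _write_bundle(bundle, cfg)
    return bundle


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["analyses"] = list(cfg.analyses)
    d["affect_items"] = list(cfg.affect_items.items)
    d["event_items"] = list(cfg.event_items.items) if cfg.event_items else None
    return d


def _write_bundle(bundle: dict, cfg: RunConfig) -> None:
    if cfg.outdir is None:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, default=_json_default)
    if "scores" in bundle:
        bundle["scores"].to_csv(out / "scores.csv", index=False)
    if "fits" in bundle:
        with open(out / "fits.json", "w") as fh:
            json.dump(bundle["fits"], fh, indent=2, default=_json_default)
    for name, rep in bundle.get("reports", {}).items():
        with open(out / f"{name}.json", "w") as fh:
            json.dump(rep, fh, indent=2, default=_json_default)
    if "occasions" in bundle:
        for name, df in bundle["occasions"].items():
            df.to_csv(out / f"occasions_{name}.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
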