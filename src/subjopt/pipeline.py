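"""Configurable end-to-end pipeline: generate -> fit -> compare -> predict ->
analyze, with seed/config stamping and a machine-readable status file."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .task import TaskSpec
from . import transforms, synth, io as sio
from .hierarchical import HierarchicalSpec, fit_hierarchical, group_posterior, map_estimates
from .likelihood import fit_subjects_ml, compare_models, predict_context_thresholds
from .behavior import fit_empirical_thresholds

log = logging.getLogger("subjopt")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["generate", "fit", "analyze"],
    "task": {"K": 5, "n_rounds": 200},
    "generate": {
        "n_subjects": 8,
        "model": "subjective",
        "group_means": {"r": 110.51, "rho": 0.62, "s": 10.0},
        "group_sds": {"r": 0.3, "rho": 0.3, "s": 0.2},  # sampling space
    },
    "fit": {"models": ["subjective"], "n_iter": 4000, "burn_in": 1500},
    "compare": {"models": ["subjective", "constant"]},
    "predict": {"target_K": 2, "n_draws": 2000},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (cfg or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages, writing every artifact (stamped with
    the seed and a config hash) under ``out_dir``.  A stage failure halts
    the run; partial outputs are preserved and ``status.json`` records the
    failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stamp = {"seed": seed, "config_hash": sio.config_hash(config)}
    status = {"stages": {}, **stamp}
    spec = TaskSpec(**config.get("task", {}))
    data = None
    fits = {}
    try:
        for stage in config["stages"]:
            t0 = time.time()
            if stage == "generate":
                g = config["generate"]
                mus = {k: float(transforms.to_sampling(k, v))
                       for k, v in g["group_means"].items()}
                pop = synth.sample_population(mus, g["group_sds"],
                                              g["n_subjects"], seed)
                data = synth.simulate_cohort(pop, g["model"], spec,
                                             np.random.default_rng(seed + 1))
                sio.write_choices(data, out / "choices.tsv")
            elif stage == "load":
                data = sio.read_choices(config["input"]["choices"])
            elif stage == "fit":
                f = config["fit"]
                for tag in f["models"]:
                    h = HierarchicalSpec(model_tag=tag, n_iter=f["n_iter"],
                                         burn_in=f["burn_in"], seed=seed + 2)
                    chain = fit_hierarchical(data, h, spec)
                    gp = group_posterior(chain)
                    gp.to_csv(out / f"group_posterior_{tag}.tsv", sep="\t")
                    maps = map_estimates(chain)
                    with open(out / f"map_{tag}.json", "w") as fh:
                        json.dump({**stamp, "model": tag, "map": maps}, fh, indent=1)
                    fits[tag] = maps
            elif stage == "compare":
                tags = config["compare"]["models"]
                mlfits = {t: fit_subjects_ml(data, t, spec) for t in tags}
                cmp_ = compare_models(mlfits[tags[0]], mlfits[tags[1]], rng=seed)
                with open(out / "comparison.json", "w") as fh:
                    json.dump({**stamp, "models": tags,
                               "mean_delta_aic": cmp_["mean"],
                               "ci95": cmp_["ci95"]}, fh, indent=1)
            elif stage == "predict":
                tag = next(iter(fits)) if fits else "subjective"
                params = list(fits[tag].values())
                pr = predict_context_thresholds(
                    params, spec.K, config["predict"]["target_K"],
                    n_draws=config["predict"]["n_draws"], rng=seed)
                with open(out / "prediction.json", "w") as fh:
                    json.dump({**stamp, "target_K": config["predict"]["target_K"],
                               "prediction": pr["prediction"],
                               "ci95": pr["ci95"], "shift": pr["shift"]}, fh,
                              indent=1)
            elif stage == "analyze":
                rows = []
                for subj, g in data.groupby("subject_id"):
                    for f_ in fit_empirical_thresholds(g):
                        rows.append({"subject_id": subj,
                                     "opportunity": f_.opportunity,
                                     "threshold": f_.threshold,
                                     "variability": f_.variability,
                                     "n": f_.n})
                import pandas as pd

                pd.DataFrame(rows).to_csv(out / "empirical_thresholds.tsv",
                                          sep="\t", index=False)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            status["stages"][stage] = {"ok": True,
                                       "seconds": round(time.time() - t0, 2)}
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
    except Exception as exc:  # preserve partial outputs, record failure
        status["stages"][stage] = {"ok": False, "error": str(exc)}
        with open(out / "status.json", "w") as fh:
            json.dump(status, fh, indent=1)
        raise
    with open(out / "status.json", "w") as fh:
        json.dump(status, fh, indent=1)
    return status
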