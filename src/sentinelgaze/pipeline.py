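"""End-to-end pipeline: simulate/ingest -> derive -> fit -> gof -> orient.

A single hierarchical config dict drives every stage; all randomness flows
from one root seed through named per-stage substreams, so a rerun with the
same config and seed reproduces every output byte for byte.  Results land in
an output directory together with a manifest (config snapshot, seeds, output
digests, per-stage status and timings).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circstats import build_bias_table, summarize_orientation
from .distfit import (
    FAMILIES,
    SamplerConfig,
    compare_elpd,
    fit_hier_model,
    predict_status_means,
)
from .eventio import (
    derive_looks,
    extract_return_times,
    looks_to_frame,
    read_event_log,
    returns_to_frame,
    summarize_observation,
    write_event_log,
)
from .gof import mc_ks_test
from .synthgen import SimConfig, simulate_population

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_CONFIG"]

#: Stage names in execution order; each gets its own seed substream.
_STAGES = ("simulate", "derive", "fit", "gof", "orient")

DEFAULT_CONFIG: dict = {
    "seed": 20221206,
    "simulate": {},            # SimConfig field overrides; None -> use input files
    "input": None,             # {"events": <csv path>} to analyse recorded logs
    "derive": {"reference_quadrant": 1, "convention": "onset"},
    "fit": {
        "families": list(FAMILIES),
        "chains": 4,
        "iterations": 2000,
        "burnin": 1000,
        "predict_group_size": 4,
    },
    "gof": {"family": "lognormal", "B": 1000, "per_observation": True, "min_n": 5},
    "orient": {"B": 2000, "level": 0.95},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results") -> dict:
    """Run every stage and write the results bundle; returns the manifest.

    Stages: simulate (or read the configured input logs), derive intervals,
    fit and compare the duration families, Monte-Carlo KS goodness-of-fit,
    and orientation/side-bias summaries.  A stage failure aborts the run with
    :class:`PipelineError` after writing a manifest that names the stage.
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(int(cfg["seed"]))
    stage_seeds = {name: seq for name, seq in zip(_STAGES, root.spawn(len(_STAGES)))}

    manifest: dict = {
        "package_version": __version__,
        "seed": int(cfg["seed"]),
        "config": cfg,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str, t0: float) -> None:
        manifest["stages"][stage] = {
            "status": status,
            "seconds": round(time.perf_counter() - t0, 3),
        }

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest["stages"].setdefault(stage, {})["status"] = f"failed: {exc}"
        _write_manifest(manifest, out)
        return PipelineError(stage, exc)

    # ---- stage 1: simulate or ingest -------------------------------------
    t0 = time.perf_counter()
    try:
        if cfg.get("input"):
            events, meta = read_event_log(cfg["input"]["events"])
            truth = None
        else:
            sim = SimConfig(**cfg["simulate"])
            rng = np.random.default_rng(stage_seeds["simulate"])
            events, meta, truth = simulate_population(sim, rng)
        write_event_log(events, meta, out / "event_log.csv")
        if truth is not None:
            (out / "truth.json").write_text(json.dumps(truth, indent=1))
    except Exception as exc:  # noqa: BLE001 - stage isolation by contract
        raise fail("simulate", exc) from exc
    record("simulate", "ok", t0)

    # ---- stage 2: interval derivation -------------------------------------
    t0 = time.perf_counter()
    try:
        looks_by_obs = {m.obs_id: derive_looks(events[m.obs_id]) for m in meta}
        returns_by_obs = {
            m.obs_id: extract_return_times(
                looks_by_obs[m.obs_id],
                cfg["derive"]["reference_quadrant"],
                convention=cfg["derive"]["convention"],
            )
            for m in meta
        }
        all_looks = [lk for m in meta for lk in looks_by_obs[m.obs_id]]
        looks_to_frame(all_looks).to_csv(out / "looks.csv", index=False)
        returns_to_frame(
            [rt for m in meta for rt in returns_by_obs[m.obs_id]]
        ).to_csv(out / "return_times.csv", index=False)
        summ_rows = []
        for m in meta:
            if not looks_by_obs[m.obs_id]:
                continue
            s = summarize_observation(
                looks_by_obs[m.obs_id], returns_by_obs[m.obs_id], m
            )
            occ = s.pop("occupancy")
            s.update({f"occupancy_q{q}": f for q, f in enumerate(occ, start=1)})
            summ_rows.append(s)
        pd.DataFrame(summ_rows).to_csv(out / "observations.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise fail("derive", exc) from exc
    record("derive", "ok", t0)

    # ---- stage 3: hierarchical fits and model comparison ------------------
    t0 = time.perf_counter()
    try:
        fit_cfg = cfg["fit"]
        seeds = stage_seeds["fit"].generate_state(len(fit_cfg["families"])) % (2**31)
        fits = {}
        for fam, fam_seed in zip(fit_cfg["families"], seeds):
            fits[fam] = fit_hier_model(
                all_looks,
                meta,
                fam,
                SamplerConfig(
                    chains=fit_cfg["chains"],
                    iterations=fit_cfg["iterations"],
                    burnin=fit_cfg["burnin"],
                    seed=int(fam_seed),
                ),
            )
        comparison = compare_elpd(fits)
        comparison.table.to_csv(out / "model_comparison.csv", index=False)
        report = {
            "families": {
                fam: {
                    "rhat": fit.rhat,
                    "converged": fit.converged,
                    "warnings": fit.warnings,
                    "summary": fit.summary()
                    .loc[lambda t: ~t.parameter.str.contains(r"\[")]
                    .to_dict(orient="records"),
                }
                for fam, fit in fits.items()
            },
            "best_family": comparison.best,
        }
        if "lognormal" in fits:
            report["status_predictions"] = predict_status_means(
                fits["lognormal"], at_group_size=fit_cfg["predict_group_size"]
            ).to_dict(orient="records")
        (out / "fit_report.json").write_text(json.dumps(report, indent=1))
    except Exception as exc:  # noqa: BLE001
        raise fail("fit", exc) from exc
    record("fit", "ok", t0)

    # ---- stage 4: Monte-Carlo KS goodness-of-fit --------------------------
    t0 = time.perf_counter()
    try:
        gof_cfg = cfg["gof"]
        rng = np.random.default_rng(stage_seeds["gof"])
        rows = []
        if gof_cfg["per_observation"]:
            units = [
                (m.obs_id, [lk.duration for lk in looks_by_obs[m.obs_id]])
                for m in meta
            ]
        else:
            units = [("pooled", [lk.duration for lk in all_looks])]
        for unit, durations in units:
            if len(durations) < gof_cfg["min_n"]:
                continue
            res = mc_ks_test(
                durations, gof_cfg["family"], B=gof_cfg["B"], seed=rng
            )
            rows.append(
                {
                    "unit": unit,
                    "n": res.n,
                    "D_obs": res.D_obs,
                    "p_mc": res.p_mc,
                    "fit_ok": res.fit_ok,
                    "family": res.family,
                }
            )
        pd.DataFrame(rows).to_csv(out / "ks_results.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise fail("gof", exc) from exc
    record("gof", "ok", t0)

    # ---- stage 5: orientation and side bias --------------------------------
    t0 = time.perf_counter()
    try:
        orient_cfg = cfg["orient"]
        rng = np.random.default_rng(stage_seeds["orient"])
        summaries = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for m in meta:
                lks = looks_by_obs[m.obs_id]
                if len(lks) < 5:
                    continue
                summaries.append(
                    summarize_orientation(
                        lks, B=orient_cfg["B"], level=orient_cfg["level"], seed=rng
                    )
                )
        pd.DataFrame(
            [
                {
                    "obs_id": s.obs_id,
                    "mean_angle": s.mean_angle,
                    "resultant_length": s.resultant_length,
                    "kappa": s.kappa,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "bias": s.bias,
                    "n_looks": s.n_looks,
                }
                for s in summaries
            ]
        ).to_csv(out / "orientation.csv", index=False)
        build_bias_table(summaries, meta, level=orient_cfg["level"]).to_csv(
            out / "bias_table.csv", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise fail("orient", exc) from exc
    record("orient", "ok", t0)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _digest(f)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
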