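"""End-to-end synthetic pipeline: simulate -> estimate -> model -> measure.

A single JSON-able config drives every stage; per-stage seeds are
derived from the master seed with ``numpy.random.SeedSequence.spawn`` so
stages are independently reproducible.  Each stage writes its outputs
(kernel matrices with sidecars, CSV tables) into the run directory and a
``summary.json`` aggregates effectiveness flags, similarity numbers and
the model comparison.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import af, metrics, response_models, sta, stc, validation_model
from .crf_estimation import CRF, fit_crf
from .stimulus_labels import RFFG, write_kernel
from .synthetic_data import (
    VirtualNeuron,
    gen_curved_labels,
    gen_grating_response_map,
    gen_halfplane_labels,
    make_dog_kernel,
    simulate_responses,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

log = logging.getLogger("fgfield.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "grid_size": 25,
    "labels": {"kind": "halfplane", "n": 52, "curvature_sd": 1.5},
    "neuron": {
        "kind": "rectified_linear",
        "gain": 40.0,
        "noise": "poisson",
        "crf": {"center": [12.0, 8.0], "sd": 3.0},
    },
    "n_trials": 10,
    "sta": {"n_perm": 500, "step": 10, "reps": 30},
    "af": {"beta": 0.99, "delta_inv": 1e-5, "n_pairs_target": 2100},
    "stc": {"n_rand": 200},
    "validate": {"n_kernels": 5},
    "stages": ["simulate", "crf", "sta", "af", "stc", "models", "metrics", "validate"],
}

_STAGES = ("simulate", "crf", "sta", "af", "stc", "models", "metrics", "validate")


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults and sanity-check it."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["sta"]["n_perm"] < 1:
        raise ValueError("sta.n_perm must be >= 1")
    if cfg["stc"]["n_rand"] < 1:
        raise ValueError("stc.n_rand must be >= 1")
    bad = [s for s in cfg["stages"] if s not in _STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    if cfg["labels"]["kind"] not in ("halfplane", "curved"):
        raise ValueError("labels.kind must be 'halfplane' or 'curved'")
    return cfg


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the selected stages and write outputs + summary.json to out_dir."""
    cfg = validate_config(config)
    seeds = _stage_seeds(int(cfg["seed"]))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    summary: dict = {"seed": cfg["seed"], "stages": {}}
    G = int(cfg["grid_size"])
    stages = cfg["stages"]

    state: dict = {}
    try:
        # --- simulate ---------------------------------------------------
        if "simulate" in stages:
            log.info("stage simulate")
            lcfg = cfg["labels"]
            if lcfg["kind"] == "halfplane":
                labels = gen_halfplane_labels(int(lcfg["n"]), G)
            else:
                labels = gen_curved_labels(
                    int(lcfg["n"]), G, float(lcfg["curvature_sd"]), seeds["simulate"]
                )
            ncfg = cfg["neuron"]
            crf_c = ncfg["crf"]["center"]
            crf_true = CRF(
                center=(float(crf_c[0]), float(crf_c[1])),
                sd_major=float(ncfg["crf"]["sd"]),
                sd_minor=float(ncfg["crf"]["sd"]),
                orientation=0.0,
                amplitude=1.0,
                baseline=0.0,
            )
            kernel = None
            if ncfg["kind"] in ("rectified_linear", "energy"):
                kernel = make_dog_kernel(
                    center=(float(crf_c[0]), float(crf_c[1])),
                    orientation=0.0,
                    sigma_center=float(ncfg["crf"]["sd"]),
                    sigma_surround=float(ncfg["crf"]["sd"]) * 1.5,
                    grid_size=G,
                )
            neuron = VirtualNeuron(
                kind=ncfg["kind"],
                kernel=kernel,
                crf_center=(int(round(crf_c[0])), int(round(crf_c[1]))),
                gain=float(ncfg.get("gain", 1.0)),
                noise=ncfg.get("noise", "poisson"),
            )
            spikes = simulate_responses(neuron, labels, int(cfg["n_trials"]), seeds["simulate"])
            spikes.to_csv(out / "spikes.csv")
            state.update(labels=labels, spikes=spikes, crf_true=crf_true, neuron=neuron)
            summary["stages"]["simulate"] = {
                "n_labels": labels.N,
                "total_spikes": float(spikes.totals().sum()),
            }

        # --- crf --------------------------------------------------------
        if "crf" in stages:
            log.info("stage crf")
            cmap, pos = gen_grating_response_map(
                state["crf_true"], gain=50.0, seed=seeds["crf"], grid_size=G
            )
            crf_fit = fit_crf(cmap, pos)
            state["crf"] = crf_fit
            summary["stages"]["crf"] = {
                "center": list(crf_fit.center),
                "sd_major": crf_fit.sd_major,
                "sd_minor": crf_fit.sd_minor,
            }
        elif "simulate" in stages:
            state["crf"] = state["crf_true"]

        # --- sta --------------------------------------------------------
        if "sta" in stages:
            log.info("stage sta")
            labels, spikes = state["labels"], state["spikes"]
            kern = sta.compute_sta(labels, spikes)
            kern.p_perm = sta.permutation_test(
                labels, spikes, int(cfg["sta"]["n_perm"]), seeds["sta"]
            )
            sizes, curve = sta.convergence_curve(
                labels,
                spikes,
                step=int(cfg["sta"]["step"]),
                reps=int(cfg["sta"]["reps"]),
                seed=seeds["sta"],
            )
            try:
                fit = sta.fit_convergence(sizes, curve)
                kern.convergence_ratio = fit.ratio
            except (ValueError, RuntimeError) as exc:
                log.warning("convergence fit failed: %s", exc)
            write_kernel(kern, out / "sta_kernel.tsv")
            state["sta"] = kern
            summary["stages"]["sta"] = {
                "p_perm": kern.p_perm,
                "magnitude": kern.magnitude,
                "convergence_ratio": kern.convergence_ratio,
                "effective": kern.effective,
            }

        # --- af ---------------------------------------------------------
        if "af" in stages:
            log.info("stage af")
            acfg = af.AFConfig(
                delta_inv=float(cfg["af"]["delta_inv"]),
                beta=float(cfg["af"]["beta"]),
                n_pairs_target=int(cfg["af"]["n_pairs_target"]),
                seed=seeds["af"],
            )
            kern_af = af.estimate_af(state["labels"], state["spikes"], acfg)
            write_kernel(kern_af, out / "af_kernel.tsv")
            state["af"] = kern_af
            entry = {"magnitude": kern_af.magnitude}
            if "sta" in state and state["sta"].magnitude > 0 and kern_af.magnitude > 0:
                entry["cosine_to_sta"] = metrics.cosine_similarity(kern_af, state["sta"])
            summary["stages"]["af"] = entry

        # --- stc --------------------------------------------------------
        if "stc" in stages:
            log.info("stage stc")
            labels, spikes = state["labels"], state["spikes"]
            weights = stc.normalize_spikes(spikes, order=labels.ids)
            result = stc.compute_stc(labels, weights, state["sta"])
            result = stc.significant_stcs(
                result, labels, spikes, int(cfg["stc"]["n_rand"]), seeds["stc"]
            )
            for k in result.significant_kernels():
                write_kernel(k, out / f"stc_{k.rank}.tsv")
            state["stc"] = result
            summary["stages"]["stc"] = {
                "n_significant": int(result.significant.sum()),
                "top_eigenvalue": float(result.eigenvalues[0]),
                "bottom_eigenvalue": float(result.eigenvalues[-1]),
            }

        # --- models -----------------------------------------------------
        if "models" in stages:
            log.info("stage models")
            labels, spikes = state["labels"], state["spikes"]
            fit_sta = response_models.fit_sta_model(state["sta"], labels, spikes)
            entry = {
                "sta": {"w": fit_sta.w_sta, "rmse": fit_sta.rmse, "r": fit_sta.pearson_r}
            }
            if "stc" in state:
                fit_both = response_models.fit_sta_stc_model(
                    state["sta"], state["stc"], labels, spikes
                )
                entry["sta_stc"] = {
                    "rmse": fit_both.rmse,
                    "r": fit_both.pearson_r,
                    "n_stc": fit_both.n_stc,
                }
                entry["delta_r"] = fit_both.pearson_r - fit_sta.pearson_r
            summary["stages"]["models"] = entry

        # --- metrics ----------------------------------------------------
        if "metrics" in stages:
            log.info("stage metrics")
            kern = state["sta"]
            crf_est = state.get("crf", state.get("crf_true"))
            cc = crf_est.center_cell(G)
            pref = kern.preference(cc)
            entry = {"preference": pref}
            try:
                entry["pr_ratio"] = metrics.pr_ratio(kern, pref)
                entry["overlap_ratio"] = metrics.overlap_ratio(crf_est, kern, pref)
            except ValueError as exc:
                entry["error"] = str(exc)
            ideal = sta.ideal_rffg(state["labels"], crf_est, pref)
            if kern.magnitude > 0:
                entry["cosine_to_ideal"] = metrics.cosine_similarity(kern, ideal)
            summary["stages"]["metrics"] = entry

        # --- validate ---------------------------------------------------
        if "validate" in stages:
            log.info("stage validate")
            truths = validation_model.default_truth_kernels(
                int(cfg["validate"]["n_kernels"]), G, seeds["validate"]
            )
            report = validation_model.run_validation(
                truths, state["labels"], seed=seeds["validate"]
            )
            report.to_csv(out / "validation.csv", index=False)
            summary["stages"]["validate"] = {
                "mean_cos_truth_dot": float(report["cos_truth_dot"].mean()),
                "mean_cos_label_dot": float(report["cos_label_dot"].mean()),
            }
    except Exception as exc:
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        raise RuntimeError(f"pipeline aborted in a stage: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
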