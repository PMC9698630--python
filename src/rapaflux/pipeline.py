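"""End-to-end orchestration: simulate/load -> normalize -> multivariate ->
network modules -> pathway enrichment -> constraint-based target screen.

One configuration dictionary drives every stage; each stage writes its TSV
outputs before the next starts and a JSON report aggregates the headline
results (biomarkers, selected modules, passed pathways, ranked targets).
Rerunning with an identical configuration and seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich as enrich_mod
from . import gsmm, modnet, multivariate, preprocess, synthgen
from .exceptions import ConfigurationError, StageError

log = logging.getLogger("rapaflux")

STAGES = ("preprocess", "multivariate", "modules", "enrich", "screen")


def default_config() -> dict:
    return {
        "seed": 0,
        "stages": {s: True for s in STAGES},
        "dataset": {"path": None},  # None -> simulate with the seed
        "normalization": {"transform": "log10", "scaling": "autoscale",
                          "missing_policy": "half_min_impute",
                          "missing_threshold": 0.5},
        "multivariate": {"n_components": 2, "vip_threshold": 1.0},
        "network": {"power": 9, "network_type": "unsigned",
                    "min_module_size": 3, "cut_height": 0.9,
                    "r_cut": 0.65, "p_cut": 0.01, "timepoint_h": 24},
        "enrichment": {"p_cut": 0.05, "min_hits": 3, "background": None},
        "screening": {"model_path": None, "w": 0.5, "factor": 2.0,
                      "top_k": 10, "variant": "arithmetic",
                      "apply_constraints": True},
    }


def merge_config(overrides: dict | None) -> dict:
    cfg = default_config()
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = copy.deepcopy(val)
    return cfg


def _tsv(df: pd.DataFrame, path: Path, index: bool = False, **kw) -> None:
    df.to_csv(path, sep="\t", index=index, **kw)


def run_pipeline(config: dict | None = None, outdir="rapaflux_out") -> dict:
    """Execute the configured stages in order; return (and write) the report."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "config": cfg, "stages": {}}
    stage = "setup"
    try:
        # ---- input data ---------------------------------------------------
        if cfg["dataset"]["path"]:
            ds = synthgen.read_dataset(cfg["dataset"]["path"])
            log.info("loaded dataset from %s", cfg["dataset"]["path"])
        else:
            ds = synthgen.generate_dataset(seed=seed)
            synthgen.write_dataset(ds, outdir / "dataset")
            log.info("simulated dataset with seed %d", seed)

        # ---- preprocess ---------------------------------------------------
        norm = ds
        if cfg["stages"]["preprocess"]:
            stage = "preprocess"
            log.info("[preprocess] params: %s", cfg["normalization"])
            ncfg = preprocess.NormalizationConfig(**cfg["normalization"])
            norm = preprocess.normalize(ds, ncfg)
            norm.intensities.to_csv(outdir / "normalized.tsv", sep="\t",
                                    index_label="sample_id")
            report["stages"]["preprocess"] = {
                "n_samples": len(norm.samples),
                "n_metabolites": len(norm.metabolites)}

        X = norm.intensities

        # ---- multivariate -------------------------------------------------
        if cfg["stages"]["multivariate"]:
            stage = "multivariate"
            mv = cfg["multivariate"]
            log.info("[multivariate] params: %s", mv)
            pca_res = multivariate.pca(X, n_components=mv["n_components"])
            _tsv(pca_res.scores, outdir / "pca_scores.tsv", index=True,
                 index_label="sample_id")
            Y = multivariate.one_hot(norm.metadata["condition"])
            pls = multivariate.plsda_fit(X, Y, n_components=mv["n_components"])
            vip_df = pls.vip.rename("VIP").rename_axis("metabolite").reset_index()
            vip_df["selected"] = vip_df["VIP"] > mv["vip_threshold"]
            vip_df["tier2"] = vip_df["VIP"] > 1.5
            vip_df = vip_df.sort_values(["VIP", "metabolite"],
                                        ascending=[False, True],
                                        kind="mergesort").reset_index(drop=True)
            _tsv(vip_df, outdir / "vip_scores.tsv")
            ycorr = multivariate.yield_correlation(X, norm.yields)
            _tsv(ycorr, outdir / "yield_correlation.tsv")
            biomarkers = multivariate.select_biomarkers(
                pls.vip, threshold=mv["vip_threshold"])
            report["stages"]["multivariate"] = {
                "n_biomarkers": int(len(biomarkers)),
                "biomarkers": biomarkers["metabolite"].tolist(),
                "top_yield_correlates": ycorr.head(5)["metabolite"].tolist(),
                "pca_explained_variance_ratio":
                    [float(v) for v in pca_res.explained_variance_ratio],
            }

        # ---- network modules ----------------------------------------------
        modules = None
        if cfg["stages"]["modules"]:
            stage = "modules"
            net = dict(cfg["network"])
            log.info("[modules] params: %s", net)
            tp = net.pop("timepoint_h")
            ncfg = modnet.NetworkConfig(**net)
            sub = norm.subset_timepoint(tp)
            modules = modnet.build_modules(sub.intensities,
                                           sub.metadata["condition"], ncfg)
            _tsv(modules.assignment.rename_axis("metabolite").reset_index(),
                 outdir / "modules.tsv")
            if modules.trait_correlation is not None:
                _tsv(modules.trait_correlation, outdir / "module_trait.tsv")
            if modules.eigenprofiles is not None:
                _tsv(modules.eigenprofiles, outdir / "eigenprofiles.tsv",
                     index=True, index_label="module")
            report["stages"]["modules"] = {
                "n_modules": len(modules.module_labels()),
                "module_sizes": {m: int((modules.assignment == m).sum())
                                 for m in modules.module_labels()},
                "selected": dict(sorted(modules.selected.items())),
            }

        # ---- pathway enrichment -------------------------------------------
        if cfg["stages"]["enrich"]:
            stage = "enrich"
            if modules is None:
                raise ConfigurationError("enrich stage requires modules stage")
            ecfg = cfg["enrichment"]
            log.info("[enrich] params: %s", ecfg)
            db = enrich_mod.load_bundled_db()
            res = enrich_mod.enrich_modules(
                modules, db, p_cut=ecfg["p_cut"], min_hits=ecfg["min_hits"],
                background=ecfg["background"])
            _tsv(res, outdir / "enrichment.tsv")
            passed = res[res["passed"]]
            report["stages"]["enrich"] = {
                "passed": [
                    {"query": r["query"], "pathway": r["pathway"],
                     "hits": int(r["hits"]), "p_value": float(r["p_value"]),
                     "impact": float(r["impact"])}
                    for _, r in passed.iterrows()],
            }

        # ---- constraint-based screen --------------------------------------
        if cfg["stages"]["screen"]:
            stage = "screen"
            scfg = cfg["screening"]
            log.info("[screen] params: %s", scfg)
            if scfg["model_path"]:
                model = gsmm.read_model(scfg["model_path"])
            else:
                model = synthgen.build_toy_model()
            if scfg["apply_constraints"]:
                model = gsmm.apply_experimental_constraints(model)
            wt = gsmm.fba(model)
            scores = gsmm.screen_targets(
                model, synthgen.DEFAULT_SCREEN_CANDIDATES, w=scfg["w"],
                factor=scfg["factor"], top_k=scfg["top_k"],
                variant=scfg["variant"])
            tdf = pd.DataFrame([{
                "rank": i + 1, "reaction": s.reaction_id,
                "strategy": s.strategy, "f_PH": s.f_ph,
                "mu_ratio": s.mu_ratio, "q_ratio": s.q_ratio,
                "status": s.status} for i, s in enumerate(scores)])
            _tsv(tdf, outdir / "targets.tsv")
            report["stages"]["screen"] = {
                "wild_type_growth_rate": float(wt.objective_value),
                "wild_type_rapamycin_rate": float(wt.rapamycin_rate),
                "targets": [
                    {"rank": i + 1, "reaction": s.reaction_id,
                     "strategy": s.strategy, "f_PH": float(s.f_ph),
                     "mu_ratio": float(s.mu_ratio),
                     "q_ratio": float(s.q_ratio)}
                    for i, s in enumerate(scores)],
            }
    except Exception as exc:
        _write_report(report, outdir)  # persist partial outputs
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(Path(outdir) / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
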