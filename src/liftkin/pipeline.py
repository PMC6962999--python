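"""End-to-end orchestration: simulate -> process -> qc -> link -> model.

A run is driven by a plain-text (YAML) config with a single top-level seed;
per-stage random streams are derived from it by fixed offsets, so re-running
the same config reproduces byte-identical outputs.  Every stage logs row
counts in/out, and a manifest records the config snapshot, seed, QC tallies,
and sha256 digests of all written files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from . import models, qc, spectral
from .errors import ConfigurationError, InputError, LiftkinError, StageError
from .linkage import assemble_observations
from .simulate import (
    SOYBEAN_GENOTYPES,
    CampaignConfig,
    GenotypeProfile,
    PlotSpec,
    generate_campaign,
)
from .transients import process_table

log = logging.getLogger("liftkin")

DEFAULT_MODELING = {
    "responses": ["fr2_ratio", "fvfm"],
    "split": "half-days",
    "folds": 10,
}


def demo_pipeline_config(seed: int = 0, n_days: int = 14) -> dict:
    """Config dict for the 2-genotype x 4-plot demo campaign."""
    return {
        "seed": seed,
        "campaign": {
            "n_days": n_days,
            "scans_per_day": 24,
            "measurements_per_scan": 6,
            "plots": [
                {"plot_id": "P01", "genotype": "Amarok", "replicate": 1},
                {"plot_id": "P02", "genotype": "Amarok", "replicate": 2},
                {"plot_id": "P03", "genotype": "S1", "replicate": 1},
                {"plot_id": "P04", "genotype": "S1", "replicate": 2},
            ],
        },
        "modeling": dict(DEFAULT_MODELING),
    }


def _profile_from(spec: dict) -> GenotypeProfile:
    name = spec["genotype"]
    if name in SOYBEAN_GENOTYPES and "species" not in spec:
        return SOYBEAN_GENOTYPES[name]
    return GenotypeProfile(
        name=name,
        species=spec.get("species", "soybean"),
        cold_tolerance=float(spec.get("cold_tolerance", 0.5)),
        chlorophyll_level=float(spec.get("chlorophyll_level", 1.0)),
    )


def campaign_config_from(config: dict) -> CampaignConfig:
    camp = dict(config.get("campaign", {}))
    plot_specs = camp.pop("plots", None)
    if not plot_specs:
        raise ConfigurationError("config.campaign.plots must list at least one plot")
    plots = [PlotSpec(p["plot_id"], _profile_from(p), int(p.get("replicate", 1)))
             for p in plot_specs]
    for key in ("start_date", "sowing_date"):
        if key in camp and isinstance(camp[key], str):
            camp[key] = pd.Timestamp(camp[key]).date()
    return CampaignConfig(plots=plots, seed=int(config.get("seed", 0)), **camp)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except LiftkinError as exc:
        raise StageError(name, str(exc)) from exc
    log.info("stage %s: done", name)


def run_pipeline(config, out_dir) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    ``config`` is a YAML path or an already-loaded dict (see
    :func:`demo_pipeline_config` for the schema).  Outputs land under
    ``out_dir``: bundle/ (simulated tables), derived/ (parameters, indices,
    observations, QC logs), models/ (coefficients, accuracies, partitions),
    and manifest.json.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    counts: dict = {}
    seed = int(cfg.get("seed", 0))

    if "input_dir" in cfg:
        with _stage("load_input"):
            bundle = lio.read_bundle(cfg["input_dir"])
            counts["transients_loaded"] = len(bundle.transients)
    else:
        with _stage("simulate"):
            camp_cfg = campaign_config_from(cfg)
            seed = camp_cfg.seed
            bundle = generate_campaign(camp_cfg)
            lio.write_bundle(bundle, out_dir / "bundle",
                             parquet=bool(cfg.get("parquet", True)))
            counts["transients_simulated"] = len(bundle.transients)
            counts["spectra_simulated"] = len(bundle.spectra)

    def require(table, name: str, stage: str):
        if table is None:
            raise InputError(f"{name} table missing from input bundle ({stage})")
        return table

    derived = out_dir / "derived"
    derived.mkdir(parents=True, exist_ok=True)

    with _stage("position_filter"):
        transients = qc.drop_repeated_position(bundle.transients)
        spectra = qc.drop_repeated_position(
            require(bundle.spectra, "spectra", "position_filter"))
        counts["transients_after_position_filter"] = len(transients)

    with _stage("process_transients"):
        params, failures = process_table(transients, bundle.schedule)
        params.to_csv(derived / "fluorescence_params.csv", index=False)
        failures.to_csv(derived / "transient_failures.csv", index=False)
        counts["params_rows"] = len(params)
        counts["transient_failures"] = len(failures)

    with _stage("process_spectra"):
        env = require(bundle.env, "env", "process_spectra")
        refs = require(bundle.references, "references", "process_spectra")
        indices, _lut = spectral.process_spectra(spectra, refs, env)
        indices.to_csv(derived / "spectral_indices.csv", index=False)
        counts["indices_rows"] = len(indices)

    with _stage("qc"):
        rules = qc.QCRules()
        fluor_kept, fluor_log = qc.qc_fluorescence(params, rules)
        idx_kept, idx_log = qc.qc_spectral(indices, rules)
        fluor_log.to_csv(derived / "qc_fluorescence_log.csv", index=False)
        idx_log.to_csv(derived / "qc_spectral_log.csv", index=False)
        counts["fluor_kept"] = len(fluor_kept)
        counts["fluor_rejected"] = len(params) - len(fluor_kept)
        counts["spectral_kept"] = len(idx_kept)
        counts["spectral_rejected"] = len(indices) - len(idx_kept)

    with _stage("linkage"):
        env = require(bundle.env, "env", "linkage")
        plots = require(bundle.plots, "plots", "linkage")
        pairs = spectral.pair_spectrum_to_transient(spectra, transients)
        obs = assemble_observations(fluor_kept, idx_kept, pairs, env, plots)
        obs.to_csv(derived / "observations.csv", index=False)
        counts["observations"] = len(obs)

    model_dir = out_dir / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    model_summary: dict = {}
    mcfg = {**DEFAULT_MODELING, **cfg.get("modeling", {})}

    with _stage("model"):
        for response in mcfg["responses"]:
            train, valid = models.split_train_validation(obs, mcfg["split"])
            design = models.build_design_matrix(train, response)
            fit = models.fit_lasso_cv(design, folds=int(mcfg["folds"]), seed=seed)
            fit.u.rename("coefficient").to_csv(model_dir / f"lasso_{response}_coefficients.csv")
            fit.cv_curve.to_csv(model_dir / f"lasso_{response}_cv_curve.csv", index=False)

            vdesign = design.transform(valid)
            pred = models.predict(fit, vdesign)
            vrows = valid[design.continuous + design.categorical + [response]].dropna()
            acc = models.validate_accuracy(
                vdesign.y, pred, valid.loc[vrows.index, ["genotype", "date", "hour_of_day"]])
            acc.to_csv(model_dir / f"accuracy_{response}.csv", index=False)

            order = (models.FR2_PARTITION_ORDER if response == "fr2_ratio"
                     else models.FVFM_PARTITION_ORDER)
            part = models.partition_variance(obs, response, order)
            part.to_csv(model_dir / f"anova_{response}.csv", index=False)

            predictor = "temperature" if response == "fr2_ratio" else "ppfd"
            terms = ("linear", "sqrt", "square") if response == "fr2_ratio" else ("linear", "sqrt")
            curves = models.fit_response_curve(obs, response, predictor,
                                               terms=terms, group_by="genotype")
            pd.DataFrame([{
                "group": c.group, "r_squared": c.r_squared, "n": c.n,
                **c.coefficients,
            } for c in curves]).to_csv(model_dir / f"response_{response}.csv", index=False)

            explained = part[part["factor"] != "residual"]
            model_summary[response] = {
                "lambda": fit.lambda_,
                "n_nonzero": fit.n_nonzero,
                "accuracy": acc.set_index("genotype")["pearson_r"].to_dict(),
                "top_factor": explained.loc[explained["pct_explained"].idxmax(), "factor"],
            }

    manifest = {
        "seed": seed,
        "config": cfg,
        "counts": counts,
        "models": model_summary,
        "digests": lio.digest_tree(out_dir, suffix=".csv"),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=lio._json_default, sort_keys=True))
    return manifest
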