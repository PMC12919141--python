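"""End-to-end orchestration: simulate -> derive -> score -> associate ->
sliding-window scan -> survival -> seno-age, with a run manifest.

The pipeline is driven by a single nested config (YAML/JSON-compatible
dict); every stage is also runnable standalone from its module. Given
fixed seeds a rerun is byte-identical; the manifest records seeds, input
hashes, per-stage row counts and timings. Results go to TSV/JSON files in
the output directory; logging goes to stderr.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
from typing import Any

import pandas as pd

from . import signature_derivation as sig
from . import synthetic_data as synth
from .burden_scoring import (
    ElasticNetConfig,
    composite_score,
    high_impact_panel,
    rank_and_truncate,
    select_features,
)
from .lifespan_dynamics import (
    WindowSpec,
    balanced_downsample,
    deswan_scan,
    peak_center,
    sex_stratified_scan,
)
from .longitudinal import fit_cox_left_truncated, quartile_trajectories, schoenfeld_test
from .senoage import compute_gap, fit_senoage_model, senoage_correlation_matrix
from .trait_association import cross_validate, fit_trait_model, mediate

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when the pipeline config fails validation, before analysis."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "catalog": {"n_proteins": 200, "n_core": 20, "frac_exclusive": 0.02},
        "cohort": {
            "n_participants": 600,
            "age_range": [50.0, 90.0],
            "changepoint_age": 70.0,
            "burden_loading": 0.5,
        },
    },
    "signature": {"rule": "ir-plus-chemical", "k_core": 9},
    "covariates": ["age", "sex", "race"],
    "traits": [
        {"name": "frailty", "polarity": "negative-health"},
        {"name": "diabetes", "polarity": "negative-health"},
    ],
    "elastic_net": {"n_cv_folds": 3, "n_lambdas": 12},
    "cv": {"n_iter": 10, "train_frac": 0.9},
    "deswan": {"n_per_decade": 60, "sex_balance": 0.5, "centers": list(range(60, 81))},
    "mediation": {"exposure": "sex", "outcome": "diabetes", "n_boot": 200},
    "survival": {"strata": ["sex", "race"]},
    "senoage": {"n_signatures": 3},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict, cohort: pd.DataFrame) -> None:
    """Fail fast if a referenced trait or covariate is absent."""
    header = set(cohort.columns)
    for spec in config["traits"]:
        if spec["name"] not in header:
            raise ConfigError(f"trait {spec['name']!r} not in the cohort header")
    for cov in config["covariates"]:
        if cov not in header:
            raise ConfigError(f"covariate {cov!r} not in the cohort header")
    outcome = config["mediation"]["outcome"]
    if outcome not in header:
        raise ConfigError(f"mediation outcome {outcome!r} not in the cohort header")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict | None = None, outdir: str = "senosig_run") -> dict:
    """Execute every stage on (by default) synthetic inputs; write a manifest.

    Returns the manifest dict. Any stage failure aborts with the stage name
    recorded in a partial manifest on disk.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config,
        "stages": {},
        "files": {},
        "seed": config["seed"],
    }

    def _finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        logger.info("stage %s done in %.2fs", name, time.time() - t0)

    stage = "simulate"
    try:
        t0 = time.time()
        seed = int(config["seed"])
        cat_cfg = synth.CatalogSimConfig(seed=seed, **config["simulate"]["catalog"])
        cohort_over = dict(config["simulate"]["cohort"])
        if "age_range" in cohort_over:
            cohort_over["age_range"] = tuple(cohort_over["age_range"])
        cohort_cfg = synth.CohortSimConfig(seed=seed + 1, **cohort_over)
        catalog, truth = synth.simulate_catalog(cat_cfg)
        cohort, truth = synth.simulate_cohort(cohort_cfg, truth)
        validate_config(config, cohort)
        _write_tsv(cohort, f"{outdir}/cohort.tsv")
        truth.to_json(f"{outdir}/truth.json")
        _finish_stage(stage, t0, n_participants=len(cohort))

        stage = "derive"
        t0 = time.time()
        records = sig.catalog_differential_records(catalog)
        status = sig.classify_senescence_status(
            records, rule=config["signature"]["rule"]
        )
        signatures = {
            ct: set(sig.cell_type_signature(records, ct, config["signature"]["rule"])[
                "protein"
            ])
            for ct in records["cell_type"].unique()
        }
        adult = [ct for ct in synth.ADULT_CELL_TYPES_9 if ct in signatures]
        adult_sigs = {ct: signatures[ct] for ct in adult}
        exclusive = {ct: sig.exclusive_signature(adult_sigs, ct) for ct in adult}
        k_core = min(config["signature"]["k_core"], len(signatures))
        core = sig.core_signature(signatures, k_core)
        _write_tsv(records, f"{outdir}/differential_records.tsv", index=False)
        _write_tsv(status.to_frame(), f"{outdir}/status.tsv")
        with open(f"{outdir}/signatures.json", "w") as fh:
            json.dump(
                {
                    "cell_type": {c: sorted(s) for c, s in signatures.items()},
                    "exclusive": {c: sorted(s) for c, s in exclusive.items()},
                    "core": sorted(core),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        _finish_stage(
            stage,
            t0,
            n_records=len(records),
            n_sap=int((status == "SAP").sum()),
            n_core=len(core),
        )

        stage = "score"
        t0 = time.time()
        sap_pool = sorted(
            set(status.index[status == "SAP"]) & set(cohort.columns)
        )
        enet = ElasticNetConfig(
            covariates=tuple(config["covariates"]),
            seed=seed,
            **config["elastic_net"],
        )
        panels, scores = {}, {}
        for spec in config["traits"]:
            name = spec["name"]
            sel = select_features(cohort, name, sap_pool, enet)
            panels[name] = rank_and_truncate(sel, name, spec["polarity"])
            if len(panels[name]):
                scores[name] = composite_score(cohort, panels[name])
        hip = high_impact_panel(panels) if len(panels) >= 2 else set()
        with open(f"{outdir}/panels.json", "w") as fh:
            json.dump(
                {
                    "panels": {t: p.to_dict() for t, p in panels.items()},
                    "high_impact_panel": sorted(hip),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        score_df = pd.DataFrame(scores)
        _write_tsv(score_df, f"{outdir}/scores.tsv")
        _finish_stage(stage, t0, panel_sizes={t: len(p) for t, p in panels.items()})

        stage = "associate"
        t0 = time.time()
        rows = []
        for spec in config["traits"]:
            name = spec["name"]
            if name not in scores:
                continue
            res = fit_trait_model(
                cohort, name, scores[name], covariates=config["covariates"]
            )
            cv = cross_validate(
                cohort,
                name,
                scores[name],
                n_iter=config["cv"]["n_iter"],
                train_frac=config["cv"]["train_frac"],
                seed=seed,
            )
            rows.append(
                {
                    "trait": name,
                    "effect": res.effect,
                    "se": res.se,
                    "p_value": res.p_value,
                    "family": res.family,
                    "cv_mean_r2": cv.mean_r2,
                }
            )
        _write_tsv(pd.DataFrame(rows), f"{outdir}/associations.tsv", index=False)
        _finish_stage(stage, t0, n_models=len(rows))

        stage = "mediate"
        t0 = time.time()
        med_cfg = config["mediation"]
        med_outcome = med_cfg["outcome"]
        mediator = scores.get(med_outcome)
        med_payload: dict[str, Any] = {"outcome": med_outcome}
        if mediator is not None:
            med = mediate(
                cohort,
                med_cfg["exposure"],
                mediator,
                med_outcome,
                covariates=[c for c in config["covariates"] if c not in
                            (med_cfg["exposure"], "age")] + ["age"],
                n_boot=med_cfg["n_boot"],
                seed=seed,
            )
            med_payload.update(
                acme=med.acme,
                ade=med.ade,
                total=med.total,
                prop_mediated=med.prop_mediated,
                ci=med.ci,
                n_boot=med.n_boot,
            )
        with open(f"{outdir}/mediation.json", "w") as fh:
            json.dump(med_payload, fh, indent=1, sort_keys=True)
        _finish_stage(stage, t0)

        stage = "deswan"
        t0 = time.time()
        dz = config["deswan"]
        sub, balance = balanced_downsample(
            cohort,
            n_per_decade=dz["n_per_decade"],
            sex_balance=dz["sex_balance"],
            seed=seed,
        )
        windows = WindowSpec(centers=tuple(dz["centers"]))
        prot_cols = [p for p in truth.proteins if p in cohort.columns]
        groups = {
            "SAP": set(status.index[status == "SAP"]),
            "non-SAP": set(status.index[status == "non-SAP"]),
        }
        scan = deswan_scan(sub, prot_cols, windows, covariates=("sex",), groups=groups)
        by_sex = sex_stratified_scan(sub, prot_cols, windows, groups=groups)
        peak, tied = peak_center(scan)
        _write_tsv(scan.counts, f"{outdir}/deswan_counts.tsv", index=False)
        _write_tsv(balance, f"{outdir}/deswan_balance.tsv", index=False)
        _finish_stage(
            stage,
            t0,
            peak=peak,
            tied=tied,
            peaks_by_sex={k: v for k, v in by_sex["peaks"].items()},
        )

        stage = "survival"
        t0 = time.time()
        if scores:
            surv_score = next(iter(scores.values()))
        else:
            # no trait panel survived selection; fall back to the plain
            # SAP-pool composite so the survival stage still runs
            logger.warning("no trait panels; survival uses the SAP-pool composite")
            surv_score = composite_score(cohort, sap_pool)
        cox = fit_cox_left_truncated(
            cohort, surv_score.rename("burden"), strata=config["survival"]["strata"]
        )
        schoenfeld_test(cox)
        traj = quartile_trajectories(cohort, surv_score)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "predictor": cox.predictor,
                        "log_hr": cox.log_hr,
                        "se": cox.se,
                        "p_value": cox.p_value,
                        "schoenfeld_p": cox.schoenfeld_p,
                        "n_events": cox.n_events,
                    }
                ]
            ),
            f"{outdir}/cox.tsv",
            index=False,
        )
        _write_tsv(traj["curves"], f"{outdir}/trajectories.tsv", index=False)
        _finish_stage(stage, t0, log_hr=cox.log_hr)

        stage = "senoage"
        t0 = time.time()
        gap_frames = {}
        cohort_cols = set(cohort.columns)
        pools = {}
        for ct in adult:
            # exclusive sets can be tiny on a weak catalog; fall back to the
            # full cell-type signature so the stage still demonstrates gaps
            pool = exclusive[ct] & cohort_cols
            if len(pool) < 3:
                pool = adult_sigs[ct] & cohort_cols
            if len(pool) >= 3:
                pools[ct] = pool
        chosen = list(pools)[: config["senoage"]["n_signatures"]]
        for ct in chosen:
            pool = sorted(pools[ct])
            sel = select_features(cohort, "age", pool, enet)
            panel = rank_and_truncate(sel, "age", "any")
            if len(panel) == 0:
                continue
            model = fit_senoage_model(cohort, panel, signature=ct)
            gap_frames[ct] = compute_gap(cohort, model)
        if gap_frames:
            long = pd.concat(gap_frames.values())
            _write_tsv(long, f"{outdir}/senoage.tsv")
            if len(gap_frames) >= 2:
                corr = senoage_correlation_matrix(
                    {ct: df["gap"] for ct, df in gap_frames.items()}
                )
                _write_tsv(corr, f"{outdir}/senoage_correlations.tsv")
        _finish_stage(stage, t0, signatures=list(gap_frames))

    except Exception:
        manifest["failed_stage"] = stage
        with open(f"{outdir}/manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        logger.error("pipeline aborted in stage %s", stage)
        raise

    for fname in sorted(os.listdir(outdir)):
        if fname != "manifest.json":
            manifest["files"][fname] = _sha256(os.path.join(outdir, fname))
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
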