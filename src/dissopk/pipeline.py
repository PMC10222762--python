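"""End-to-end study pipeline: generate -> screen -> correlate -> VBE -> spec.

Mirrors the biopredictive-method development workflow:

1. build the study fixture (products, methods, PK truth) and tablet batches;
2. construct the L9 design, simulate the nine dissolution runs and run the
   Q%2h/Q%12h/Q%24h screening ANOVA;
3. forward-simulate the "observed" reference plasma curve and deconvolve it
   to the in vivo fraction absorbed;
4. fit a Level-A IVIVC to every candidate dissolution condition (all
   apparatus x speed combinations, each product on noiseless mean
   profiles), convolve back, compute Cmax/AUC prediction errors and rank
   conditions by worst-case |PE|;
5. run virtual BE for each generic against the reference under the selected
   condition; 6. derive dissolution specification windows from the
   reference plus the products with the best VBE outcomes.

Everything is driven by one :class:`~dissopk.config.StudyConfig`; a fixed
config gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, synthetic
from .config import StudyConfig
from .dissolution import derive_spec
from .doe import check_orthogonality, doe_anova, l9_design
from .geometry import batch_geometry_summary
from .io import write_dissolution_csv, write_plasma_csv
from .ivivc import (
    InputFunction,
    OralKernel,
    classify_biopredictive,
    convolve_predict,
    deconvolve_fabs,
    fit_ivivc,
    prediction_error,
    rank_methods,
)
from .pk import derive_disposition, pk_metrics
from .vbe import PopulationModel, run_vbe

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full study and return the report dictionary.

    When ``outdir`` is given, all intermediate CSV/JSON artefacts are
    written there, each stamped with the config hash and the seeds used.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()} seed={config.seed}"
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    fixture = _build_fixture(config)
    report["fixture"] = {"seed": fixture.seed, "params": _jsonable(fixture.params_log)}

    report["geometry"] = _geometry_stage(config, fixture)
    design, diss_runs, anova = _doe_stage(config, fixture, out, stamp)
    report["doe"] = {
        "orthogonal": bool(check_orthogonality(design)[0]),
        "anova": anova.to_dict(orient="records"),
    }

    observed, fabs, kernel = _plasma_stage(config, fixture, out, stamp)
    ivivc_rows, ranking, models = _ivivc_stage(config, fixture, observed, fabs, kernel)
    selected = ranking.iloc[0]
    report["ivivc"] = {
        "run_table": ivivc_rows.to_dict(orient="records"),
        "ranking": ranking.to_dict(orient="records"),
        "selected_method": {
            "apparatus": str(selected["apparatus"]),
            "speed_rpm": int(selected["speed_rpm"]),
            "medium": "0.9% NaCl",  # screening found no medium effect
        },
    }

    vbe_results, passing = _vbe_stage(config, fixture, models, selected)
    report["vbe"] = vbe_results

    report["derived_spec"] = _spec_stage(config, fixture, selected, passing)

    if out is not None:
        ivivc_rows.to_csv(out / "ivivc_runs.csv", index=False)
        ranking.to_csv(out / "method_ranking.csv", index=False)
        anova.to_csv(out / "doe_anova.csv", index=False)
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


@_stage("fixture")
def _build_fixture(config: StudyConfig) -> synthetic.StudyFixture:
    fixture = synthetic.make_study_fixture(config.seed)
    return dataclasses.replace(
        fixture, disposition=config.disposition, absorption=config.absorption
    )


@_stage("geometry")
def _geometry_stage(config: StudyConfig, fixture) -> list[dict]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for name, product in fixture.products.items():
        batch = batch_geometry_summary(product.sample_tablets(12, rng))
        rows.append(
            {
                "product": name,
                "n": batch.n,
                "sa_v_mean": batch.sa_v_mean,
                "sa_v_sd": batch.sa_v_sd,
                "weight_mean": batch.weight_mean,
                "thickness_mean": batch.thickness_mean,
                "cross_dim_mean": batch.cross_dim_mean,
            }
        )
    return rows


@_stage("doe")
def _doe_stage(config: StudyConfig, fixture, out, stamp):
    design = l9_design()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    profiles = []
    rows = []
    for run_no, method in enumerate(fixture.methods, start=1):
        product_name = datasets.DOE_RUNS.loc[run_no - 1, "product"]
        profile = synthetic.simulate_dissolution(
            fixture.products[product_name],
            method,
            n_units=config.doe.n_units,
            seed=rng,
            noise_cv=config.doe.noise_cv,
        )
        profiles.append(profile)
        for unit in range(profile.n_units):
            one_unit = profile.q[unit]
            interp = lambda t: float(
                np.interp(t, np.concatenate(([0.0], profile.times)),
                          np.concatenate(([0.0], one_unit)))
            )
            rows.append(
                {"run": run_no, "unit": unit + 1, "q2h": interp(2.0),
                 "q12h": interp(12.0), "q24h": interp(24.0)}
            )
        if out is not None:
            write_dissolution_csv(
                profile, out / f"dissolution_run{run_no}.csv",
                header_comment=f"{stamp} run={run_no} method={method.label}",
            )
    responses = pd.DataFrame(rows)
    anova = doe_anova(design, responses)
    return design, profiles, anova


@_stage("plasma")
def _plasma_stage(config: StudyConfig, fixture, out, stamp):
    ref = fixture.products["Reference"]
    sinker = synthetic.MethodFixture(medium="0.9% NaCl", apparatus="paddle_sinker", speed_rpm=50)
    release = synthetic.effective_release(ref, sinker)
    t_rel = np.arange(0.25, 36.0 + 0.125, 0.25)
    from .dissolution import weibull_release

    frac = weibull_release(t_rel, release) / 100.0
    observed = synthetic.simulate_observed_plasma(
        fixture.disposition,
        fixture.absorption,
        in_vivo_release=(t_rel, frac),
        noise_cv=config.fixtures.plasma_noise_cv,
        seed=np.random.default_rng(np.random.SeedSequence([config.seed, 3])),
    )
    d = derive_disposition(fixture.disposition)
    # mechanistic deconvolution: kernel includes the absorption chain, so
    # the recovered input is the fraction released in vivo
    kernel = OralKernel.from_cat(d, fixture.absorption)
    fabs = deconvolve_fabs(
        observed, d, dose_mg=fixture.absorption.dose_mg, kernel=kernel
    )
    if out is not None:
        write_plasma_csv(observed, out / "observed_plasma.csv", header_comment=stamp)
    return observed, fabs, kernel


@_stage("ivivc")
def _ivivc_stage(config: StudyConfig, fixture, observed, fabs: InputFunction, kernel):
    d = derive_disposition(fixture.disposition)
    dose = fixture.absorption.dose_mg
    obs_metrics = pk_metrics(observed)
    doe_products = [n for n, p in fixture.products.items() if p.in_doe]
    rows = []
    models = {}
    for apparatus in ("basket", "paddle_sinker", "paddle"):
        for speed in (50, 75, 100):
            method = synthetic.MethodFixture(
                medium="0.9% NaCl", apparatus=apparatus, speed_rpm=speed
            )
            for product_name in doe_products:
                # ranking uses noiseless mean profiles: deterministic and
                # free of unit-level assay noise
                profile = synthetic.simulate_dissolution(
                    fixture.products[product_name], method, n_units=1,
                    seed=0, noise_cv=0.0,
                )
                model = fit_ivivc(fabs, profile)
                models[(apparatus, speed, product_name)] = (model, profile)
                pred = convolve_predict(
                    model, profile, d, dose_mg=dose, t_grid=observed.times_h,
                    kernel=kernel,
                )
                pred_metrics = pk_metrics(pred)
                pe_c = prediction_error(obs_metrics.cmax_ng_ml, pred_metrics.cmax_ng_ml)
                pe_a = prediction_error(obs_metrics.auc_0t, pred_metrics.auc_0t)
                rows.append(
                    {
                        "apparatus": apparatus,
                        "speed_rpm": speed,
                        "product": product_name,
                        "r_squared": model.r_squared,
                        "pe_cmax": pe_c,
                        "pe_auc": pe_a,
                        "biopredictive": classify_biopredictive(pe_c, pe_a),
                    }
                )
    df = pd.DataFrame(rows)
    ranking = rank_methods(df)
    return df, ranking, models


@_stage("vbe")
def _vbe_stage(config: StudyConfig, fixture, models, selected):
    apparatus = str(selected["apparatus"])
    speed = int(selected["speed_rpm"])
    method = synthetic.MethodFixture(medium="0.9% NaCl", apparatus=apparatus, speed_rpm=speed)
    ref_model, ref_profile = models[(apparatus, speed, "Reference")]
    results = {}
    passing = []
    test_products = [n for n in fixture.products if n != "Reference"]
    for i, name in enumerate(sorted(test_products)):
        test_profile = synthetic.simulate_dissolution(
            fixture.products[name], method, n_units=1, seed=0, noise_cv=0.0
        )
        pm = PopulationModel(
            n_subjects=config.population.n_subjects,
            n_trials=config.population.n_trials,
            cv_cl=config.population.cv_cl,
            cv_vc=config.population.cv_vc,
            cv_ka=config.population.cv_ka,
            cv_within=config.population.cv_within,
            seed=int(np.random.SeedSequence([config.seed, 4, i]).generate_state(1)[0] % (2**31)),
        )
        study = run_vbe(
            test_profile, ref_profile, ref_model, pm, fixture.disposition,
            dose_mg=fixture.absorption.dose_mg, absorption=fixture.absorption,
        )
        results[name] = {
            "pass_count": study.pass_count,
            "n_trials": study.n_trials,
            "trial_seeds": list(study.trial_seeds),
        }
        if study.pass_count >= int(0.9 * study.n_trials):
            passing.append(name)
    return results, passing


@_stage("spec")
def _spec_stage(config: StudyConfig, fixture, selected, passing):
    method = synthetic.MethodFixture(
        medium="0.9% NaCl", apparatus=str(selected["apparatus"]),
        speed_rpm=int(selected["speed_rpm"]),
    )
    names = ["Reference"] + [p for p in passing if p != "Reference"]
    profiles = [
        synthetic.simulate_dissolution(
            fixture.products[n], method, n_units=1, seed=0, noise_cv=0.0
        )
        for n in names
    ]
    if len(profiles) < 2:
        profiles = profiles * 2  # reference-only fallback window
    spec = derive_spec(profiles)
    return {
        "from_products": names,
        "windows": [
            {"time_h": p.time_h, "lower": p.lower, "upper": p.upper,
             "inclusive": p.inclusive}
            for p in spec.points
        ],
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
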