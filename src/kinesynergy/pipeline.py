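"""End-to-end orchestration: simulate/ingest -> preprocess -> principal
movements -> gait events -> DP/NJI -> mixed models.

Normal-walking trials feed the principal-movement decomposition and PA_kRMS
(the independent variables); perturbed-walking trials feed heel-strike
detection, DP and NJI (the dependent variables).  All outputs are plain
CSV/JSON written under the configured output directory together with a
manifest of parameters and seed, and the run is deterministic for a fixed
config + seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coordination import trial_dp
from .io import MarkerTrial, lowpass_trial, read_markers, resample_to
from .models import (
    ModelSpec,
    bonferroni_gate,
    compare_models,
    fit_mixed,
    lrt,
    model_indices,
    stepwise_eliminate,
)
from .posture import (
    build_posture_matrix,
    compute_pms,
    differentiate_scores,
    loo_validate,
    pa_rms,
    project_scores,
    spectral_noise_check,
)
from .simulate import GaitSimConfig, generate_cohort
from .smoothness import nji, select_side

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Single-config description of a full analysis run."""

    sim: GaitSimConfig | None = None
    input_dir: str | None = None  # directory of TSV trials (alternative to sim)
    n_resample: int | None = 5000  # normal-trial length normalization
    filter_order: int = 4
    filter_cutoff_hz: float = 20.0
    deriv_filter_order: int = 3
    deriv_filter_cutoff_hz: float = 10.0
    k_max: int = 7
    validate_pms: bool = True
    angle_threshold_deg: float = 15.0
    spectral_cutoff_hz: float = 5.0
    spectral_max_fraction: float = 0.01
    n_grid: int = 100
    responses: tuple[str, ...] = ("DP", "DPxNJI")
    alpha_random: float = 0.05
    alpha_fixed: float = 0.05
    bonferroni_alpha: float = 0.007
    random_trial_terms: bool = True
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            if "speeds" in sim:
                sim["speeds"] = tuple(sim["speeds"])
            cfg.sim = GaitSimConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    pm_summary: dict
    pa_table: pd.DataFrame
    dp_table: pd.DataFrame
    nji_table: pd.DataFrame
    dataset: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    final_models: dict[str, dict]
    elimination_logs: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_trials(config: PipelineConfig) -> tuple[list[MarkerTrial], pd.DataFrame | None]:
    if config.sim is not None:
        cohort, truth = generate_cohort(config.sim)
        return [trial for trial, _ in cohort], truth
    if config.input_dir is None:
        raise ValueError("pipeline config needs either a simulation config or input_dir")
    paths = sorted(Path(config.input_dir).glob("*.tsv"))
    if not paths:
        raise ValueError(f"no TSV trials found under {config.input_dir}")
    return [read_markers(p) for p in paths], None


def _preprocess(trial: MarkerTrial, config: PipelineConfig) -> MarkerTrial:
    out = trial
    if trial.condition == "normal" and config.n_resample:
        out = resample_to(out, config.n_resample)
    return lowpass_trial(out, config.filter_order, config.filter_cutoff_hz)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring.

    Raises with the offending stage and trial on any per-trial failure.
    """
    trials, truth = _load_trials(config)
    normal = [t for t in trials if t.condition == "normal"]
    perturbed = [t for t in trials if t.condition == "perturbed"]
    if not normal or not perturbed:
        raise ValueError("pipeline needs both normal and perturbed trials")

    normal = [_stage("preprocess", t, _preprocess, config) for t in normal]
    perturbed = [
        _stage(
            "preprocess",
            t,
            lambda tr, cfg: lowpass_trial(tr, cfg.filter_order, cfg.filter_cutoff_hz),
            config,
        )
        for t in perturbed
    ]

    # --- principal movements from normal walking ---
    matrix = build_posture_matrix(normal)
    if config.validate_pms:
        pms = loo_validate(normal, config.k_max, config.angle_threshold_deg)
    else:
        pms = compute_pms(matrix, config.k_max)
    kept = [int(i) for i in pms.validated_indices()]

    pa_rows = []
    spectral_rows = []
    for t in normal:
        pp = project_scores(pms, matrix, t.key)
        ts = differentiate_scores(
            pp,
            matrix.fs[t.key],
            trial_key=t.key,
            prefilter=(config.deriv_filter_order, config.deriv_filter_cutoff_hz),
        )
        for i in kept:
            rep = spectral_noise_check(
                ts.pp[:, i],
                ts.fs,
                config.spectral_cutoff_hz,
                config.spectral_max_fraction,
            )
            spectral_rows.append(
                dict(
                    subject=t.subject_id,
                    speed=t.speed,
                    k=i + 1,
                    fraction_above=rep.fraction_above,
                    passed=rep.passed,
                )
            )
            rec = pa_rms(ts.pa[:, i], t.speed, subject=t.subject_id, k=i + 1)
            pa_rows.append(rec)
    pa_table = pd.DataFrame(
        [
            dict(
                subject=r.subject,
                speed=r.speed,
                k=r.k,
                pa_rms_raw=r.pa_rms_raw,
                pa_rms_norm=r.pa_rms_norm,
            )
            for r in pa_rows
        ]
    )

    # --- dependent variables from perturbed walking ---
    dp_records, dp_rows, nji_records, nji_rows = [], [], [], []
    for t in perturbed:
        record, _ = _stage("deviation-phase", t, lambda tr, cfg: trial_dp(tr, n_grid=cfg.n_grid), config)
        dp_records.append(record)
        for (prox, dist, side), v in record.pair_dp.items():
            dp_rows.append(
                dict(
                    subject=t.subject_id,
                    speed=t.speed,
                    pair=f"{prox}-{dist}",
                    side=side,
                    dp=v,
                    trial_dp=record.trial_dp,
                )
            )
        sides = {}
        for side in ("left", "right"):
            wrist = t.marker(f"{side[0].upper()}WRI")
            sides[side] = nji(wrist, t.fs, subject=t.subject_id, speed=t.speed, side=side)
        chosen = select_side(sides["left"], sides["right"])
        nji_records.append(chosen)
        for side in ("left", "right"):
            r = sides[side]
            nji_rows.append(
                dict(
                    subject=t.subject_id,
                    speed=t.speed,
                    side=side,
                    nji=r.nji,
                    selected=r is chosen,
                )
            )

    from .models import assemble_dataset  # local import avoids cycle at module load

    dataset = assemble_dataset(pa_rows, dp_records, nji_records)

    # --- mixed-effects model selection per response and synergy ---
    random_terms = (
        ("participant_intercept", "participant_slope", "trial_intercept", "trial_slope")
        if config.random_trial_terms
        else ("participant_intercept", "participant_slope")
    )
    comparisons: dict[str, pd.DataFrame] = {}
    finals: dict[str, dict] = {}
    logs: dict[str, pd.DataFrame] = {}
    for response in config.responses:
        fits = []
        for i in kept:
            pa_col = f"PA{i + 1}_RMS_norm"
            maximal = ModelSpec(
                response=response, pa=pa_col, random_terms=random_terms, k=i + 1
            )
            final_spec, log = stepwise_eliminate(
                maximal, dataset, config.alpha_random, config.alpha_fixed
            )
            logs[f"{response}_PA{i + 1}"] = log
            fits.append(fit_mixed(final_spec, dataset))
        table = compare_models(fits, baseline_index=0)
        comparisons[response] = table
        usable = [f for f in fits if not f.singular] or fits
        best = min(usable, key=lambda f: f.aic)
        null_spec = ModelSpec(
            response=response,
            pa=best.spec.pa,
            fixed_terms=(),
            random_terms=best.spec.random_terms,
            k=best.spec.k,
        )
        null_fit = fit_mixed(null_spec, dataset)
        indices = model_indices(best, null_fit)
        if "PA" in best.spec.fixed_terms:
            chi2, dfd, p_pa = lrt(best, fit_mixed(best.spec.drop_fixed("PA"), dataset))
        else:
            chi2, dfd, p_pa = float("nan"), 0, float("nan")
        finals[response] = dict(
            k=best.spec.k,
            pa=best.spec.pa,
            fixed_terms=list(best.spec.fixed_terms),
            random_terms=list(best.spec.random_terms),
            beta=dict(zip(best.fe_params.index, map(float, best.fe_params))),
            se=dict(zip(best.fe_bse.index, map(float, best.fe_bse))),
            vcomps={k: float(v) for k, v in best.vcomps.items()},
            resid_var=best.resid_var,
            p_pa_lrt=p_pa,
            significant_bonferroni=(
                bool(bonferroni_gate([p_pa], config.bonferroni_alpha)[0])
                if np.isfinite(p_pa)
                else False
            ),
            singular=best.singular,
            **{k: v for k, v in indices.items() if k != "total_null"},
        )

    pm_summary = dict(
        k=pms.k,
        variance_fractions=[float(f) for f in pms.variance_fractions],
        eigenvalues=[float(v) for v in pms.eigenvalues],
        validation_angles_deg=(
            [float(a) for a in pms.validation_angles]
            if pms.validation_angles is not None
            else None
        ),
        validated=(
            [bool(v) for v in pms.validated] if pms.validated is not None else None
        ),
        eigenvectors=[[float(x) for x in v] for v in pms.eigenvectors],
    )

    manifest = dict(
        package_version=__version__,
        config=_config_dict(config),
        seed=config.sim.seed if config.sim is not None else None,
        n_trials=len(trials),
        validated_pms=[i + 1 for i in kept],
    )
    result = PipelineResult(
        pm_summary=pm_summary,
        pa_table=pa_table,
        dp_table=pd.DataFrame(dp_rows),
        nji_table=pd.DataFrame(nji_rows),
        dataset=dataset,
        comparisons=comparisons,
        final_models=finals,
        elimination_logs=logs,
        manifest=manifest,
    )
    if truth is not None:
        result.manifest["truth_table"] = truth.to_dict(orient="records")
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _stage(name, trial, fn, config):
    try:
        return fn(trial, config)
    except Exception as exc:  # annotate with stage + trial, re-raise
        raise RuntimeError(f"pipeline stage {name!r} failed on trial {trial.key}: {exc}") from exc


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir", None)  # output location is not an analysis parameter
    sim = d.get("sim")
    if sim is not None and sim.get("synergy_vectors") is not None:
        sim["synergy_vectors"] = np.asarray(sim["synergy_vectors"]).tolist()
    return d


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "pm.json", "w") as fh:
        json.dump(result.pm_summary, fh, indent=1, sort_keys=True)
    result.pa_table.to_csv(out_dir / "pa_rms.csv", index=False, float_format="%.10g")
    result.dp_table.to_csv(out_dir / "dp.csv", index=False, float_format="%.10g")
    result.nji_table.to_csv(out_dir / "nji.csv", index=False, float_format="%.10g")
    result.dataset.to_csv(out_dir / "dataset.csv", index=False, float_format="%.10g")
    for response, table in result.comparisons.items():
        table.to_csv(out_dir / f"comparison_{response}.csv", index=False, float_format="%.10g")
    with open(out_dir / "final_models.json", "w") as fh:
        json.dump(result.final_models, fh, indent=1, sort_keys=True, default=float)
    for name, log in result.elimination_logs.items():
        log.to_csv(out_dir / f"elimination_{name}.csv", index=False, float_format="%.10g")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True, default=str)
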