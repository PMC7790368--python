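"""Shared study configuration for the numbered analysis drivers.

One synthetic cohort stands in for the study data: 13 subjects, three belt
speeds, one steady and one perturbed trial each, generated with a fixed seed.
Trial durations are shorter than a full lab session (20 s steady / 60 s
perturbed) so the whole analysis reruns in about a minute; every statistic is
computed by the same package code regardless of duration.
"""

from pathlib import Path

from kinesynergy import GaitSimConfig
from kinesynergy.pipeline import PipelineConfig

STUDY_SEED = 20260929
RESULTS = Path(__file__).resolve().parent.parent / "results"
PIPELINE_DIR = RESULTS / "pipeline"


def study_sim_config() -> GaitSimConfig:
    return GaitSimConfig(
        n_subjects=13,
        duration_s=20.0,
        perturbed_duration_s=60.0,
        noise_sd=0.002,
        seed=STUDY_SEED,
    )


def study_pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        sim=study_sim_config(),
        n_resample=2000,
        k_max=4,
        validate_pms=True,
        responses=("DP", "DPxNJI"),
        out_dir=str(PIPELINE_DIR),
    )
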