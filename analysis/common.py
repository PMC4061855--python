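"""Shared configuration for the analysis drivers.

One desk-scale study is threaded through scripts 01-05: all three language
groups (4 subjects each), two sessions, two oddball blocks per session of
30 standards + 15 deviants, full 39-channel montage, alpha and gamma bands
on a 1 Hz grid.  Subject screening uses a minimum of 10 artifact-free
trials per cell, the same rule as the full-size study scaled to these
trial counts.
"""

from pathlib import Path

from toneosc import pipeline, synth

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis_run"

MASTER_SEED = 2013


def study_design(master_seed: int = MASTER_SEED) -> synth.StudyDesign:
    return synth.scaled_design(
        master_seed=master_seed,
        groups={"English": 4, "Chinese": 4, "Thai": 4},
        n_standards=30,
        n_deviants=15,
        n_blocks=2,
        artifact_rate={"Chinese": 0.24, "English": 0.18, "Thai": 0.26},
    )


def study_config(master_seed: int = MASTER_SEED) -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(
        design=study_design(master_seed),
        f_min=8.0,
        f_max=50.0,
        f_step=1.0,
        min_trials=10,
        single_precision=True,
        out_dir=str(SCRATCH),
    )


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
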