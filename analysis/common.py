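"""Shared configuration for the numbered analysis drivers.

The drivers run the desk-scale study (12 subjects per group, 300 frames at
TR 0.72 s) out of ``scratch/analysis`` and copy their headline tables into
``results/``.  Each driver ensures its prerequisite stages have run.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from protoconn.pipeline import STAGE_ORDER, PipelineConfig, STAGES

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
WORKDIR = ROOT / "scratch" / "analysis"

_SENTINELS = {
    "simulate": "data/manifest.tsv",
    "preprocess": "preproc/fd.tsv",
    "connectivity": "fc",
    "fingerprint": "fingerprint/language_fingerprints.tsv",
    "dice": "dice/dice_long.tsv",
    "stats": "stats/language_anova.tsv",
}


def get_config() -> PipelineConfig:
    return PipelineConfig(output_dir=str(WORKDIR), n_per_group=12,
                          n_timepoints=300, master_seed=7)


def ensure_stages(upto: str) -> PipelineConfig:
    """Run any missing pipeline stages up to (and including) ``upto``."""
    cfg = get_config()
    for stage in STAGE_ORDER:
        if not (WORKDIR / _SENTINELS[stage]).exists():
            print(f"[driver] running missing stage: {stage}")
            STAGES[stage](cfg)
        if stage == upto:
            break
    return cfg


def publish(src: Path, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    dst = RESULTS / name
    shutil.copyfile(src, dst)
    print(f"[driver] wrote {dst.relative_to(ROOT)}")
    return dst
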