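"""Shared locations and the demo study profile for the analysis scripts.

The drivers run in order (01 → 06) from the repository root. Bulky
intermediates (FASTQ, genome, per-tag tables) live under scratch/demo;
the headline tables each step reports are copied into results/.
"""

from pathlib import Path
import shutil

from emmir.config import PipelineConfig, SimulateParams

RUN_DIR = Path("scratch/demo")
RESULTS = Path("results")
SEED = 20170606 % (2**31 - 1)


def demo_config() -> PipelineConfig:
    cfg = PipelineConfig(output_dir=str(RUN_DIR), seed=SEED)
    cfg.simulate = SimulateParams(
        genome_length=60_000,
        n_mirnas=30,
        n_conserved=8,
        n_up=6,
        n_down=3,
        fold=8.0,
        library_depth=30_000,
        nb_dispersion=0.1,
        contaminant_fraction=0.2,
    )
    return cfg


def load_config() -> PipelineConfig:
    path = RUN_DIR / "config.yaml"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    return PipelineConfig.from_yaml(path)


def publish(*names: str) -> None:
    """Copy per-run output tables into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        src = RUN_DIR / name
        if src.exists():
            shutil.copy(src, RESULTS / name)
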