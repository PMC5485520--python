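"""Pipeline configuration: one YAML document, one key per stage parameter.

Defaults equal the published analysis settings: 18 nt minimum tag length,
<= 2 mismatches for conserved assignment, < 200 bp locus clustering,
±200 nt precursor flanks, inverted-repeat scoring 40/3/−3/6 with a 240 nt
span cap and 10 nt extension, significance threshold 0.05, and the
3-mismatch / 0-indel target rule with positions 10–11 protected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulateParams:
    genome_length: int = 100_000
    gc: float = 0.45
    n_mirnas: int = 50
    n_conserved: int = 10
    n_up: int = 8
    n_down: int = 4
    fold: float = 8.0
    n_replicates: int = 2
    library_depth: int = 100_000
    nb_dispersion: float = 0.1
    contaminant_fraction: float = 0.2
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = ""


@dataclass
class PreprocessParams:
    min_len: int = 18
    max_len: int = 30


@dataclass
class MapParams:
    k: int = 12
    max_mismatches: int = 0
    max_hits: int = 100


@dataclass
class DiscoveryParams:
    conserved_max_mismatches: int = 2
    cluster_max_gap: int = 200
    flank: int = 200
    ir_threshold: int = 40
    ir_match: int = 3
    ir_mismatch: int = -3
    ir_gap_penalty: int = 6
    ir_max_repeat: int = 240
    ir_min_loop: int = 3
    extend_pad: int = 10
    fold_min_loop: int = 3
    mature_min_len: int = 18
    mature_max_len: int = 25
    max_unpaired: int = 4
    max_unpaired_run: int = 2
    max_bulges: int = 1
    bulge_size: int = 2
    min_hairpin_len: int = 60


@dataclass
class QuantifyParams:
    alpha: float = 0.05
    pseudocount: float = 0.5


@dataclass
class TargetParams:
    max_mismatches: int = 3
    protected_positions: tuple[int, int] = (10, 11)


@dataclass
class QpcrParams:
    reference_id: str = "18S"
    control_sample: str = "control"
    equal_var: bool = True


@dataclass
class PipelineConfig:
    """Paths plus per-stage parameters; ``seed`` drives all randomness."""

    output_dir: str = "emmir_out"
    seed: int = 0
    genome: str | None = None
    mature_reference: str | None = None
    ncrna_references: dict[str, str] = field(default_factory=dict)
    transcripts: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)
    ct_table: str | None = None
    simulate: SimulateParams = field(default_factory=SimulateParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    map: MapParams = field(default_factory=MapParams)
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    targets: TargetParams = field(default_factory=TargetParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("simulate", SimulateParams),
            ("preprocess", PreprocessParams),
            ("map", MapParams),
            ("discovery", DiscoveryParams),
            ("quantify", QuantifyParams),
            ("targets", TargetParams),
            ("qpcr", QpcrParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "targets" in kwargs and isinstance(kwargs["targets"], TargetParams):
            tp = kwargs["targets"]
            kwargs["targets"] = TargetParams(
                max_mismatches=tp.max_mismatches,
                protected_positions=tuple(tp.protected_positions),
            )
        return cls(**kwargs)
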