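"""Pipeline configuration: every tunable constant in one validated object."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class DesignConfig:
    n_courses: int = 3
    durations: tuple = (44, 36, 28)
    interval_h: float = 4.0
    pool_size: int = 10


@dataclass
class SimulationConfig:
    n_proteins: int = 1525
    frac_rhythmic: float = 0.2
    noise_sd: float = 0.2
    dropout_midpoint: float = 20_000.0
    dropout_slope: float = 1.2
    dropout: bool = True
    phase_grid_h: float = 2.0


@dataclass
class QuantConfig:
    charges: tuple = (2, 3, 4)
    top_k_spectra: int = 5
    min_peptides: int = 2
    normalize: bool = True


@dataclass
class RhythmConfig:
    alpha_anova: float = 0.1
    alpha_jtk: float = 0.1
    period_h: float = 24.0
    lag_grid_step_h: float = 2.0
    min_reps_per_bin: int = 2
    min_peptides_per_sample: int = 2


@dataclass
class ProteogenomicsConfig:
    n_species: int = 39
    n_overlap: int = 2
    n_uncalled: int = 25
    n_wobbly: int = 94
    n_gap: int = 120
    n_base_proteins: int = 60
    base_protein_length: tuple = (150, 300)
    n_same_score_decoys: int = 20
    n_il_decoys: int = 20
    n_conspecific_only: int = 10
    score_mean: float = 60.0
    score_sd: float = 8.0
    collection_threshold: float = 35.6
    target_threshold: float = 19.0
    score_tol: float = 0.0
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    max_missed_cleavages: int = 2


@dataclass
class PipelineConfig:
    """All knobs for one end-to-end run (simulation mode)."""

    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    rhythm: RhythmConfig = field(default_factory=RhythmConfig)
    progen: ProteogenomicsConfig = field(default_factory=ProteogenomicsConfig)

    def validate(self) -> "PipelineConfig":
        for name, a in [("alpha_anova", self.rhythm.alpha_anova),
                        ("alpha_jtk", self.rhythm.alpha_jtk)]:
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.rhythm.period_h <= 0:
            raise ValueError("period must be > 0")
        if not 0 <= self.simulation.frac_rhythmic <= 1:
            raise ValueError("frac_rhythmic must be in [0, 1]")
        if self.quant.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        sections = {"design": DesignConfig, "simulation": SimulationConfig,
                    "quant": QuantConfig, "rhythm": RhythmConfig,
                    "progen": ProteogenomicsConfig}
        kw = {}
        for key, val in doc.items():
            if key in sections:
                sub = sections[key](**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in (val or {}).items()})
                kw[key] = sub
            elif key == "seed":
                kw["seed"] = int(val)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kw).validate()
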