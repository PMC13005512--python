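"""Pipeline configuration (YAML-backed).

Collects the tunable knobs of the pipeline in one serialisable object:
solver settings, validation selection thresholds, disease-scaling factors,
clustering/seeding choices and the modifier-score positivity threshold.
Functions throughout the package take these values as explicit arguments;
the config object is the convenience layer that holds and documents the
defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # solver
    entropy_weight: float = 1.0
    solver_tolerance: float = 1e-9
    flux_export_floor: float = 1e-9
    # extraction
    active_gene_threshold: float = 10.0  # FPKM
    extraction_flux_tolerance: float = 1e-6
    # validation selection (None disables a criterion)
    min_accuracy: float | None = 0.65
    min_rho: float | None = 0.56
    max_distance: float | None = None
    # disease construction
    gba1_factor: float = 0.10
    down_factor: float = 0.50
    up_factor: float = 1.50
    down_range: tuple[float, float] = (0.30, 0.70)
    up_range: tuple[float, float] = (1.30, 1.70)
    # simulation setup
    atpm_lb: float = 44.8
    biomass_lb: float = 3.45
    ganglioside_uptake_levels: tuple[float, ...] = (0.1, 1.0, 5.0, 10.0)
    atpm_sweep_levels: tuple[float, ...] = (20.0, 30.0, 40.0, 44.8)
    # ensembles and statistics
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    adjust_flux_pvalues: bool = False  # optional BH correction
    strong_rho: float = 0.7
    weak_rho: float = 0.3
    module_cut_distance: float = 0.3
    # clustering / embedding
    tsne_seed: int = 0
    silhouette_threshold: float = 0.25
    # modifier-gene scoring
    rts_positivity_threshold: float = 0.0
    mta_gap_fraction: float = 0.1
    # global randomness
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ganglioside_uptake_levels", "atpm_sweep_levels", "down_range", "up_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
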