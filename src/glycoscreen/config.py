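"""Configuration objects for the synthetic-data generator and the pipeline.

The simulator emulates three data layers of a breast-cancer study: a clinical
cohort (log2 expression + survival + covariates, METABRIC-like), a cell-line
panel (expression + log10 metabolite concentrations, CCLE-like), and imaging /
assay inputs.  ``SimConfig`` holds every knob; its defaults are the study
conditions the pipeline is designed around (1904-sample cohort with a 15.7%
triple-negative fraction, a 46-line panel, a 17,329-gene regulation table with
53.5% of genes downregulated).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


def _default_subtype_proportions() -> dict[str, float]:
    # METABRIC-like subtype mix; TNBC fraction 299/1904 ~ 0.157.
    return {
        "TNBC": 0.157,
        "LumA": 0.370,
        "LumB": 0.250,
        "HER2": 0.120,
        "NormalLike": 0.103,
    }


def _default_block_structure() -> dict[str, float]:
    # gene-module -> |correlation| with the matching metabolite block; the
    # glycolytic module correlates +r with glycolytic metabolites and -r with
    # FAO metabolites, and vice versa for the FAO module.
    return {"glycolytic": 0.8, "fao": 0.8}


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic-data generator.

    One global ``seed`` feeds independent named sub-streams (one per output
    table), so generating one table never perturbs another.
    """

    seed: int = 0
    # cohort
    n_samples: int = 1904
    n_genes: int = 200
    subtype_proportions: Mapping[str, float] = field(
        default_factory=_default_subtype_proportions
    )
    planted_subtype_log2fc: Mapping[str, float] = field(default_factory=dict)
    planted_log_hr: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.03  # events per year
    censor_rate: float = 0.05  # censorings per year
    max_followup: float = 20.0  # years
    # cell-line panel
    n_lines: int = 46
    n_metabolites: int = 100
    block_structure: Mapping[str, float] = field(default_factory=_default_block_structure)
    # regulation table
    p_down: float = 0.535
    n_regulated: int = 17329
    # imaging
    image_size_px: int = 256
    pixel_size_nm: float = 100.0
    membrane_fraction: float = 0.5
    cells_per_image: int = 5
    image_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"subtype proportions must sum to 1, got {total:.6g}"
            )
        if any(p < 0 for p in self.subtype_proportions.values()):
            raise ConfigurationError("subtype proportions must be non-negative")
        for name in ("n_samples", "n_genes", "n_lines", "n_metabolites",
                     "n_regulated", "image_size_px", "cells_per_image"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.p_down <= 1.0:
            raise ConfigurationError("p_down must lie in [0, 1]")
        if not 0.0 <= self.membrane_fraction <= 1.0:
            raise ConfigurationError("membrane_fraction must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be > 0")
        if any(abs(r) > 1 for r in self.block_structure.values()):
            raise ConfigurationError("block correlations must lie in [-1, 1]")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("subtype_proportions", "planted_subtype_log2fc",
                  "planted_log_hr", "block_structure"):
            d[k] = dict(d[k])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))
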