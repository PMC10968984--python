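"""Analysis configuration shared by the pipeline driver and the CLI."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the phasor drug-response pipeline.

    Lifetimes are in seconds; ``tau_free``/``tau_bound`` are the NAD(P)H
    component endpoints, ``tau_ref`` the calibration standard (fluorescein).
    """

    harmonic: int = 1
    intensity_threshold: float = 100.0   # photons/pixel
    smooth_passes: int = 1
    tau_free: float = 0.4e-9
    tau_bound: float = 3.4e-9
    tau_ref: float = 4e-9
    n_bins: int = 100
    alpha: float = 0.05
    dr_threshold: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "AnalysisConfig":
        """Copy with non-None overrides applied (explicit flags win)."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def log_parameters(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))
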