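"""Run configuration (YAML, schema-validated) and run logging.

Every CLI stage resolves its settings from defaults < config file < command
line flags, requires an explicit seed for stochastic stages, and writes a
RunLog JSON next to its outputs so every file is traceable to one run.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .io import file_digest

__all__ = ["RunConfig", "RunLog", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    model: str = "ginkgo"
    diploids_per_deme: int = 10
    n_loci: int = 100
    locus_length_bp: int = 100_000
    layout: str = "loci"
    deme_sizes: dict[str, float] = {}
    missing_rate: float = 0.0


class FitConfig(_Strict):
    template: str = "ginkgo-admixture"
    n_sims: int = 20_000
    n_restarts: int = 3
    n_boot: int = 100


class ScanConfig(_Strict):
    window_bp: int = 100_000
    min_snps: int = 10
    z_fst_min: float = 2.326
    z_he_max: float = -2.326
    grid_points: int = 50


class RunConfig(_Strict):
    """Top-level configuration; unknown keys are rejected."""

    seed: int | None = None
    threads: int = 1
    simulate: SimulateConfig = SimulateConfig()
    fit: FitConfig = FitConfig()
    scan: ScanConfig = ScanConfig()


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


class RunLog:
    """Timestamped record of one pipeline stage."""

    def __init__(self, stage: str, seed: int | None, params: dict | None = None):
        from . import __version__

        self.record = {
            "stage": stage,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "version": __version__,
            "python": platform.python_version(),
            "seed": seed,
            "params": params or {},
            "inputs": {},
            "outputs": [],
        }

    def add_input(self, path: str | Path) -> None:
        self.record["inputs"][str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.record["outputs"].append(str(path))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.record, indent=2) + "\n")
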