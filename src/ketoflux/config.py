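"""Run configuration: schema-validated loading with defaults and manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["RunConfig", "SolverConfig", "load_config", "save_config", "write_manifest"]


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    fixture: str | None = None  # path; None -> shipped default fixture
    design: str | None = None  # path to a study-design YAML/JSON (optional)
    doses: list[float] = [192.0, 573.0]  # mg/kg
    knockout_sets: list[int] | None = None  # None -> all 15
    variants: list[int] | None = None  # explicit variant list alternative
    output_dir: str = "out"
    seed: int = 0
    t_end_h: float = 6.0
    dt_h: float = 0.01
    solver: SolverConfig = SolverConfig()
    figures: bool = True

    @field_validator("doses")
    @classmethod
    def _doses_non_negative(cls, v):
        if any(d < 0 for d in v):
            raise ValueError("doses must be non-negative")
        return v

    def resolve_paths(self, base: Path) -> None:
        for attr in ("fixture", "design"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                candidate = base / val
                if candidate.exists():
                    setattr(self, attr, str(candidate))
                else:
                    raise FileNotFoundError(f"{attr} file not found: {val}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; defaults filled in."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    cfg = RunConfig.model_validate(data or {})
    cfg.resolve_paths(path.parent)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def write_manifest(output_dir: str | Path, cfg: RunConfig | None, seed: int, extra: dict | None = None) -> Path:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    import numpy
    import scipy

    from . import __version__

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    payload = cfg.model_dump() if cfg is not None else {}
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "ketoflux": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        manifest.update(extra)
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
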