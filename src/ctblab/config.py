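"""Config (YAML/JSON) loading and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .design import DesignConfig
from .simulate import StudyConfig

__all__ = ["load_study_config", "load_design_config", "save_config", "write_manifest"]


def _read_mapping(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return data


def load_study_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return StudyConfig()
    return StudyConfig.from_dict(_read_mapping(path))


def load_design_config(path: str | Path | None) -> DesignConfig:
    if path is None:
        return DesignConfig()
    data = _read_mapping(path)
    if "design" in data:  # allow passing a full study config
        data = data["design"]
    return DesignConfig.from_dict(data)


def save_config(config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, stage: str, config_dict: dict,
                   seeds: dict, outputs: list[str]) -> Path:
    """Record everything needed to reproduce a pipeline stage."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "python": platform.python_version(),
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "seeds": seeds,
        "outputs": outputs,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
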