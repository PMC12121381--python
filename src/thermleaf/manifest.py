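"""Run manifests: enough metadata next to every output to regenerate it."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .config import AnalysisConfig, config_to_dict

__all__ = ["RunManifest", "write_manifest"]


def config_hash(config: AnalysisConfig) -> str:
    """SHA-256 of the canonical YAML form of a config."""
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_sha256: str
    seeds: list[int] = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )


def write_manifest(
    out_path: str | Path,
    command: str,
    config: AnalysisConfig,
    seeds: list[int] | None = None,
) -> Path:
    """Write ``<out>.manifest.json`` beside an output file; returns its path."""
    manifest = RunManifest(
        command=command,
        config_sha256=config_hash(config),
        seeds=list(seeds or []),
    )
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path
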