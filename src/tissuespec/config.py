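"""Run configuration: YAML loading, config hashing, provenance logging."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from ._version import __version__
from .classify import ClassificationConfig

log = logging.getLogger("tissuespec")


def load_classification_config(
    path: str | Path | None = None, **overrides
) -> ClassificationConfig:
    """Build a ClassificationConfig from an optional YAML file plus overrides.

    YAML keys mirror the dataclass fields; explicit keyword overrides (CLI
    flags) win over file values.
    """
    fields: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if "classification" in loaded:
            loaded = loaded["classification"]
        fields.update(loaded)
    fields.update({k: v for k, v in overrides.items() if v is not None})
    return ClassificationConfig(**fields)


def config_hash(config: ClassificationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def log_provenance(config: ClassificationConfig | None, inputs: dict[str, Path]) -> None:
    log.info("tissuespec v%s", __version__)
    if config is not None:
        log.info("config hash %s: %s", config_hash(config), asdict(config))
    for name, path in inputs.items():
        if path is not None and Path(path).exists():
            log.info("input %s: %s (sha1 %s)", name, path, file_checksum(path))
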