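"""Run manifests: every CLI subcommand records what it ran with."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import __version__


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str, subcommand: str, params: dict,
                   inputs: list[str] | None = None,
                   extra: dict | None = None) -> Path:
    params = {k: v for k, v in sorted(params.items())}
    manifest = {
        "subcommand": subcommand,
        "params": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": params.get("seed"),
        "inputs": {p: _digest(p) for p in (inputs or [])},
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if extra:
        manifest.update(extra)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
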