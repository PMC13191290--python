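"""Stage run manifests: input/output checksums keyed by config hash."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def checksum_map(paths: list[Path], base: Path) -> dict[str, str]:
    return {str(p.relative_to(base)): sha256_file(p) for p in sorted(paths)}


def record_stage(
    workdir: str | Path,
    stage: str,
    inputs: list[Path],
    outputs: list[Path],
    config_hash: str,
) -> Path:
    """Write workdir/manifest/<stage>.json and return its path.

    The timestamp is informational; determinism comparisons use the
    input/output checksum maps only.
    """
    workdir = Path(workdir)
    mdir = workdir / "manifest"
    mdir.mkdir(parents=True, exist_ok=True)
    entry = {
        "stage": stage,
        "config_hash": config_hash,
        "inputs": checksum_map([Path(p) for p in inputs], workdir),
        "outputs": checksum_map([Path(p) for p in outputs], workdir),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = mdir / f"{stage}.json"
    path.write_text(json.dumps(entry, indent=2, sort_keys=True) + "\n")
    return path


def load_stage(workdir: str | Path, stage: str) -> dict:
    path = Path(workdir) / "manifest" / f"{stage}.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest for stage '{stage}' at {path}")
    return json.loads(path.read_text())
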