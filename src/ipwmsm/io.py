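"""Artefact IO: atomic table writes, manifests, run logging."""
from __future__ import annotations

import datetime as _dt
import json
import logging
import os
import tempfile
from pathlib import Path

import pandas as pd

from .errors import ArtefactError

log = logging.getLogger("ipwmsm")


def setup_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level)


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_table(df: pd.DataFrame, path) -> str:
    """Write a DataFrame as CSV or Parquet by extension, atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        if path.suffix == ".parquet":
            df.to_parquet(tmp, index=False)
        else:
            df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return str(path)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ArtefactError(f"missing artefact: {path}")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_manifest(outdir, *, config_hash: str, seed: int | None, extra: dict | None = None) -> str:
    """Record provenance for a run: config hash, seed, software version, schema."""
    from . import __version__

    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "version": __version__,
        "schema_version": 1,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    manifest.update(extra or {})
    path = Path(outdir) / "manifest.json"
    atomic_write_text(path, json.dumps(manifest, indent=2))
    return str(path)
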