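"""CSV round-tripping for datasets, link files and report tables.

All files are UTF-8 CSV with a header row and ISO dates.  Every file
written by the pipeline starts with ``#`` comment lines recording the
tool version, master seed and a hash of the configuration, so a result
file is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .synth import SynthConfig

DATE_COLUMNS = ("birth_date", "death_date", "separation_date", "event_date")


def config_hash(config: SynthConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed, cfg_hash) -> str:
    lines = [f"# slklink {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config: {cfg_hash}")
    return "\n".join(lines) + "\n"


def write_csv(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if col in DATE_COLUMNS:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        out.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"record_id": str, "person_key": str})
    for col in df.columns:
        if col in DATE_COLUMNS:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    return df


def write_manifest(path, config: SynthConfig, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "slklink",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
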