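"""Result serialisation: CSV curves/tables with a provenance header,
JSON scalars, YAML run configs.

All writers put provenance into ``#``-prefixed comment lines so the data
block stays machine-readable; readers round-trip at full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "config_digest",
    "write_curve_csv",
    "read_curve_csv",
    "write_json",
    "load_config",
]

PathLike = Union[str, Path]


def config_digest(config: dict) -> str:
    """Short stable digest of a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_lines(config: Optional[dict], seed: Optional[int]) -> list[str]:
    lines = [f"# mevstem {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_digest: {config_digest(config)}")
        lines.append(f"# config: {json.dumps(config, sort_keys=True, default=str)}")
    return lines


def write_curve_csv(
    path: PathLike,
    df: pd.DataFrame,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a DataFrame as CSV with a provenance comment header, floats at
    full (repr) precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_curve_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path: PathLike, payload: dict, config: Optional[dict] = None,
               seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = dict(payload)
    out["_provenance"] = {
        "package": f"mevstem {__version__}",
        "seed": seed,
        "config_digest": config_digest(config) if config else None,
    }
    path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def load_config(path: PathLike) -> dict:
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
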