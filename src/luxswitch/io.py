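"""Configuration files, run manifests and tabular output.

Parameter files are flat ``key: value`` mappings (YAML) using the canonical
parameter names; unspecified keys keep their default values.  Every output
directory receives a run manifest echoing the full parameterization, the
seeds and the package version, sufficient to reproduce the run.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .parameters import ParameterSet, build_parameter_set


def load_config(path) -> dict:
    """Read a flat ``key: value`` parameter file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    return data


def params_from_config(path, construct: str | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a config file plus defaults."""
    cfg = load_config(path)
    if construct is not None:
        cfg["construct"] = construct
    return build_parameter_set(cfg)


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def write_table(records, path, columns: list[str] | None = None) -> None:
    """Write records as a UTF-8 CSV with header ('.' decimal separator).

    ``records`` is a DataFrame or a list of mappings.  When ``columns`` is
    given, the records must contain exactly those columns (schema check).
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(
        list(records), columns=columns)
    if columns is not None:
        missing = set(columns) - set(df.columns)
        extra = set(df.columns) - set(columns)
        if missing or extra:
            raise ValueError(
                f"schema mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
        df = df[columns]
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_manifest(out_dir, params: ParameterSet, protocol: Mapping,
                   seeds) -> Path:
    """Write the run manifest (parameters, protocol, seeds, version)."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "luxswitch",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": params.to_dict(),
        "protocol": dict(protocol),
        "seeds": list(seeds) if hasattr(seeds, "__iter__") else [seeds],
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
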