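"""CSV interchange with schema validation, YAML config, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SITE_SCHEMA = {
    "site_id": str, "habitat": str, "latitude_proxy": float,
    "substrate_cover": float, "exposure": float, "min_salinity": float,
}
QUADRAT_SCHEMA = {
    "site_id": str, "quadrat_index": int, "count": int,
    "substrate_cover": float, "is_first": bool,
}
PROJECTION_SCHEMA = {
    "site_id": str, "habitat": str, "substrate_cover": float,
    "exposure": float, "min_salinity": float, "depth": float, "area_m2": float,
}

_HABITAT_ALIASES = {
    "natural": "natural", "natural_rocky": "natural_rocky", "rocky": "natural_rocky",
    "marina": "marina", "pier": "pier",
}


def _fail(path, row, message):
    raise ValueError(f"{path}, row {row}: {message}")


def _validate(df: pd.DataFrame, schema: dict, path) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col, typ in schema.items():
        if typ is int:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals != vals.round())
            if bad.any():
                _fail(path, int(bad.idxmax()) + 2, f"non-integer {col!r}")
            df[col] = vals.astype(int)
        elif typ is float:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                _fail(path, int(vals.isna().idxmax()) + 2, f"non-numeric {col!r}")
            df[col] = vals.astype(float)
        elif typ is bool:
            df[col] = df[col].astype(bool)
        else:
            df[col] = df[col].astype(str)
    return df


def read_survey(sites_path, quadrats_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the site and quadrat tables.

    Counts must be non-negative integers, percent covers within [0, 100],
    exactly one targeted first quadrat per site; habitat labels are
    normalized.  Errors name the offending file and row.
    """
    sites = _validate(pd.read_csv(sites_path), SITE_SCHEMA, sites_path)
    quadrats = _validate(pd.read_csv(quadrats_path), QUADRAT_SCHEMA, quadrats_path)

    bad = ~sites["habitat"].str.lower().isin(_HABITAT_ALIASES)
    if bad.any():
        _fail(sites_path, int(bad.idxmax()) + 2,
              f"unknown habitat {sites['habitat'][bad.idxmax()]!r}")
    sites["habitat"] = sites["habitat"].str.lower().map(_HABITAT_ALIASES)

    for df, path in ((sites, sites_path), (quadrats, quadrats_path)):
        out = (df["substrate_cover"] < 0) | (df["substrate_cover"] > 100)
        if out.any():
            _fail(path, int(out.idxmax()) + 2, "substrate_cover outside [0, 100]")
    neg = quadrats["count"] < 0
    if neg.any():
        _fail(quadrats_path, int(neg.idxmax()) + 2, "negative count")
    firsts = quadrats.groupby("site_id")["is_first"].sum()
    if (firsts != 1).any():
        bad_site = firsts.index[firsts != 1][0]
        raise ValueError(
            f"{quadrats_path}: site {bad_site!r} must have exactly one first quadrat"
        )
    unknown = set(quadrats["site_id"]) - set(sites["site_id"])
    if unknown:
        raise ValueError(f"{quadrats_path}: quadrats reference unknown sites {sorted(unknown)[:3]}")
    return sites, quadrats


def read_projection(path) -> pd.DataFrame:
    df = _validate(pd.read_csv(path), PROJECTION_SCHEMA, path)
    df["habitat"] = df["habitat"].str.lower().map(_HABITAT_ALIASES)
    if df["habitat"].isna().any():
        _fail(path, int(df["habitat"].isna().idxmax()) + 2, "unknown habitat")
    if (df["area_m2"] <= 0).any():
        _fail(path, int((df["area_m2"] <= 0).idxmax()) + 2, "area_m2 must be > 0")
    return df


def write_tables(out_dir, **tables) -> dict[str, str]:
    """Write named DataFrames as CSV under out_dir; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int,
                   inputs: dict[str, str] | None = None) -> str:
    """Emit the run manifest: config hash, seed, version, input digests."""
    from . import __version__

    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest()[:16],
        "seed": seed,
        "package_version": __version__,
        "input_digests": {k: _digest(v) for k, v in (inputs or {}).items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return str(path)
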