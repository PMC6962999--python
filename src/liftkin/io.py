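"""Reading and writing the campaign tables.

Tables travel as delimited text (CSV, with flashlet arrays packed into
semicolon-joined cells) plus a columnar binary alternative (Parquet with list
columns).  A manifest JSON records the seed and config of each bundle.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

ARRAY_COLUMNS = ("yields", "background")


def pack_array(a: np.ndarray) -> str:
    return ";".join(format(x, ".9g") for x in np.asarray(a, float))


def unpack_array(s: str) -> np.ndarray:
    return np.fromstring(s, sep=";") if s else np.empty(0)


def write_transients_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in ARRAY_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(pack_array)
    out.to_csv(path, index=False)


def read_transients_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    for col in ARRAY_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(unpack_array)
    return df


def write_transients_parquet(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in ARRAY_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda a: np.asarray(a, float).tolist())
    out.to_parquet(path, index=False)


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (dt.date, dt.datetime, pd.Timestamp)):
        return o.isoformat()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (tuple, set)):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_bundle(bundle, out_dir: Path, parquet: bool = True) -> dict[str, str]:
    """Write all bundle tables; returns {relative path: sha256}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_transients_csv(bundle.transients, out_dir / "transients.csv")
    bundle.spectra.to_csv(out_dir / "spectra.csv", index=False)
    bundle.references.to_csv(out_dir / "references.csv", index=False)
    bundle.env.to_csv(out_dir / "env.csv", index=False)
    bundle.plots.to_csv(out_dir / "plots.csv", index=False)
    pd.DataFrame({"time_ms": bundle.schedule.times}).to_csv(
        out_dir / "schedule.csv", index=False)
    if parquet:
        write_transients_parquet(bundle.transients, out_dir / "transients.parquet")
        bundle.spectra.to_parquet(out_dir / "spectra.parquet", index=False)
        bundle.env.to_parquet(out_dir / "env.parquet", index=False)
    manifest = {
        "seed": bundle.config.seed,
        "config": dataclasses.asdict(bundle.config),
        "n_transients": len(bundle.transients),
        "n_spectra": len(bundle.spectra),
        "n_references": len(bundle.references),
    }
    (out_dir / "bundle_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default, sort_keys=True))
    return digest_tree(out_dir, suffix=".csv")


def read_bundle(in_dir: Path):
    """Load a bundle directory written by :func:`write_bundle`.

    Missing optional tables (env, references) load as None; the caller raises
    at the stage that actually needs them.
    """
    from .errors import InputError
    from .schedule import FlashSchedule
    from .simulate import CampaignBundle

    in_dir = Path(in_dir)

    def maybe(name: str, **kw):
        p = in_dir / name
        return pd.read_csv(p, **kw) if p.exists() else None

    transients = (in_dir / "transients.csv")
    if not transients.exists():
        raise InputError(f"no transients.csv under {in_dir}")
    sched_df = maybe("schedule.csv")
    if sched_df is None:
        raise InputError(f"no schedule.csv under {in_dir}")
    return CampaignBundle(
        transients=read_transients_csv(transients),
        spectra=maybe("spectra.csv", parse_dates=["timestamp"]),
        references=maybe("references.csv", parse_dates=["timestamp"]),
        env=maybe("env.csv", parse_dates=["timestamp"]),
        plots=maybe("plots.csv", parse_dates=["sowing_date"]),
        schedule=FlashSchedule(sched_df["time_ms"].to_numpy()),
        config=None,
    )


def digest_tree(root: Path, suffix: str = "") -> dict[str, str]:
    """sha256 of every file under root (optionally filtered by suffix)."""
    root = Path(root)
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file() and (not suffix or p.suffix == suffix):
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
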