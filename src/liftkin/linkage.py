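"""Joining fluorescence, spectral, and environmental records into observations.

Environmental records (PPFD, air temperature, relative humidity) are linked
to measurements taken in the same minute; multiple stations reporting the
same minute are averaged.  Vapor pressure deficit is derived from temperature
and humidity by the Magnus formula.  The assembled observation table carries
one row per kept fluorescence measurement with its paired spectral indices
(absent allowed) and calendar covariates (days after sowing, week, month,
hour of day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

ENV_VALUE_COLUMNS = ["ppfd", "temperature", "rh"]


def compute_vpd(temperature, rh):
    """Vapor pressure deficit (kPa) via the Magnus saturation formula.

    es = 0.6108 * exp(17.27 T / (T + 237.3)); vpd = es * (1 - rh/100).
    """
    t = np.asarray(temperature, dtype=float)
    h = np.asarray(rh, dtype=float)
    if np.any((h < 0) | (h > 100)):
        raise InputError("relative humidity must be in [0, 100] %")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    vpd = es * (1.0 - h / 100.0)
    if np.isscalar(temperature) and np.isscalar(rh):
        return float(vpd)
    return vpd


def link_environment(measurements: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """Exact same-minute join of environmental values onto measurements.

    Timestamps are truncated (not rounded) to the minute; stations reporting
    the same minute are averaged.  Measurements without an environmental
    record get ``env_linked = False`` and NaN values (they are excluded from
    modeling, not from the table).
    """
    env_min = (
        env.assign(minute=env["timestamp"].dt.floor("min"))
        .groupby("minute")[ENV_VALUE_COLUMNS]
        .mean()
    )
    out = measurements.copy()
    minute = out["timestamp"].dt.floor("min")
    joined = env_min.reindex(minute.to_numpy())
    for col in ENV_VALUE_COLUMNS:
        out[col] = joined[col].to_numpy()
    out["env_linked"] = np.isfinite(out["ppfd"].to_numpy())
    return out


def assemble_observations(
    fluor: pd.DataFrame,
    indices: pd.DataFrame,
    pairs: pd.DataFrame,
    env: pd.DataFrame,
    plots: pd.DataFrame,
) -> pd.DataFrame:
    """Build the observation table feeding the models.

    ``fluor`` is the QC-kept fluorescence parameter table, ``indices`` the
    QC-kept spectral-index table, ``pairs`` the spectrum-to-transient links.
    The join is left on the fluorescence side: measurements without a paired
    (surviving) spectrum keep NaN index values.
    """
    if "sowing_date" not in plots.columns or plots["sowing_date"].isna().any():
        raise ConfigurationError("plot metadata must provide a sowing_date per plot")

    idx_cols = [c for c in indices.columns
                if c not in ("timestamp", "plot_id", "species", "genotype",
                             "line_index", "position_in_line", "seq", "ppfd",
                             "corrected", "undefined")]
    linked = pairs.dropna(subset=["measurement_id"]).merge(
        indices[idx_cols], on="spectrum_id", how="inner")

    obs = fluor.merge(linked, on="measurement_id", how="left")
    obs = link_environment(obs, env)
    with np.errstate(invalid="ignore"):
        obs["vpd"] = np.where(
            obs["env_linked"],
            compute_vpd(obs["temperature"].fillna(0.0), obs["rh"].fillna(50.0)),
            np.nan,
        )

    meta = plots.set_index("plot_id")
    sowing = pd.to_datetime(obs["plot_id"].map(meta["sowing_date"]))
    ts = obs["timestamp"]
    obs["das"] = (ts.dt.normalize() - sowing.dt.normalize()).dt.days
    obs["date"] = ts.dt.date
    obs["week"] = ts.dt.isocalendar().week.astype(int)
    obs["month"] = ts.dt.month
    obs["hour_of_day"] = ts.dt.hour
    if (obs["das"] < 0).any():
        raise ConfigurationError("measurement earlier than sowing date")
    return obs
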