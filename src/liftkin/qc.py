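"""Record-discard rules for fluorescence parameters and spectral indices.

Fluorescence records are dropped when the signal-to-noise ratio falls below a
species-specific threshold (50 for maize, rapeseed and soybean; 100 for
barley and wheat), when F_v/F_m or F_r1/F_v are negative, or when F_r1/F_v
exceeds 0.35 / F_r2/F_v exceeds 0.8.  All inequalities are strict: a value
exactly at a threshold survives.

Spectral-index records are dropped when the PPFD of their minute is below
30 umol m-2 s-1, and then per species and per index by Tukey fences
(Q1 - 1.5 IQR, Q3 + 1.5 IQR) to remove soil hits and similar outliers.

Additionally, the third measurement of each scan line is excluded because the
positioning system most likely measured the same spot twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEFAULT_SNR_MIN = {
    "maize": 50.0, "rapeseed": 50.0, "soybean": 50.0,
    "barley": 100.0, "wheat": 100.0,
}

#: index columns screened by the Tukey-fence rule when present
FENCE_INDEX_COLUMNS = [
    "ndvi", "ndvi_ii", "gndvi", "mtci", "pri",
    "pndvi", "pndvi_ii", "pgndvi", "pmtci", "ppri",
]


@dataclass(frozen=True)
class QCRules:
    snr_min_by_species: dict = field(default_factory=lambda: dict(DEFAULT_SNR_MIN))
    fr1_max: float = 0.35
    fr2_max: float = 0.8
    ppfd_min_spectral: float = 30.0
    iqr_factor: float = 1.5
    drop_third_in_line: bool = True

    def __post_init__(self):
        if self.fr1_max <= 0 or self.fr2_max <= 0 or self.ppfd_min_spectral <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.iqr_factor <= 0:
            raise ConfigurationError("iqr_factor must be > 0")


def _row_ids(df: pd.DataFrame, id_column: str | None) -> pd.Series:
    if id_column and id_column in df.columns:
        return df[id_column]
    return pd.Series(df.index, index=df.index)


def qc_fluorescence(
    params: pd.DataFrame,
    rules: QCRules = QCRules(),
    id_column: str = "measurement_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the fluorescence discard rules; returns (kept, rejection log).

    The log has one row per (record, fired rule).  Rules are conjunctive, so
    the kept set does not depend on their order.
    """
    unknown = set(params["species"]) - set(rules.snr_min_by_species)
    if unknown:
        raise ConfigurationError(f"no SNR threshold for species: {sorted(unknown)}")
    ids = _row_ids(params, id_column)
    snr_thr = params["species"].map(rules.snr_min_by_species)

    checks = [
        ("snr", params["snr"] < snr_thr, params["snr"], snr_thr),
        ("fvfm_negative", params["fvfm"] < 0, params["fvfm"], 0.0),
        ("fr1_negative", params["fr1_ratio"] < 0, params["fr1_ratio"], 0.0),
        ("fr1_high", params["fr1_ratio"] > rules.fr1_max, params["fr1_ratio"], rules.fr1_max),
        ("fr2_high", params["fr2_ratio"] > rules.fr2_max, params["fr2_ratio"], rules.fr2_max),
    ]
    log_rows = []
    dropped = pd.Series(False, index=params.index)
    for rule, mask, value, threshold in checks:
        mask = mask.fillna(False)
        dropped |= mask
        thr = threshold if np.isscalar(threshold) else threshold[mask]
        log_rows.append(pd.DataFrame({
            "row_id": ids[mask], "rule": rule, "value": value[mask], "threshold": thr,
        }))
    log = pd.concat(log_rows, ignore_index=True) if log_rows else pd.DataFrame(
        columns=["row_id", "rule", "value", "threshold"])
    return params[~dropped].copy(), log


def qc_spectral(
    indices: pd.DataFrame,
    rules: QCRules = QCRules(),
    id_column: str = "spectrum_id",
    index_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the spectral discard rules; returns (kept, rejection log).

    Rows need linked ``ppfd`` and ``species``.  Low-light rows go first; Tukey
    fences are then computed per species on the surviving rows, one fence per
    index column; a row is dropped when any of its index values falls outside
    its fence.  Species with fewer than 4 usable values for an index skip the
    fence for that index (logged).
    """
    cols = [c for c in (index_columns or FENCE_INDEX_COLUMNS) if c in indices.columns]
    ids = _row_ids(indices, id_column)
    log_rows: list[dict] = []

    low = indices["ppfd"] < rules.ppfd_min_spectral
    low = low.fillna(True)  # unlinked PPFD cannot be certified bright
    for i in indices.index[low]:
        log_rows.append({"row_id": ids[i], "rule": "ppfd_low",
                         "value": indices.at[i, "ppfd"],
                         "threshold": rules.ppfd_min_spectral})
    bright = indices[~low]

    dropped = pd.Series(False, index=bright.index)
    for species, group in bright.groupby("species"):
        for col in cols:
            vals = group[col].dropna()
            if len(vals) < 4:
                log_rows.append({"row_id": f"species:{species}",
                                 "rule": f"fence_skipped:{col}",
                                 "value": float(len(vals)), "threshold": 4.0})
                continue
            q1, q3 = np.percentile(vals, [25, 75])
            lo = q1 - rules.iqr_factor * (q3 - q1)
            hi = q3 + rules.iqr_factor * (q3 - q1)
            bad = group.index[(group[col] < lo) | (group[col] > hi)]
            for i in bad:
                if not dropped[i]:
                    log_rows.append({"row_id": ids[i], "rule": f"fence:{col}",
                                     "value": bright.at[i, col],
                                     "threshold": lo if bright.at[i, col] < lo else hi})
                dropped[i] = True
    log = pd.DataFrame(log_rows, columns=["row_id", "rule", "value", "threshold"])
    return bright[~dropped].copy(), log


def drop_repeated_position(measurements: pd.DataFrame) -> pd.DataFrame:
    """Remove the third measurement of each scan line (1-based position)."""
    if "position_in_line" not in measurements.columns:
        return measurements.copy()
    return measurements[measurements["position_in_line"] != 3].copy()
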