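"""Spectral data processing: binning, dark current, reference correction, indices.

Raw spectrometer digital numbers (DN) on a ~0.46-nm native grid are averaged
to one value per even wavelength between 400 and 800 nm.  The prior night's
dark-current spectrum is subtracted.  Absolute reflectance is recovered by
dividing by a PPFD-matched gray-panel reference spectrum (the panel reflects
50 % of incoming irradiance), looked up from a table of panel scans binned in
10 umol m-2 s-1 PPFD steps over 100-1350.  Five two/three-band indices are
computed from corrected reflectance, and "pseudo" variants of the same
formulas directly from raw DN (robust when absolute correction is fragile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyLUTError, MissingBandError, MissingDarkError
from .simulate import WL_GRID

DN_COLUMNS = [f"dn_{int(w)}" for w in WL_GRID]

#: PPFD range covered by the reference lookup table
LUT_MIN_PPFD = 100.0
LUT_MAX_PPFD = 1350.0
LUT_STEP = 10.0

#: reflectance of the gray reference panel
PANEL_REFLECTANCE = 0.5

#: index name -> (band formula) on corrected reflectance R or raw DN
INDEX_BANDS = {
    "ndvi": (750, 706),
    "ndvi_ii": (740, 680),
    "gndvi": (740, 540),
    "pri": (530, 570),
}


@dataclass
class RawSpectrum:
    """One binned spectrum on the fixed even 400-800 nm grid."""

    wavelengths: np.ndarray
    dn: np.ndarray
    timestamp: Optional[pd.Timestamp] = None
    target: str = "canopy"  # canopy | gray_reference | dark
    plot_id: Optional[str] = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.dn = np.asarray(self.dn, dtype=float)
        if not np.array_equal(self.wavelengths, WL_GRID):
            raise MissingBandError("spectrum is not on the even 400-800 nm grid")
        if len(self.dn) != len(WL_GRID) or not np.all(np.isfinite(self.dn)):
            raise MissingBandError("dn must be finite with one value per bin")


def band_index(wavelength: int) -> int:
    return int((wavelength - 400) // 2)


def bin_wavelengths(native_wl: np.ndarray, native_dn: np.ndarray, **meta
                    ) -> RawSpectrum:
    """Average native-resolution samples into 2-nm bins.

    Each even-wavelength bin c collects native samples with wavelength in the
    half-open interval [c-1, c+1).
    """
    wl = np.asarray(native_wl, dtype=float)
    dn = np.asarray(native_dn, dtype=float)
    centers = 2.0 * np.floor((wl + 1.0) / 2.0)
    out = np.full(len(WL_GRID), np.nan)
    for i, c in enumerate(WL_GRID):
        sel = centers == c
        if not np.any(sel):
            raise MissingBandError(f"no native samples for the {int(c)} nm bin")
        out[i] = dn[sel].mean()
    return RawSpectrum(WL_GRID, out, **meta)


def subtract_dark_current(dn: np.ndarray, dark_dn: np.ndarray) -> np.ndarray:
    """Subtract a dark-current spectrum, clipping at zero."""
    return np.clip(np.asarray(dn, float) - np.asarray(dark_dn, float), 0.0, None)


def prior_night_dark(references: pd.DataFrame, day: pd.Timestamp) -> np.ndarray:
    """Latest dark scan before 04:00 of ``day`` (the preceding night)."""
    cutoff = pd.Timestamp(day).normalize() + pd.Timedelta(hours=4)
    darks = references[references["target"] == "dark"]
    darks = darks[darks["timestamp"] < cutoff]
    if darks.empty:
        raise MissingDarkError(f"no dark scan before {cutoff}")
    row = darks.loc[darks["timestamp"].idxmax()]
    return row[DN_COLUMNS].to_numpy(dtype=float)


@dataclass
class ReferenceLUT:
    """Mean gray-panel DN spectrum per 10-umol PPFD bin (centers 105...1345)."""

    bin_centers: np.ndarray
    spectra: np.ndarray          # (n_bins, 201)
    filled: np.ndarray           # True where the bin had its own scans

    def lookup(self, ppfd: float) -> np.ndarray:
        """Spectrum of the bin whose center is closest to ``ppfd``.

        Exact ties between two centers resolve toward the lower bin.
        """
        idx = int(np.argmin(np.abs(self.bin_centers - ppfd)))
        return self.spectra[idx]


def build_reference_lut(gray: pd.DataFrame, env: Optional[pd.DataFrame] = None
                        ) -> ReferenceLUT:
    """Build the PPFD-keyed reference lookup table from gray-panel scans.

    Scans need a ``ppfd`` column (or ``env`` to join it by minute); scans with
    PPFD outside [100, 1350] are discarded; empty interior bins are filled
    from the nearest nonempty bin.
    """
    gray = gray[gray["target"] == "gray_reference"].copy() if "target" in gray else gray.copy()
    if "ppfd" not in gray.columns:
        if env is None:
            raise EmptyLUTError("gray scans lack PPFD and no env table given")
        env_min = env.groupby(env["timestamp"].dt.floor("min"))["ppfd"].mean()
        gray["ppfd"] = gray["timestamp"].dt.floor("min").map(env_min)
    usable = gray[(gray["ppfd"] >= LUT_MIN_PPFD) & (gray["ppfd"] <= LUT_MAX_PPFD)]
    if usable.empty:
        raise EmptyLUTError("no gray-reference scans inside the 100-1350 PPFD range")

    edges = np.arange(LUT_MIN_PPFD, LUT_MAX_PPFD + LUT_STEP, LUT_STEP)
    centers = edges[:-1] + LUT_STEP / 2.0
    n_bins = len(centers)
    spectra = np.zeros((n_bins, len(WL_GRID)))
    filled = np.zeros(n_bins, dtype=bool)
    bins = np.clip(((usable["ppfd"] - LUT_MIN_PPFD) // LUT_STEP).astype(int), 0, n_bins - 1)
    dn = usable[DN_COLUMNS].to_numpy(dtype=float)
    for b in np.unique(bins):
        spectra[b] = dn[bins == b].mean(axis=0)
        filled[b] = True
    nonempty = np.flatnonzero(filled)
    for b in np.flatnonzero(~filled):
        nearest = nonempty[np.argmin(np.abs(nonempty - b))]
        spectra[b] = spectra[nearest]
    return ReferenceLUT(centers, spectra, filled)


def normalize_reflectance(dn: np.ndarray, ppfd: float, lut: ReferenceLUT
                          ) -> Optional[np.ndarray]:
    """Convert dark-subtracted DN to reflectance via the 50 % panel.

    R(lambda) = dn / (dn_ref / 0.5).  Returns None (uncorrectable) when PPFD
    is below the LUT range; bands where the reference is non-positive are NaN.
    """
    if ppfd < LUT_MIN_PPFD:
        return None
    ref = lut.lookup(ppfd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ref > 0, np.asarray(dn, float) * PANEL_REFLECTANCE / ref, np.nan)
    return r


def _nd(a: float, b: float) -> float:
    denom = a + b
    if denom == 0:
        return np.nan
    return (a - b) / denom


def compute_indices(raw_dn: np.ndarray, corrected: Optional[np.ndarray] = None
                    ) -> dict:
    """Spectral indices from corrected reflectance and raw-DN pseudo variants.

    NDVI = (R750-R706)/(R750+R706); NDVI_II = (R740-R680)/(R740+R680);
    GNDVI = (R740-R540)/(R740+R540); MTCI = (R754-R710)/(R710+R680);
    PRI = (R530-R570)/(R530+R570).  Pseudo indices (p-prefixed) apply the same
    formulas to raw DN.  ``reflectance_sum`` is the raw-DN sum over 450-800 nm
    inclusive; ``r685`` is the raw DN at the fluorescence detection band
    (mean of the 684 and 686 nm bins).  Zero denominators give NaN and are
    listed under ``undefined``.
    """
    raw_dn = np.asarray(raw_dn, dtype=float)

    def bands(arr):
        return {w: arr[band_index(w)] for w in (530, 540, 570, 680, 706, 710, 740, 750, 754)}

    out: dict = {}
    undefined: list[str] = []

    def fill(prefix: str, arr: Optional[np.ndarray]):
        if arr is None:
            for name in list(INDEX_BANDS) + ["mtci"]:
                out[prefix + name] = np.nan
            return
        b = bands(arr)
        for name, (hi, lo) in INDEX_BANDS.items():
            v = _nd(b[hi], b[lo])
            out[prefix + name] = v
            if np.isnan(v) and not (np.isnan(b[hi]) or np.isnan(b[lo])):
                undefined.append(prefix + name)
        denom = b[710] + b[680]
        out[prefix + "mtci"] = (b[754] - b[710]) / denom if denom != 0 else np.nan
        if denom == 0:
            undefined.append(prefix + "mtci")

    fill("", corrected)
    fill("p", raw_dn)
    out["reflectance_sum"] = float(raw_dn[band_index(450): band_index(800) + 1].sum())
    out["r685"] = float(0.5 * (raw_dn[band_index(684)] + raw_dn[band_index(686)]))
    out["undefined"] = ";".join(undefined)
    return out


def pair_spectrum_to_transient(spectra: pd.DataFrame, transients: pd.DataFrame
                               ) -> pd.DataFrame:
    """Link each spectrum to the ChlF measurement taken immediately before it.

    Both tables need (plot_id, line_index, seq); within a scan line the
    spectrum pairs with the transient of the largest seq strictly below its
    own.  Spectra with no preceding measurement in their scan stay unpaired
    (measurement_id = NaN).
    """
    left = spectra[["spectrum_id", "plot_id", "line_index", "seq"]].sort_values("seq")
    right = transients[["measurement_id", "plot_id", "line_index", "seq"]].sort_values("seq")
    pairs = pd.merge_asof(
        left, right, on="seq", by=["plot_id", "line_index"],
        direction="backward", allow_exact_matches=False,
    )
    return pairs[["spectrum_id", "measurement_id"]]


def process_spectra(
    spectra: pd.DataFrame,
    references: pd.DataFrame,
    env: pd.DataFrame,
    lut: Optional[ReferenceLUT] = None,
) -> tuple[pd.DataFrame, ReferenceLUT]:
    """Dark-subtract, correct, and index every canopy spectrum.

    Returns the indices table (one row per spectrum, with a ``corrected``
    flag; corrected indices are NaN for uncorrectable records) and the LUT
    used (built from the dark-subtracted gray scans when not supplied).
    """
    env_min = env.groupby(env["timestamp"].dt.floor("min"))[["ppfd"]].mean()["ppfd"]

    darks_by_day: dict = {}

    def dark_for(ts: pd.Timestamp) -> np.ndarray:
        day = pd.Timestamp(ts).normalize()
        if day not in darks_by_day:
            darks_by_day[day] = prior_night_dark(references, day)
        return darks_by_day[day]

    if lut is None:
        gray = references[references["target"] == "gray_reference"].copy()
        dn = gray[DN_COLUMNS].to_numpy(dtype=float)
        for i, (_, row) in enumerate(gray.iterrows()):
            dn[i] = subtract_dark_current(dn[i], dark_for(row["timestamp"]))
        gray[DN_COLUMNS] = dn
        lut = build_reference_lut(gray)

    meta_cols = [c for c in ("spectrum_id", "timestamp", "plot_id", "species",
                             "genotype", "line_index", "position_in_line", "seq")
                 if c in spectra.columns]
    rows = []
    for _, row in spectra.iterrows():
        dn = subtract_dark_current(row[DN_COLUMNS].to_numpy(dtype=float),
                                   dark_for(row["timestamp"]))
        ppfd = float(env_min.get(pd.Timestamp(row["timestamp"]).floor("min"), np.nan))
        corrected = None
        if np.isfinite(ppfd):
            corrected = normalize_reflectance(dn, ppfd, lut)
        rec = {c: row[c] for c in meta_cols}
        rec["ppfd"] = ppfd
        rec["corrected"] = corrected is not None
        rec.update(compute_indices(dn, corrected))
        rows.append(rec)
    return pd.DataFrame(rows), lut
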