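"""Seeded synthetic semi-field campaign generator.

This module emulates the statistical structure of an automated canopy
chlorophyll-fluorescence campaign so that every downstream stage (transient
processing, spectral processing, QC, linkage, modeling) is testable without
any external download:

* minute-resolution environment (diurnal PPFD with cloud flecks, a diurnal
  temperature course with a seasonal trend, relative humidity);
* FRR flashlet transients whose relaxation is a three-exponential mixture with
  Arrhenius temperature scaling (phases ~0.2 / 0.7 / 2-3 ms: Q_A- to Q_B,
  Q_B- to Q_B2-, and plastoquinone exchange at the Q_B pocket) and
  Stern-Volmer NPQ quenching of F_m' under light;
* genotype-specific cold tolerance (scaling the activation energy downward)
  and chlorophyll level (scaling red absorption);
* canopy reflectance spectra (green bump, red trough, red edge, NIR plateau)
  with a PRI-band dip tracking the quenching state, dark current and shot
  noise, plus occasional flat soil-hit outliers;
* hourly gray-panel reference scans and nightly dark-current scans.

All randomness flows from a single integer seed; identical seeds produce
byte-identical serialized bundles.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, SimulationError
from .schedule import FlashSchedule, generate_flash_schedule
from .transients import DARK_PPFD_THRESHOLD, TransientTrace

R_GAS = 8.31446  # J mol-1 K-1

#: even 2-nm wavelength grid, 400-800 nm inclusive (201 bins)
WL_GRID = np.arange(400, 801, 2, dtype=float)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and optical parameters of the transient simulator.

    The three relaxation phases carry the reoxidation time constants reported
    for PSII (fast ~0.2 ms, mid ~0.7 ms, slow 2-3 ms).  The amplitude weights
    describe the *apparent* contribution of each phase to the observed
    canopy-level relaxation; the slow plastoquinone-exchange phase dominates
    because re-excitation by the relaxation flashlets is not modeled.
    """

    f0_dark: float = 1000.0      # basal yield, instrument digital units
    fm_dark: float = 5000.0      # maximal dark-adapted yield
    tau_fast: float = 0.2        # ms
    tau_mid: float = 0.7         # ms
    tau_slow: float = 3.0        # ms
    amp_fast: float = 0.08
    amp_mid: float = 0.17
    amp_slow: float = 0.75
    e_act: float = 30000.0       # J mol-1, Arrhenius activation energy
    t_ref: float = 20.0          # deg C reference for the tau values
    npq_max: float = 1.5         # maximal Stern-Volmer quenching
    k_npq: float = 350.0         # half-saturation PPFD for quenching
    sigma_abs: float = 0.04      # excitation probability per flashlet

    def __post_init__(self):
        taus = (self.tau_fast, self.tau_mid, self.tau_slow)
        amps = (self.amp_fast, self.amp_mid, self.amp_slow)
        if any(t <= 0 for t in taus):
            raise ConfigurationError("all time constants must be > 0")
        if any(a < 0 for a in amps) or abs(sum(amps) - 1.0) > 1e-9:
            raise ConfigurationError("amplitude weights must be >= 0 and sum to 1")
        if not self.fm_dark > self.f0_dark:
            raise ConfigurationError("fm_dark must exceed f0_dark")
        if self.e_act < 0:
            raise ConfigurationError("e_act must be >= 0")

    @property
    def taus(self) -> np.ndarray:
        return np.array([self.tau_fast, self.tau_mid, self.tau_slow])

    @property
    def amps(self) -> np.ndarray:
        return np.array([self.amp_fast, self.amp_mid, self.amp_slow])


DEFAULT_KINETICS = KineticParams()


@dataclass(frozen=True)
class GenotypeProfile:
    """Genotype-level modifiers of the kinetic and optical model."""

    name: str
    species: str = "soybean"
    cold_tolerance: float = 0.5   # 1 = most tolerant; scales e_act downward
    chlorophyll_level: float = 1.0  # in (0, 1]; scales red absorption

    def __post_init__(self):
        if self.species not in {"barley", "maize", "soybean", "wheat", "arabidopsis"}:
            raise ConfigurationError(f"unknown species {self.species!r}")
        if not 0.0 <= self.cold_tolerance <= 1.0:
            raise ConfigurationError("cold_tolerance must be in [0, 1]")
        if not 0.0 < self.chlorophyll_level <= 1.0:
            raise ConfigurationError("chlorophyll_level must be in (0, 1]")


#: soybean panel: cold-tolerant (Amarok, Gallec, Tourmaline) vs cold-sensitive
#: genotypes, plus the chlorophyll-deficient MinnGold mutant.  Tolerance and
#: chlorophyll magnitudes are the generator's own calibration.
SOYBEAN_GENOTYPES = {
    "Amarok": GenotypeProfile("Amarok", "soybean", cold_tolerance=0.85),
    "Gallec": GenotypeProfile("Gallec", "soybean", cold_tolerance=0.70),
    "Tourmaline": GenotypeProfile("Tourmaline", "soybean", cold_tolerance=0.70),
    "22216": GenotypeProfile("22216", "soybean", cold_tolerance=0.15),
    "S1": GenotypeProfile("S1", "soybean", cold_tolerance=0.10),
    "Protibus": GenotypeProfile("Protibus", "soybean", cold_tolerance=0.20),
    "Bahia": GenotypeProfile("Bahia", "soybean", cold_tolerance=0.40),
    "Eiko": GenotypeProfile("Eiko", "soybean", cold_tolerance=0.40),
    "MinnGold": GenotypeProfile("MinnGold", "soybean", cold_tolerance=0.35,
                                chlorophyll_level=0.45),
}


@dataclass(frozen=True)
class PlotSpec:
    plot_id: str
    profile: GenotypeProfile
    replicate: int = 1


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions of a synthetic campaign."""

    n_days: int = 14
    plots: Sequence[PlotSpec] = ()
    scans_per_day: int = 24          # hourly scan rounds
    measurements_per_scan: int = 6   # 5-7 combined measurements per scan line
    seed: int = 0
    noise_sd_rel: float = 0.02       # Gaussian yield noise relative to Fm'
    leaf_angle_sd: float = 0.25      # lognormal sigma of amplitude scaling
    soil_hit_rate: float = 0.03      # probability a spectrum targets soil
    start_date: dt.date = dt.date(2017, 4, 1)
    sowing_date: dt.date = dt.date(2017, 3, 18)
    # climate envelope: seasonal mean ramp plus diurnal amplitude
    t_mean_start: float = 9.0
    t_mean_end: float = 29.0
    t_diurnal_amp: float = 7.5
    ppfd_max: float = 1800.0
    bg_per_ppfd: float = 0.12        # detector background DN per umol m-2 s-1
    kinetics: KineticParams = DEFAULT_KINETICS

    def __post_init__(self):
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.measurements_per_scan not in (5, 6, 7):
            raise ConfigurationError("measurements_per_scan must be 5, 6 or 7")
        if not 1 <= self.scans_per_day <= 24:
            raise ConfigurationError("scans_per_day must be in [1, 24]")
        for bad in ("noise_sd_rel", "leaf_angle_sd", "soil_hit_rate"):
            if getattr(self, bad) < 0:
                raise ConfigurationError(f"{bad} must be >= 0")


def demo_config(seed: int = 0, n_days: int = 14) -> CampaignConfig:
    """Two-genotype (cold-tolerant vs cold-sensitive), four-plot demo campaign."""
    plots = [
        PlotSpec("P01", SOYBEAN_GENOTYPES["Amarok"], 1),
        PlotSpec("P02", SOYBEAN_GENOTYPES["Amarok"], 2),
        PlotSpec("P03", SOYBEAN_GENOTYPES["S1"], 1),
        PlotSpec("P04", SOYBEAN_GENOTYPES["S1"], 2),
    ]
    return CampaignConfig(n_days=n_days, plots=plots, seed=seed)


# ---------------------------------------------------------------------------
# environment


def _ar1(rng: np.random.Generator, n: int, phi: float, innov_sd: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, innov_sd, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def diurnal_temperature(hour: np.ndarray, mean: np.ndarray, amp: float) -> np.ndarray:
    """Piecewise-cosine diurnal course: minimum at 05:00, maximum at 14:00."""
    hour = np.asarray(hour, dtype=float)
    rising = (hour >= 5.0) & (hour <= 14.0)
    t_rise = mean - amp * np.cos(np.pi * (hour - 5.0) / 9.0)
    t_fall = mean + amp * np.cos(np.pi * ((hour - 14.0) % 24.0) / 15.0)
    return np.where(rising, t_rise, t_fall)


def generate_environment(config: CampaignConfig) -> pd.DataFrame:
    """Minute-resolution PPFD / temperature / RH series for the campaign.

    PPFD is zero at night and follows a smooth solar arc modulated by seeded
    cloud flecks; temperature follows a diurnal piecewise-cosine course on a
    linear seasonal ramp; RH is anti-correlated with temperature, in [20, 100].
    """
    if config.n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_days * 1440
    idx = pd.date_range(pd.Timestamp(config.start_date), periods=n, freq="min")
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    day = np.repeat(np.arange(config.n_days), 1440)

    elev = np.sin(np.pi * (hour - 6.0) / 14.0)
    elev = np.where((hour >= 6.0) & (hour <= 20.0), np.clip(elev, 0.0, None), 0.0)
    cloud = 0.3 + 0.7 * expit(_ar1(rng, n, 0.997, 0.05) * 3.0)
    ppfd = config.ppfd_max * elev ** 1.3 * cloud

    if config.n_days > 1:
        seasonal = config.t_mean_start + (
            (config.t_mean_end - config.t_mean_start) * day / (config.n_days - 1)
        )
    else:
        seasonal = np.full(n, config.t_mean_start)
    temperature = diurnal_temperature(hour, seasonal, config.t_diurnal_amp)
    temperature = temperature + _ar1(rng, n, 0.99, 0.03)

    rh = 88.0 - 2.0 * (temperature - 10.0) + _ar1(rng, n, 0.99, 0.3)
    rh = np.clip(rh, 20.0, 100.0)

    return pd.DataFrame(
        {"timestamp": idx, "ppfd": ppfd, "temperature": temperature, "rh": rh}
    )


# ---------------------------------------------------------------------------
# transient simulation


def scaled_taus(kin: KineticParams, temperature: float, cold_tolerance: float = 0.0
                ) -> np.ndarray:
    """Arrhenius-scaled time constants at ``temperature`` (deg C).

    Cold tolerance lowers the effective activation energy:
    ``e_eff = e_act * (1 - cold_tolerance)``, so tolerant genotypes keep fast
    relaxation in the cold.
    """
    e_eff = kin.e_act * (1.0 - cold_tolerance)
    t_k = temperature + 273.15
    t_ref_k = kin.t_ref + 273.15
    factor = np.exp((e_eff / R_GAS) * (1.0 / t_k - 1.0 / t_ref_k))
    return kin.taus * factor


def npq_at(kin: KineticParams, ppfd: float) -> float:
    """Stern-Volmer NPQ with hyperbolic light dependence."""
    if ppfd <= 0:
        return 0.0
    return kin.npq_max * ppfd / (ppfd + kin.k_npq)


def simulate_transient(
    kin: KineticParams,
    temperature: float,
    ppfd: float,
    schedule: FlashSchedule,
    amplitude_scale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    *,
    cold_tolerance: float = 0.0,
    noise_sd_rel: float = 0.0,
    bg_per_ppfd: float = 0.12,
    ambient_ppfd: Optional[float] = None,
    **meta,
) -> TransientTrace:
    """Simulate one flashlet transient.

    Induction closes reaction centers per flashlet with probability
    ``sigma_abs`` (single-hit Poisson, no connectivity); relaxation reopens
    them as a three-exponential mixture with Arrhenius-scaled time constants.
    Yields are ``scale * (F0' + (Fm' - F0') * q)`` plus the ambient background
    channel and additive Gaussian noise; ``Fm' = fm_dark / (1 + NPQ)`` while
    F0' is left unquenched.

    ``ppfd`` is the light level experienced by the measured leaf;
    ``ambient_ppfd`` (default: same) is the station-level value recorded with
    the trace and used for dark/light classification.
    """
    for name, v in (("temperature", temperature), ("ppfd", ppfd),
                    ("amplitude_scale", amplitude_scale)):
        if not np.isfinite(v):
            raise SimulationError(f"non-finite {name}")
    if not -10.0 <= temperature <= 45.0:
        raise SimulationError(f"temperature {temperature} outside [-10, 45] C")
    if ppfd < 0:
        raise SimulationError("ppfd must be >= 0")

    amb = ppfd if ambient_ppfd is None else float(ambient_ppfd)
    npq = npq_at(kin, ppfd)
    fm_p = kin.fm_dark / (1.0 + npq)
    f0_p = kin.f0_dark

    n_ind = schedule.n_induction
    k = np.arange(n_ind)
    q_ind = 1.0 - (1.0 - kin.sigma_abs) ** k
    q_end = 1.0 - (1.0 - kin.sigma_abs) ** n_ind

    taus = scaled_taus(kin, temperature, cold_tolerance)
    dt_rel = schedule.relaxation_times - schedule.induction_end
    decay = np.sum(kin.amps[:, None] * np.exp(-dt_rel[None, :] / taus[:, None]), axis=0)
    q = np.concatenate([q_ind, q_end * decay])

    signal = amplitude_scale * (f0_p + (fm_p - f0_p) * q)
    bg_mean = bg_per_ppfd * amb
    bg_sd = noise_sd_rel * kin.fm_dark * (0.15 + amb / 20000.0)

    n = len(schedule)
    if rng is not None and noise_sd_rel > 0:
        yield_sd = noise_sd_rel * amplitude_scale * fm_p
        yields = signal + bg_mean + rng.normal(0.0, np.hypot(yield_sd, bg_sd), n)
        background = np.clip(bg_mean + rng.normal(0.0, bg_sd, n), 0.0, None)
    else:
        yields = signal + bg_mean
        background = np.full(n, bg_mean)

    return TransientTrace(
        schedule=schedule,
        yields=yields,
        background=background,
        adaptation_state="dark" if amb < DARK_PPFD_THRESHOLD else "light",
        ambient_ppfd=amb,
        **meta,
    )


# ---------------------------------------------------------------------------
# spectra


def vegetation_reflectance(profile: GenotypeProfile, npq_state: float = 0.0
                           ) -> np.ndarray:
    """True canopy reflectance on the 2-nm grid.

    Green bump near 550 nm, chlorophyll red trough near 680 nm (shallower for
    chlorophyll-deficient genotypes), logistic red edge to an NIR plateau, and
    a 531-nm dip that deepens with the quenching state (the PRI response).
    """
    wl = WL_GRID
    red_edge = expit((wl - 715.0) / 12.0)
    vis = (
        0.04
        + 0.06 * np.exp(-(((wl - 550.0) / 22.0) ** 2))
        + 0.10 * (1.0 - profile.chlorophyll_level) * np.exp(-(((wl - 678.0) / 35.0) ** 2))
        - 0.04 * npq_state * np.exp(-(((wl - 531.0) / 10.0) ** 2))
    )
    r = 0.45 * red_edge + np.clip(vis, 0.005, None) * (1.0 - red_edge)
    return r


def soil_reflectance() -> np.ndarray:
    """Flat, featureless soil spectrum (spectral outlier)."""
    return 0.15 + 0.0003 * (WL_GRID - 400.0)


_IRRADIANCE_SHAPE = np.exp(-(((WL_GRID - 580.0) / 180.0) ** 2))
DARK_CURRENT_DN = 120.0
# gain and shot-noise factor sized for a ~1.8 s integration: per-band relative
# noise stays around 1% over the LUT's PPFD range
DETECTOR_GAIN = 20.0
_SHOT_NOISE_FACTOR = 0.4


def simulate_spectrum(
    profile: GenotypeProfile,
    ppfd: float,
    npq_state: float = 0.0,
    amplitude_scale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    *,
    target: str = "canopy",
    soil: bool = False,
) -> np.ndarray:
    """Raw digital-number spectrum on the 400-800 nm 2-nm grid.

    ``target`` selects the reflector: "canopy" (vegetation or soil outlier),
    "gray_reference" (50 % panel), or "dark" (shutter closed).  At ppfd = 0
    the output is the dark-current offset plus read noise.
    """
    if ppfd < 0:
        raise SimulationError("ppfd must be >= 0")
    if target == "dark" or ppfd == 0.0:
        signal = np.zeros_like(WL_GRID)
    else:
        if target == "gray_reference":
            refl = np.full_like(WL_GRID, 0.5)
        elif soil:
            refl = soil_reflectance()
        else:
            refl = vegetation_reflectance(profile, npq_state)
        signal = ppfd * _IRRADIANCE_SHAPE * refl * DETECTOR_GAIN * amplitude_scale
    dn = signal + DARK_CURRENT_DN
    if rng is not None:
        sd = _SHOT_NOISE_FACTOR * np.sqrt(np.clip(signal, 0.0, None)) + 2.0
        dn = dn + rng.normal(0.0, sd)
    return dn


# ---------------------------------------------------------------------------
# campaign assembly


@dataclass
class CampaignBundle:
    """All tables of one synthetic campaign."""

    transients: pd.DataFrame
    spectra: pd.DataFrame
    references: pd.DataFrame
    env: Optional[pd.DataFrame]
    plots: Optional[pd.DataFrame]
    schedule: FlashSchedule
    config: Optional[CampaignConfig]


def _scan_hours(scans_per_day: int) -> list[int]:
    return sorted({int(round(h)) for h in np.linspace(0, 23, scans_per_day)})


def generate_campaign(config: CampaignConfig) -> CampaignBundle:
    """Generate a full campaign bundle (see module docstring).

    Every scan produces ``measurements_per_scan`` paired (transient, spectrum)
    records 2 s apart on one scan line; nightly dark scans and hourly
    gray-panel scans populate the references table.
    """
    if not config.plots:
        raise ConfigurationError("campaign needs at least one plot")
    env = generate_environment(config)
    env_lookup = env.set_index("timestamp")
    schedule = generate_flash_schedule()
    rng = np.random.default_rng([config.seed, 202])
    kin = config.kinetics
    start = pd.Timestamp(config.start_date)
    hours = _scan_hours(config.scans_per_day)

    transient_rows: list[dict] = []
    spectra_rows: list[dict] = []
    reference_rows: list[dict] = []
    t_counter = s_counter = 0
    line_index = 0

    def env_at(ts: pd.Timestamp) -> tuple[float, float]:
        row = env_lookup.loc[ts.floor("min")]
        return float(row["ppfd"]), float(row["temperature"])

    dn_cols = [f"dn_{int(w)}" for w in WL_GRID]

    for day in range(config.n_days):
        day_start = start + pd.Timedelta(days=day)

        # nightly dark-current scan at 02:10
        ts_dark = day_start + pd.Timedelta(hours=2, minutes=10)
        dn = simulate_spectrum(next(iter(SOYBEAN_GENOTYPES.values())), 0.0,
                               rng=rng, target="dark")
        reference_rows.append({"timestamp": ts_dark, "target": "dark", "ppfd": 0.0,
                               **dict(zip(dn_cols, dn))})

        for hour in hours:
            # hourly gray-panel scan at minute 30
            ts_gray = day_start + pd.Timedelta(hours=hour, minutes=30)
            g_ppfd, _ = env_at(ts_gray)
            dn = simulate_spectrum(next(iter(SOYBEAN_GENOTYPES.values())), g_ppfd,
                                   rng=rng, target="gray_reference")
            reference_rows.append({"timestamp": ts_gray, "target": "gray_reference",
                                   "ppfd": g_ppfd, **dict(zip(dn_cols, dn))})

            for p_idx, plot in enumerate(config.plots):
                line_index += 1
                profile = plot.profile
                for m in range(config.measurements_per_scan):
                    t_sec = hour * 3600 + p_idx * 30 + m * 2
                    ts_f = day_start + pd.Timedelta(seconds=t_sec)
                    ppfd, temp = env_at(ts_f)

                    penetration = min(1.0, float(np.exp(rng.normal(-0.3, 0.35))))
                    ppfd_leaf = ppfd * penetration
                    scale = float(np.exp(rng.normal(0.0, config.leaf_angle_sd)))

                    t_counter += 1
                    mid = f"T{t_counter:06d}"
                    trace = simulate_transient(
                        kin, temp, ppfd_leaf, schedule, scale, rng,
                        cold_tolerance=profile.cold_tolerance,
                        noise_sd_rel=config.noise_sd_rel,
                        bg_per_ppfd=config.bg_per_ppfd,
                        ambient_ppfd=ppfd,
                    )
                    transient_rows.append({
                        "measurement_id": mid,
                        "timestamp": ts_f.floor("min"),
                        "plot_id": plot.plot_id,
                        "species": profile.species,
                        "genotype": profile.name,
                        "line_index": line_index,
                        "position_in_line": m + 1,
                        "seq": 2 * m,
                        "adaptation_state": trace.adaptation_state,
                        "ambient_ppfd": ppfd,
                        "sim_temperature": temp,
                        "sim_ppfd_leaf": ppfd_leaf,
                        "sim_scale": scale,
                        "yields": trace.yields,
                        "background": trace.background,
                    })

                    s_counter += 1
                    npq_state = npq_at(kin, ppfd_leaf) / kin.npq_max
                    soil = bool(rng.random() < config.soil_hit_rate)
                    dn = simulate_spectrum(profile, ppfd, npq_state, scale, rng,
                                           soil=soil)
                    spectra_rows.append({
                        "spectrum_id": f"S{s_counter:06d}",
                        "timestamp": (ts_f + pd.Timedelta(seconds=1)).floor("min"),
                        "plot_id": plot.plot_id,
                        "species": profile.species,
                        "genotype": profile.name,
                        "line_index": line_index,
                        "position_in_line": m + 1,
                        "seq": 2 * m + 1,
                        "target": "canopy",
                        "sim_soil": soil,
                        "sim_npq_state": npq_state,
                        **dict(zip(dn_cols, dn)),
                    })

    plots = pd.DataFrame(
        [{"plot_id": p.plot_id, "genotype": p.profile.name,
          "species": p.profile.species, "replicate": p.replicate,
          "cold_tolerance": p.profile.cold_tolerance,
          "chlorophyll_level": p.profile.chlorophyll_level,
          "sowing_date": config.sowing_date}
         for p in config.plots]
    )
    return CampaignBundle(
        transients=pd.DataFrame(transient_rows),
        spectra=pd.DataFrame(spectra_rows),
        references=pd.DataFrame(reference_rows),
        env=env,
        plots=plots,
        schedule=schedule,
        config=config,
    )
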