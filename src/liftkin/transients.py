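"""Fluorescence statistics from raw flashlet transients.

A transient is processed into the standard PSII efficiency parameters and the
electron-transport (Q_A- reoxidation) area-ratio statistics:

* ``F_o`` — yield of the first flashlet (``F'`` in the light-adapted state);
* ``F_m`` — mean yield of the 301st and 302nd flashlets, i.e. the first two
  relaxation flashlets (the 300th is quenched and never used);
* ``F_v = F_m - F_o`` and ``F_v/F_m`` (``F_q'/F_m'`` in the light);
* ``F_r1/F_v`` and ``F_r2/F_v`` — the area between F_m and the relaxation
  curve, integrated over the windows [0.8, 1.47] ms and [0.8, 5.9] ms and
  normalized by the F_v area of that window.  Values near 1 mean complete
  relaxation within the window, i.e. efficient reoxidation.

Flashlet ordinals are 1-based in the definitions above; window times are
measured from the first excitation flashlet, so both windows sit inside the
relaxation phase that starts at 0.75 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTraceError,
    InsufficientSamplesError,
    MalformedTraceError,
)
from .schedule import FlashSchedule

#: ambient PPFD (umol photons m-2 s-1) below which a sample counts as dark-adapted
DARK_PPFD_THRESHOLD = 5.0


@dataclass(frozen=True)
class RelaxationWindow:
    """Integration window for a reoxidation statistic, in ms."""

    t_start: float
    t_end: float
    label: str = ""

    def __post_init__(self):
        if not (0.0 < self.t_start < self.t_end):
            raise ValueError("require 0 < t_start < t_end")

    @property
    def width(self) -> float:
        return self.t_end - self.t_start


#: window for F_r1/F_v — first exponential decay phase
W1 = RelaxationWindow(0.8, 1.47, "W1")
#: window for F_r2/F_v — through the second decay phase
W2 = RelaxationWindow(0.8, 5.9, "W2")


@dataclass
class TransientTrace:
    """One FRR measurement: flashlet yields plus acquisition metadata."""

    schedule: FlashSchedule
    yields: np.ndarray
    background: np.ndarray  # per-flashlet ambient signal estimate, same units
    adaptation_state: str = "dark"  # "dark" | "light"
    ambient_ppfd: float = 0.0
    timestamp: Optional[pd.Timestamp] = None
    plot_id: Optional[str] = None
    species: Optional[str] = None
    genotype: Optional[str] = None
    line_index: Optional[int] = None
    position_in_line: Optional[int] = None
    measurement_id: Optional[str] = None

    def __post_init__(self):
        self.yields = np.asarray(self.yields, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim == 0:
            bg = np.full(len(self.yields), float(bg))
        self.background = bg
        if len(self.yields) != len(self.schedule):
            raise MalformedTraceError(
                f"{len(self.yields)} yields for a {len(self.schedule)}-flashlet schedule"
            )
        if len(self.background) != len(self.yields):
            raise MalformedTraceError("background length does not match yields")
        if self.ambient_ppfd < 0:
            raise MalformedTraceError("ambient_ppfd must be >= 0")


@dataclass(frozen=True)
class FluorescenceParams:
    """Derived statistics for one trace."""

    fo: float
    fm: float
    fv: float
    fvfm: float
    fr1_ratio: float
    fr2_ratio: float
    snr: float
    adaptation_state: str


def subtract_background(trace: TransientTrace) -> TransientTrace:
    """Subtract the per-flashlet background estimate, clipping at zero.

    Idempotent: the returned trace carries a zero background channel (the
    original readings are not needed again downstream of SNR estimation).
    """
    bg = trace.background
    if not np.all(np.isfinite(bg)) or np.any(bg < 0):
        raise MalformedTraceError("background must be finite and >= 0")
    return replace(
        trace,
        yields=np.clip(trace.yields - bg, 0.0, None),
        background=np.zeros_like(bg),
    )


def extract_fo_fm(trace: TransientTrace) -> tuple[float, float]:
    """Return (F_o, F_m): first flashlet, mean of the 301st and 302nd."""
    y = trace.yields
    if len(y) < 302:
        raise MalformedTraceError("need at least 302 flashlets to retrieve F_m")
    fo = float(y[0])
    fm = float(0.5 * (y[300] + y[301]))  # 1-based ordinals 301, 302
    return fo, fm


def compute_psii_efficiency(fo: float, fm: float) -> float:
    """(F_m - F_o) / F_m; equals F_q'/F_m' for light-adapted traces."""
    if fm <= 0:
        raise DegenerateTraceError(f"fm = {fm} <= 0")
    return (fm - fo) / fm


def compute_reoxidation_efficiency(
    trace: TransientTrace, fo: float, fm: float, window: RelaxationWindow
) -> float:
    """Area-ratio reoxidation statistic over ``window``.

    ratio = integral_{t0}^{t1} (fm - F(t)) dt / ((fm - fo) * (t1 - t0))

    The numerator uses the trapezoidal rule on the flashlet samples inside the
    window, with linear interpolation of F at both window edges (exact for
    piecewise-linear transients).
    """
    if fm <= fo:
        raise DegenerateTraceError(f"fm = {fm} <= fo = {fo}")
    t = trace.schedule.times
    y = trace.yields
    if window.t_start < trace.schedule.induction_end or window.t_end > t[-1]:
        raise InsufficientSamplesError(
            f"window [{window.t_start}, {window.t_end}] ms outside relaxation phase"
        )
    inside = (t > window.t_start) & (t < window.t_end)
    if not np.any(inside):
        raise InsufficientSamplesError("no flashlet samples inside window")
    edges = np.interp([window.t_start, window.t_end], t, y)
    tt = np.concatenate([[window.t_start], t[inside], [window.t_end]])
    yy = np.concatenate([[edges[0]], y[inside], [edges[1]]])
    numerator = np.trapezoid(fm - yy, tt)
    return float(numerator / ((fm - fo) * window.width))


def compute_snr(trace: TransientTrace) -> float:
    """Signal-to-noise ratio: F_m over the SD of the background readings.

    A noiseless background (zero SD) returns +inf as a sentinel.
    """
    _, fm = extract_fo_fm(subtract_background(trace))
    sd = float(np.std(trace.background, ddof=1)) if len(trace.background) > 1 else 0.0
    if sd == 0.0:
        return float("inf")
    return fm / sd


def process_transient(
    trace: TransientTrace,
    w1: RelaxationWindow = W1,
    w2: RelaxationWindow = W2,
) -> FluorescenceParams:
    """Full per-trace pipeline: background subtraction through SNR."""
    snr = compute_snr(trace)
    sub = subtract_background(trace)
    fo, fm = extract_fo_fm(sub)
    if fm <= fo:
        raise DegenerateTraceError("no variable fluorescence (fm <= fo)")
    fvfm = compute_psii_efficiency(fo, fm)
    fr1 = compute_reoxidation_efficiency(sub, fo, fm, w1)
    fr2 = compute_reoxidation_efficiency(sub, fo, fm, w2)
    return FluorescenceParams(
        fo=fo, fm=fm, fv=fm - fo, fvfm=fvfm,
        fr1_ratio=fr1, fr2_ratio=fr2, snr=snr,
        adaptation_state=trace.adaptation_state,
    )


_META_COLUMNS = [
    "measurement_id", "timestamp", "plot_id", "species", "genotype",
    "line_index", "position_in_line", "adaptation_state", "ambient_ppfd",
]


def trace_from_row(row: pd.Series, schedule: FlashSchedule) -> TransientTrace:
    """Rebuild a TransientTrace from one row of a transients table."""
    return TransientTrace(
        schedule=schedule,
        yields=np.asarray(row["yields"], dtype=float),
        background=np.asarray(row["background"], dtype=float),
        adaptation_state=row.get("adaptation_state", "dark"),
        ambient_ppfd=float(row.get("ambient_ppfd", 0.0)),
        timestamp=row.get("timestamp"),
        plot_id=row.get("plot_id"),
        species=row.get("species"),
        genotype=row.get("genotype"),
        line_index=row.get("line_index"),
        position_in_line=row.get("position_in_line"),
        measurement_id=row.get("measurement_id"),
    )


def process_table(
    transients: pd.DataFrame, schedule: FlashSchedule
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every row of a transients table, order-preserving.

    Returns ``(params, failures)``: one parameter row per successfully
    processed trace, and a log of traces that raised (degenerate, malformed),
    with the error class and message.
    """
    records, failures = [], []
    for _, row in transients.iterrows():
        meta = {c: row.get(c) for c in _META_COLUMNS if c in transients.columns}
        try:
            p = process_transient(trace_from_row(row, schedule))
        except Exception as exc:  # noqa: BLE001 - logged, not swallowed silently
            failures.append({**meta, "error": type(exc).__name__, "message": str(exc)})
            continue
        rec = dict(meta)
        rec.update(
            fo=p.fo, fm=p.fm, fv=p.fv, fvfm=p.fvfm,
            fr1_ratio=p.fr1_ratio, fr2_ratio=p.fr2_ratio, snr=p.snr,
        )
        records.append(rec)
    params = pd.DataFrame(records)
    fail = pd.DataFrame(failures, columns=_META_COLUMNS + ["error", "message"])
    return params, fail
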