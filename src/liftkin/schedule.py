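"""Fast-repetition-rate flashlet timing.

A measurement consists of an excitation (induction) phase of 300 flashlets
packed into 0.75 ms, which cumulatively closes PSII reaction centers, followed
by a relaxation phase of 127 flashlets triggered at decreasing repetition rate
over the next 200 ms, which samples the reopening (Q_A- reoxidation) kinetics.

The instrument's exact relaxation timing profile is not published; this module
uses geometric gap growth starting from the induction spacing, with the growth
ratio solved numerically so the 127 gaps fill exactly 200 ms.  That reproduces
the dense-early / sparse-late sampling required by the 0.8-5.9 ms integration
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

N_INDUCTION = 300
N_RELAXATION = 127
INDUCTION_MS = 0.75
RELAXATION_MS = 200.0


@dataclass(frozen=True)
class FlashSchedule:
    """Strictly increasing flashlet times in ms from the first flashlet."""

    times: np.ndarray
    n_induction: int = N_INDUCTION
    n_relaxation: int = N_RELAXATION

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or len(t) != self.n_induction + self.n_relaxation:
            raise ValueError("schedule length must equal n_induction + n_relaxation")
        if t[0] != 0.0:
            raise ValueError("schedule must start at t = 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("flashlet times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def induction_times(self) -> np.ndarray:
        return self.times[: self.n_induction]

    @property
    def relaxation_times(self) -> np.ndarray:
        return self.times[self.n_induction:]

    @property
    def induction_end(self) -> float:
        """Time of the last excitation flashlet (ms)."""
        return float(self.times[self.n_induction - 1])


def generate_flash_schedule(
    n_induction: int = N_INDUCTION,
    n_relaxation: int = N_RELAXATION,
    induction_ms: float = INDUCTION_MS,
    relaxation_ms: float = RELAXATION_MS,
) -> FlashSchedule:
    """Build the default 427-flashlet schedule.

    Induction flashlets are uniformly spaced on [0, induction_ms]; relaxation
    gaps grow geometrically from the induction spacing and sum exactly to
    ``relaxation_ms``.
    """
    d = induction_ms / (n_induction - 1)
    induction = np.linspace(0.0, induction_ms, n_induction)

    # gaps g_k = d * r^k for k = 1..n_relaxation must sum to relaxation_ms
    def gap_sum(r: float) -> float:
        k = np.arange(1, n_relaxation + 1)
        return d * np.sum(r ** k) - relaxation_ms

    ratio = brentq(gap_sum, 1.0 + 1e-9, 2.0, xtol=1e-14, rtol=1e-15)
    gaps = d * ratio ** np.arange(1, n_relaxation + 1)
    relaxation = induction_ms + np.cumsum(gaps)
    # pin the endpoint exactly despite float accumulation
    relaxation[-1] = induction_ms + relaxation_ms
    return FlashSchedule(np.concatenate([induction, relaxation]),
                         n_induction=n_induction, n_relaxation=n_relaxation)
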