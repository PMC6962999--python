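import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import liftkin as lk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule() -> lk.FlashSchedule:
    return lk.generate_flash_schedule()


@pytest.fixture(scope="session")
def kin() -> lk.KineticParams:
    return lk.DEFAULT_KINETICS


def make_exponential_trace(schedule, fo, fm, taus, amps, scale=1.0):
    """Noiseless trace: saturating induction from fo to fm, then a
    sum-of-exponentials relaxation measured from the induction end."""
    taus = np.atleast_1d(np.asarray(taus, float))
    amps = np.atleast_1d(np.asarray(amps, float))
    t = schedule.times
    n_ind = schedule.n_induction
    q_ind = 1.0 - (1.0 - 0.08) ** np.arange(n_ind)  # ~1 - 1e-11 at the end
    dt = t[n_ind:] - schedule.induction_end
    decay = np.sum(amps[:, None] * np.exp(-dt[None, :] / taus[:, None]), axis=0)
    y = fo + (fm - fo) * np.concatenate([q_ind, decay])
    return lk.TransientTrace(schedule, y * scale, 0.0)


def closed_form_ratio(taus, amps, window) -> float:
    """Analytic area ratio for a sum-of-exponentials relaxation (origin 0.75 ms)."""
    taus = np.atleast_1d(np.asarray(taus, float))
    amps = np.atleast_1d(np.asarray(amps, float))
    a = window.t_start - 0.75
    b = window.t_end - 0.75
    integral = np.sum(amps * taus * (np.exp(-a / taus) - np.exp(-b / taus)))
    return 1.0 - integral / (b - a)


@pytest.fixture(scope="session")
def demo_bundle() -> lk.CampaignBundle:
    """The default two-genotype, four-plot, 14-day campaign (seed 1)."""
    return lk.generate_campaign(lk.demo_config(seed=1))


@pytest.fixture(scope="session")
def demo_params(demo_bundle):
    transients = lk.drop_repeated_position(demo_bundle.transients)
    params, failures = lk.process_table(transients, demo_bundle.schedule)
    assert failures.empty
    return params


@pytest.fixture(scope="session")
def demo_linked(demo_bundle, demo_params):
    """QC-kept fluorescence parameters with same-minute environment joined."""
    kept, _ = lk.qc_fluorescence(demo_params)
    return lk.link_environment(kept, demo_bundle.env)


@pytest.fixture(scope="session")
def demo_observations(demo_bundle, demo_params):
    transients = lk.drop_repeated_position(demo_bundle.transients)
    spectra = lk.drop_repeated_position(demo_bundle.spectra)
    indices, _ = lk.process_spectra(spectra, demo_bundle.references, demo_bundle.env)
    fluor_kept, _ = lk.qc_fluorescence(demo_params)
    idx_kept, _ = lk.qc_spectral(indices)
    pairs = lk.pair_spectrum_to_transient(spectra, transients)
    return lk.assemble_observations(
        fluor_kept, idx_kept, pairs, demo_bundle.env, demo_bundle.plots)
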