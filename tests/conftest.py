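import numpy as np
import pytest

import dcequant as dq


@pytest.fixture(scope="session")
def ct_schedule():
    return dq.SamplingSchedule.ct_brain()


@pytest.fixture(scope="session")
def mri_schedule():
    return dq.SamplingSchedule.mri_flash()


@pytest.fixture(scope="session")
def acq_ct():
    return dq.AcquisitionParams(dose=60.0)


@pytest.fixture(scope="session")
def acq_mri():
    return dq.AcquisitionParams(dose=15.0)


@pytest.fixture(scope="session")
def ct_aif(acq_ct):
    """CT arterial input function on a dense uniform grid (mgI/mL)."""
    t_fine = np.arange(0.0, 180.05, 0.1)
    return dq.generate_population_aif(dq.aif_ct_preset(acq_ct.dose), t_fine)


@pytest.fixture(scope="session")
def small_phantom():
    return dq.reference_phantom(grid_shape=(16, 16, 6), rng_seed=0)


def riemann_tofts(t_query, aif, ktrans, kep, vb, hct, z_s=0.0, dt=0.01):
    """Brute-force midpoint-Riemann evaluation of the modified Tofts model.

    Independent oracle: direct quadrature of the convolution integral at a
    fine step, no recursion or interpolation of the model curve.
    """
    out = np.empty(len(t_query))
    for i, tq in enumerate(np.asarray(t_query, float)):
        t_eff = tq - z_s
        if t_eff <= 0:
            out[i] = 0.0
            continue
        s = np.arange(0.0, t_eff, dt) + dt / 2.0
        ca = np.interp(s, aif.times_s, aif.conc, left=0.0)
        conv = np.sum(ca * np.exp(-(kep / 60.0) * (t_eff - s))) * dt
        ca_t = np.interp(t_eff, aif.times_s, aif.conc)
        out[i] = (ktrans / 60.0) / (1.0 - hct) * conv + vb * ca_t
    return out
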