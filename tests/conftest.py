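from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cardioswi.metrics import sweep_report
from cardioswi.phantom import PhantomSpec, phantom_rois, simulate_kspace
from cardioswi.recon import hpf_phase, reconstruct, sos_magnitude
from cardioswi.swi import swi_series


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """Study-condition phantom: 192 grid, 12 echoes, 4 coils, noisy."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_flat_coil(default_spec):
    """Noise-free single-coil acquisition for exact roundtrip checks."""
    spec = default_spec.with_(noise_sigma=0.0, n_coils=1)
    return SimpleNamespace(spec=spec, kspace=simulate_kspace(spec))


@pytest.fixture(scope="session")
def pipeline(default_spec):
    """Full reconstruction chain on the default noisy phantom (seed 0)."""
    k = simulate_kspace(default_spec)
    es = reconstruct(k)
    mag = sos_magnitude(es)
    phase, valid = hpf_phase(es)
    rois = phantom_rois(default_spec)
    swi_stacks = {n: swi_series(mag, phase, n_multiplies=n, valid=valid) for n in (3, 6)}
    return SimpleNamespace(
        spec=default_spec,
        kspace=k,
        series=es,
        mag=mag,
        phase=phase,
        valid=valid,
        rois=rois,
        swi3=swi_stacks[3],
        swi6=swi_stacks[6],
    )


@pytest.fixture(scope="session")
def sweep_table(pipeline):
    """Contrast/SDNR for every (source, n_te) on the default phantom."""
    return sweep_report(
        pipeline.mag,
        {"swi3": pipeline.swi3, "swi6": pipeline.swi6},
        pipeline.rois,
        echo_times=pipeline.series.echo_times,
        valid=np.broadcast_to(pipeline.valid, pipeline.mag.shape),
    )
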